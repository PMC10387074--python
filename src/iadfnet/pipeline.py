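"""End-to-end orchestration: simulate or load, then chronology -> climate ->
cluster -> fit -> correlate, writing every artifact to a run directory.

Intermediate CSVs are the contract between stages; each stage can also be
run standalone on files through the CLI.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .chronology import METHODS, build_chronology
from .climate import annual_mean_spei, annual_summaries, spei6, validate_monthly_climate
from .response_analysis import monthly_correlations, select_standardization
from .site_clustering import climate_features, select_k
from .synthetic_data import default_scenario, generate_network
from .tree_ring_io import (
    read_iadf_flags,
    read_rwl,
    read_site_table,
    write_iadf_flags,
    write_rwl,
    write_site_table,
)
from .zaga_gam import GamSpec, build_model_table, cvm_test, effect_summary, fit_zaga_gam, quantile_residuals

__all__ = ["PipelineConfig", "run"]

log = logging.getLogger("iadfnet")


@dataclass
class PipelineConfig:
    """Validated run configuration (see ``PipelineConfig.from_yaml``)."""

    simulate: bool = True
    sites_per_archetype: int = 12
    rwl_path: str | None = None
    flags_path: str | None = None
    sites_path: str | None = None
    climate_path: str | None = None
    period: tuple[int, int] = (1979, 2000)
    method: str = "stabilized"
    k_range: tuple[int, int] = (2, 10)
    response: str = "stabilized"
    weights: str = "none"
    nu_full: bool = False
    seed: int = 42

    def __post_init__(self) -> None:
        if self.period[1] - self.period[0] + 1 < 5:
            raise ValueError("common period must span >= 5 years")
        if self.method not in METHODS:
            raise ValueError(f"unknown standardization method {self.method!r}")
        if not self.simulate:
            missing = [
                k for k in ("rwl_path", "flags_path", "sites_path", "climate_path")
                if getattr(self, k) is None
            ]
            if missing:
                raise ValueError(f"file-based run needs paths: {missing}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "period" in raw:
            raw["period"] = tuple(raw["period"])
        if "k_range" in raw:
            raw["k_range"] = tuple(raw["k_range"])
        return cls(**raw)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            log.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s: done", name)
            return out
        return wrapped
    return deco


def run(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute all stages and write artifacts; returns a result summary dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    log.info("iadfnet %s seed=%d config=%s", __version__, config.seed, config)

    try:
        # --- data ---
        if config.simulate:
            scenario = default_scenario(config.sites_per_archetype, seed=config.seed)
            sites, climates, series = _stage("simulate")(generate_network)(
                scenario, config.seed
            )
            write_rwl(series, out / "network.rwl")
            write_iadf_flags(series, out / "iadf_flags.csv")
            write_site_table(sites, out / "sites.csv")
            climates.to_csv(out / "climate.csv", index=False)
            true_archetypes = {s.site_id: s.archetype for s in scenario.sites}
            (out / "true_archetypes.json").write_text(json.dumps(true_archetypes))
        else:
            def load():
                sites = read_site_table(config.sites_path)
                species_of = {s.site_id: s for s in sites}
                series = read_rwl(config.rwl_path)
                series = read_iadf_flags(config.flags_path, series)
                climates = validate_monthly_climate(pd.read_csv(config.climate_path))
                if "spei6" not in climates.columns:
                    parts = []
                    lat = {s.site_id: s.latitude for s in sites}
                    for sid, grp in climates.groupby("site_id"):
                        parts.append(spei6(grp, config.period, latitude=lat[sid]))
                    climates = pd.concat(parts, ignore_index=True)
                return sites, climates, series
            sites, climates, series = _stage("load")(load)()

        # --- chronologies ---
        def chronologies():
            groups: dict[tuple[str, str], list] = {}
            for s in series:
                groups.setdefault((s.site_id, s.species_code), []).append(s)
            chrons = [build_chronology(g) for g in groups.values()]
            frames = []
            for ch in chrons:
                fr = ch.to_frame()
                fr.insert(0, "species", ch.species_code)
                fr.insert(0, "site_id", ch.site_id)
                frames.append(fr)
            pd.concat(frames, ignore_index=True).to_csv(out / "chronologies.csv", index=False)
            return chrons
        chrons = _stage("chronology")(chronologies)()

        # --- climate summaries ---
        def climate_stage():
            ann = annual_summaries(climates)
            if "spei6" in climates.columns:
                ann = ann.merge(annual_mean_spei(climates), on=["site_id", "year"], how="left")
            ann.to_csv(out / "annual_climate.csv", index=False)
            return ann
        annual = _stage("climate")(climate_stage)()

        # --- clustering ---
        def cluster_stage():
            feats, dist = climate_features(sites, climates, config.period)
            model, profile = select_k(sites, dist, range(config.k_range[0], config.k_range[1] + 1))
            model.to_frame().to_csv(out / "clusters.csv", index=False)
            profile.to_csv(out / "silhouette_profile.csv", index=False)
            return model, profile
        cluster_model, sil_profile = _stage("cluster")(cluster_stage)()

        # --- model fit ---
        def fit_stage():
            assignment = {sid: f"c{lbl + 1}" for sid, lbl in cluster_model.assignment.items()}
            table = build_model_table(
                chrons, sites, annual,
                method=config.response, period=config.period,
                cluster_assignment=assignment, weights=config.weights,
            )
            table.frame.to_csv(out / "model_table.csv", index=False)
            fit = fit_zaga_gam(table, GamSpec(nu_full=config.nu_full))
            if fit.nu == 0.0:
                log.warning("no zero responses; nu fixed at 0")
            (out / "zaga_fit.json").write_text(json.dumps(fit.to_json_dict(), indent=2))
            summary = effect_summary(fit)
            summary.to_csv(out / "effect_summary.csv", index=False)
            wide = summary.pivot(index="species", columns="variable", values="sign")
            wide.to_csv(out / "effect_signs.csv")
            res = quantile_residuals(fit, config.seed)
            w2, p = cvm_test(res)
            (out / "residual_diagnostics.json").write_text(
                json.dumps({"cvm_W2": w2, "cvm_p": p, "n": len(res)})
            )
            return fit, summary, (w2, p)
        fit, summary, cvm = _stage("fit")(fit_stage)()

        # --- correlations ---
        def correlate_stage():
            all_rows = []
            selections = []
            for ch in chrons:
                clim_site = climates[climates["site_id"] == ch.site_id]
                sets = {}
                for m in METHODS:
                    if np.isfinite(ch.series(m)).sum() < 5:
                        continue
                    tab = monthly_correlations(ch, m, clim_site, config.period)
                    tab.insert(0, "species", ch.species_code)
                    tab.insert(0, "site_id", ch.site_id)
                    sets[m] = tab
                    all_rows.append(tab)
                if sets:
                    best, _ = select_standardization(sets)
                    selections.append(
                        {"site_id": ch.site_id, "species": ch.species_code, "best_method": best}
                    )
            pd.concat(all_rows, ignore_index=True).to_csv(out / "correlations.csv", index=False)
            sel = pd.DataFrame(selections)
            sel.to_csv(out / "method_selection.csv", index=False)
            return sel
        selections = _stage("correlate")(correlate_stage)()

        result = {
            "n_series": len(series),
            "n_rings": int(sum(len(s) for s in series)),
            "selected_k": cluster_model.k,
            "mean_silhouette": cluster_model.mean_silhouette,
            "r_squared": fit.r_squared,
            "converged": fit.converged,
            "nu": fit.nu,
            "cvm_p": cvm[1],
            "best_method_mode": (
                selections["best_method"].mode().iloc[0] if len(selections) else None
            ),
        }
        (out / "summary.json").write_text(json.dumps(result, indent=2))
        log.info("run complete: %s", result)
        return result
    finally:
        log.removeHandler(handler)
        handler.close()
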