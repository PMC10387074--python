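"""Synthetic tree-ring network generator.

Emulates a European IADF network — sites spread over four climate archetypes,
eleven species, negative-exponential ring-width age trends, and IADF
occurrence driven by ring width (bell-shaped), cambial age (juvenile peak
near 30 years) and site-level climate anomalies with species-specific signs —
so that every downstream stage (chronology building, clustering, the
zero-adjusted gamma model) can be exercised without any external download.

The generative IADF model is a Bernoulli draw per ring with

    logit p = b0 + b_rw1*rw + b_rw2*rw^2 + b_age*max(0, age - 30)
              + b_temp*dT + b_prcp*dP + b_spei*spei

where ``rw`` is ring width (1/100 mm), ``dT``/``dP`` are within-site annual
temperature (degC) and precipitation (per 100 mm) anomalies, and ``spei`` is
the annual mean 6-month SPEI.  ``b_rw2 < 0`` makes the width response
concave; the age effect is a hinge past the juvenile peak — deliberately
simpler than the Weibull curve the estimation side fits, so the detrending
step is tested against a model it does not nest.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .climate import annual_mean_spei, annual_summaries, spei6
from .tree_ring_io import RingSeries, SiteMeta

__all__ = [
    "GrowthParams",
    "IadfLogit",
    "SpeciesParams",
    "ClimateArchetype",
    "SiteSpec",
    "Scenario",
    "DEFAULT_SPECIES",
    "ARCHETYPES",
    "default_scenario",
    "generate_climate",
    "generate_ring_widths",
    "iadf_probability",
    "generate_network",
]

LAPSE_RATE = 0.0065  # degC per m; fixed environmental lapse rate
JUVENILE_PEAK_AGE = 30.0  # yr; hinge point of the generative age effect


@dataclass(frozen=True)
class GrowthParams:
    """Ring-width growth model: negative-exponential age curve with
    multiplicative climate modulation and lognormal noise."""

    mean_juvenile_width: float  # 1/100 mm, expected width at age 0
    age_decay_rate: float  # 1/yr
    climate_sensitivity: float  # unitless multiplier on the annual climate score
    noise_sd: float  # log-scale SD

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class IadfLogit:
    """Coefficients of the generative IADF logistic model."""

    b0: float
    b_rw1: float  # per 1/100 mm
    b_rw2: float  # per (1/100 mm)^2, < 0 for a bell shape
    b_age: float  # per yr past the juvenile peak, <= 0
    b_temp: float  # per degC anomaly
    b_prcp: float  # per 100 mm anomaly
    b_spei: float  # per SPEI unit

    def __post_init__(self) -> None:
        if self.b_rw2 >= 0:
            raise ValueError("b_rw2 must be < 0 (bell-shaped width response)")
        peak = -self.b_rw1 / (2.0 * self.b_rw2)
        if not (0 < peak < np.inf):
            raise ValueError("implied peak ring width must be positive and finite")

    @property
    def peak_width(self) -> float:
        """Ring width (1/100 mm) at which the width term is maximal."""
        return -self.b_rw1 / (2.0 * self.b_rw2)


@dataclass(frozen=True)
class SpeciesParams:
    species_code: str
    growth: GrowthParams
    iadf: IadfLogit


@dataclass(frozen=True)
class ClimateArchetype:
    """Monthly climate normals defining one of the four site archetypes."""

    name: str
    monthly_temp_mean: tuple  # 12 values, degC at sea level
    monthly_temp_amplitude_sd: float  # degC, interannual noise per month
    monthly_prcp_mean: tuple  # 12 values, mm
    prcp_dispersion: float  # coefficient of variation of monthly totals
    interannual_trend: float = 0.0  # degC/yr

    def __post_init__(self) -> None:
        if len(self.monthly_temp_mean) != 12 or len(self.monthly_prcp_mean) != 12:
            raise ValueError("12 monthly values required")
        if min(self.monthly_prcp_mean) < 0:
            raise ValueError("monthly precipitation normals must be >= 0")


# Four archetypes spanning humid-Atlantic to continental conditions.  Cluster 4
# is the only one with sub-zero winter normals and a summer precipitation
# maximum; clusters 2 and 3 share hot dry summers but differ in winter.
ARCHETYPES: dict[str, ClimateArchetype] = {
    "cluster1_humid": ClimateArchetype(
        "cluster1_humid",
        (6, 7, 9, 11, 14, 18, 20, 20, 17, 13, 9, 7),
        1.0,
        (110, 95, 85, 90, 80, 55, 30, 40, 70, 120, 130, 120),
        0.45,
    ),
    "cluster2_dry_warm": ClimateArchetype(
        "cluster2_dry_warm",
        (8, 9, 12, 14, 18, 23, 26, 26, 22, 17, 12, 9),
        1.1,
        (55, 50, 45, 45, 40, 20, 8, 10, 30, 60, 65, 60),
        0.6,
    ),
    "cluster3_mild_winter": ClimateArchetype(
        "cluster3_mild_winter",
        (13, 13, 14, 16, 19, 23, 26, 26, 23, 20, 16, 14),
        1.0,
        (120, 105, 80, 60, 40, 15, 5, 8, 40, 110, 140, 130),
        0.6,
    ),
    "cluster4_continental": ClimateArchetype(
        "cluster4_continental",
        (-3, -2, 2, 8, 13, 16, 18, 17, 13, 8, 3, -1),
        1.4,
        (30, 28, 32, 38, 55, 70, 90, 80, 55, 42, 38, 35),
        0.5,
    ),
}


def _gym(code: str, juvenile: float, decay: float, b0: float,
         b_temp: float, b_prcp: float, b_spei: float) -> SpeciesParams:
    # gymnosperm width response peaks at 150 (1/100 mm), inside the 1-2 mm band
    return SpeciesParams(
        code,
        GrowthParams(juvenile, decay, 0.3, 0.3),
        IadfLogit(b0, 0.024, -8.0e-5, -0.02, b_temp, b_prcp, b_spei),
    )


def _ang(code: str, juvenile: float, decay: float, b0: float,
         b_temp: float, b_prcp: float, b_spei: float) -> SpeciesParams:
    # angiosperm width response peaks at 250 (1/100 mm), i.e. in the 2-3 mm band
    return SpeciesParams(
        code,
        GrowthParams(juvenile, decay, 0.3, 0.3),
        IadfLogit(b0, 0.025, -5.0e-5, -0.015, b_temp, b_prcp, b_spei),
    )


# Species-level defaults.  Climate-coefficient signs follow the network-wide
# pattern: temperature positive for most species (not PISY/QUIL/LADE/QURO),
# precipitation negative for ARUN and PIAB, positive (with SPEI) for the
# drought-tolerant bimodal growers PIPI, PIPN and QUIL.  Intercepts are set so
# marginal IADF proportions range from a few percent (montane conifers) to
# roughly half of rings in the most IADF-prone Mediterranean species.
DEFAULT_SPECIES: dict[str, SpeciesParams] = {
    "ARUN": _ang("ARUN", 300, 0.020, -3.58, 1.2, -0.8, 0.0),
    "ERAR": _ang("ERAR", 290, 0.020, -1.69, 1.2, 0.0, 0.0),
    "LADE": _gym("LADE", 260, 0.022, -2.78, 0.0, 0.0, 0.0),
    "PIAB": _gym("PIAB", 270, 0.020, -2.67, 1.2, -0.8, 0.0),
    "PIHA": _gym("PIHA", 230, 0.025, -2.67, 1.2, 0.0, 0.0),
    "PINI": _gym("PINI", 240, 0.022, -3.30, 1.2, 0.0, 0.0),
    "PIPI": _gym("PIPI", 280, 0.024, -1.25, 1.2, 0.6, 0.6),
    "PIPN": _gym("PIPN", 260, 0.024, -2.16, 1.2, 0.6, 0.6),
    "PISY": _gym("PISY", 240, 0.022, -3.50, 0.0, 0.0, 0.0),
    "QUIL": _ang("QUIL", 260, 0.020, -4.62, 0.0, 0.6, 0.6),
    "QURO": _ang("QURO", 310, 0.018, -3.57, 0.0, 0.0, 0.0),
}


@dataclass(frozen=True)
class SiteSpec:
    """One simulated site: where it is, its archetype, and what grows there."""

    site_id: str
    archetype: str
    species_code: str
    latitude: float
    longitude: float
    altitude: float
    country: str = "SIM"
    n_trees: int = 15
    series_length: int = 60
    stagger: int = 10  # max years by which younger trees shorten the series


@dataclass(frozen=True)
class Scenario:
    """A full simulated-network description."""

    sites: tuple
    year_start: int = 1931
    year_end: int = 2000
    species: Mapping[str, SpeciesParams] = field(default_factory=lambda: DEFAULT_SPECIES)
    archetypes: Mapping[str, ClimateArchetype] = field(default_factory=lambda: ARCHETYPES)

    @property
    def years(self) -> range:
        return range(self.year_start, self.year_end + 1)


# Species sets per archetype mirror the network's cluster memberships; PIHA,
# PIPI and PIPN each occur in two archetypes, which keeps species and cluster
# effects jointly identifiable in the downstream regression.
_ARCHETYPE_SPECIES = {
    "cluster1_humid": ("PINI", "PIHA", "PIPI"),
    "cluster2_dry_warm": ("PIHA", "PIPN", "PIPI"),
    "cluster3_mild_winter": ("ARUN", "QUIL", "PIPN"),
    "cluster4_continental": ("PIAB", "PISY", "QURO"),
}

_ARCHETYPE_GEO = {  # (lat range, lon range, alt range, country)
    "cluster1_humid": ((42.0, 46.0), (-8.5, 9.0), (300, 800), "Humidia"),
    "cluster2_dry_warm": ((37.5, 41.5), (-6.0, 0.5), (300, 800), "Aridia"),
    "cluster3_mild_winter": ((35.5, 39.0), (-9.0, 12.0), (0, 250), "Litoralia"),
    "cluster4_continental": ((50.5, 61.5), (15.0, 24.5), (50, 450), "Borealia"),
}


def default_scenario(sites_per_archetype: int = 12, *, seed: int = 0) -> Scenario:
    """The default network: 12 sites per archetype, 3 species each rotating
    across sites, 15 trees per site, 60-year series ending in 2000."""
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x51735)))
    sites = []
    for a_idx, (name, species) in enumerate(_ARCHETYPE_SPECIES.items()):
        (lat0, lat1), (lon0, lon1), (alt0, alt1), country = _ARCHETYPE_GEO[name]
        for j in range(sites_per_archetype):
            sites.append(
                SiteSpec(
                    site_id=f"S{a_idx + 1}{j + 1:02d}",
                    archetype=name,
                    species_code=species[j % len(species)],
                    latitude=round(float(rng.uniform(lat0, lat1)), 3),
                    longitude=round(float(rng.uniform(lon0, lon1)), 3),
                    altitude=round(float(rng.uniform(alt0, alt1))),
                    country=country,
                )
            )
    return Scenario(sites=tuple(sites))


# ---------------------------------------------------------------------------
# Climate generation
# ---------------------------------------------------------------------------


def generate_climate(
    meta: SiteMeta,
    years: Sequence[int] | range,
    archetype: ClimateArchetype,
    seed: int | np.random.SeedSequence,
) -> pd.DataFrame:
    """Monthly tmean/tmin/tmax/prcp for one site.

    Temperatures are the archetype normals minus the lapse-rate offset for
    the site's altitude, plus interannual noise; monthly precipitation totals
    are gamma-distributed around the archetype normals.  Deterministic for a
    fixed seed.
    """
    years = list(years)
    if not years:
        raise ValueError("empty year range")
    rng = np.random.default_rng(seed)
    n = len(years) * 12
    year_col = np.repeat(years, 12)
    month_col = np.tile(np.arange(1, 13), len(years))
    base = np.tile(np.asarray(archetype.monthly_temp_mean, dtype=float), len(years))
    prcp_mean = np.tile(np.asarray(archetype.monthly_prcp_mean, dtype=float), len(years))

    y_mid = 0.5 * (years[0] + years[-1])
    tmean = (
        base
        - LAPSE_RATE * meta.altitude
        + archetype.interannual_trend * (year_col - y_mid)
        + rng.normal(0.0, archetype.monthly_temp_amplitude_sd, n)
    )
    half_range_lo = 3.0 + np.abs(rng.normal(1.5, 0.8, n))
    half_range_hi = 3.0 + np.abs(rng.normal(1.5, 0.8, n))
    cv = archetype.prcp_dispersion
    shape = 1.0 / cv**2
    prcp = np.where(
        prcp_mean > 0, rng.gamma(shape, np.maximum(prcp_mean, 1e-12) * cv**2 / 1.0), 0.0
    )
    return pd.DataFrame(
        {
            "site_id": meta.site_id,
            "year": year_col,
            "month": month_col,
            "tmean": tmean,
            "tmin": tmean - half_range_lo,
            "tmax": tmean + half_range_hi,
            "prcp": prcp,
        }
    )


# ---------------------------------------------------------------------------
# Ring widths
# ---------------------------------------------------------------------------


def _annual_climate_score(climate: pd.DataFrame) -> pd.Series:
    """Standardized annual growth score: mean of z-scored annual temperature
    and precipitation, re-standardized over the site's years."""
    ann = annual_summaries(climate).set_index("year")
    z = ann[["temp", "tp"]].apply(lambda c: (c - c.mean()) / (c.std(ddof=0) or 1.0))
    score = (z["temp"] + z["tp"]) / np.sqrt(2.0)
    sd = score.std(ddof=0)
    return score / (sd if sd > 0 else 1.0)


def generate_ring_widths(
    climate: pd.DataFrame,
    sp: SpeciesParams,
    n_trees: int,
    series_length: int,
    seed: int | np.random.SeedSequence,
    *,
    site_id: str = "",
    stagger: int = 0,
    quantize: bool = False,
) -> list[RingSeries]:
    """Ring-width series for ``n_trees`` trees (IADF flags unset).

    Expected width at cambial age a is ``mean_juvenile_width *
    exp(-age_decay_rate * a)``, modulated multiplicatively by
    ``exp(climate_sensitivity * score_year)`` and lognormal noise.  All trees
    end in the last climate year; with ``stagger > 0`` each tree's length is
    shortened by a uniform 0..stagger years, producing a sample-depth ramp.
    ``quantize`` rounds widths to the 0.01 mm resolution of the Tucson format
    (minimum one unit).
    """
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    rng = np.random.default_rng(seed)
    score = _annual_climate_score(climate)
    last_year = int(climate["year"].max())
    g = sp.growth
    out: list[RingSeries] = []
    for t in range(n_trees):
        cut = int(rng.integers(0, stagger + 1)) if stagger > 0 else 0
        length = max(series_length - cut, 5)
        first_year = last_year - length + 1
        ages = np.arange(1, length + 1, dtype=float)
        years = np.arange(first_year, last_year + 1)
        s = score.reindex(years).fillna(0.0).to_numpy()
        mu = g.mean_juvenile_width * np.exp(-g.age_decay_rate * ages)
        w = mu * np.exp(g.climate_sensitivity * s) * np.exp(rng.normal(0.0, g.noise_sd, length))
        if quantize:
            w = np.maximum(np.round(w), 1.0)
        tree_id = f"{site_id}{sp.species_code[:2]}{t + 1:02d}" if site_id else f"T{t + 1:03d}"
        out.append(
            RingSeries(
                core_id=tree_id[:8],
                tree_id=tree_id[:8],
                site_id=site_id,
                species_code=sp.species_code,
                first_year=first_year,
                widths=w,
            )
        )
    return out


# ---------------------------------------------------------------------------
# IADF occurrence
# ---------------------------------------------------------------------------


def iadf_probability(rw, cambial_age, temp, prcp, spei, sp: SpeciesParams):
    """Per-ring IADF probability under the generative logistic model.

    ``rw`` in 1/100 mm, ``cambial_age`` in years, ``temp`` in degC anomaly,
    ``prcp`` in 100 mm anomaly, ``spei`` unitless.
    """
    b = sp.iadf
    rw = np.asarray(rw, dtype=float)
    eta = (
        b.b0
        + b.b_rw1 * rw
        + b.b_rw2 * rw**2
        + b.b_age * np.maximum(0.0, np.asarray(cambial_age, dtype=float) - JUVENILE_PEAK_AGE)
        + b.b_temp * np.asarray(temp, dtype=float)
        + b.b_prcp * np.asarray(prcp, dtype=float)
        + b.b_spei * np.asarray(spei, dtype=float)
    )
    p = 1.0 / (1.0 + np.exp(-eta))
    return p if p.ndim else float(p)


# ---------------------------------------------------------------------------
# Whole-network generation
# ---------------------------------------------------------------------------


def generate_network(
    scenario: Scenario, seed: int
) -> tuple[list[SiteMeta], pd.DataFrame, list[RingSeries]]:
    """Simulate the full network: site metadata, monthly climate (with SPEI-6
    appended), and flagged ring-width series.  Bit-identical for a fixed seed.

    The climate anomalies driving IADF occurrence are within-site annual
    anomalies (temperature in degC, precipitation per 100 mm) plus the annual
    mean SPEI, so species effects and site effects stay separable.
    """
    for s in scenario.sites:
        if s.species_code not in scenario.species:
            raise ValueError(f"no SpeciesParams for species {s.species_code!r}")
        if s.archetype not in scenario.archetypes:
            raise ValueError(f"unknown archetype {s.archetype!r}")

    root = np.random.SeedSequence(seed)
    site_seeds = root.spawn(len(scenario.sites))
    sites: list[SiteMeta] = []
    clim_frames: list[pd.DataFrame] = []
    all_series: list[RingSeries] = []

    cal = (scenario.year_start, scenario.year_end)
    for spec_site, sseq in zip(scenario.sites, site_seeds):
        meta = SiteMeta(
            spec_site.site_id,
            spec_site.latitude,
            spec_site.longitude,
            spec_site.altitude,
            spec_site.country,
            frozenset({spec_site.species_code}),
        )
        sites.append(meta)
        clim_seed, growth_seed, flag_seed = sseq.spawn(3)
        clim = generate_climate(
            meta, scenario.years, scenario.archetypes[spec_site.archetype], clim_seed
        )
        clim = spei6(clim, cal, latitude=meta.latitude)
        clim_frames.append(clim)

        ann = annual_summaries(clim).set_index("year")
        temp_anom = (ann["temp"] - ann["temp"].mean()).to_dict()
        prcp_anom = ((ann["tp"] - ann["tp"].mean()) / 100.0).to_dict()
        sp_ann = annual_mean_spei(clim).set_index("year")["spei"].to_dict()

        sp = scenario.species[spec_site.species_code]
        series = generate_ring_widths(
            clim,
            sp,
            spec_site.n_trees,
            spec_site.series_length,
            growth_seed,
            site_id=spec_site.site_id,
            stagger=spec_site.stagger,
            quantize=True,
        )
        frng = np.random.default_rng(flag_seed)
        for s in series:
            years = s.years
            p = iadf_probability(
                s.widths,
                s.cambial_ages,
                np.array([temp_anom.get(int(y), 0.0) for y in years]),
                np.array([prcp_anom.get(int(y), 0.0) for y in years]),
                np.array([sp_ann.get(int(y), 0.0) for y in years]),
                sp,
            )
            flags = (frng.uniform(size=len(p)) < p).astype(int)
            all_series.append(s.with_flags(flags))

    climates = pd.concat(clim_frames, ignore_index=True)
    return sites, climates, all_series
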