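"""IADF frequency chronologies and their four standardization variants.

For each site x species group and calendar year, ``N`` counts cores whose
ring carries an IADF and ``n`` counts cores whose ring is readable (missing
flags contribute to neither: an unreadable ring is not evidence of absence).
Four response variants are derived:

``F``             relative frequency N/n
``f_stab``        stabilized frequency F * sqrt(n), damping the variance
                  inflation of years with shallow sample depth
``f_age_detr``    residual of F from a 3-parameter Weibull-peak curve in the
                  mean cambial age of the contributing rings
``f_rw_detr``     residual of F from a 3-parameter Chapman-Richards curve in
                  the mean ring width

Detrending is by subtraction rather than division because F can be exactly 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .tree_ring_io import MISSING_FLAG, RingSeries

__all__ = [
    "FrequencyChronology",
    "DetrendFit",
    "relative_frequency",
    "stabilized_frequency",
    "weibull_peak",
    "chapman_richards",
    "fit_detrend_curve",
    "detrended_frequency",
    "build_chronology",
    "METHODS",
]

METHODS = ("F", "stabilized", "age_detrended", "rw_detrended")
_METHOD_COLUMN = {
    "F": "F",
    "stabilized": "f_stab",
    "age_detrended": "f_age_detr",
    "rw_detrended": "f_rw_detr",
}


def relative_frequency(N, n):
    """Relative IADF frequency F = N/n; NaN (flagged missing) where n == 0."""
    N = np.asarray(N, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any((N < 0) | (N > n)):
        raise ValueError("need 0 <= N <= n")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(n > 0, N / np.where(n > 0, n, 1), np.nan)
    return out if out.ndim else float(out)


def stabilized_frequency(F, n):
    """Sample-depth-stabilized frequency f = F * sqrt(n)."""
    F = np.asarray(F, dtype=float)
    n = np.asarray(n, dtype=float)
    out = F * np.sqrt(n)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Detrending curves
# ---------------------------------------------------------------------------


def weibull_peak(x, A, b, c):
    """Three-parameter Weibull-type peak curve A*(x/b)**(c-1)*exp(-(x/b)**c).

    Rises to a single interior maximum and decays — the shape of the juvenile
    peak in IADF frequency versus cambial age.
    """
    x = np.asarray(x, dtype=float)
    with np.errstate(over="ignore", invalid="ignore"):
        u = x / b
        return A * u ** (c - 1.0) * np.exp(-(u**c))


def chapman_richards(x, a, b, c):
    """Chapman-Richards saturating curve a*(1 - exp(-b*x))**c."""
    x = np.asarray(x, dtype=float)
    with np.errstate(over="ignore", invalid="ignore"):
        return a * (1.0 - np.exp(-b * x)) ** c


_FAMILIES = {"weibull3": weibull_peak, "chapman3": chapman_richards}


@dataclass
class DetrendFit:
    """A fitted 3-parameter detrending curve."""

    family: Literal["weibull3", "chapman3"]
    params: tuple[float, float, float]
    predictor: Literal["age", "ring_width"]
    sse: float
    converged: bool

    def predict(self, x) -> np.ndarray:
        return _FAMILIES[self.family](np.asarray(x, dtype=float), *self.params)


def _starting_grid(family: str, x: np.ndarray, y: np.ndarray, n_starts: int) -> np.ndarray:
    ymax = max(float(np.nanmax(y)), 1e-6)
    rng = np.random.default_rng(20230729)  # fixed shuffle: fits are deterministic
    if family == "weibull3":
        b_grid = np.geomspace(max(x.min(), 1e-3), x.max(), 6)
        c_grid = np.array([0.8, 1.5, 2.5, 4.0])
        starts = [(ymax, b, c) for b in b_grid for c in c_grid]
    else:
        b_grid = np.geomspace(0.1 / x.max(), 10.0 / max(x.min(), 1e-3), 6)
        c_grid = np.array([0.5, 1.0, 2.0, 4.0])
        starts = [(ymax, b, c) for b in b_grid for c in c_grid]
    starts = np.array(starts)
    rng.shuffle(starts)
    return starts[:n_starts]


def fit_detrend_curve(
    x: Sequence[float],
    y: Sequence[float],
    family: Literal["weibull3", "chapman3"],
    *,
    predictor: Literal["age", "ring_width"] | None = None,
    n_starts: int = 20,
) -> DetrendFit:
    """Least-squares fit of a 3-parameter detrending curve, multi-start.

    Twenty starting points from a coarse log-grid over the parameters (fixed
    shuffle); the best sum of squared errors wins.  The ``converged`` flag is
    honest: it reflects the optimizer's status at the winning start.
    """
    if family not in _FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 10:
        raise ValueError("need >= 10 (x, y) pairs")
    if np.any(x <= 0):
        raise ValueError("predictor values must be > 0")
    if predictor is None:
        predictor = "age" if family == "weibull3" else "ring_width"

    if not np.any(y != 0):
        return DetrendFit(family, (0.0, float(np.median(x)), 1.0), predictor, 0.0, True)

    func = _FAMILIES[family]

    def resid(theta):
        r = func(x, *theta) - y
        return np.where(np.isfinite(r), r, 1e6)

    best = None
    lower = np.array([-np.inf, 1e-8, 1e-3])
    upper = np.array([np.inf, np.inf, np.inf])
    for theta0 in _starting_grid(family, x, y, n_starts):
        try:
            sol = least_squares(
                resid, theta0, bounds=(lower, upper), xtol=1e-14, ftol=1e-14, gtol=1e-14
            )
        except ValueError:
            continue
        sse = float(np.sum(sol.fun**2))
        if best is None or sse < best[0]:
            best = (sse, sol)
    if best is None:
        raise RuntimeError("all optimization starts failed")
    sse, sol = best
    return DetrendFit(family, tuple(float(p) for p in sol.x), predictor, sse, bool(sol.success))


def detrended_frequency(chron: "FrequencyChronology", fit: DetrendFit) -> np.ndarray:
    """Residual series: observed F minus the fitted curve at each year's predictor."""
    if not fit.converged:
        raise ValueError("detrend fit did not converge")
    pred_x = chron.mean_age if fit.predictor == "age" else chron.mean_rw
    resid = chron.F - fit.predict(pred_x)
    return resid


# ---------------------------------------------------------------------------
# Chronology container and builder
# ---------------------------------------------------------------------------


@dataclass
class FrequencyChronology:
    """Per-year IADF counts, sample depth, and the four frequency variants."""

    site_id: str
    species_code: str
    years: np.ndarray
    N: np.ndarray
    n: np.ndarray
    F: np.ndarray
    f_stab: np.ndarray
    f_age_detr: np.ndarray
    f_rw_detr: np.ndarray
    mean_rw: np.ndarray
    mean_age: np.ndarray
    age_fit: DetrendFit | None = None
    rw_fit: DetrendFit | None = None

    def series(self, method: str) -> np.ndarray:
        """The response series selected by standardization method."""
        if method not in _METHOD_COLUMN:
            raise ValueError(f"unknown method {method!r}; one of {METHODS}")
        return getattr(self, _METHOD_COLUMN[method])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": self.years,
                "N": self.N,
                "n": self.n,
                "F": self.F,
                "f_stab": self.f_stab,
                "f_age_detr": self.f_age_detr,
                "f_rw_detr": self.f_rw_detr,
                "mean_rw": self.mean_rw,
                "mean_age": self.mean_age,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def build_chronology(
    series: Sequence[RingSeries],
    *,
    detrend: bool = True,
    min_years_for_detrend: int = 10,
) -> FrequencyChronology:
    """Build the IADF frequency chronology of one site x species group.

    Missing flags are excluded from both N and n.  ``mean_rw`` and
    ``mean_age`` average over all cores with a ring that year (width is
    always measurable even when the IADF flag is not).  When ``detrend`` and
    enough years are available, the age (Weibull) and ring-width (Chapman)
    curves are fitted at chronology level and their residual series filled;
    otherwise the detrended variants are NaN.
    """
    if not series:
        raise ValueError("empty group")
    site_id = series[0].site_id
    species = series[0].species_code
    y0 = min(s.first_year for s in series)
    y1 = max(s.last_year for s in series)
    years = np.arange(y0, y1 + 1)
    n_years = len(years)

    N = np.zeros(n_years, dtype=int)
    n = np.zeros(n_years, dtype=int)
    rw_sum = np.zeros(n_years)
    rw_cnt = np.zeros(n_years, dtype=int)
    age_sum = np.zeros(n_years)

    for s in series:
        sl = slice(s.first_year - y0, s.first_year - y0 + len(s))
        flags = s.iadf_flags
        present = flags != MISSING_FLAG
        N[sl] += flags == 1
        n[sl] += present
        rw_sum[sl] += s.widths
        rw_cnt[sl] += 1
        age_sum[sl] += s.cambial_ages

    F = relative_frequency(N, n)
    f_stab = stabilized_frequency(np.nan_to_num(F, nan=0.0), n)
    f_stab = np.where(n > 0, f_stab, np.nan)
    with np.errstate(invalid="ignore"):
        mean_rw = np.where(rw_cnt > 0, rw_sum / np.maximum(rw_cnt, 1), np.nan)
        mean_age = np.where(rw_cnt > 0, age_sum / np.maximum(rw_cnt, 1), np.nan)

    chron = FrequencyChronology(
        site_id, species, years, N, n, F, f_stab,
        np.full(n_years, np.nan), np.full(n_years, np.nan), mean_rw, mean_age,
    )

    ok = np.isfinite(F)
    if detrend and ok.sum() >= min_years_for_detrend:
        age_fit = fit_detrend_curve(mean_age[ok], F[ok], "weibull3", predictor="age")
        rw_fit = fit_detrend_curve(mean_rw[ok], F[ok], "chapman3", predictor="ring_width")
        if age_fit.converged:
            chron.f_age_detr = detrended_frequency(chron, age_fit)
            chron.age_fit = age_fit
        if rw_fit.converged:
            chron.f_rw_detr = detrended_frequency(chron, rw_fit)
            chron.rw_fit = rw_fit
    return chron
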