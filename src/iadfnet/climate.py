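"""Annual climate summaries and a self-contained SPEI-6 drought index.

Monthly climate lives in a long-format :class:`pandas.DataFrame` (one row per
site, year, month) with columns ``tmean``/``tmin``/``tmax`` in degrees C and
``prcp`` in mm.  The drought index is the standardized precipitation-
evapotranspiration index at a 6-month time scale: the climatic water balance
D = precipitation - potential evapotranspiration is summed over backward
6-month windows, a 3-parameter log-logistic distribution is fitted to each
calendar month's window sums over a calibration period by L-moments, and the
fitted CDF values are mapped through the standard-normal quantile function.
PET uses the Thornthwaite temperature-only formulation, the simplest variant
compatible with monthly-temperature-only inputs.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "validate_monthly_climate",
    "annual_summaries",
    "thornthwaite_pet",
    "spei6",
    "annual_mean_spei",
]

CLIMATE_COLUMNS = ["site_id", "year", "month", "tmean", "tmin", "tmax", "prcp"]

#: Days per month (PET day-count correction; leap days ignored at monthly scale).
_MONTH_DAYS = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31], dtype=float)
#: Mid-month day of year, used for solar declination.
_MID_DOY = np.array([15, 45, 74, 105, 135, 166, 196, 227, 258, 288, 319, 349], dtype=float)


def validate_monthly_climate(clim: pd.DataFrame) -> pd.DataFrame:
    """Check invariants (tmin <= tmean <= tmax, prcp >= 0, complete years)."""
    missing = set(CLIMATE_COLUMNS) - set(clim.columns)
    if missing:
        raise ValueError(f"climate table missing columns: {sorted(missing)}")
    if ((clim["tmin"] > clim["tmean"]) | (clim["tmean"] > clim["tmax"])).any():
        raise ValueError("tmin <= tmean <= tmax violated")
    if (clim["prcp"] < 0).any():
        raise ValueError("negative precipitation")
    return clim


def annual_summaries(clim: pd.DataFrame) -> pd.DataFrame:
    """Mean annual temperature and total annual precipitation per site-year.

    Years with fewer than 12 months are dropped with a warning: an annual
    mean over a partial year would confound the seasonal cycle with the
    interannual signal.
    """
    counts = clim.groupby(["site_id", "year"])["month"].nunique()
    incomplete = counts[counts < 12]
    if len(incomplete):
        warnings.warn(
            f"dropping {len(incomplete)} incomplete site-years from annual summaries",
            stacklevel=2,
        )
    out = (
        clim.groupby(["site_id", "year"])
        .agg(temp=("tmean", "mean"), tp=("prcp", "sum"), n_months=("month", "nunique"))
        .reset_index()
    )
    out = out[out["n_months"] == 12].drop(columns="n_months")
    return out.reset_index(drop=True)


def _day_length_hours(latitude: float, month_idx: np.ndarray) -> np.ndarray:
    """Mean day length (hours) per month from latitude and solar declination."""
    phi = np.deg2rad(latitude)
    delta = 0.4093 * np.sin(2.0 * np.pi * _MID_DOY[month_idx] / 365.0 - 1.405)
    cos_omega = np.clip(-np.tan(phi) * np.tan(delta), -1.0, 1.0)
    omega = np.arccos(cos_omega)
    return 24.0 * omega / np.pi


def thornthwaite_pet(clim: pd.DataFrame, latitude: float) -> pd.Series:
    """Monthly potential evapotranspiration (mm), Thornthwaite formulation.

    The annual heat index is computed per year from that year's positive
    monthly mean temperatures; PET is zero for months with tmean <= 0 and
    follows the high-temperature polynomial above 26.5 degrees C.  The
    uncorrected value is scaled by day length / 12 and month length / 30.

    Returns a Series aligned with ``clim``'s index.
    """
    if not (-65 <= latitude <= 65):
        raise ValueError("latitude outside [-65, 65]")
    pet = pd.Series(0.0, index=clim.index)
    for _, grp in clim.groupby(["site_id", "year"]):
        t = grp["tmean"].to_numpy(dtype=float)
        tpos = np.where(t > 0.0, t, 0.0)
        heat_index = np.sum((tpos / 5.0) ** 1.514)
        if heat_index <= 0:
            continue
        a = (
            6.75e-7 * heat_index**3
            - 7.71e-5 * heat_index**2
            + 1.792e-2 * heat_index
            + 0.49239
        )
        raw = np.where(
            t <= 0.0,
            0.0,
            np.where(
                t < 26.5,
                16.0 * (10.0 * tpos / heat_index) ** a,
                -415.85 + 32.24 * t - 0.43 * t**2,
            ),
        )
        m = grp["month"].to_numpy(dtype=int) - 1
        corr = (_day_length_hours(latitude, m) / 12.0) * (_MONTH_DAYS[m] / 30.0)
        pet.loc[grp.index] = np.maximum(raw * corr, 0.0)
    return pet


def _pwm(x: np.ndarray) -> tuple[float, float, float]:
    """First three unbiased probability-weighted moments b0, b1, b2."""
    x = np.sort(np.asarray(x, dtype=float))
    n = len(x)
    i = np.arange(1, n + 1)
    b0 = x.mean()
    b1 = np.sum((i - 1) * x) / (n * (n - 1))
    b2 = np.sum((i - 1) * (i - 2) * x) / (n * (n - 1) * (n - 2))
    return b0, b1, b2


def _fit_loglogistic(x: np.ndarray) -> tuple[float, float, float]:
    """L-moment fit of the 3-parameter log-logistic (scale, shape, origin).

    CDF: F(x) = (1 + (scale / (x - origin))**shape)**-1 for x > origin.
    Raises ``ValueError`` when the moments give an invalid shape or when the
    fitted origin is not below all calibration values.
    """
    b0, b1, b2 = _pwm(x)
    denom = 6.0 * b1 - b0 - 6.0 * b2
    if denom == 0:
        raise ValueError("degenerate PWMs")
    shape = (2.0 * b1 - b0) / denom
    if not np.isfinite(shape) or shape <= 1.0:
        # Gamma(1 +/- 1/shape) requires shape > 1 for a finite mean
        raise ValueError(f"invalid log-logistic shape {shape}")
    g = special.gamma(1.0 + 1.0 / shape) * special.gamma(1.0 - 1.0 / shape)
    scale = (b0 - 2.0 * b1) * shape / g
    origin = b0 - scale * g
    if scale <= 0 or np.any(x <= origin):
        raise ValueError("log-logistic fit does not cover the calibration data")
    return scale, shape, origin


def _loglogistic_cdf(x: np.ndarray, scale: float, shape: float, origin: float) -> np.ndarray:
    cdf = np.zeros_like(x, dtype=float)
    pos = x > origin
    cdf[pos] = 1.0 / (1.0 + (scale / (x[pos] - origin)) ** shape)
    return cdf


_CDF_EPS = 1e-6  # keeps the normal quantile finite for out-of-range balances


def spei6(
    clim: pd.DataFrame,
    calibration: tuple[int, int],
    *,
    latitude: float | None = None,
    window: int = 6,
) -> pd.DataFrame:
    """Monthly SPEI at a 6-month scale for a single site.

    The window is backward-looking and labelled by its final month; per
    calendar month a 3-parameter log-logistic is fitted by L-moments to the
    window sums whose final month falls inside ``calibration`` (inclusive
    year range).  Months whose L-moment fit fails fall back to empirical-
    quantile standardization and are flagged in the ``spei6_fallback`` column.

    Requires a ``latitude`` (or a single-site frame whose PET was precomputed
    in a ``pet`` column).  Returns a copy of ``clim`` with ``spei6`` and
    ``spei6_fallback`` columns; the first ``window - 1`` months are NaN.
    """
    clim = clim.sort_values(["year", "month"]).reset_index(drop=True)
    if clim["site_id"].nunique() != 1:
        raise ValueError("spei6 operates on one site at a time")
    cal_lo, cal_hi = calibration
    n_cal_years = cal_hi - cal_lo + 1
    if n_cal_years < 20:
        raise ValueError("need >= 20 calibration years")

    if "pet" in clim.columns:
        pet = clim["pet"].to_numpy(dtype=float)
    else:
        if latitude is None:
            raise ValueError("latitude required to compute PET")
        pet = thornthwaite_pet(clim, latitude).to_numpy()
    balance = clim["prcp"].to_numpy(dtype=float) - pet

    d = pd.Series(balance).rolling(window).sum().to_numpy()
    months = clim["month"].to_numpy(dtype=int)
    years = clim["year"].to_numpy(dtype=int)
    in_cal = (years >= cal_lo) & (years <= cal_hi)

    spei = np.full(len(clim), np.nan)
    fallback = np.zeros(len(clim), dtype=bool)
    for m in range(1, 13):
        sel = (months == m) & np.isfinite(d)
        cal = sel & in_cal
        x_cal = d[cal]
        if len(x_cal) < 10:
            continue
        if np.ptp(x_cal) == 0:
            raise ValueError(f"degenerate water balance (zero variance) in month {m}")
        try:
            scale, shape, origin = _fit_loglogistic(x_cal)
            cdf = _loglogistic_cdf(d[sel], scale, shape, origin)
        except ValueError:
            # empirical-quantile standardization (Hazen plotting positions)
            ranks = np.searchsorted(np.sort(x_cal), d[sel], side="right")
            cdf = (ranks - 0.5) / len(x_cal)
            fallback[sel] = True
        spei[sel] = stats.norm.ppf(np.clip(cdf, _CDF_EPS, 1.0 - _CDF_EPS))

    out = clim.copy()
    out["spei6"] = spei
    out["spei6_fallback"] = fallback
    return out


def annual_mean_spei(clim_with_spei: pd.DataFrame) -> pd.DataFrame:
    """Per-year mean of the 12 monthly SPEI-6 values (years with all 12 only)."""
    g = clim_with_spei.dropna(subset=["spei6"]).groupby(["site_id", "year"])
    out = g.agg(spei=("spei6", "mean"), n_months=("month", "nunique")).reset_index()
    return out[out["n_months"] == 12].drop(columns="n_months").reset_index(drop=True)
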