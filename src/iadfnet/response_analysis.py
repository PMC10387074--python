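"""Monthly climate-frequency correlations and standardization selection.

Each chronology's response series is correlated (Pearson, two-sided t test)
with every monthly climate variable — tmean, tmin, tmax, prcp, spei6 — for
months January..December of the ring's calendar year, plus the annual
summary, over a common period.  Comparing the correlation tables across the
four standardization variants identifies the variant carrying the strongest
climate signal for that chronology; the choice is reported, never silently
applied.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .chronology import METHODS, FrequencyChronology
from .climate import annual_mean_spei, annual_summaries

__all__ = ["monthly_correlations", "select_standardization", "VARIABLES"]

VARIABLES = ("tmean", "tmin", "tmax", "prcp", "spei6")


def monthly_correlations(
    chron: FrequencyChronology,
    method: str,
    clim: pd.DataFrame,
    period: tuple[int, int],
) -> pd.DataFrame:
    """Correlation table: 5 variables x (12 months + annual).

    Missing chronology years are dropped pairwise; a zero-variance pairing
    yields a missing r.  Columns: method, variable, month (1..12 or
    'annual'), r, p, n.
    """
    lo, hi = period
    resp = pd.Series(chron.series(method), index=chron.years)
    resp = resp[(resp.index >= lo) & (resp.index <= hi)].dropna()
    sub = clim[(clim["year"] >= lo) & (clim["year"] <= hi)]
    if len(resp) < 5:
        raise ValueError("fewer than 5 overlapping years in the common period")

    rows = []

    def corr(x: pd.Series, variable: str, month) -> None:
        pair = pd.concat([resp, x], axis=1, join="inner").dropna()
        n = len(pair)
        if n < 3 or pair.iloc[:, 0].std() == 0 or pair.iloc[:, 1].std() == 0:
            rows.append(
                {"method": method, "variable": variable, "month": month,
                 "r": np.nan, "p": np.nan, "n": n}
            )
            return
        r, p = stats.pearsonr(pair.iloc[:, 0], pair.iloc[:, 1])
        rows.append(
            {"method": method, "variable": variable, "month": month,
             "r": float(r), "p": float(p), "n": n}
        )

    ann_t = annual_summaries(sub).set_index("year")
    ann_spei = annual_mean_spei(sub).set_index("year") if "spei6" in sub.columns else None
    for var in VARIABLES:
        if var not in sub.columns:
            continue
        for m in range(1, 13):
            x = sub[sub["month"] == m].set_index("year")[var]
            corr(x, var, m)
        if var == "prcp":
            corr(ann_t["tp"], var, "annual")
        elif var == "spei6" and ann_spei is not None:
            corr(ann_spei["spei"], var, "annual")
        else:
            x = sub.groupby("year")[var].mean()
            corr(x, var, "annual")
    return pd.DataFrame(rows)


def select_standardization(
    sets: dict[str, pd.DataFrame], *, functional: str = "max_abs_r"
) -> tuple[str, pd.DataFrame]:
    """Pick the standardization variant with the strongest climate signal.

    ``max_abs_r`` scores each method by its largest |r| over all
    variable-months; ``mean_abs_r_significant`` averages |r| over cells with
    p < 0.05.  Ties break by the fixed order F < stabilized < age_detrended
    < rw_detrended.  Returns the winner and a per-method comparison table.
    """
    if not sets:
        raise ValueError("no correlation sets")
    rows = []
    for m in METHODS:
        if m not in sets:
            continue
        tab = sets[m]
        r = tab["r"].abs()
        if r.notna().sum() == 0:
            rows.append({"method": m, "score": np.nan, "n_cells": 0})
            continue
        if functional == "max_abs_r":
            score = float(r.max())
        elif functional == "mean_abs_r_significant":
            sig = tab["p"] < 0.05
            score = float(r[sig].mean()) if sig.any() else 0.0
        else:
            raise ValueError(f"unknown functional {functional!r}")
        rows.append({"method": m, "score": score, "n_cells": int(r.notna().sum())})
    table = pd.DataFrame(rows)
    if table.empty or table["score"].isna().all():
        raise ValueError("all correlations missing; cannot select a method")
    # stable idxmax respects the METHODS preference order on ties
    winner = table.loc[table["score"].idxmax(), "method"]
    return str(winner), table
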