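"""Climate-based site clustering: standardized features, PAM, silhouette.

Sites are described by their long-term monthly climatologies (12 x tmean,
tmin, tmax, prcp) plus latitude and longitude — 50 features, each z-scored
across sites — and clustered on Euclidean distances with the classic
k-medoids PAM algorithm (deterministic BUILD seeding followed by
steepest-descent SWAP).  The number of clusters is chosen by maximizing the
mean silhouette over a k range, ties going to the smaller k.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .tree_ring_io import SiteMeta

__all__ = [
    "ClusterModel",
    "climate_features",
    "pam_cluster",
    "silhouette_scores",
    "select_k",
]


@dataclass
class ClusterModel:
    """A PAM clustering of the network's sites."""

    k: int
    site_ids: list
    medoid_indices: np.ndarray  # indices into site_ids
    labels: np.ndarray  # cluster label (0..k-1) per site
    objective: float  # total distance of points to their medoid
    silhouettes: np.ndarray | None = None
    feature_names: list | None = None
    standardization: pd.DataFrame | None = None  # per-feature mean and SD

    @property
    def medoid_site_ids(self) -> list:
        return [self.site_ids[i] for i in self.medoid_indices]

    @property
    def mean_silhouette(self) -> float:
        if self.silhouettes is None:
            raise ValueError("silhouettes not computed")
        return float(np.mean(self.silhouettes))

    @property
    def assignment(self) -> dict:
        return dict(zip(self.site_ids, self.labels))

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"site_id": self.site_ids, "cluster": self.labels + 1})
        if self.silhouettes is not None:
            out["silhouette"] = self.silhouettes
        return out


def climate_features(
    sites: Sequence[SiteMeta],
    climates: pd.DataFrame,
    period: tuple[int, int],
    *,
    single_total_precipitation: bool = False,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Standardized climate feature matrix and Euclidean distance matrix.

    Features are per-month climatological means of tmean/tmin/tmax/prcp over
    ``period`` plus raw latitude and longitude; each column is z-scored
    across sites.  ``single_total_precipitation`` collapses the 12 monthly
    precipitation columns into one mean-annual-total column (the alternative
    reading of "total precipitation" as a clustering variable).

    Zero-variance columns are dropped with a warning.  Returns the
    standardized feature frame (indexed by site_id) and the condensed-to-
    square distance matrix in the same site order.
    """
    lo, hi = period
    sub = climates[(climates["year"] >= lo) & (climates["year"] <= hi)]
    site_ids = [s.site_id for s in sites]
    missing = set(site_ids) - set(sub["site_id"].unique())
    if missing:
        raise ValueError(f"no climate in period for sites: {sorted(missing)}")

    clim = (
        sub.groupby(["site_id", "month"])[["tmean", "tmin", "tmax", "prcp"]]
        .mean()
        .unstack("month")
    )
    clim.columns = [f"{var}_m{month:02d}" for var, month in clim.columns]
    if single_total_precipitation:
        prcp_cols = [c for c in clim.columns if c.startswith("prcp_")]
        clim["prcp_annual_total"] = clim[prcp_cols].sum(axis=1)
        clim = clim.drop(columns=prcp_cols)
    clim = clim.loc[site_ids]
    clim["latitude"] = [s.latitude for s in sites]
    clim["longitude"] = [s.longitude for s in sites]

    sd = clim.std(ddof=0)
    dead = sd[sd == 0].index.tolist()
    if dead:
        warnings.warn(f"dropping zero-variance features: {dead}", stacklevel=2)
        clim = clim.drop(columns=dead)
        sd = sd.drop(index=dead)
    z = (clim - clim.mean()) / sd
    dist = squareform(pdist(z.to_numpy(), metric="euclidean"))
    return z, dist


def _pam_build(dist: np.ndarray, k: int, first: int) -> list[int]:
    """Greedy BUILD seeding starting from a given first medoid."""
    medoids = [first]
    nearest = dist[first].copy()
    while len(medoids) < k:
        gains = np.sum(np.maximum(nearest[None, :] - dist, 0.0), axis=1)
        gains[medoids] = -np.inf
        j = int(np.argmax(gains))
        medoids.append(j)
        nearest = np.minimum(nearest, dist[j])
    return medoids


def _pam_swap(dist: np.ndarray, medoids: list[int]) -> tuple[list[int], float]:
    """Steepest-descent SWAP until no single exchange improves the objective."""
    n = dist.shape[0]
    medoids = list(medoids)
    current = float(dist[medoids].min(axis=0).sum())
    while True:
        best = (current - 1e-12, -1, -1)
        for mi in range(len(medoids)):
            others = [m for j, m in enumerate(medoids) if j != mi]
            without = dist[others].min(axis=0)
            # objective of swapping medoid mi for every candidate h at once
            objs = np.minimum(without[None, :], dist).sum(axis=1)
            objs[medoids] = np.inf
            h = int(np.argmin(objs))
            if objs[h] < best[0]:
                best = (float(objs[h]), mi, h)
        if best[1] < 0:
            return medoids, current
        medoids[best[1]] = best[2]
        current = best[0]


def pam_cluster(dist: np.ndarray, k: int) -> ClusterModel:
    """Deterministic PAM (k-medoids): greedy BUILD then steepest-descent SWAP.

    BUILD picks a first medoid, then repeatedly the point yielding the
    largest decrease in total distance-to-nearest-medoid; SWAP applies the
    best strictly-improving (medoid, non-medoid) exchange until none remains.
    Because a single BUILD seeding can strand SWAP in a local optimum, the
    procedure restarts BUILD deterministically from every possible first
    medoid and keeps the best final objective — no randomness anywhere, and
    the objective is non-increasing within each descent.
    """
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ValueError("dist must be a square matrix")
    if not (2 <= k < n):
        raise ValueError(f"need 2 <= k < n ({k=}, {n=})")

    best_meds, best_obj = None, np.inf
    for first in range(n):
        meds, obj = _pam_swap(dist, _pam_build(dist, k, first))
        if obj < best_obj - 1e-12:
            best_meds, best_obj = meds, obj

    med_arr = np.array(sorted(best_meds))
    labels = np.argmin(dist[med_arr], axis=0)
    return ClusterModel(
        k=k,
        site_ids=list(range(n)),
        medoid_indices=med_arr,
        labels=labels,
        objective=float(dist[med_arr].min(axis=0).sum()),
    )


def silhouette_scores(labels: np.ndarray, dist: np.ndarray) -> np.ndarray:
    """Per-point silhouette s = (b - a)/max(a, b).

    ``a`` is the mean distance to co-cluster points (excluding self), ``b``
    the smallest mean distance to another cluster.  Points in singleton
    clusters — and the fully degenerate case a = b = 0 — score 0.
    """
    labels = np.asarray(labels)
    n = len(labels)
    clusters = np.unique(labels)
    if len(clusters) < 2:
        raise ValueError("silhouette needs >= 2 clusters")
    s = np.zeros(n)
    for i in range(n):
        same = labels == labels[i]
        n_same = same.sum()
        if n_same == 1:
            continue  # singleton convention: 0
        a = dist[i, same].sum() / (n_same - 1)
        b = min(dist[i, labels == c].mean() for c in clusters if c != labels[i])
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return s


def select_k(
    sites: Sequence[SiteMeta] | Sequence[str],
    dist: np.ndarray,
    k_range: Sequence[int] = range(2, 11),
) -> tuple[ClusterModel, pd.DataFrame]:
    """PAM at every k in ``k_range``; return the model maximizing the mean
    silhouette (ties to smaller k) plus the full silhouette profile."""
    k_range = [k for k in k_range if 2 <= k < dist.shape[0]]
    if not k_range:
        raise ValueError("empty k range")
    site_ids = [s.site_id if isinstance(s, SiteMeta) else s for s in sites]
    best: ClusterModel | None = None
    profile = []
    for k in sorted(k_range):
        model = pam_cluster(dist, k)
        model.site_ids = site_ids
        model.silhouettes = silhouette_scores(model.labels, dist)
        profile.append({"k": k, "mean_silhouette": model.mean_silhouette})
        if best is None or model.mean_silhouette > best.mean_silhouette + 1e-12:
            best = model
    return best, pd.DataFrame(profile)
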