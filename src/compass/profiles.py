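"""Per-animal mean daily profiles and cohort-level hierarchical clustering.

A daily profile folds a binned series at 24 h and reports the per-bin mean
and SEM over days — the standard way to present a week of home-cage data
for one animal.  Across a cohort, the profile matrix (animals x bins) is
clustered hierarchically to reveal groups of animals with similar activity
(or sleep) patterns; activity- and sleep-based orderings can differ because
sleep is not simply the absence of activity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = ["DailyProfile", "daily_profile", "ClusterResult", "cluster_profiles"]


@dataclass
class DailyProfile:
    """Mean and SEM of activity per time-of-day bin, over complete days."""

    bin_s: int
    mean: np.ndarray
    sem: np.ndarray
    n_days: int

    @property
    def n_bins(self) -> int:
        return len(self.mean)


def daily_profile(values: np.ndarray, bin_s: int = 1800,
                  period_s: float = 86400) -> DailyProfile:
    """Fold a binned series into days and average per time-of-day bin.

    An incomplete trailing day is excluded.  SEM = sd / sqrt(n_days)
    (sample sd over days); with a single day SEM is reported as 0 with a
    warning, since day-to-day spread cannot be estimated.
    """
    x = np.asarray(values, dtype=float)
    p = period_s / bin_s
    if p != int(p):
        raise ValueError("period_s is not a whole number of bins")
    p = int(p)
    n_days = len(x) // p
    if n_days < 1:
        raise ValueError("need at least one complete day")
    mat = x[:n_days * p].reshape(n_days, p)
    mean = mat.mean(axis=0)
    if n_days == 1:
        warnings.warn("single day: SEM undefined, reporting 0", stacklevel=2)
        sem = np.zeros(p)
    else:
        sem = mat.std(axis=0, ddof=1) / np.sqrt(n_days)
    return DailyProfile(bin_s=bin_s, mean=mean, sem=sem, n_days=n_days)


@dataclass
class ClusterResult:
    """Hierarchical clustering of a cohort profile matrix."""

    labels: list[str]          # animal labels in canonical (sorted) order
    linkage: np.ndarray        # scipy linkage matrix over the sorted rows
    order: list[int]           # leaf order (indices into labels)
    matrix: np.ndarray         # (normalised) profiles reordered by leaf order
    metric: str
    method: str
    normalise: str | None

    @property
    def ordered_labels(self) -> list[str]:
        return [self.labels[i] for i in self.order]

    def cut(self, k: int) -> dict[str, int]:
        """Flat cluster assignment (1..k), keyed by animal label."""
        assign = hierarchy.fcluster(self.linkage, k, criterion="maxclust")
        return {lab: int(c) for lab, c in zip(self.labels, assign)}


def cluster_profiles(matrix: np.ndarray, labels: list[str] | None = None,
                     metric: str = "euclidean", method: str = "average",
                     normalise: str | None = "zscore") -> ClusterResult:
    """Cluster per-animal profiles (rows) hierarchically.

    Rows are z-scored per animal by default so that clustering reflects the
    *shape* of the daily pattern rather than overall activity level; a
    constant profile cannot be z-scored and is an error naming the animal.
    Leaf ordering is made deterministic and permutation-invariant by sorting
    rows by label before clustering.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 animals")
    if labels is None:
        labels = [f"animal_{i:02d}" for i in range(X.shape[0])]
    if len(labels) != X.shape[0]:
        raise ValueError("one label per row required")
    if normalise not in (None, "zscore"):
        raise ValueError(f"unknown normalisation {normalise!r}")

    order0 = sorted(range(len(labels)), key=lambda i: labels[i])
    X = X[order0]
    sorted_labels = [labels[i] for i in order0]

    if normalise == "zscore":
        sd = X.std(axis=1, ddof=0)
        flat = np.flatnonzero(sd == 0)
        if len(flat):
            raise ValueError(f"constant profile cannot be z-scored: "
                             f"{sorted_labels[flat[0]]}")
        X = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]

    Z = hierarchy.linkage(pdist(X, metric=metric), method=method)
    leaf_order = hierarchy.leaves_list(Z).tolist()
    return ClusterResult(labels=sorted_labels, linkage=Z, order=leaf_order,
                         matrix=X[leaf_order], metric=metric, method=method,
                         normalise=normalise)
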