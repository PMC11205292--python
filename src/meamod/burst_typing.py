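"""Activity typing: does a module's burst-size distribution contain a
distinct cluster of large bursts?

The decision is the K-means + Davies-Bouldin rule: split the per-burst SBE
values into two clusters with an *exact* 1-D k-means (dynamic programming
over sorted values — optimal clusters are contiguous in sorted order, so no
random initialization and no seed), then compute the Davies-Bouldin index of
the split.  The activity is type 1 (a large-burst cluster exists) iff the
index is at most ``db_threshold`` (0.5) and each cluster holds at least
``min_cluster_fraction`` (10%) of the bursts; otherwise it is type 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .burst_analysis import BurstCatalog
from .errors import (
    DegenerateInputError,
    InsufficientDataError,
    UndefinedIndexError,
    ValidationError,
)
from .io_core import register_report_type

__all__ = [
    "ActivityTypeParams",
    "ActivityTypeResult",
    "kmeans_1d",
    "davies_bouldin",
    "classify_activity",
]


@dataclass
class ActivityTypeParams:
    db_threshold: float = 0.5
    min_cluster_fraction: float = 0.10
    feature: str = "sbe"  # or "duration"
    scatter_exponent: int = 2  # q in the DB scatter: 1 = MAD, 2 = rms
    min_bursts: int = 10

    def __post_init__(self) -> None:
        if not (0 < self.db_threshold):
            raise ValidationError("db_threshold must be positive")
        if not (0 < self.min_cluster_fraction < 0.5):
            raise ValidationError("min_cluster_fraction must be in (0, 0.5)")
        if self.feature not in ("sbe", "duration"):
            raise ValidationError(f"unknown feature {self.feature!r}")
        if self.scatter_exponent not in (1, 2):
            raise ValidationError("scatter_exponent must be 1 or 2")


@register_report_type
@dataclass
class ActivityTypeResult:
    """Outcome of the one-vs-two-cluster decision for one module."""

    labels: List[int]            # cluster id per burst, ordered by centroid
    centroids: List[float]
    db_index: Optional[float]    # None when undefined (< 2 distinct values)
    decided_type: str            # "type1" or "type2"
    large_burst_indices: List[int]
    feature: str = "sbe"


def kmeans_1d(values: Sequence[float], k: int = 2) -> Tuple[np.ndarray, np.ndarray]:
    """Exact optimal 1-D k-means by dynamic programming.

    Returns ``(labels, centroids)`` with clusters numbered by ascending
    centroid.  The optimal partition minimizing within-cluster sum of squares
    is contiguous in sorted order; the DP searches all contiguous partitions,
    so the result is deterministic and globally optimal.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValidationError("values must be 1-D")
    n = x.size
    if k < 1:
        raise ValidationError("k must be >= 1")
    if np.unique(x).size < k:
        raise DegenerateInputError(f"need at least {k} distinct values, got {np.unique(x).size}")

    order = np.argsort(x, kind="stable")
    xs = x[order]
    cs = np.concatenate(([0.0], np.cumsum(xs)))
    css = np.concatenate(([0.0], np.cumsum(xs * xs)))

    if k == 1:
        bounds = [0, n]
    elif k == 2:
        # vectorized scan over the n-1 contiguous splits
        i = np.arange(1, n)
        wl = css[i] - cs[i] ** 2 / i
        wr = (css[n] - css[i]) - (cs[n] - cs[i]) ** 2 / (n - i)
        split = int(np.argmin(wl + wr)) + 1
        bounds = [0, split, n]
    else:
        bounds = _kmeans_dp_bounds(xs, cs, css, k)

    labels_sorted = np.empty(n, dtype=int)
    centroids = np.empty(k, dtype=float)
    for c in range(k):
        lo, hi = bounds[c], bounds[c + 1]
        labels_sorted[lo:hi] = c
        centroids[c] = xs[lo:hi].mean()

    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted
    return labels, centroids


def _kmeans_dp_bounds(xs: np.ndarray, cs: np.ndarray, css: np.ndarray, k: int) -> List[int]:
    """Cluster boundaries of the optimal contiguous partition (general k)."""
    n = xs.size

    def seg_cost(i: int, j: int) -> float:
        # within-cluster sum of squares of xs[i:j]
        m = j - i
        s = cs[j] - cs[i]
        return (css[j] - css[i]) - s * s / m

    INF = float("inf")
    # dp[m][j] = min cost of splitting xs[:j] into m clusters
    dp = np.full((k + 1, n + 1), INF)
    back = np.zeros((k + 1, n + 1), dtype=int)
    dp[0][0] = 0.0
    for m in range(1, k + 1):
        for j in range(m, n + 1):
            best, arg = INF, m - 1
            for i in range(m - 1, j):
                if dp[m - 1][i] == INF:
                    continue
                c = dp[m - 1][i] + seg_cost(i, j)
                if c < best:
                    best, arg = c, i
            dp[m][j] = best
            back[m][j] = arg

    bounds = [n]
    j = n
    for m in range(k, 0, -1):
        j = back[m][j]
        bounds.append(j)
    return bounds[::-1]  # 0 = b0 < b1 < ... < bk = n


def davies_bouldin(values: Sequence[float], labels: Sequence[int], q: int = 2) -> float:
    """Davies-Bouldin index DB = (1/k) * sum_i max_{j!=i} (s_i + s_j) / d_ij.

    ``s_i`` is the within-cluster scatter around the centroid (q = 1: mean
    absolute deviation; q = 2: root mean square), ``d_ij`` the distance
    between centroids.  For two clusters this reduces to (s1 + s2) / d12.
    Scale-invariant: multiplying all values by c > 0 leaves DB unchanged.
    """
    x = np.asarray(values, dtype=float)
    lab = np.asarray(labels)
    ids = np.unique(lab)
    if ids.size < 2:
        raise ValidationError("need >= 2 non-empty clusters")
    if q not in (1, 2):
        raise ValidationError("q must be 1 or 2")
    cents = np.array([x[lab == i].mean() for i in ids])
    if q == 1:
        scat = np.array([np.abs(x[lab == i] - c).mean() for i, c in zip(ids, cents)])
    else:
        scat = np.array([np.sqrt(((x[lab == i] - c) ** 2).mean()) for i, c in zip(ids, cents)])
    k = ids.size
    worst = np.empty(k)
    for a in range(k):
        best = -np.inf
        for b in range(k):
            if a == b:
                continue
            d = abs(cents[a] - cents[b])
            if d == 0:
                raise UndefinedIndexError("coincident centroids: DB undefined")
            best = max(best, (scat[a] + scat[b]) / d)
        worst[a] = best
    return float(worst.mean())


def classify_activity(
    cat: BurstCatalog, params: Optional[ActivityTypeParams] = None
) -> ActivityTypeResult:
    """Decide type 1 vs type 2 activity for one module's burst catalog."""
    if params is None:
        params = ActivityTypeParams()
    values = cat.sbe_values() if params.feature == "sbe" else cat.duration_values_ms()
    n = values.size
    if n < params.min_bursts:
        raise InsufficientDataError(
            f"{n} bursts < minimum {params.min_bursts}: activity type undecidable"
        )
    if np.unique(values).size < 2:
        return ActivityTypeResult(
            labels=[0] * n,
            centroids=[float(values.mean())],
            db_index=None,
            decided_type="type2",
            large_burst_indices=[],
            feature=params.feature,
        )
    labels, centroids = kmeans_1d(values, k=2)
    db = davies_bouldin(values, labels, q=params.scatter_exponent)
    frac_small = float(np.mean(labels == 0))
    frac_large = 1.0 - frac_small
    is_type1 = db <= params.db_threshold and min(frac_small, frac_large) >= params.min_cluster_fraction
    large_idx = [int(i) for i in np.flatnonzero(labels == 1)] if is_type1 else []
    return ActivityTypeResult(
        labels=[int(v) for v in labels],
        centroids=[float(c) for c in centroids],
        db_index=float(db),
        decided_type="type1" if is_type1 else "type2",
        large_burst_indices=large_idx,
        feature=params.feature,
    )
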