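"""Independent oracles used to check the implementation.

Each oracle recomputes a quantity by the most direct method available
(counting, enumeration, closed form) and never shares code with the
implementation path it checks.
"""

from __future__ import annotations

import math
from itertools import combinations
from typing import Dict, List, Sequence, Tuple

import numpy as np

from meamod import Burst, BurstCatalog


def cfp_oracle(ti: np.ndarray, tj: np.ndarray, bin_ms: float, n_bins: int) -> np.ndarray:
    """Direct counting oracle for the CFP curve.

    For every reference spike on i, walk the (sorted) spikes of j inside the
    lag window and mark which bins contain at least one; the curve is the
    per-bin count divided by the number of reference spikes.
    """
    bin_s = bin_ms * 1e-3
    tau_max = bin_s * n_bins
    counts = np.zeros(n_bins, dtype=np.int64)
    tj = np.sort(np.asarray(tj, dtype=float))
    for t in np.asarray(ti, dtype=float):
        hit = set()
        start = np.searchsorted(tj, t, side="right")
        for u in tj[start:]:
            lag = u - t
            if lag > tau_max:
                break
            if lag > 0:
                b = math.ceil(lag / bin_s) - 1
                if 0 <= b < n_bins:
                    hit.add(b)
        for b in hit:
            counts[b] += 1
    return counts / max(len(ti), 1)


def db_two_cluster_oracle(values: Sequence[float], labels: Sequence[int], q: int = 2) -> float:
    """(s1 + s2) / d12 evaluated directly for a two-cluster labeling."""
    x = np.asarray(values, dtype=float)
    lab = np.asarray(labels)
    ids = sorted(set(lab.tolist()))
    assert len(ids) == 2
    a, b = x[lab == ids[0]], x[lab == ids[1]]
    ca, cb = a.mean(), b.mean()
    if q == 1:
        sa, sb = np.abs(a - ca).mean(), np.abs(b - cb).mean()
    else:
        sa, sb = np.sqrt(((a - ca) ** 2).mean()), np.sqrt(((b - cb) ** 2).mean())
    return (sa + sb) / abs(ca - cb)


def exhaustive_kmeans_wcss(values: Sequence[float], k: int) -> float:
    """Minimum within-cluster sum of squares over all contiguous partitions
    of the sorted values, by brute-force enumeration of split points."""
    xs = np.sort(np.asarray(values, dtype=float))
    n = xs.size

    def wcss(seg: np.ndarray) -> float:
        return float(((seg - seg.mean()) ** 2).sum())

    best = math.inf
    for cuts in combinations(range(1, n), k - 1):
        bounds = (0, *cuts, n)
        total = sum(wcss(xs[bounds[c]:bounds[c + 1]]) for c in range(k))
        best = min(best, total)
    return best


def wcss_of_labeling(values: Sequence[float], labels: Sequence[int]) -> float:
    x = np.asarray(values, dtype=float)
    lab = np.asarray(labels)
    return float(sum(((x[lab == c] - x[lab == c].mean()) ** 2).sum() for c in set(lab.tolist())))


def mann_whitney_exact_oracle(a: Sequence[float], b: Sequence[float]) -> Tuple[float, float]:
    """Exhaustive-enumeration two-sided Mann-Whitney p-value (no ties).

    Enumerates every assignment of the pooled values into groups of sizes
    (|a|, |b|), computes the U statistic of the first group for each, and
    returns (U_observed, two-sided p) with p = 2 * min(P(U <= u), P(U >= u))
    capped at 1.
    """
    xa = np.asarray(list(a), dtype=float)
    xb = np.asarray(list(b), dtype=float)
    pooled = np.concatenate([xa, xb])
    na = xa.size

    def u_stat(group_a: np.ndarray, group_b: np.ndarray) -> float:
        return float(sum((x > y) + 0.5 * (x == y) for x in group_a for y in group_b))

    u_obs = u_stat(xa, xb)
    us = []
    idx = np.arange(pooled.size)
    for comb in combinations(idx, na):
        mask = np.zeros(pooled.size, dtype=bool)
        mask[list(comb)] = True
        us.append(u_stat(pooled[mask], pooled[~mask]))
    us = np.asarray(us)
    p_le = np.mean(us <= u_obs)
    p_ge = np.mean(us >= u_obs)
    return u_obs, min(1.0, 2.0 * min(p_le, p_ge))


def match_one_to_one(planted: Sequence[float], detected: Sequence[float], tol: float) -> int:
    """Greedy one-to-one matching of event times within tolerance; returns
    the number of matched planted events."""
    det = sorted(detected)
    used = [False] * len(det)
    matched = 0
    for t in sorted(planted):
        best, best_d = None, tol
        for k, d in enumerate(det):
            if used[k]:
                continue
            if abs(d - t) < best_d:
                best, best_d = k, abs(d - t)
            if d - t >= tol:
                break
        if best is not None:
            used[best] = True
            matched += 1
    return matched


def catalog_from_sbe(values: Sequence[float], module: str = "source",
                     scale: int = 1000) -> BurstCatalog:
    """Burst catalog whose SBE values equal ``values`` to 1/scale precision."""
    bursts = []
    for k, v in enumerate(values):
        onset = float(k)
        bursts.append(
            Burst(module, onset, onset + 0.05, {"e1": int(round(v * scale))}, scale)
        )
    return BurstCatalog(module, bursts, recording_minutes=max(len(bursts) / 60.0, 1.0))
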