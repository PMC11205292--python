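"""Conditional-firing-probability (CFP) functional connectivity.

For an ordered electrode pair (i, j) the CFP curve gives, per lag bin b
covering (0, tau_max], the probability that electrode j fires at least one
spike with lag in bin b after a reference spike on electrode i.  The curve
is a probability (each bin value in [0, 1]), not a raw count histogram.

A pair is functionally connected when the curve is not flat: its peak
exceeds the background mean by ``flatness_k`` background standard
deviations (background = all bins except the peak bin), and the peak is
supported by at least ``min_peak_hits`` reference spikes.  The count guard
matters for sparse trains: a curve of near-zero Poisson counts almost
always has a maximum exceeding mean + k*sd because the background sd is
tiny, so without a minimum coincidence count the rule would declare
connections out of noise.  Connection strength is the peak probability and
latency the center of the peak bin.

Pairs are evaluated within each module and from Source to Target; backward
Target->Source pairs are not analyzed because burst propagation in these
preparations is essentially one-directional.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np

from .errors import ValidationError
from .io_core import ElectrodeMap, SpikeTrainSet, register_report_type

__all__ = [
    "CFPParams",
    "CFPCurve",
    "ConnectivityResult",
    "compute_cfp",
    "flatness_test",
    "connectivity_matrix",
]


@dataclass
class CFPParams:
    tau_max_ms: float = 50.0
    bin_ms: float = 1.0
    flatness_k: float = 3.0
    min_peak_hits: int = 5
    min_reference_spikes: int = 50

    def __post_init__(self) -> None:
        if not (self.bin_ms > 0):
            raise ValidationError("bin_ms must be > 0")
        if not (self.tau_max_ms >= self.bin_ms):
            raise ValidationError("tau_max_ms must be >= bin_ms")
        if not (self.flatness_k > 0):
            raise ValidationError("flatness_k must be > 0")
        if self.min_reference_spikes < 1:
            raise ValidationError("min_reference_spikes must be >= 1")
        if self.min_peak_hits < 0:
            raise ValidationError("min_peak_hits must be >= 0")

    @property
    def n_bins(self) -> int:
        return int(round(self.tau_max_ms / self.bin_ms))


@register_report_type
@dataclass
class CFPCurve:
    """CFP curve and derived connection descriptors for one ordered pair."""

    i: str
    j: str
    curve: List[float]
    n_reference_spikes: int
    defined: bool
    connected: bool
    strength: Optional[float]    # peak probability, iff connected
    latency_ms: Optional[float]  # peak-bin center, iff connected


@register_report_type
@dataclass
class ConnectivityResult:
    """Curves grouped by pair class, with group medians over connected pairs."""

    intra_source: List[CFPCurve]
    intra_target: List[CFPCurve]
    source_to_target: List[CFPCurve]
    group_median_strength: Dict[str, Optional[float]]
    group_median_latency_ms: Dict[str, Optional[float]]


def _cfp_counts(ti: np.ndarray, tj: np.ndarray, bin_s: float, n_bins: int) -> np.ndarray:
    """Number of reference spikes on i followed by >= 1 spike on j in each
    lag bin (b*bin, (b+1)*bin], fully vectorized."""
    tau_max = bin_s * n_bins
    left = np.searchsorted(tj, ti, side="right")
    right = np.searchsorted(tj, ti + tau_max, side="right")
    counts = right - left
    total = int(counts.sum())
    if total == 0:
        return np.zeros(n_bins, dtype=np.int64)
    ref_ids = np.repeat(np.arange(ti.size), counts)
    offsets = np.concatenate(([0], np.cumsum(counts)))[:-1]
    flat = np.arange(total) - np.repeat(offsets, counts) + np.repeat(left, counts)
    lags = tj[flat] - ti[ref_ids]
    bins = np.ceil(lags / bin_s).astype(np.int64) - 1
    ok = (lags > 0) & (bins >= 0) & (bins < n_bins)
    keys = ref_ids[ok] * n_bins + bins[ok]
    uniq = np.unique(keys)
    return np.bincount(uniq % n_bins, minlength=n_bins)


def compute_cfp(
    sts: SpikeTrainSet, i: str, j: str, params: Optional[CFPParams] = None
) -> CFPCurve:
    """CFP curve for the ordered pair (i, j)."""
    if params is None:
        params = CFPParams()
    if i == j:
        raise ValidationError("CFP requires two distinct electrodes")
    ti = sts.spikes.get(i, np.empty(0))
    tj = sts.spikes.get(j, np.empty(0))
    n_ref = int(ti.size)
    n_bins = params.n_bins
    if n_ref < params.min_reference_spikes:
        return CFPCurve(i, j, [0.0] * n_bins, n_ref, False, False, None, None)
    hits = _cfp_counts(ti, tj, params.bin_ms * 1e-3, n_bins)
    curve = hits / n_ref
    c = CFPCurve(i, j, [float(v) for v in curve], n_ref, True, False, None, None)
    if flatness_test(c, params):
        peak = int(np.argmax(curve))
        c.connected = True
        c.strength = float(curve[peak])
        c.latency_ms = float((peak + 0.5) * params.bin_ms)
    return c


def flatness_test(curve: CFPCurve, params: Optional[CFPParams] = None) -> bool:
    """Connected iff the peak exceeds the off-peak mean by k off-peak sds
    and is supported by at least ``min_peak_hits`` reference spikes."""
    if params is None:
        params = CFPParams()
    if not curve.defined:
        raise ValidationError("flatness test on an undefined curve")
    y = np.asarray(curve.curve, dtype=float)
    if y.size < 3:
        raise ValidationError("flatness test needs >= 3 bins")
    peak = int(np.argmax(y))
    rest = np.delete(y, peak)
    if y[peak] <= rest.mean() + params.flatness_k * rest.std():
        return False
    peak_hits = int(round(y[peak] * curve.n_reference_spikes))
    return peak_hits >= params.min_peak_hits


def _median_or_none(values: List[float]) -> Optional[float]:
    return float(np.median(values)) if values else None


def connectivity_matrix(
    sts: SpikeTrainSet, emap: ElectrodeMap, params: Optional[CFPParams] = None
) -> ConnectivityResult:
    """All intra-Source, intra-Target and Source->Target CFP curves."""
    if params is None:
        params = CFPParams()
    emap.require_coverage(sts)
    src = sorted(emap.electrodes("source"))
    tgt = sorted(emap.electrodes("target"))
    # channel-labeled electrodes join no group; pairs involving them can
    # still be evaluated directly with compute_cfp
    groups: Dict[str, List[CFPCurve]] = {"intra_source": [], "intra_target": [], "source_to_target": []}
    for a in src:
        for b in src:
            if a != b:
                groups["intra_source"].append(compute_cfp(sts, a, b, params))
    for a in tgt:
        for b in tgt:
            if a != b:
                groups["intra_target"].append(compute_cfp(sts, a, b, params))
    for a in src:
        for b in tgt:
            groups["source_to_target"].append(compute_cfp(sts, a, b, params))
    med_s = {}
    med_l = {}
    for name, curves in groups.items():
        conn = [c for c in curves if c.connected]
        med_s[name] = _median_or_none([c.strength for c in conn])
        med_l[name] = _median_or_none([c.latency_ms for c in conn])
    return ConnectivityResult(
        intra_source=groups["intra_source"],
        intra_target=groups["intra_target"],
        source_to_target=groups["source_to_target"],
        group_median_strength=med_s,
        group_median_latency_ms=med_l,
    )
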