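"""Pairing of Source and Target bursts and propagation probabilities.

A Source burst counts as propagated when a Target burst starts within the
onset-lag window after it (default (0, 100] ms — intermodular delays in
these preparations are tens of milliseconds).  Pairing is greedy
earliest-first and one-to-one, which is deterministic given the
time-ordered catalogs.  PPST is the fraction of Source bursts that
propagated to the Target; PPTS the reverse direction with the lag sign
flipped.  An alternative overlap-based pairing (bursts whose
[onset, offset) intervals intersect) is available via ``pairing``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

from .burst_analysis import BurstCatalog
from .errors import ValidationError
from .io_core import register_report_type

__all__ = ["PropagationParams", "PropagationResult", "pair_bursts", "propagation_probability"]


@dataclass
class PropagationParams:
    max_onset_lag_ms: float = 100.0
    min_onset_lag_ms: float = 0.0
    pairing: str = "onset_lag"  # or "overlap"

    def __post_init__(self) -> None:
        if not (self.max_onset_lag_ms > self.min_onset_lag_ms):
            raise ValidationError("max_onset_lag_ms must exceed min_onset_lag_ms")
        if self.pairing not in ("onset_lag", "overlap"):
            raise ValidationError(f"unknown pairing mode {self.pairing!r}")


@register_report_type
@dataclass
class PropagationResult:
    """Burst pairs and propagation probabilities for one recording.

    ``ppst``/``ppts`` are None (undefined, flagged) when the corresponding
    catalog is empty, never silently zero.
    """

    pairs_st: List[List[float]]  # [source_index, target_index, lag_ms]
    pairs_ts: List[List[float]]
    ppst: Optional[float]
    ppts: Optional[float]
    n_source_bursts: int
    n_target_bursts: int


def _greedy_onset_pairs(
    from_onsets, to_onsets, min_lag_s: float, max_lag_s: float
) -> List[List[float]]:
    """One-to-one greedy pairing: each burst of the leading catalog takes the
    earliest unpaired burst of the other catalog with onset lag in
    (min_lag, max_lag]."""
    pairs: List[List[float]] = []
    j = 0
    used = set()
    for i, t0 in enumerate(from_onsets):
        while j < len(to_onsets) and to_onsets[j] - t0 <= min_lag_s:
            j += 1
        jj = j
        while jj < len(to_onsets) and jj in used:
            jj += 1
        if jj < len(to_onsets):
            lag = to_onsets[jj] - t0
            if min_lag_s < lag <= max_lag_s:
                used.add(jj)
                pairs.append([float(i), float(jj), float(lag * 1e3)])
    return pairs


def _overlap_pairs(src: BurstCatalog, tgt: BurstCatalog) -> List[List[float]]:
    pairs: List[List[float]] = []
    used = set()
    for i, sb in enumerate(src.bursts):
        for j, tb in enumerate(tgt.bursts):
            if j in used:
                continue
            if sb.onset_s < tb.offset_s and tb.onset_s < sb.offset_s:
                pairs.append([float(i), float(j), float((tb.onset_s - sb.onset_s) * 1e3)])
                used.add(j)
                break
    return pairs


def pair_bursts(
    src: BurstCatalog, tgt: BurstCatalog, params: Optional[PropagationParams] = None
) -> List[List[float]]:
    """Source->Target burst pairs ``[src_index, tgt_index, lag_ms]``."""
    if params is None:
        params = PropagationParams()
    if params.pairing == "overlap":
        return _overlap_pairs(src, tgt)
    return _greedy_onset_pairs(
        src.onsets(), tgt.onsets(), params.min_onset_lag_ms * 1e-3, params.max_onset_lag_ms * 1e-3
    )


def propagation_probability(
    src: BurstCatalog, tgt: BurstCatalog, params: Optional[PropagationParams] = None
) -> PropagationResult:
    """PPST and PPTS with the pairs behind each ratio."""
    if params is None:
        params = PropagationParams()
    pairs_st = pair_bursts(src, tgt, params)
    pairs_ts = pair_bursts(tgt, src, params)
    n_s, n_t = len(src.bursts), len(tgt.bursts)
    ppst = len(pairs_st) / n_s if n_s else None
    ppts = len(pairs_ts) / n_t if n_t else None
    return PropagationResult(pairs_st, pairs_ts, ppst, ppts, n_s, n_t)
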