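"""Network-burst detection per module and burst statistics.

A network burst is a brief epoch of synchronized high-rate spiking across a
module's electrodes.  Detection pools all module spikes, bins them (50 ms
default, half-open bins from t = 0), takes maximal runs of bins at or above
a rate threshold as candidates, merges candidates separated by less than a
gap, and discards candidates with too few spikes.  The default threshold is
expressed per electrode (0.1 spikes/bin/electrode) so that the same setting
transfers across modules of different sizes.

Derived per-burst quantities follow the field's conventions: SBE is the
total spike count normalized by the number of module electrodes, BD the
onset-to-offset interval in milliseconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np

from .errors import ValidationError
from .io_core import ElectrodeMap, SpikeTrainSet, register_report_type

__all__ = [
    "BurstDetectionParams",
    "Burst",
    "BurstCatalog",
    "firing_rate",
    "detect_bursts",
    "burst_sbe",
    "burst_duration",
    "bursts_per_minute",
]


@dataclass
class BurstDetectionParams:
    """Burst-detector configuration; exactly one thresholding mode is active.

    ``threshold_per_electrode`` (spikes/bin/electrode, default 0.25) scales
    with module size; ``rate_threshold_spikes_per_bin`` is an absolute
    alternative.  The default is chosen so that for typical module sizes a
    bin needs at least two pooled spikes to count as burst activity — a
    lone spike on one electrode is background, not a network event, and a
    sub-one-spike effective threshold lets stray background spikes extend
    burst onsets and bias every onset-lag statistic downstream.
    ``merge_gap_ms`` joins candidates closer than the gap and
    ``min_burst_spikes`` drops candidates with fewer total spikes.
    """

    bin_ms: float = 50.0
    threshold_per_electrode: Optional[float] = 0.25
    rate_threshold_spikes_per_bin: Optional[float] = None
    min_burst_spikes: int = 5
    merge_gap_ms: float = 100.0
    # burst boundaries anchor on the first/last run of `anchor_spikes`
    # pooled spikes inside `anchor_window_ms`; an isolated spike that shares
    # the onset bin with the true burst start would otherwise define the
    # onset and bias onset-lag statistics (set anchor_spikes=1 to disable)
    anchor_spikes: int = 3
    anchor_window_ms: float = 25.0

    def __post_init__(self) -> None:
        if not (self.bin_ms > 0):
            raise ValidationError("bin_ms must be > 0")
        if self.merge_gap_ms < 0:
            raise ValidationError("merge_gap_ms must be >= 0")
        if self.min_burst_spikes < 0:
            raise ValidationError("min_burst_spikes must be >= 0")
        if self.anchor_spikes < 1 or self.anchor_window_ms <= 0:
            raise ValidationError("anchor_spikes must be >= 1 and anchor_window_ms > 0")
        modes = (self.threshold_per_electrode, self.rate_threshold_spikes_per_bin)
        if sum(m is not None for m in modes) != 1:
            raise ValidationError("exactly one thresholding mode must be set")
        active = next(m for m in modes if m is not None)
        if not (active > 0):
            raise ValidationError("threshold must be > 0")


@register_report_type
@dataclass
class Burst:
    """One detected network burst in one module."""

    module: str
    onset_s: float
    offset_s: float
    spike_counts: Dict[str, int]
    n_electrodes_in_module: int

    def __post_init__(self) -> None:
        if not (self.offset_s > self.onset_s):
            raise ValidationError("burst offset must be after onset")
        if self.n_electrodes_in_module <= 0:
            raise ValidationError("n_electrodes_in_module must be positive")

    @property
    def total_spikes(self) -> int:
        return int(sum(self.spike_counts.values()))


@register_report_type
@dataclass
class BurstCatalog:
    """Time-ordered, non-overlapping bursts of one module in one recording."""

    module: str
    bursts: List[Burst]
    recording_minutes: float

    def __post_init__(self) -> None:
        if not (self.recording_minutes > 0):
            raise ValidationError("recording_minutes must be positive")
        onsets = [b.onset_s for b in self.bursts]
        if onsets != sorted(onsets):
            raise ValidationError("bursts must be sorted by onset")
        for a, b in zip(self.bursts, self.bursts[1:]):
            if b.onset_s < a.offset_s:
                raise ValidationError("bursts must not overlap")

    def __len__(self) -> int:
        return len(self.bursts)

    def onsets(self) -> np.ndarray:
        return np.asarray([b.onset_s for b in self.bursts], dtype=float)

    def sbe_values(self) -> np.ndarray:
        return np.asarray([burst_sbe(b) for b in self.bursts], dtype=float)

    def duration_values_ms(self) -> np.ndarray:
        return np.asarray([burst_duration(b) for b in self.bursts], dtype=float)


def firing_rate(sts: SpikeTrainSet, emap: ElectrodeMap, module: str) -> float:
    """Module firing rate: total spikes on the module's electrodes per second."""
    electrodes = emap.electrodes(module)
    if not electrodes:
        raise ValidationError(f"module {module!r} has no electrodes")
    if not (sts.duration_s > 0):
        raise ValidationError("zero-duration recording")
    return sts.n_spikes(electrodes) / sts.duration_s


def _candidate_runs(counts: np.ndarray, threshold: float) -> List[tuple]:
    """Maximal runs of bins with count >= threshold, as (first_bin, last_bin)."""
    supra = counts >= threshold
    if not supra.any():
        return []
    idx = np.flatnonzero(supra)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))
    return [(int(idx[s]), int(idx[e])) for s, e in zip(starts, ends)]


def _anchor_boundaries(
    pooled: np.ndarray, onset: float, offset: float, k: int, win_s: float
) -> tuple:
    """Snap burst boundaries to the first/last run of k spikes within win_s.

    Falls back to the first/last spike when no such run exists (small
    bursts), so anchoring never empties a burst.
    """
    lo = int(np.searchsorted(pooled, onset, side="left"))
    hi = int(np.searchsorted(pooled, offset, side="right"))
    spk = pooled[lo:hi]
    if spk.size < k or k == 1:
        return onset, offset
    dense = np.flatnonzero(spk[k - 1:] - spk[: spk.size - k + 1] <= win_s)
    if dense.size == 0:
        return onset, offset
    return float(spk[dense[0]]), float(spk[dense[-1] + k - 1])


def detect_bursts(
    sts: SpikeTrainSet,
    emap: ElectrodeMap,
    module: str,
    params: Optional[BurstDetectionParams] = None,
) -> BurstCatalog:
    """Detect network bursts on one module's pooled spike counts."""
    if params is None:
        params = BurstDetectionParams()
    electrodes = sorted(emap.electrodes(module))
    if not electrodes:
        raise ValidationError(f"module {module!r} has no electrodes")
    n_elec = len(electrodes)
    if params.rate_threshold_spikes_per_bin is not None:
        threshold = params.rate_threshold_spikes_per_bin
    else:
        threshold = params.threshold_per_electrode * n_elec

    pooled = np.sort(
        np.concatenate([sts.spikes.get(e, np.empty(0)) for e in electrodes])
    )
    minutes = sts.duration_s / 60.0
    if pooled.size == 0:
        return BurstCatalog(module, [], minutes)

    bin_s = params.bin_ms * 1e-3
    n_bins = int(np.ceil(sts.duration_s / bin_s)) + 1
    bins_of_spike = np.minimum((pooled / bin_s).astype(int), n_bins - 1)
    counts = np.bincount(bins_of_spike, minlength=n_bins)

    # candidate intervals in spike times: onset = first spike in first supra
    # bin, offset = last spike in last supra bin.  Candidates below the
    # minimum spike count are dropped *before* merging: otherwise isolated
    # background spikes (a single spike exceeds any per-electrode threshold
    # < 1/n_electrodes) get glued onto real bursts and drag their onsets
    # earlier, which biases every onset-lag statistic downstream.
    intervals = []
    for b0, b1 in _candidate_runs(counts, threshold):
        lo = int(np.searchsorted(bins_of_spike, b0, side="left"))
        hi = int(np.searchsorted(bins_of_spike, b1, side="right"))
        if hi - lo >= max(params.min_burst_spikes, 1):
            intervals.append((pooled[lo], pooled[hi - 1]))

    # merge surviving candidates separated by < merge_gap_ms
    gap_s = params.merge_gap_ms * 1e-3
    merged: List[list] = []
    for onset, offset in intervals:
        if merged and onset - merged[-1][1] < gap_s:
            merged[-1][1] = max(merged[-1][1], offset)
        else:
            merged.append([onset, offset])

    bursts: List[Burst] = []
    for onset, offset in merged:
        onset, offset = _anchor_boundaries(
            pooled, onset, offset, params.anchor_spikes, params.anchor_window_ms * 1e-3
        )
        spike_counts = {}
        total = 0
        for e in electrodes:
            t = sts.spikes.get(e, np.empty(0))
            c = int(np.searchsorted(t, offset, side="right") - np.searchsorted(t, onset, side="left"))
            spike_counts[e] = c
            total += c
        if total < params.min_burst_spikes:
            continue
        if offset <= onset:  # single-spike candidate: zero-length interval
            continue
        bursts.append(Burst(module, float(onset), float(offset), spike_counts, n_elec))
    return BurstCatalog(module, bursts, minutes)


def burst_sbe(b: Burst) -> float:
    """Spikes per burst per electrode: total spikes / module electrode count."""
    return b.total_spikes / b.n_electrodes_in_module


def burst_duration(b: Burst) -> float:
    """Burst duration in milliseconds."""
    return (b.offset_s - b.onset_s) * 1e3


def bursts_per_minute(cat: BurstCatalog) -> float:
    """Detected burst count divided by recording time in minutes."""
    return len(cat.bursts) / cat.recording_minutes
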