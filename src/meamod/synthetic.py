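"""Synthetic two-module MEA recordings with planted ground truth.

The generator emulates the phenomenology of a Source/Target microfluidic
culture rather than any biophysics: Source network bursts arrive as a
hard-core renewal process; each burst's size (SBE, spikes per burst per
electrode) is drawn from a log-normal mixture — one component gives the
unimodal, type-2-like regime, two components the bimodal, type-1-like
regime — and its duration follows an affine map of SBE with
multiplicative jitter (defaults solve SBE 35 -> BD 292 ms and SBE 1.9 ->
BD ~43 ms).  Within a burst, spiking is organized as a sequence of network
events: every module electrode fires in an event with a common
participation probability, offset by a fixed per-electrode delay.  Each
module's electrodes split into an "early" half (delay ~0) and a "late"
half (delay drawn around the intramodular lag), which plants sharp
pairwise CFP lags.  With the configured probability (optionally an
increasing logistic function of SBE) a burst propagates: the Target module
replays the event sequence shifted by a per-burst propagation delay, which
also sets the planted Source->Target pairwise lags.  Independent Poisson
background spiking is added on every electrode.

Everything is drawn from one seeded generator in a fixed order, so output
is bit-reproducible from (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .errors import GenerationError, ValidationError
from .io_core import RawRecording, SpikeTrainSet, register_report_type

__all__ = [
    "SynthConfig",
    "PlantedBurst",
    "GroundTruth",
    "generate_recording",
    "generate_raw",
    "TYPE1_MIXTURE",
    "TYPE2_MIXTURE",
]

# default SBE mixtures echoing the two activity regimes: component medians
# 2 and 35 spikes/electrode; the large-burst peak spans roughly 20-40
TYPE1_MIXTURE: List[Tuple[float, float, float]] = [(0.6, 2.0, 0.5), (0.4, 35.0, 0.25)]
TYPE2_MIXTURE: List[Tuple[float, float, float]] = [(1.0, 2.0, 0.5)]


@dataclass
class SynthConfig:
    """Study conditions for one synthetic recording.

    ``sbe_mixture`` is a list of (weight, median, log_sd) log-normal
    components.  ``bd_a_ms_per_spike``/``bd_b_ms`` set BD = a*SBE + b with
    multiplicative jitter ``bd_jitter_frac``.  ``propagation_prob`` is the
    per-burst Source->Target propagation probability; setting
    ``prop_prob_slope`` switches to a logistic dependence on SBE around
    ``prop_prob_midpoint``.  ``propagation_lag_ms`` (mean, sd) is the Source->Target
    propagation delay: one delay per recording is drawn from it (a
    culture's intermodular conduction path is fixed, so the delay is a
    property of the recording, not of the burst) and each propagated burst
    adds ``prop_onset_jitter_ms`` of per-burst jitter; the per-recording
    delay is therefore also the planted intermodular pairwise CFP lag.
    ``intramodular_lag_ms`` (mean, sd) sets the planted early->late
    pairwise lag within each module.
    """

    n_source_electrodes: int = 8
    n_target_electrodes: int = 8
    duration_s: float = 600.0
    sample_rate_hz: float = 20000.0
    background_rate_hz_per_electrode: float = 0.2
    burst_rate_per_min: float = 6.0
    min_burst_separation_s: float = 1.0
    sbe_mixture: List[Tuple[float, float, float]] = field(
        default_factory=lambda: list(TYPE1_MIXTURE)
    )
    bd_a_ms_per_spike: float = 7.5
    bd_b_ms: float = 28.5
    bd_jitter_frac: float = 0.10
    propagation_prob: float = 0.27
    prop_prob_slope: Optional[float] = None
    prop_prob_midpoint: float = 10.0
    propagation_lag_ms: Tuple[float, float] = (20.0, 5.0)
    prop_onset_jitter_ms: float = 1.0
    intramodular_lag_ms: Tuple[float, float] = (4.0, 1.0)
    spike_jitter_ms: float = 0.3
    target_burst_rate_per_min: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_source_electrodes < 1 or self.n_target_electrodes < 1:
            raise ValidationError("each module needs at least one electrode")
        if not (self.duration_s > 0):
            raise ValidationError("duration_s must be positive")
        w = sum(c[0] for c in self.sbe_mixture)
        if self.sbe_mixture and abs(w - 1.0) > 1e-9:
            raise ValidationError(f"mixture weights must sum to 1, got {w}")
        if not (0.0 <= self.propagation_prob <= 1.0):
            raise ValidationError("propagation_prob must be in [0, 1]")
        if self.background_rate_hz_per_electrode < 0:
            raise ValidationError("background rate must be >= 0")
        if self.burst_rate_per_min < 0 or self.target_burst_rate_per_min < 0:
            raise ValidationError("burst rates must be >= 0")
        if self.burst_rate_per_min > 0:
            mean_gap = 60.0 / self.burst_rate_per_min
            max_med = max((c[1] for c in self.sbe_mixture), default=0.0)
            typ_bd_s = (self.bd_a_ms_per_spike * max_med + self.bd_b_ms) * 1e-3
            if mean_gap <= self.min_burst_separation_s or mean_gap < 2.0 * typ_bd_s:
                raise GenerationError(
                    "infeasible config: burst durations/separation exceed the "
                    "mean inter-burst interval"
                )


@register_report_type
@dataclass
class PlantedBurst:
    module: str
    onset_s: float
    bd_ms: float
    sbe: float          # realized spikes-per-electrode
    n_spikes: int


@register_report_type
@dataclass
class GroundTruth:
    """Everything the pipeline is supposed to recover."""

    bursts: List[PlantedBurst]
    source_burst_indices: List[int]
    target_burst_indices: List[int]
    propagation_pairs: List[List[float]]   # [source_idx, target_idx, lag_ms]
    electrode_delays_ms: Dict[str, float]  # per-electrode event delay
    pair_lags_ms: Dict[str, float]         # "i->j" -> planted CFP lag
    background_rate_hz_per_electrode: float


def _electrode_ids(prefix: str, n: int) -> List[str]:
    return [f"{prefix}{k+1:02d}" for k in range(n)]


def _renewal_onsets(rng, rate_per_min: float, duration_s: float, min_sep: float,
                    margin_s: float) -> np.ndarray:
    """Hard-core renewal process: gap = min_sep + Exp(mean_gap - min_sep)."""
    if rate_per_min <= 0:
        return np.empty(0)
    mean_gap = 60.0 / rate_per_min
    exp_mean = max(mean_gap - min_sep, 1e-3)
    onsets = []
    t = float(rng.uniform(0, mean_gap))
    while t < duration_s - margin_s:
        onsets.append(t)
        t += min_sep + float(rng.exponential(exp_mean))
    return np.asarray(onsets)


def _module_delays(rng, ids: List[str], intra_mean: float, intra_sd: float) -> Dict[str, float]:
    """Early half fires at the event time, late half after the intramodular lag."""
    half = len(ids) // 2
    delays = {}
    for k, e in enumerate(ids):
        if k < max(half, 1) and len(ids) > 1:
            delays[e] = 0.0
        else:
            delays[e] = max(0.5, float(rng.normal(intra_mean, intra_sd)))
    if len(ids) == 1:
        delays[ids[0]] = 0.0
    return delays


def _burst_spikes(rng, events_s: np.ndarray, ids: List[str],
                  delays_ms: Dict[str, float], p: float, jitter_ms: float,
                  out: Dict[str, list]) -> int:
    """Plant one burst's spikes; returns the number of spikes placed."""
    n = 0
    fire = rng.random((len(ids), events_s.size)) < p
    if not fire.any():
        fire[0, 0] = True  # a planted burst always contains >= 1 spike
    jit = rng.normal(0.0, jitter_ms * 1e-3, size=fire.shape)
    for r, e in enumerate(ids):
        sel = fire[r]
        if sel.any():
            t = events_s[sel] + delays_ms[e] * 1e-3 + jit[r, sel]
            out[e].append(t)
            n += int(sel.sum())
    return n


def generate_recording(cfg: SynthConfig) -> Tuple[SpikeTrainSet, GroundTruth]:
    """Generate one recording plus the ground truth planted into it."""
    rng = np.random.default_rng(cfg.seed)
    src_ids = _electrode_ids("S", cfg.n_source_electrodes)
    tgt_ids = _electrode_ids("T", cfg.n_target_electrodes)

    intra_mean, intra_sd = cfg.intramodular_lag_ms
    prop_mean, prop_sd = cfg.propagation_lag_ms
    # one intermodular conduction delay per recording
    delta_rec_ms = max(5.0, float(rng.normal(prop_mean, prop_sd)))
    delays = {}
    delays.update(_module_delays(rng, src_ids, intra_mean, intra_sd))
    delays.update(_module_delays(rng, tgt_ids, intra_mean, intra_sd))

    max_med = max((c[1] for c in cfg.sbe_mixture), default=0.0)
    margin = (cfg.bd_a_ms_per_spike * 3 * max_med + cfg.bd_b_ms + delta_rec_ms + 10.0) * 1e-3
    onsets = _renewal_onsets(rng, cfg.burst_rate_per_min, cfg.duration_s,
                             cfg.min_burst_separation_s, margin)

    spikes: Dict[str, list] = {e: [] for e in src_ids + tgt_ids}
    bursts: List[PlantedBurst] = []
    src_idx: List[int] = []
    tgt_idx: List[int] = []
    prop_pairs: List[List[float]] = []

    weights = np.asarray([c[0] for c in cfg.sbe_mixture]) if cfg.sbe_mixture else None

    for onset in onsets:
        comp = int(rng.choice(len(cfg.sbe_mixture), p=weights))
        _, med, lsd = cfg.sbe_mixture[comp]
        sbe = float(np.exp(rng.normal(np.log(med), lsd)))
        bd_ms = (cfg.bd_a_ms_per_spike * sbe + cfg.bd_b_ms) * max(
            0.2, 1.0 + float(rng.normal(0.0, cfg.bd_jitter_frac))
        )
        bd_ms = max(bd_ms, 5.0)
        n_spk = max(1, int(round(sbe * cfg.n_source_electrodes)))
        n_events = max(1, int(np.ceil(n_spk / cfg.n_source_electrodes)))
        p = n_spk / (n_events * cfg.n_source_electrodes)
        if n_events == 1:
            events = np.asarray([onset])
        else:
            inner = np.sort(rng.uniform(0.0, bd_ms * 1e-3, n_events - 2)) if n_events > 2 else np.empty(0)
            events = onset + np.concatenate(([0.0], inner, [bd_ms * 1e-3]))
        n_placed = _burst_spikes(rng, events, src_ids, delays, p, cfg.spike_jitter_ms, spikes)
        if n_placed == 0:
            continue
        i_src = len(bursts)
        bursts.append(PlantedBurst("source", float(onset), float(bd_ms),
                                   n_placed / cfg.n_source_electrodes, n_placed))
        src_idx.append(i_src)

        if cfg.prop_prob_slope is not None:
            prob = 1.0 / (1.0 + np.exp(-cfg.prop_prob_slope * (sbe - cfg.prop_prob_midpoint)))
        else:
            prob = cfg.propagation_prob
        if rng.random() < prob:
            lag_ms = max(2.0, delta_rec_ms + float(rng.normal(0.0, cfg.prop_onset_jitter_ms)))
            t_events = events + lag_ms * 1e-3
            n_spk_t = max(1, int(round(sbe * cfg.n_target_electrodes)))
            p_t = min(1.0, n_spk_t / (n_events * cfg.n_target_electrodes))
            n_placed_t = _burst_spikes(rng, t_events, tgt_ids, delays, p_t,
                                       cfg.spike_jitter_ms, spikes)
            if n_placed_t:
                i_tgt = len(bursts)
                bursts.append(PlantedBurst("target", float(onset + lag_ms * 1e-3),
                                           float(bd_ms),
                                           n_placed_t / cfg.n_target_electrodes,
                                           n_placed_t))
                tgt_idx.append(i_tgt)
                prop_pairs.append([float(i_src), float(i_tgt), lag_ms])

    # independent (non-propagated) Target bursts, off by default
    if cfg.target_burst_rate_per_min > 0:
        t_onsets = _renewal_onsets(rng, cfg.target_burst_rate_per_min, cfg.duration_s,
                                   cfg.min_burst_separation_s, margin)
        existing = np.sort([bursts[i].onset_s for i in tgt_idx])
        for onset in t_onsets:
            k = np.searchsorted(existing, onset)
            near = [existing[m] for m in (k - 1, k) if 0 <= m < existing.size]
            if any(abs(onset - x) < cfg.min_burst_separation_s for x in near):
                continue
            comp = int(rng.choice(len(cfg.sbe_mixture), p=weights))
            _, med, lsd = cfg.sbe_mixture[comp]
            sbe = float(np.exp(rng.normal(np.log(med), lsd)))
            bd_ms = max(5.0, (cfg.bd_a_ms_per_spike * sbe + cfg.bd_b_ms)
                        * max(0.2, 1.0 + float(rng.normal(0.0, cfg.bd_jitter_frac))))
            n_spk = max(1, int(round(sbe * cfg.n_target_electrodes)))
            n_events = max(1, int(np.ceil(n_spk / cfg.n_target_electrodes)))
            p = n_spk / (n_events * cfg.n_target_electrodes)
            if n_events == 1:
                events = np.asarray([onset])
            else:
                inner = np.sort(rng.uniform(0.0, bd_ms * 1e-3, n_events - 2)) if n_events > 2 else np.empty(0)
                events = onset + np.concatenate(([0.0], inner, [bd_ms * 1e-3]))
            n_placed = _burst_spikes(rng, events, tgt_ids, delays, p,
                                     cfg.spike_jitter_ms, spikes)
            if n_placed:
                tgt_idx.append(len(bursts))
                bursts.append(PlantedBurst("target", float(onset), float(bd_ms),
                                           n_placed / cfg.n_target_electrodes, n_placed))

    # independent Poisson background on every electrode
    bg = cfg.background_rate_hz_per_electrode
    if bg > 0:
        for e in src_ids + tgt_ids:
            n = rng.poisson(bg * cfg.duration_s)
            spikes[e].append(rng.uniform(0.0, cfg.duration_s, n))

    final: Dict[str, np.ndarray] = {}
    for e in src_ids + tgt_ids:
        t = np.concatenate(spikes[e]) if spikes[e] else np.empty(0)
        t = np.unique(np.clip(t, 0.0, cfg.duration_s))
        final[e] = t

    # planted pairwise CFP lags: within a module the early->late delay
    # difference; across modules the propagation delay plus the delay
    # difference (only lags > 0 are observable)
    pair_lags: Dict[str, float] = {}
    for mod_ids in (src_ids, tgt_ids):
        for a in mod_ids:
            for b in mod_ids:
                if a != b and delays[b] - delays[a] > 0:
                    pair_lags[f"{a}->{b}"] = delays[b] - delays[a]
    for a in src_ids:
        for b in tgt_ids:
            pair_lags[f"{a}->{b}"] = delta_rec_ms + delays[b] - delays[a]

    sts = SpikeTrainSet(final, duration_s=cfg.duration_s, sample_rate_hz=cfg.sample_rate_hz)
    gt = GroundTruth(
        bursts=bursts,
        source_burst_indices=src_idx,
        target_burst_indices=tgt_idx,
        propagation_pairs=prop_pairs,
        electrode_delays_ms={e: float(d) for e, d in delays.items()},
        pair_lags_ms=pair_lags,
        background_rate_hz_per_electrode=bg,
    )
    return sts, gt


def make_electrode_map(cfg: SynthConfig):
    """ElectrodeMap matching generate_recording's electrode naming."""
    from .io_core import ElectrodeMap

    assignment = {e: "source" for e in _electrode_ids("S", cfg.n_source_electrodes)}
    assignment.update({e: "target" for e in _electrode_ids("T", cfg.n_target_electrodes)})
    return ElectrodeMap(assignment)


def _spike_kernel(sr: float) -> Tuple[np.ndarray, int]:
    """Stereotyped biphasic waveform (unit trough amplitude) and trough index."""
    neg = max(2, int(round(0.4e-3 * sr)))
    pos = max(2, int(round(0.5e-3 * sr)))
    w = np.concatenate([
        -np.sin(np.pi * np.arange(neg) / neg),
        0.4 * np.sin(np.pi * np.arange(pos) / pos),
    ])
    return w, int(np.argmin(w))


def generate_raw(
    cfg: SynthConfig,
    sts: SpikeTrainSet,
    noise_sd_uV: float,
    spike_amp_uV: float,
    seed: Optional[int] = None,
) -> RawRecording:
    """Gaussian noise plus a biphasic waveform at every spike time.

    The waveform trough lands on the spike's sample, so threshold detection
    recovers the planted times to within one sample on noise-free traces.
    """
    if not (spike_amp_uV > 0):
        raise ValidationError("spike_amp_uV must be positive")
    if noise_sd_uV < 0:
        raise ValidationError("noise_sd_uV must be >= 0")
    sr = cfg.sample_rate_hz
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n = int(round(sts.duration_s * sr))
    kernel, k0 = _spike_kernel(sr)
    traces = {}
    for e, times in sts.spikes.items():
        x = rng.normal(0.0, noise_sd_uV, n) if noise_sd_uV > 0 else np.zeros(n)
        for t in times:
            c = int(round(t * sr))
            lo = c - k0
            hi = lo + kernel.size
            klo = max(0, -lo)
            khi = kernel.size - max(0, hi - n)
            if khi > klo:
                x[lo + klo : lo + khi] += spike_amp_uV * kernel[klo:khi]
        traces[e] = x
    return RawRecording(traces, sample_rate_hz=sr)
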