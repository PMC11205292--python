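"""Threshold spike detection on raw extracellular traces.

The threshold is a multiple of a robust noise estimate derived from the
signal median, sigma = median(|x|) / 0.6745 (0.6745 is the 75th percentile
of the standard normal, so for pure Gaussian noise the estimator converges
to the noise standard deviation while remaining insensitive to the rare,
large spike deflections).  Extracellular spikes are predominantly negative
deflections, hence the negative default polarity.  Crossings within the
dead time of an accepted spike are suppressed and the reported time is the
extremum inside the dead-time window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

from .errors import ConfigurationError, ValidationError
from .io_core import RawRecording, SpikeTrainSet

__all__ = ["SpikeDetectionParams", "estimate_noise_sigma", "detect_spikes"]

_NORM_Q75 = 0.6745


@dataclass
class SpikeDetectionParams:
    """Configuration for threshold spike detection.

    threshold_factor : multiples of the robust noise sigma (default 8).
    dead_time_ms : refractory window after an accepted spike (default 1.0).
    polarity : 'negative', 'positive' or 'both' (default 'negative').
    bandpass_hz : optional (low, high) causal Butterworth band-pass applied
        before detection; off by default.
    """

    threshold_factor: float = 8.0
    dead_time_ms: float = 1.0
    polarity: str = "negative"
    bandpass_hz: Optional[Tuple[float, float]] = None
    bandpass_order: int = 2

    def __post_init__(self) -> None:
        if not (self.threshold_factor > 0):
            raise ValidationError("threshold_factor must be > 0")
        if not (self.dead_time_ms > 0):
            raise ValidationError("dead_time_ms must be > 0")
        if self.polarity not in ("negative", "positive", "both"):
            raise ValidationError(f"unknown polarity {self.polarity!r}")


def estimate_noise_sigma(trace: np.ndarray) -> float:
    """Robust noise standard deviation: median(|x|) / 0.6745."""
    x = np.asarray(trace, dtype=float)
    if x.size == 0:
        raise ValidationError("cannot estimate noise on an empty trace")
    return float(np.median(np.abs(x)) / _NORM_Q75)


def _bandpass(x: np.ndarray, sr: float, low: float, high: float, order: int) -> np.ndarray:
    from scipy.signal import butter, lfilter

    nyq = sr / 2.0
    b, a = butter(order, [low / nyq, high / nyq], btype="band")
    return lfilter(b, a, x)


def _detect_on_trace(x: np.ndarray, sr: float, params: SpikeDetectionParams) -> np.ndarray:
    sigma = estimate_noise_sigma(x)
    thr = params.threshold_factor * sigma
    if params.polarity == "negative":
        supra = x < -thr
    elif params.polarity == "positive":
        supra = x > thr
    else:
        supra = np.abs(x) > thr
    candidates = np.flatnonzero(supra)
    if candidates.size == 0:
        return np.empty(0, dtype=float)
    dead = max(1, int(round(params.dead_time_ms * 1e-3 * sr)))
    out = []
    pos = 0
    n_cand = candidates.size
    while pos < n_cand:
        i = candidates[pos]
        window = x[i : i + dead]
        if params.polarity == "negative":
            ext = i + int(np.argmin(window))
        elif params.polarity == "positive":
            ext = i + int(np.argmax(window))
        else:
            ext = i + int(np.argmax(np.abs(window)))
        out.append(ext)
        # next accepted crossing must start after the dead time of the extremum
        pos = int(np.searchsorted(candidates, ext + dead, side="left"))
    return np.asarray(out, dtype=float) / sr


def detect_spikes(rec: RawRecording, params: Optional[SpikeDetectionParams] = None) -> SpikeTrainSet:
    """Detect multiunit spikes on every electrode of a raw recording."""
    if params is None:
        params = SpikeDetectionParams()
    if not getattr(rec, "sample_rate_hz", None):
        raise ConfigurationError("raw recording has no sample_rate_hz")
    sr = rec.sample_rate_hz
    spikes = {}
    for eid, trace in rec.traces.items():
        x = np.asarray(trace, dtype=float)
        if params.bandpass_hz is not None:
            low, high = params.bandpass_hz
            x = _bandpass(x, sr, low, high, params.bandpass_order)
        spikes[eid] = _detect_on_trace(x, sr, params)
    duration = rec.n_samples / sr if rec.n_samples else 1.0
    return SpikeTrainSet(spikes, duration_s=duration, sample_rate_hz=sr)
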