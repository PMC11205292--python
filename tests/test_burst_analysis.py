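import numpy as np
import pytest

from meamod import (
    Burst,
    BurstCatalog,
    BurstDetectionParams,
    ElectrodeMap,
    SpikeTrainSet,
    SynthConfig,
    ValidationError,
    burst_duration,
    burst_sbe,
    bursts_per_minute,
    detect_bursts,
    firing_rate,
    generate_recording,
    make_electrode_map,
)
from meamod.burst_analysis import _candidate_runs
from meamod.synthetic import TYPE2_MIXTURE
from tests.helpers import match_one_to_one


class TestFiringRate:
    def test_spikes_per_second_arithmetic(self):
        times = np.linspace(0.5, 599.5, 600)
        sts = SpikeTrainSet({"e1": times}, duration_s=600.0)
        emap = ElectrodeMap({"e1": "source"})
        assert firing_rate(sts, emap, "source") == pytest.approx(1.0)

    def test_no_spikes_is_zero(self):
        sts = SpikeTrainSet({"e1": np.array([])}, duration_s=600.0)
        emap = ElectrodeMap({"e1": "source"})
        assert firing_rate(sts, emap, "source") == 0.0

    def test_module_without_electrodes_rejected(self):
        sts = SpikeTrainSet({"e1": np.array([])}, duration_s=600.0)
        emap = ElectrodeMap({"e1": "source"})
        with pytest.raises(ValidationError):
            firing_rate(sts, emap, "target")

    def test_planted_rate_recovery(self):
        # 8 electrodes x 14.25 Hz background = 114 spikes/s planted
        cfg = SynthConfig(seed=21, burst_rate_per_min=0.0,
                          background_rate_hz_per_electrode=14.25)
        sts, _ = generate_recording(cfg)
        emap = make_electrode_map(cfg)
        rate = firing_rate(sts, emap, "source")
        lam = 114.0 * 600.0
        half = 2.576 * np.sqrt(lam) / 600.0  # Poisson 99% interval on the rate
        assert abs(rate - 114.0) <= half


class TestDetectBursts:
    def test_empty_spike_set(self):
        sts = SpikeTrainSet({"e1": np.array([]), "e2": np.array([])}, duration_s=60.0)
        emap = ElectrodeMap({"e1": "source", "e2": "source"})
        cat = detect_bursts(sts, emap, "source")
        assert len(cat) == 0

    def test_isolated_packet_is_one_burst(self):
        rng = np.random.default_rng(0)
        emap = ElectrodeMap({f"e{k}": "source" for k in range(4)})
        spikes = {}
        packet = np.sort(rng.uniform(5.0, 5.2, 50))
        for k in range(4):
            spikes[f"e{k}"] = packet[k::4]
        sts = SpikeTrainSet(spikes, duration_s=60.0)
        cat = detect_bursts(sts, emap, "source")
        assert len(cat) == 1
        assert cat.bursts[0].total_spikes == 50

    def test_planted_burst_recovery(self):
        cfg = SynthConfig(seed=5, burst_rate_per_min=12.0)
        sts, gt = generate_recording(cfg)
        cat = detect_bursts(sts, make_electrode_map(cfg), "source")
        planted = [gt.bursts[i].onset_s for i in gt.source_burst_indices]
        matched = match_one_to_one(planted, cat.onsets(), tol=0.05)
        assert matched / len(planted) >= 0.95

    def test_spike_conservation(self, default_recording):
        _, sts, _, emap = default_recording
        cat = detect_bursts(sts, emap, "source")
        for b in cat.bursts:
            for e, c in b.spike_counts.items():
                t = sts.spikes[e]
                direct = int(np.sum((t >= b.onset_s) & (t <= b.offset_s)))
                assert c == direct

    def test_relabeling_invariance(self, default_recording):
        _, sts, _, emap = default_recording
        cat = detect_bursts(sts, emap, "source")
        renamed = SpikeTrainSet(
            {f"x_{e}": t for e, t in sts.spikes.items()}, sts.duration_s, sts.sample_rate_hz
        )
        emap2 = ElectrodeMap({f"x_{e}": m for e, m in emap.assignment.items()})
        cat2 = detect_bursts(renamed, emap2, "source")
        assert np.allclose(cat.sbe_values(), cat2.sbe_values())
        assert np.allclose(cat.duration_values_ms(), cat2.duration_values_ms())

    def test_lower_threshold_extends_candidates(self):
        """Lowering the threshold can only grow the supra-threshold bin set;
        every high-threshold candidate run lies inside a low-threshold run."""
        rng = np.random.default_rng(2)
        counts = rng.poisson(1.0, 200)
        hi = _candidate_runs(counts, 3.0)
        lo = _candidate_runs(counts, 1.0)
        assert sum(b1 - b0 + 1 for b0, b1 in lo) >= sum(b1 - b0 + 1 for b0, b1 in hi)
        for b0, b1 in hi:
            assert any(l0 <= b0 and b1 <= l1 for l0, l1 in lo)

    def test_threshold_mode_exclusivity(self):
        with pytest.raises(ValidationError):
            BurstDetectionParams(threshold_per_electrode=0.25,
                                 rate_threshold_spikes_per_bin=2.0)
        with pytest.raises(ValidationError):
            BurstDetectionParams(threshold_per_electrode=None,
                                 rate_threshold_spikes_per_bin=None)


class TestBurstStatistics:
    def test_sbe_arithmetic(self):
        b = Burst("source", 1.0, 1.292, {"e1": 40, "e2": 30}, 2)
        assert burst_sbe(b) == pytest.approx(35.0)
        assert burst_duration(b) == pytest.approx(292.0)

    def test_sbe_partial_participation(self):
        b = Burst("source", 0.0, 0.1, {"e1": 3, "e2": 5, "e3": 0}, 10)
        assert burst_sbe(b) == pytest.approx(0.8)

    def test_zero_length_burst_rejected(self):
        with pytest.raises(ValidationError):
            Burst("source", 1.0, 1.0, {"e1": 5}, 1)

    def test_bursts_per_minute_arithmetic(self):
        bursts = [Burst("source", float(k), k + 0.1, {"e1": 5}, 1) for k in range(30)]
        cat = BurstCatalog("source", bursts, recording_minutes=10.0)
        assert bursts_per_minute(cat) == pytest.approx(3.0)
        assert bursts_per_minute(BurstCatalog("source", [], 10.0)) == 0.0

    def test_planted_burst_rate_recovery(self):
        """Mean detected bursts/min over 100 seeds close to the planted 6/min."""
        rates = []
        for seed in range(100):
            cfg = SynthConfig(seed=seed, sbe_mixture=list(TYPE2_MIXTURE),
                              background_rate_hz_per_electrode=0.0)
            sts, _ = generate_recording(cfg)
            cat = detect_bursts(sts, make_electrode_map(cfg), "source")
            rates.append(bursts_per_minute(cat))
        assert abs(np.mean(rates) - 6.0) <= 0.75

    def test_planted_bd_median_recovery(self):
        cfg = SynthConfig(seed=3, burst_rate_per_min=12.0)
        sts, gt = generate_recording(cfg)
        cat = detect_bursts(sts, make_electrode_map(cfg), "source")
        planted_md = np.median([gt.bursts[i].bd_ms for i in gt.source_burst_indices])
        detected_md = np.median(cat.duration_values_ms())
        assert abs(detected_md - planted_md) <= 50.0
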