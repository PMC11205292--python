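import numpy as np
import pytest

from meamod import (
    CFPCurve,
    CFPParams,
    ElectrodeMap,
    SpikeTrainSet,
    ValidationError,
    compute_cfp,
    connectivity_matrix,
    flatness_test,
)
from tests.helpers import cfp_oracle


class TestComputeCfp:
    def test_deterministic_lag(self, two_electrode_trains):
        c = compute_cfp(two_electrode_trains, "i", "j")
        curve = np.asarray(c.curve)
        assert curve[4] == pytest.approx(1.0)  # 4.5 ms lag -> bin (4, 5]
        assert np.all(curve[np.arange(50) != 4] == 0.0)
        assert c.connected
        assert c.strength == pytest.approx(1.0)
        assert c.latency_ms == pytest.approx(4.5)

    def test_silent_follower_not_connected(self):
        sts = SpikeTrainSet(
            {"i": np.arange(1.0, 101.0), "j": np.array([])}, duration_s=120.0
        )
        c = compute_cfp(sts, "i", "j")
        assert not c.connected
        assert max(c.curve) == 0.0

    def test_same_electrode_rejected(self, two_electrode_trains):
        with pytest.raises(ValidationError):
            compute_cfp(two_electrode_trains, "i", "i")

    def test_too_few_reference_spikes_undefined(self):
        sts = SpikeTrainSet({"i": np.array([1.0]), "j": np.array([2.0])}, duration_s=10.0)
        c = compute_cfp(sts, "i", "j")
        assert not c.defined and not c.connected

    def test_matches_counting_oracle_exactly(self):
        rng = np.random.default_rng(13)
        params = CFPParams()
        for trial in range(20):
            rate_i = rng.uniform(2, 30)
            rate_j = rng.uniform(2, 30)
            dur = 20.0
            ti = np.sort(rng.uniform(0, dur, rng.poisson(rate_i * dur)))
            tj = np.sort(rng.uniform(0, dur, rng.poisson(rate_j * dur)))
            ti, tj = np.unique(ti), np.unique(tj)
            sts = SpikeTrainSet({"i": ti, "j": tj}, duration_s=dur)
            c = compute_cfp(sts, "i", "j", params)
            if not c.defined:
                continue
            expected = cfp_oracle(ti, tj, params.bin_ms, params.n_bins)
            assert np.array_equal(np.asarray(c.curve), expected)

    def test_time_shift_invariance(self, two_electrode_trains):
        base = compute_cfp(two_electrode_trains, "i", "j")
        shift = 7.0
        shifted = SpikeTrainSet(
            {e: t + shift for e, t in two_electrode_trains.spikes.items()},
            duration_s=two_electrode_trains.duration_s + shift,
        )
        c = compute_cfp(shifted, "i", "j")
        assert c.curve == base.curve

    def test_curve_values_bounded(self):
        rng = np.random.default_rng(3)
        ti = np.unique(np.sort(rng.uniform(0, 10, 500)))
        tj = np.unique(np.sort(rng.uniform(0, 10, 2000)))
        c = compute_cfp(SpikeTrainSet({"i": ti, "j": tj}, duration_s=10.0), "i", "j")
        arr = np.asarray(c.curve)
        assert np.all((arr >= 0) & (arr <= 1))


class TestFlatnessTest:
    def _curve(self, values, n_ref=100):
        return CFPCurve("i", "j", list(values), n_ref, True, False, None, None)

    def test_all_zero_not_connected(self):
        assert not flatness_test(self._curve([0.0] * 50))

    def test_constant_positive_not_connected(self):
        assert not flatness_test(self._curve([0.3] * 50))

    def test_single_peak_connected(self):
        y = [0.0] * 50
        y[10] = 1.0
        assert flatness_test(self._curve(y))

    def test_peak_without_support_not_connected(self):
        # same shape but only 3 coincidences behind the peak
        y = [0.0] * 50
        y[10] = 1.0
        assert not flatness_test(self._curve(y, n_ref=3))

    def test_needs_three_bins(self):
        with pytest.raises(ValidationError):
            flatness_test(self._curve([0.0, 1.0]))


class TestConnectivityMatrix:
    def test_pair_combinatorics(self):
        rng = np.random.default_rng(0)
        spikes = {e: np.unique(np.sort(rng.uniform(0, 60, 200))) for e in "abcd"}
        sts = SpikeTrainSet(spikes, duration_s=60.0)
        emap = ElectrodeMap({"a": "source", "b": "source", "c": "target", "d": "target"})
        res = connectivity_matrix(sts, emap)
        assert len(res.intra_source) == 2
        assert len(res.intra_target) == 2
        assert len(res.source_to_target) == 4  # and no target->source pairs

    def test_single_electrode_module_has_empty_intra_group(self):
        rng = np.random.default_rng(1)
        spikes = {e: np.unique(np.sort(rng.uniform(0, 60, 200))) for e in "ab"}
        sts = SpikeTrainSet(spikes, duration_s=60.0)
        emap = ElectrodeMap({"a": "source", "b": "target"})
        res = connectivity_matrix(sts, emap)
        assert res.intra_source == []
        assert res.group_median_strength["intra_source"] is None
        assert len(res.source_to_target) == 1

    def test_planted_lag_ordering(self, default_recording):
        _, sts, gt, emap = default_recording
        res = connectivity_matrix(sts, emap)
        lat_intra = [c.latency_ms for grp in (res.intra_source, res.intra_target)
                     for c in grp if c.connected]
        lat_inter = [c.latency_ms for c in res.source_to_target if c.connected]
        assert lat_intra and lat_inter
        assert np.median(lat_intra) < np.median(lat_inter)

    def test_planted_pairwise_lag_recovery(self, default_recording):
        """Connected pairs' latencies agree with the planted lags to ~1.5 ms."""
        _, sts, gt, emap = default_recording
        res = connectivity_matrix(sts, emap)
        errs = []
        for c in res.source_to_target:
            if c.connected:
                errs.append(abs(c.latency_ms - gt.pair_lags_ms[f"{c.i}->{c.j}"]))
        assert errs and np.median(errs) <= 1.5
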