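import numpy as np
import pytest
from hypothesis import given, strategies as st

from meamod import (
    ActivityTypeParams,
    DegenerateInputError,
    InsufficientDataError,
    UndefinedIndexError,
    classify_activity,
    davies_bouldin,
    kmeans_1d,
)
from tests.helpers import (
    catalog_from_sbe,
    db_two_cluster_oracle,
    exhaustive_kmeans_wcss,
    wcss_of_labeling,
)


class TestKmeans1d:
    def test_symmetric_separation(self):
        labels, centroids = kmeans_1d([1, 1, 9, 9], k=2)
        assert list(labels) == [0, 0, 1, 1]
        assert list(centroids) == [1.0, 9.0]

    def test_optimal_split_of_four_points(self):
        # exhaustive check over the 3 contiguous splits puts {0,2} | {10,12}
        labels, centroids = kmeans_1d([0, 2, 10, 12], k=2)
        assert list(labels) == [0, 0, 1, 1]
        assert list(centroids) == [1.0, 11.0]

    def test_k1_is_global_mean(self):
        labels, centroids = kmeans_1d([3.0, 5.0, 10.0], k=1)
        assert list(labels) == [0, 0, 0]
        assert centroids[0] == pytest.approx(6.0)

    def test_too_few_distinct_values(self):
        with pytest.raises(DegenerateInputError):
            kmeans_1d([4.0, 4.0, 4.0], k=2)

    @pytest.mark.parametrize("k", [2, 3])
    def test_dp_attains_exhaustive_minimum(self, k):
        rng = np.random.default_rng(17)
        for _ in range(60):
            n = rng.integers(k + 1, 13)
            x = rng.normal(0, 10, n)
            labels, _ = kmeans_1d(x, k=k)
            assert wcss_of_labeling(x, labels) == pytest.approx(
                exhaustive_kmeans_wcss(x, k), rel=1e-12, abs=1e-9
            )

    def test_determinism(self):
        x = np.random.default_rng(5).normal(0, 1, 40)
        l1, c1 = kmeans_1d(x, k=2)
        l2, c2 = kmeans_1d(x, k=2)
        assert np.array_equal(l1, l2) and np.array_equal(c1, c2)


class TestDaviesBouldin:
    def test_zero_scatter(self):
        assert davies_bouldin([1, 1, 1, 5, 5, 5], [0, 0, 0, 1, 1, 1]) == 0.0

    @pytest.mark.parametrize("q", [1, 2])
    def test_hand_evaluated_value(self, q):
        # {0,2} vs {10,12}: s1 = s2 = 1 for both scatter exponents, d = 10
        assert davies_bouldin([0, 2, 10, 12], [0, 0, 1, 1], q=q) == pytest.approx(0.2)

    @pytest.mark.parametrize("q", [1, 2])
    def test_matches_closed_form_oracle(self, q):
        rng = np.random.default_rng(8)
        for _ in range(50):
            n = int(rng.integers(4, 40))
            x = rng.normal(0, 5, n)
            split = int(rng.integers(1, n))
            labels = np.array([0] * split + [1] * (n - split))
            xs = np.sort(x)
            if np.unique([xs[:split].mean(), xs[split:].mean()]).size < 2:
                continue
            assert davies_bouldin(xs, labels, q=q) == pytest.approx(
                db_two_cluster_oracle(xs, labels, q=q), rel=1e-12
            )

    @given(c=st.floats(min_value=1e-6, max_value=1e6))
    def test_scale_invariance(self, c):
        x = np.array([0.0, 2.0, 10.0, 12.0, 30.0])
        labels = np.array([0, 0, 1, 1, 1])
        assert davies_bouldin(x * c, labels) == pytest.approx(
            davies_bouldin(x, labels), rel=1e-9
        )

    def test_label_permutation_symmetry(self):
        x = np.array([0.0, 2.0, 10.0, 12.0])
        a = davies_bouldin(x, [0, 0, 1, 1])
        b = davies_bouldin(x, [1, 1, 0, 0])
        assert a == pytest.approx(b)

    def test_coincident_centroids_undefined(self):
        with pytest.raises(UndefinedIndexError):
            davies_bouldin([1.0, 3.0, 1.0, 3.0], [0, 0, 1, 1])


class TestClassifyActivity:
    def test_bimodal_is_type1_with_high_centroid_cluster(self):
        rng = np.random.default_rng(2)
        values = np.concatenate([
            np.exp(rng.normal(np.log(2.0), 0.4, 20)),
            np.exp(rng.normal(np.log(35.0), 0.25, 20)),
        ])
        res = classify_activity(catalog_from_sbe(values))
        assert res.decided_type == "type1"
        assert set(res.large_burst_indices) == set(range(20, 40))
        assert res.centroids[1] > res.centroids[0]

    def test_broad_unimodal_is_type2(self):
        rng = np.random.default_rng(4)
        values = np.exp(rng.normal(np.log(2.0), 0.5, 40))
        res = classify_activity(catalog_from_sbe(values))
        # the optimal split of this sample is not a valid two-cluster
        # structure under the DB <= 0.5 AND >= 10% rule
        assert res.decided_type == "type2"
        assert res.large_burst_indices == []

    def test_ten_percent_rule_forces_type2(self):
        values = [2.0 + 0.01 * k for k in range(39)] + [35.0]
        res = classify_activity(catalog_from_sbe(values))
        assert res.decided_type == "type2"

    def test_decision_is_exact_conjunction(self):
        rng = np.random.default_rng(6)
        values = np.concatenate([
            np.exp(rng.normal(np.log(2.0), 0.4, 30)),
            np.exp(rng.normal(np.log(35.0), 0.25, 10)),
        ])
        cat = catalog_from_sbe(values)
        res = classify_activity(cat)
        assert res.decided_type == "type1"
        # same data, but a min-fraction bar the 25% large cluster cannot meet
        res2 = classify_activity(cat, ActivityTypeParams(min_cluster_fraction=0.30))
        assert res2.decided_type == "type2"
        # same data, but a DB bar below the observed index
        res3 = classify_activity(cat, ActivityTypeParams(db_threshold=res.db_index * 0.5))
        assert res3.decided_type == "type2"

    def test_too_few_bursts(self):
        with pytest.raises(InsufficientDataError):
            classify_activity(catalog_from_sbe([1.0, 2.0, 3.0]))

    def test_constant_values_are_type2_with_undefined_db(self):
        res = classify_activity(catalog_from_sbe([2.0] * 20))
        assert res.decided_type == "type2"
        assert res.db_index is None

    def test_duration_feature(self):
        values = np.concatenate([np.full(20, 2.0) + np.arange(20) * 0.01,
                                 np.full(20, 35.0) + np.arange(20) * 0.01])
        res = classify_activity(
            catalog_from_sbe(values), ActivityTypeParams(feature="sbe")
        )
        assert res.decided_type == "type1"
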