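"""DTW k-means: recovery on separable data, determinism, validation indices."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score, davies_bouldin_score

from crt_cluster import cluster as clu, dtw


def two_groups(rng, n=10, length=20, centers=(2.0, 8.0), noise=0.1):
    data, labels = [], []
    for c, center in enumerate(centers):
        for _ in range(n):
            data.append(center + noise * rng.normal(size=length))
            labels.append(c)
    return data, np.array(labels)


class TestFit:
    def test_separated_groups_recovered_perfectly(self):
        data, truth = two_groups(np.random.default_rng(0))
        model = clu.fit(data, k=2, n_init=10, seed=3)
        assert adjusted_rand_score(truth, model.labels_) == 1.0

    def test_k1_barycenter_matches_dba_and_inertia_matches_objective(self):
        rng = np.random.default_rng(1)
        data = [rng.normal(size=12) for _ in range(6)]
        model = clu.fit(data, k=1, n_init=2, seed=0)
        expected = sum(dtw.dtw_sqdist(s, model.barycenters[0]) for s in data)
        assert model.inertia == pytest.approx(expected)
        assert model.summed_dtw == pytest.approx(
            sum(dtw.dtw_distance(s, model.barycenters[0]).distance for s in data))

    def test_inertia_history_monotone(self):
        rng = np.random.default_rng(5)
        data = [rng.normal(size=15) + (3.0 if i % 2 else 0.0)
                for i in range(14)]
        model = clu.fit(data, k=2, n_init=3, seed=1)
        assert np.all(np.diff(model.inertia_history_) <= 1e-9)

    def test_same_seed_reproduces_labels(self):
        rng = np.random.default_rng(7)
        data = [rng.normal(size=18) for _ in range(20)]
        a = clu.fit(data, k=3, n_init=5, seed=11)
        b = clu.fit(data, k=3, n_init=5, seed=11)
        assert np.array_equal(a.labels_, b.labels_)
        assert a.inertia == b.inertia

    def test_k_exceeding_dataset_rejected(self):
        with pytest.raises(ValueError):
            clu.fit([[1.0, 2.0]], k=2)

    def test_identical_dataset_warns(self):
        with pytest.warns(UserWarning, match="identical"):
            clu.fit([np.ones(5)] * 4, k=2, n_init=1, seed=0)

    def test_no_empty_clusters_with_distinct_series(self):
        rng = np.random.default_rng(2)
        data, _ = two_groups(rng, n=6)
        model = clu.fit(data, k=3, n_init=4, seed=5)
        assert set(model.labels_) == {0, 1, 2}


@pytest.fixture(scope="module")
def model():
    data, _ = two_groups(np.random.default_rng(4))
    return clu.fit(data, k=2, n_init=5, seed=2)


class TestAssign:

    def test_barycenters_map_to_their_own_label(self, model):
        for j, b in enumerate(model.barycenters):
            assert clu.assign(model, b) == j

    def test_invariant_to_duplicated_terminal_sample(self, model):
        rng = np.random.default_rng(9)
        for _ in range(50):
            s = rng.choice([2.0, 8.0]) + 0.1 * rng.normal(size=20)
            assert clu.assign(model, np.append(s, s[-1])) == clu.assign(model, s)


class TestValidation:
    def test_silhouette_high_for_separated_groups(self):
        data, _ = two_groups(np.random.default_rng(6), n=8)
        scores = clu.silhouette_sweep(data, k_range=[2], seed=0, n_init=3)
        assert scores.silhouette_by_k[2] > 0.9

    def test_silhouette_near_zero_without_structure(self):
        rng = np.random.default_rng(8)
        data = [1.0 + 0.3 * rng.normal(size=20) for _ in range(16)]
        scores = clu.silhouette_sweep(data, k_range=[2], seed=0, n_init=3)
        assert abs(scores.silhouette_by_k[2]) < 0.25

    def test_davies_bouldin_small_for_tight_far_clusters(self):
        data, truth = two_groups(np.random.default_rng(10), noise=0.01)
        model = clu.fit(data, k=2, n_init=3, seed=0)
        assert clu.davies_bouldin(data, model.labels_, model) < 0.1

    def test_davies_bouldin_grows_as_clusters_approach(self):
        rng = np.random.default_rng(11)
        dbs = []
        for gap in (6.0, 3.0, 1.5):
            data, truth = two_groups(rng, centers=(2.0, 2.0 + gap), noise=0.2)
            model = clu.fit(data, k=2, n_init=3, seed=1)
            dbs.append(clu.davies_bouldin(data, model.labels_, model))
        assert dbs[0] < dbs[1] < dbs[2]

    def test_davies_bouldin_matches_euclidean_reference_on_constant_series(self):
        """For constant equal-length series DTW reduces to Euclidean distance
        and the index must agree with the standard reference implementation."""
        rng = np.random.default_rng(12)
        length = 6
        values = np.concatenate([rng.normal(0, 0.3, 9), rng.normal(4, 0.3, 9)])
        data = [np.full(length, v) for v in values]
        labels = np.array([0] * 9 + [1] * 9)
        barys = [dtw.dba_barycenter([data[i] for i in np.where(labels == c)[0]])
                 for c in (0, 1)]
        model = clu.ClusterModel(k=2, barycenters=barys, n_init=1, max_iter=1,
                                 seed=0, inertia=0.0, summed_dtw=0.0)
        mine = clu.davies_bouldin(data, labels, model)
        ref = davies_bouldin_score(np.stack(data), labels)
        assert mine == pytest.approx(ref, rel=1e-6)

    def test_validation_scores_bounds_checked(self):
        with pytest.raises(ValueError):
            clu.ValidationScores(silhouette_by_k={2: 1.5})
        with pytest.raises(ValueError):
            clu.ValidationScores(silhouette_by_k={2: 0.5}, davies_bouldin=-0.1)


class TestCanonicalize:
    def test_relabel_by_ascending_mean(self):
        labels = np.array([0, 0, 1, 1, 2, 2])
        values = np.array([0.9, 0.8, 0.1, 0.2, 0.5, 0.5])
        new, mapping = clu.canonicalize_labels(labels, values)
        assert mapping == {1: 0, 2: 1, 0: 2}
        assert np.array_equal(new, [2, 2, 0, 0, 1, 1])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            clu.canonicalize_labels([0, 1], [0.1])
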