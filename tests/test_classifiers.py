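"""Accuracy arithmetic, KNN vs brute-force/scikit-learn oracles, and
Lloyd K-means vs exhaustive and scikit-learn references."""

import itertools

import numpy as np
import pytest
from sklearn.cluster import KMeans as SKKMeans
from sklearn.neighbors import KNeighborsClassifier

import rehabselect as rs
from rehabselect.classifiers import (
    ClassifierConfigError,
    ConfusionCounts,
    confusion_from_predictions,
    kmeans_inertia,
    kmeans_test_accuracy,
    knn_test_accuracy,
)


class TestAccuracy:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ((3, 2, 0, 0), 1.0),
            ((0, 0, 2, 3), 0.0),
            ((45, 30, 15, 10), 0.75),
            ((1, 0, 1, 0), 0.5),
        ],
    )
    def test_hand_computed_tables(self, counts, expected):
        assert rs.evaluate_accuracy(ConfusionCounts(*counts)) == expected

    def test_complement_identity(self, rng):
        for _ in range(50):
            tp, tn, fp, fn = rng.integers(0, 20, size=4)
            if tp + tn + fp + fn == 0:
                continue
            c = ConfusionCounts(int(tp), int(tn), int(fp), int(fn))
            acc = rs.evaluate_accuracy(c)
            assert 0.0 <= acc <= 1.0
            assert acc == pytest.approx(1 - (c.fp + c.fn) / c.total)

    def test_empty_evaluation_rejected(self):
        with pytest.raises(ValueError):
            rs.evaluate_accuracy(ConfusionCounts(0, 0, 0, 0))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(-1, 0, 0, 0)

    def test_confusion_from_predictions_counts(self):
        c = confusion_from_predictions([1, 1, 0, 0, 1], [1, 0, 0, 1, 1])
        assert (c.tp, c.tn, c.fp, c.fn) == (2, 1, 1, 1)


def _brute_force_knn(X, y, q, k):
    order = sorted(range(len(X)), key=lambda i: (float(np.sum((X[i] - q) ** 2)), i))
    votes = [y[i] for i in order[:k]]
    ones = sum(votes)
    return int(2 * ones > k)


class TestKNN:
    def test_simple_1d_majority(self):
        X = np.array([[0.0], [0.2], [1.0]])
        y = np.array([0, 0, 1])
        assert rs.knn_classify(X, y, np.array([0.1]), rs.KNNConfig(K=3)) == 0

    def test_k1_exact_match_returns_that_label(self, cohort):
        X, y = cohort.features, cohort.labels
        for i in (0, 17, 119):
            assert rs.knn_classify(X, y, X[i], rs.KNNConfig(K=1)) == y[i]

    def test_k1_nearer_point_wins(self):
        X = np.array([[0.0], [1.0]])
        y = np.array([0, 1])
        assert rs.knn_classify(X, y, np.array([0.4]), rs.KNNConfig(K=1)) == 0

    def test_matches_brute_force_oracle_on_random_instances(self, rng):
        for _ in range(1000):
            n = int(rng.integers(3, 15))
            d = int(rng.integers(1, 5))
            k = int(rng.choice([1, 3, 5]))
            if k > n:
                continue
            X = rng.normal(size=(n, d))
            y = rng.integers(0, 2, size=n)
            q = rng.normal(size=d)
            assert rs.knn_classify(X, y, q, rs.KNNConfig(K=k)) == \
                _brute_force_knn(X, y, q, k)

    def test_matches_sklearn_on_cohort_splits(self, cohort, rng):
        for k in (3, 5, 7, 11, 13):
            part = rs.random_partition(cohort, 0.6, int(rng.integers(1000)))
            from rehabselect.data import split_arrays
            Xtr, ytr, Xte, yte = split_arrays(cohort, part)
            sk = KNeighborsClassifier(n_neighbors=k).fit(Xtr, ytr)
            ours = rs.knn_classify(Xtr, ytr, Xte, rs.KNNConfig(K=k))
            # ties at the K-th distance are resolved differently; on
            # continuous synthetic features they are absent
            assert np.array_equal(ours, sk.predict(Xte))

    def test_k_exceeding_train_size_rejected(self):
        X = np.zeros((2, 16))
        with pytest.raises(ClassifierConfigError):
            rs.knn_classify(X, np.array([0, 1]), np.zeros(16), rs.KNNConfig(K=3))

    def test_even_k_tie_resolves_to_class_zero(self):
        X = np.array([[0.0], [1.0]])
        y = np.array([1, 0])
        assert rs.knn_classify(X, y, np.array([0.5]), rs.KNNConfig(K=2)) == 0

    def test_unsupported_metric_rejected(self):
        with pytest.raises(ClassifierConfigError):
            rs.KNNConfig(K=3, metric="manhattan")


def _exhaustive_2means_inertia(X):
    """Global 2-means optimum by enumerating all nonempty 2-partitions."""
    n = len(X)
    best = np.inf
    for bits in itertools.product((0, 1), repeat=n):
        if sum(bits) in (0, n):
            continue
        m = np.array(bits, bool)
        inertia = (np.sum((X[m] - X[m].mean(0)) ** 2)
                   + np.sum((X[~m] - X[~m].mean(0)) ** 2))
        best = min(best, inertia)
    return best


class TestKMeans:
    def test_two_well_separated_pairs(self):
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        model = rs.kmeans_fit(X, K=2, seed=0)
        centers = sorted(float(c[0]) for c in model.centroids)
        assert centers == pytest.approx([0.5, 10.5])

    def test_identical_points_k1(self):
        X = np.full((5, 3), 2.5)
        model = rs.kmeans_fit(X, K=1, seed=0)
        np.testing.assert_allclose(model.centroids[0], [2.5, 2.5, 2.5])

    def test_matches_exhaustive_optimum_small_instances(self, rng):
        for trial in range(30):
            n = int(rng.integers(4, 9))
            X = rng.normal(size=(n, 2)) * 3
            best = _exhaustive_2means_inertia(X)
            # Lloyd is a local method: take the best over all distinct
            # initial centroid pairs (deterministic restarts)
            fitted = min(
                kmeans_inertia(X, rs.kmeans_fit(X, K=2, init_indices=(i, j)))
                for i, j in itertools.combinations(range(n), 2)
            )
            assert fitted >= best - 1e-9
            assert fitted == pytest.approx(best, rel=1e-6)

    def test_objective_never_increases(self, rng):
        X = rng.normal(size=(30, 4))
        init_idx = np.random.default_rng(3).choice(30, size=2, replace=False)
        init = X[init_idx]
        init_inertia = kmeans_inertia(X, rs.KMeansModel(K=2, centroids=init.copy()))
        model = rs.kmeans_fit(X, K=2, seed=3)
        assert kmeans_inertia(X, model) <= init_inertia + 1e-12

    def test_comparable_to_sklearn_inertia(self, cohort):
        X = cohort.features
        ours = kmeans_inertia(X, rs.kmeans_fit(X, K=2, seed=0))
        sk = SKKMeans(n_clusters=2, n_init=10, random_state=0).fit(X)
        assert ours <= sk.inertia_ * 1.05

    def test_too_few_points_rejected(self):
        with pytest.raises(ClassifierConfigError):
            rs.kmeans_fit(np.zeros((1, 2)), K=2)


class TestClusterClassMapping:
    def _model(self, c0, c1):
        return rs.KMeansModel(K=2, centroids=np.array([[c0], [c1]], float))

    def test_majority_mapping(self):
        model = self._model(0.0, 10.0)
        X = np.array([[0.1], [0.2], [0.3], [10.0]])
        y = np.array([0, 0, 1, 1])
        model = rs.map_clusters_to_classes(model, X, y)
        assert model.cluster_to_class == {0: 0, 1: 1}

    def test_empty_cluster_maps_to_own_index(self):
        model = self._model(0.0, 100.0)
        X = np.array([[0.1], [0.2]])
        y = np.array([1, 1])
        model = rs.map_clusters_to_classes(model, X, y)
        assert model.cluster_to_class[1] == 1   # no members -> own index

    def test_tied_cluster_maps_to_own_index(self):
        model = self._model(0.0, 10.0)
        X = np.array([[0.1], [0.2], [9.9], [10.1]])
        y = np.array([0, 1, 0, 1])
        model = rs.map_clusters_to_classes(model, X, y)
        assert model.cluster_to_class == {0: 0, 1: 1}

    def test_nearest_centroid_rules(self):
        model = self._model(0.5, 10.5)
        model.cluster_to_class = {0: 0, 1: 1}
        assert rs.nearest_centroid_classify(model, np.array([2.0])) == 0
        assert rs.nearest_centroid_classify(model, np.array([5.5])) == 0  # tie
        assert rs.nearest_centroid_classify(model, np.array([10.5])) == 1


class TestEndToEndEvaluators:
    def test_separable_toy_is_perfect(self, toy_table):
        from rehabselect.data import split_arrays
        part = rs.random_partition(toy_table, 0.5, 3)
        Xtr, ytr, Xte, yte = split_arrays(toy_table, part)
        assert knn_test_accuracy(Xtr, ytr, Xte, yte, rs.KNNConfig(K=1)) == 1.0
        assert kmeans_test_accuracy(Xtr, ytr, Xte, yte, seed=0) == 1.0

    def test_standardize_flag_changes_geometry(self, cohort):
        from rehabselect.data import split_arrays
        part = rs.random_partition(cohort, 0.5, 11)
        Xtr, ytr, Xte, yte = split_arrays(cohort, part)
        raw = knn_test_accuracy(Xtr, ytr, Xte, yte, rs.KNNConfig(K=3))
        z = knn_test_accuracy(Xtr, ytr, Xte, yte, rs.KNNConfig(K=3),
                              standardize=True)
        assert 0.0 <= raw <= 1.0 and 0.0 <= z <= 1.0
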