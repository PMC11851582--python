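"""Base learners: accuracy, K-nearest neighbors, and 2-means classification.

Both classifiers operate on raw (unstandardized) feature values by default;
pass ``standardize=True`` to the convenience evaluators for a z-scored
sensitivity check.  Distances are Euclidean; other metric tags raise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class ClassifierConfigError(ValueError):
    """Raised for inconsistent classifier configuration (e.g. K > |train|)."""


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion-table counts for one evaluation."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion_from_predictions(y_true, y_pred) -> ConfusionCounts:
    """Count tp/tn/fp/fn treating class 1 as positive."""
    t = np.asarray(y_true, dtype=np.int64)
    p = np.asarray(y_pred, dtype=np.int64)
    if t.shape != p.shape:
        raise ValueError("y_true and y_pred differ in length")
    return ConfusionCounts(
        tp=int(np.sum((t == 1) & (p == 1))),
        tn=int(np.sum((t == 0) & (p == 0))),
        fp=int(np.sum((t == 0) & (p == 1))),
        fn=int(np.sum((t == 1) & (p == 0))),
    )


def evaluate_accuracy(counts: ConfusionCounts) -> float:
    """Classification accuracy (tp + tn) / (tp + tn + fp + fn)."""
    if counts.total == 0:
        raise ValueError("accuracy undefined for an empty evaluation")
    return (counts.tp + counts.tn) / counts.total


@dataclass(frozen=True)
class KNNConfig:
    K: int = 3
    metric: str = "euclidean"

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ClassifierConfigError(f"K must be >= 1, got {self.K}")
        if self.metric != "euclidean":
            raise ClassifierConfigError(f"unsupported metric '{self.metric}'")


def knn_classify(X_train, y_train, query, config: KNNConfig = KNNConfig()):
    """Majority vote among the K nearest training cases (Euclidean distance).

    Neighbors are ranked by (distance, training order) so ties at the K-th
    neighbor resolve deterministically.  For even K a tied vote resolves to
    class 0; odd K cannot tie on a binary problem.  *query* may be a single
    vector or a (M, d) matrix; the return matches.
    """
    X = np.asarray(X_train, dtype=float)
    y = np.asarray(y_train, dtype=np.int64)
    if X.shape[0] == 0:
        raise ClassifierConfigError("empty training set")
    if config.K > X.shape[0]:
        raise ClassifierConfigError(
            f"K={config.K} exceeds training-set size {X.shape[0]}"
        )
    Q = np.asarray(query, dtype=float)
    single = Q.ndim == 1
    Q = np.atleast_2d(Q)
    # (M, n) distance matrix; stable argsort keeps training order on ties
    d2 = np.sum((Q[:, None, :] - X[None, :, :]) ** 2, axis=2)
    order = np.argsort(d2, axis=1, kind="stable")[:, : config.K]
    votes = y[order].sum(axis=1)
    pred = (2 * votes > config.K).astype(np.int64)
    return int(pred[0]) if single else pred


@dataclass
class KMeansModel:
    """Fitted centroids plus a cluster-index -> class-label map."""

    K: int
    centroids: np.ndarray                      # (K, d)
    cluster_to_class: dict[int, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "K": self.K,
            "centroids": self.centroids.tolist(),
            "cluster_to_class": {str(k): v for k, v in self.cluster_to_class.items()},
        }


def _assign(points: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    d2 = np.sum((points[:, None, :] - centroids[None, :, :]) ** 2, axis=2)
    return np.argmin(d2, axis=1)   # argmin takes the lower index on ties


def kmeans_fit(points, K: int = 2, seed=0, max_iter: int = 100,
               tol: float = 1e-6, init_indices=None) -> KMeansModel:
    """Lloyd's algorithm: alternate nearest-centroid assignment and mean update.

    Centroids initialize from K distinct points sampled by the seeded
    generator (or taken from *init_indices* for deterministic restarts); a
    cluster emptied during iteration is re-seeded with the point currently
    farthest from its own centroid.  Stops at an assignment fixed-point, a
    centroid shift below *tol*, or *max_iter* sweeps; the within-cluster sum
    of squares never increases across sweeps.
    """
    X = np.asarray(points, dtype=float)
    n = X.shape[0]
    if K < 1:
        raise ClassifierConfigError(f"K must be >= 1, got {K}")
    if n < K:
        raise ClassifierConfigError(f"need at least K={K} points, got {n}")
    if init_indices is not None:
        idx = np.asarray(init_indices, dtype=np.int64)
        if idx.shape != (K,) or len(np.unique(idx)) != K:
            raise ClassifierConfigError("init_indices must name K distinct points")
        centroids = X[idx].copy()
    else:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        centroids = X[rng.choice(n, size=K, replace=False)].copy()
    assign = _assign(X, centroids)
    for _ in range(max_iter):
        new_centroids = centroids.copy()
        for c in range(K):
            members = X[assign == c]
            if len(members):
                new_centroids[c] = members.mean(axis=0)
            else:
                dist_own = np.sum((X - centroids[assign]) ** 2, axis=1)
                new_centroids[c] = X[int(np.argmax(dist_own))]
        shift = float(np.max(np.sqrt(np.sum((new_centroids - centroids) ** 2, axis=1))))
        centroids = new_centroids
        new_assign = _assign(X, centroids)
        if np.array_equal(new_assign, assign) or shift < tol:
            assign = new_assign
            break
        assign = new_assign
    return KMeansModel(K=K, centroids=centroids)


def kmeans_inertia(points, model: KMeansModel) -> float:
    """Within-cluster sum of squared distances under the model's assignment."""
    X = np.asarray(points, dtype=float)
    assign = _assign(X, model.centroids)
    return float(np.sum((X - model.centroids[assign]) ** 2))


def map_clusters_to_classes(model: KMeansModel, X_train, y_train) -> KMeansModel:
    """Map each cluster to the majority class of its training members.

    An empty cluster, or a tied vote, maps to the cluster's own index — a
    deterministic fallback that keeps the model total.
    """
    X = np.asarray(X_train, dtype=float)
    y = np.asarray(y_train, dtype=np.int64)
    assign = _assign(X, model.centroids)
    mapping: dict[int, int] = {}
    for c in range(model.K):
        members = y[assign == c]
        if len(members) == 0:
            mapping[c] = c
            continue
        ones = int(members.sum())
        zeros = len(members) - ones
        mapping[c] = c if ones == zeros else int(ones > zeros)
    model.cluster_to_class = mapping
    return model


def nearest_centroid_classify(model: KMeansModel, query):
    """Assign queries to the nearest centroid and return the mapped class."""
    if not model.cluster_to_class:
        raise ClassifierConfigError("model has no cluster-to-class mapping")
    Q = np.asarray(query, dtype=float)
    single = Q.ndim == 1
    Q = np.atleast_2d(Q)
    clusters = _assign(Q, model.centroids)
    classes = np.array([model.cluster_to_class[int(c)] for c in clusters],
                       dtype=np.int64)
    return int(classes[0]) if single else classes


def _maybe_standardize(X_train, X_test, standardize: bool):
    if not standardize:
        return X_train, X_test
    mu = X_train.mean(axis=0)
    sd = X_train.std(axis=0)
    sd[sd == 0] = 1.0
    return (X_train - mu) / sd, (X_test - mu) / sd


def knn_test_accuracy(X_train, y_train, X_test, y_test,
                      config: KNNConfig = KNNConfig(),
                      standardize: bool = False) -> float:
    """Train-free KNN evaluation: accuracy of the vote on the test side."""
    Xtr, Xte = _maybe_standardize(np.asarray(X_train, float),
                                  np.asarray(X_test, float), standardize)
    pred = knn_classify(Xtr, y_train, Xte, config)
    return evaluate_accuracy(confusion_from_predictions(y_test, pred))


def kmeans_test_accuracy(X_train, y_train, X_test, y_test, seed=0,
                         standardize: bool = False) -> float:
    """2-means on the training side, majority mapping, nearest-centroid test."""
    Xtr, Xte = _maybe_standardize(np.asarray(X_train, float),
                                  np.asarray(X_test, float), standardize)
    model = kmeans_fit(Xtr, K=2, seed=seed)
    model = map_clusters_to_classes(model, Xtr, y_train)
    pred = nearest_centroid_classify(model, Xte)
    return evaluate_accuracy(confusion_from_predictions(y_test, pred))
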