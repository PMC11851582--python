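"""GA clustering classifier (GAClust).

A binary genome of length S assigns each training case to cluster 0 or 1.
The two cluster centroids (mean feature vectors) then classify the test set
by nearest centroid, with the cluster index taken directly as the predicted
class.  Fitness is the resulting test-set accuracy, maximized by the GA.

Measuring fitness on the test set follows the procedure this implements and
is optimistically biased as an estimate of out-of-sample performance; see
docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classifiers import confusion_from_predictions, evaluate_accuracy
from .ga import GAConfig, GARunTrace, evolve


@dataclass(frozen=True)
class ClusterAssignment:
    """A genome over the training set plus the centroids it induces.

    A centroid is ``None`` exactly when its cluster received no cases.
    """

    genome: np.ndarray
    centroid_0: np.ndarray | None
    centroid_1: np.ndarray | None

    def to_dict(self) -> dict:
        return {
            "genome": self.genome.astype(int).tolist(),
            "centroid_0": None if self.centroid_0 is None else self.centroid_0.tolist(),
            "centroid_1": None if self.centroid_1 is None else self.centroid_1.tolist(),
        }


def centroids_from_assignment(X_train, genome) -> ClusterAssignment:
    """Mean feature vector of each cluster named by the genome bits."""
    X = np.asarray(X_train, dtype=float)
    g = np.asarray(genome, dtype=np.uint8)
    if g.shape != (X.shape[0],):
        raise ValueError(
            f"genome length {g.shape[0]} does not match training size {X.shape[0]}"
        )
    c0 = X[g == 0].mean(axis=0) if np.any(g == 0) else None
    c1 = X[g == 1].mean(axis=0) if np.any(g == 1) else None
    return ClusterAssignment(genome=g.copy(), centroid_0=c0, centroid_1=c1)


def classify_by_assignment(assignment: ClusterAssignment, X_test) -> np.ndarray:
    """Nearest-centroid prediction; cluster index IS the predicted class.

    If one cluster is empty every test case receives the other cluster's
    class; exact ties on distance resolve to class 0.
    """
    Xt = np.atleast_2d(np.asarray(X_test, dtype=float))
    c0, c1 = assignment.centroid_0, assignment.centroid_1
    if c0 is None and c1 is None:
        raise ValueError("assignment has no cases at all")
    if c0 is None:
        return np.ones(Xt.shape[0], dtype=np.int64)
    if c1 is None:
        return np.zeros(Xt.shape[0], dtype=np.int64)
    d0 = np.sum((Xt - c0) ** 2, axis=1)
    d1 = np.sum((Xt - c1) ** 2, axis=1)
    return (d1 < d0).astype(np.int64)


def gaclust_fitness(genome, X_train, X_test, y_test) -> float:
    """Test-set accuracy of the nearest-centroid classifier the genome induces."""
    assignment = centroids_from_assignment(X_train, genome)
    pred = classify_by_assignment(assignment, X_test)
    return evaluate_accuracy(confusion_from_predictions(y_test, pred))


def run_gaclust(X_train, X_test, y_test,
                config: GAConfig = GAConfig()) -> tuple[ClusterAssignment, GARunTrace]:
    """Evolve cluster-assignment genomes of length |train|; return the best."""
    X = np.asarray(X_train, dtype=float)
    if X.shape[0] == 0 or np.asarray(X_test).shape[0] == 0:
        raise ValueError("train and test sets must be nonempty")
    best, trace = evolve(
        lambda g: gaclust_fitness(g, X, X_test, y_test), X.shape[0], config
    )
    return centroids_from_assignment(X, best), trace
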