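"""Hybrid instance-selection algorithms: GAKNN, GAKmeans, GA2Clust.

An outer GA evolves a membership genome of length N — gene 1 puts the case
in the training set, gene 0 in the test set — under the two-objective
fitness

    f = acc - alpha * S / N

where ``acc`` is the test-side accuracy of the wrapped evaluator (KNN,
2-means nearest-centroid, or an inner GA clustering run), ``S`` the number
of selected training cases, and ``alpha`` the weight trading accuracy
against training-set size.  Degenerate genomes (S = 0 or S = N) and
evaluator misconfiguration (e.g. K > S for KNN) score accuracy 0, keeping
the fitness total so the GA can escape.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, replace

import numpy as np

from . import classifiers
from .data import LabeledTable
from .ga import GAConfig, GARunTrace, evolve
from .gaclust import run_gaclust

logger = logging.getLogger(__name__)

_INT31 = 2**31


@dataclass(frozen=True)
class HybridFitnessConfig:
    """Which evaluator supplies ``acc`` and how strongly size is penalized."""

    alpha: float
    evaluator: str                       # "knn" | "kmeans" | "gaclust"
    knn_config: classifiers.KNNConfig | None = None
    kmeans_seed: int = 0
    inner_ga: GAConfig | None = None

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")
        if self.evaluator not in ("knn", "kmeans", "gaclust"):
            raise ValueError(f"unknown evaluator '{self.evaluator}'")
        if self.evaluator == "knn" and self.knn_config is None:
            raise ValueError("knn evaluator needs a KNNConfig")
        if self.evaluator == "gaclust" and self.inner_ga is None:
            raise ValueError("gaclust evaluator needs an inner GAConfig")


@dataclass
class SubsetResult:
    """Outcome of a hybrid run: the selected subset and its scores."""

    algorithm: str
    best_genome: np.ndarray
    S: int
    n_cases: int
    accuracy: float
    fitness: float
    alpha: float
    trace: GARunTrace
    train_ids: tuple[int, ...] = ()

    @property
    def train_fraction(self) -> float:
        return self.S / self.n_cases

    def to_dict(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "best_genome": self.best_genome.astype(int).tolist(),
            "S": self.S,
            "n_cases": self.n_cases,
            "train_fraction": self.train_fraction,
            "accuracy": self.accuracy,
            "fitness": self.fitness,
            "alpha": self.alpha,
            "train_ids": list(self.train_ids),
        }


def _genome_seed(outer_seed: int, genome: np.ndarray) -> int:
    """Deterministic sub-seed for inner stochastic evaluators, < 2^31."""
    crc = zlib.crc32(np.asarray(genome, dtype=np.uint8).tobytes())
    return (outer_seed * 1_000_003 + crc) % _INT31


def _split_by_genome(table: LabeledTable, genome: np.ndarray):
    bits = np.asarray(genome, dtype=bool)
    X, y = table.features, table.labels
    return X[bits], y[bits], X[~bits], y[~bits]


def subset_accuracy(genome, table: LabeledTable, config: HybridFitnessConfig,
                    outer_seed: int = 0) -> float:
    """Test-side accuracy of the configured evaluator for one membership genome.

    Returns 0.0 for degenerate genomes and for evaluator configurations the
    subset cannot support (logged at warning level).
    """
    g = np.asarray(genome, dtype=np.uint8)
    s = int(g.sum())
    n = table.n_cases
    if s == 0 or s == n:
        return 0.0
    Xtr, ytr, Xte, yte = _split_by_genome(table, g)
    try:
        if config.evaluator == "knn":
            return classifiers.knn_test_accuracy(Xtr, ytr, Xte, yte, config.knn_config)
        if config.evaluator == "kmeans":
            seed = _genome_seed(outer_seed ^ config.kmeans_seed, g)
            return classifiers.kmeans_test_accuracy(Xtr, ytr, Xte, yte, seed=seed)
        inner = replace(config.inner_ga, seed=_genome_seed(outer_seed, g))
        assignment, inner_trace = run_gaclust(Xtr, Xte, yte, inner)
        return max(inner_trace.best_fitness)
    except classifiers.ClassifierConfigError as exc:
        logger.warning("evaluator failed for S=%d: %s; scoring accuracy 0", s, exc)
        return 0.0


def hybrid_fitness(genome, table: LabeledTable, config: HybridFitnessConfig,
                   outer_seed: int = 0) -> tuple[float, float, int]:
    """(fitness, accuracy, S) for one membership genome under f = acc - alpha*S/N."""
    g = np.asarray(genome, dtype=np.uint8)
    s = int(g.sum())
    acc = subset_accuracy(g, table, config, outer_seed)
    return acc - config.alpha * s / table.n_cases, acc, s


class _CachedFitness:
    """Memoize fitness by exact bit string; inner runs are seeded from the
    genome so cached and fresh evaluations agree."""

    def __init__(self, table: LabeledTable, config: HybridFitnessConfig, seed: int):
        self.table = table
        self.config = config
        self.seed = seed
        self.cache: dict[bytes, float] = {}
        self.calls = 0
        self.evals = 0
        self.best_legal: np.ndarray | None = None
        self.best_legal_fitness = -np.inf

    def __call__(self, genome: np.ndarray) -> float:
        self.calls += 1
        g = np.asarray(genome, dtype=np.uint8)
        key = g.tobytes()
        if key not in self.cache:
            self.evals += 1
            self.cache[key] = hybrid_fitness(g, self.table, self.config,
                                             self.seed)[0]
        fit = self.cache[key]
        s = int(g.sum())
        if 0 < s < self.table.n_cases and fit > self.best_legal_fitness:
            self.best_legal_fitness = fit
            self.best_legal = g.copy()
        return fit


def _run_hybrid(table: LabeledTable, fit_config: HybridFitnessConfig,
                ga_config: GAConfig, algorithm: str) -> SubsetResult:
    if table.n_cases < 4:
        raise ValueError("need at least 4 cases for subset selection")
    cached = _CachedFitness(table, fit_config, ga_config.seed)
    best, trace = evolve(cached, table.n_cases, ga_config)
    # the reported subset must be a legal partition; degenerate genomes can
    # outrank legal ones under extreme alpha but are not usable selections
    if int(best.sum()) in (0, table.n_cases):
        if cached.best_legal is None:
            raise RuntimeError("no non-degenerate genome was ever evaluated")
        best = cached.best_legal
    fitness, accuracy, s = hybrid_fitness(best, table, fit_config, ga_config.seed)
    ids = tuple(int(i) for i in table.table.case_ids[np.asarray(best, bool)])
    return SubsetResult(
        algorithm=algorithm, best_genome=np.asarray(best, dtype=np.uint8),
        S=s, n_cases=table.n_cases, accuracy=accuracy, fitness=fitness,
        alpha=fit_config.alpha, trace=trace, train_ids=ids,
    )


def run_gaknn(table: LabeledTable, K: int = 3, alpha: float = 0.28,
              config: GAConfig = GAConfig(population_size=100, generations=100)
              ) -> SubsetResult:
    """Instance selection wrapped around a K-nearest-neighbors evaluator."""
    fit = HybridFitnessConfig(alpha=alpha, evaluator="knn",
                              knn_config=classifiers.KNNConfig(K=K))
    return _run_hybrid(table, fit, config, "gaknn")


def run_gakmeans(table: LabeledTable, alpha: float = 0.5,
                 config: GAConfig = GAConfig(population_size=100, generations=500)
                 ) -> SubsetResult:
    """Instance selection wrapped around the 2-means nearest-centroid evaluator."""
    fit = HybridFitnessConfig(alpha=alpha, evaluator="kmeans")
    return _run_hybrid(table, fit, config, "gakmeans")


def run_ga2clust(table: LabeledTable, alpha: float = 0.625,
                 outer: GAConfig = GAConfig(population_size=100, generations=100),
                 inner: GAConfig = GAConfig(population_size=20, generations=50)
                 ) -> SubsetResult:
    """Nested GA: the outer GA selects the subset, an inner GA clustering run
    on each induced split supplies the accuracy term."""
    fit = HybridFitnessConfig(alpha=alpha, evaluator="gaclust", inner_ga=inner)
    return _run_hybrid(table, fit, outer, "ga2clust")
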