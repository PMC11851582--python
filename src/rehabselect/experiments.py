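"""Training-fraction sweep harness, subset-count combinatorics, and report
writing (CSV always, plots optionally).

The sweep reproduces the replicated-split experiment design: for each
training fraction, many independent random partitions are drawn, the chosen
base learner is trained on the training side and scored on the test side,
and the per-fraction accuracy distribution is summarized by mean, standard
deviation, minimum, maximum and the count of perfect (accuracy = 1)
replicates.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import classifiers
from .data import LabeledTable, random_partition, split_arrays, train_fraction_size
from .ga import GARunTrace
from .selection import SubsetResult

DEFAULT_FRACTIONS = tuple(round(0.1 * k, 1) for k in range(1, 10))


def count_subsets(N: int, S: int) -> int:
    """Exact number of ways to choose S training cases out of N."""
    if not 0 <= S <= N:
        raise ValueError(f"S={S} out of range 0..{N}")
    return math.comb(N, S)


def total_search_space(N: int) -> tuple[int, int]:
    """(sum of C(N,S) over S=1..N-1, total genome count 2^N), both exact.

    The sum over non-degenerate training sizes has closed form 2^N - 2.
    """
    if N < 2:
        raise ValueError("N must be >= 2")
    return 2**N - 2, 2**N


@dataclass(frozen=True)
class SweepCell:
    """Accuracy summary for one (algorithm, fraction) combination."""

    algorithm: str
    fraction: float
    S: int
    replicates: int
    mean: float
    std: float
    min: float
    max: float
    perfect_count: int
    accuracies: tuple[float, ...] = ()


@dataclass(frozen=True)
class SweepResult:
    cells: tuple[SweepCell, ...]

    def cell(self, fraction: float) -> SweepCell:
        for c in self.cells:
            if abs(c.fraction - fraction) < 1e-12:
                return c
        raise KeyError(f"no cell for fraction {fraction}")


def phase1_sweep(table: LabeledTable, algorithm: str,
                 fractions=DEFAULT_FRACTIONS, replicates: int = 200,
                 seed: int = 0, K: int = 3,
                 keep_accuracies: bool = False) -> SweepResult:
    """Replicated random-split evaluation of a Phase-I base learner.

    ``algorithm`` is "knn" (with parameter K) or "kmeans" (K = 2 clusters,
    fresh seeded initialization per replicate).  All fractions are validated
    before any computation; identical seeds give identical results.
    """
    if algorithm not in ("knn", "kmeans"):
        raise ValueError(f"unknown algorithm '{algorithm}'")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    n = table.n_cases
    for f in fractions:
        s = train_fraction_size(n, f)
        if s < 1 or s > n - 1:
            raise ValueError(f"fraction {f} gives illegal training size {s}")
    knn_config = classifiers.KNNConfig(K=K)
    master = np.random.SeedSequence(seed).spawn(len(fractions))
    cells = []
    for f, ss in zip(fractions, master):
        rng = np.random.default_rng(ss)
        accs = np.empty(replicates)
        for r in range(replicates):
            part = random_partition(table, f, rng)
            Xtr, ytr, Xte, yte = split_arrays(table, part)
            if algorithm == "knn":
                accs[r] = classifiers.knn_test_accuracy(Xtr, ytr, Xte, yte, knn_config)
            else:
                accs[r] = classifiers.kmeans_test_accuracy(
                    Xtr, ytr, Xte, yte, seed=rng.integers(2**31)
                )
        cells.append(SweepCell(
            algorithm=algorithm, fraction=float(f),
            S=train_fraction_size(n, f), replicates=replicates,
            mean=float(accs.mean()), std=float(accs.std(ddof=0)),
            min=float(accs.min()), max=float(accs.max()),
            perfect_count=int(np.sum(accs == 1.0)),
            accuracies=tuple(accs) if keep_accuracies else (),
        ))
    return SweepResult(cells=tuple(cells))


def _write_csv(path: Path, header: list[str], rows: list[list]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        w.writerows(rows)


def write_reports(result, out_dir, prefix: str = "report",
                  plots: bool = False) -> list[Path]:
    """Write deterministic CSV reports (and optional plots) for a result.

    Accepts a SweepResult, a GARunTrace, or a SubsetResult; returns the list
    of files written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if isinstance(result, SweepResult):
        path = out / f"{prefix}_sweep.csv"
        _write_csv(
            path,
            ["algorithm", "fraction", "S", "replicates", "mean", "std",
             "min", "max", "perfect_count"],
            [[c.algorithm, c.fraction, c.S, c.replicates,
              f"{c.mean:.6f}", f"{c.std:.6f}", f"{c.min:.6f}", f"{c.max:.6f}",
              c.perfect_count] for c in result.cells],
        )
        written.append(path)
        if plots:
            written.append(_plot_sweep(result, out / f"{prefix}_sweep.png"))
    elif isinstance(result, GARunTrace):
        path = out / f"{prefix}_trace.csv"
        _write_csv(
            path,
            ["generation", "best_fitness", "mean_fitness", "best_popcount"],
            [[r["generation"], f"{r['best_fitness']:.6f}",
              f"{r['mean_fitness']:.6f}", r["best_popcount"]]
             for r in result.to_rows()],
        )
        written.append(path)
        if plots:
            written.append(_plot_trace(result, out / f"{prefix}_trace.png"))
    elif isinstance(result, SubsetResult):
        trace_path = out / f"{prefix}_trace.csv"
        _write_csv(
            trace_path,
            ["generation", "best_fitness", "mean_fitness", "best_S"],
            [[r["generation"], f"{r['best_fitness']:.6f}",
              f"{r['mean_fitness']:.6f}", r["best_popcount"]]
             for r in result.trace.to_rows()],
        )
        written.append(trace_path)
        ids_path = out / f"{prefix}_training_cases.txt"
        ids_path.write_text(" ".join(str(i) for i in result.train_ids) + "\n")
        written.append(ids_path)
        if plots:
            written.append(
                _plot_subset_trace(result, out / f"{prefix}_convergence.png")
            )
    else:
        raise TypeError(f"cannot report on {type(result).__name__}")
    return written


def _plot_sweep(result: SweepResult, path: Path) -> Path:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fracs = [c.fraction for c in result.cells]
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
    ax1.errorbar(fracs, [c.mean for c in result.cells],
                 yerr=[c.std for c in result.cells], fmt="o-", capsize=3)
    ax1.set_xlabel("training fraction")
    ax1.set_ylabel("accuracy")
    ax1.set_title("mean ± std")
    ax2.plot(fracs, [c.mean for c in result.cells], "r.-", label="mean")
    ax2.plot(fracs, [c.max for c in result.cells], "g.-", label="max")
    ax2.plot(fracs, [c.min for c in result.cells], "b.-", label="min")
    ax2.set_xlabel("training fraction")
    ax2.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return path


def _plot_trace(trace: GARunTrace, path: Path) -> Path:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(trace.best_fitness, label="best fitness")
    ax.plot(trace.mean_fitness, label="mean fitness")
    ax.set_xlabel("generation")
    ax.set_ylabel("fitness")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return path


def _plot_subset_trace(result: SubsetResult, path: Path) -> Path:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax1 = plt.subplots(figsize=(6, 4))
    ax1.plot(result.trace.best_fitness, "r-", label="best fitness")
    ax1.set_xlabel("generation")
    ax1.set_ylabel("fitness", color="r")
    ax2 = ax1.twinx()
    ax2.plot(result.trace.best_popcount, "b-", label="S")
    ax2.set_ylabel("training-set size S", color="b")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return path
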