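"""Generic binary genetic algorithm: roulette selection, uniform crossover,
bit-flip mutation, elitism, and the generation loop with trace recording.

Genomes are numpy uint8 bit vectors.  One master seed spawns independent
named streams (init, selection, crossover, mutation) so individual operators
are replayable; the whole run is reproducible bit-for-bit from the seed.

Fitness may be negative (the subset-selection objective subtracts a size
penalty), so roulette weights use the shift policy w_i = f_i - min(f) + eps;
when all fitnesses are equal this degrades gracefully to uniform selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

_EPS = 1e-9


@dataclass(frozen=True)
class GAConfig:
    """Evolution settings.  Defaults follow the Phase-I clustering runs:
    population 20, crossover 0.8, mutation 0.01, two elites."""

    population_size: int = 20
    generations: int = 50
    crossover_prob: float = 0.8
    mutation_prob: float = 0.01
    elitism_count: int = 2
    seed: int = 0
    init_density: float = 0.5    # expected fraction of ones in initial genomes

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if not 0 <= self.elitism_count < self.population_size:
            raise ValueError("elitism_count must be in [0, population_size)")
        for name in ("crossover_prob", "mutation_prob", "init_density"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")


@dataclass
class GARunTrace:
    """Per-generation statistics of an evolution run."""

    best_fitness: list[float] = field(default_factory=list)
    mean_fitness: list[float] = field(default_factory=list)
    best_popcount: list[int] = field(default_factory=list)
    best_genome: list[np.ndarray] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.best_fitness)

    def to_rows(self) -> list[dict]:
        return [
            {
                "generation": g,
                "best_fitness": self.best_fitness[g],
                "mean_fitness": self.mean_fitness[g],
                "best_popcount": self.best_popcount[g],
            }
            for g in range(len(self))
        ]


def selection_weights(fitnesses: Sequence[float]) -> np.ndarray:
    """Shifted-fitness roulette weights, normalized to sum to 1."""
    f = np.asarray(fitnesses, dtype=float)
    if f.size == 0:
        raise ValueError("empty population")
    w = f - f.min() + _EPS
    return w / w.sum()


def roulette_select(fitnesses: Sequence[float], rng: np.random.Generator) -> int:
    """Sample one parent index with probability proportional to shifted fitness."""
    return int(rng.choice(len(fitnesses), p=selection_weights(fitnesses)))


def uniform_crossover(parent_a: np.ndarray, parent_b: np.ndarray,
                      crossover_prob: float, rng: np.random.Generator):
    """With probability *crossover_prob*, swap each locus by a fair coin.

    At every locus the multiset {child1[j], child2[j]} equals
    {parent_a[j], parent_b[j]}; without crossover the offspring are clones.
    """
    a = np.asarray(parent_a, dtype=np.uint8)
    b = np.asarray(parent_b, dtype=np.uint8)
    if a.shape != b.shape:
        raise ValueError("parent genomes differ in length")
    if rng.random() >= crossover_prob:
        return a.copy(), b.copy()
    mask = rng.random(a.shape[0]) < 0.5
    c1 = np.where(mask, b, a)
    c2 = np.where(mask, a, b)
    return c1.astype(np.uint8), c2.astype(np.uint8)


def bitflip_mutation(genome: np.ndarray, mutation_prob: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Flip each bit independently with probability *mutation_prob*."""
    g = np.asarray(genome, dtype=np.uint8)
    flips = rng.random(g.shape[0]) < mutation_prob
    return (g ^ flips.astype(np.uint8)).astype(np.uint8)


def _spawn_streams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(4)
    names = ("init", "selection", "crossover", "mutation")
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


def evolve(fitness_fn: Callable[[np.ndarray], float], L: int,
           config: GAConfig) -> tuple[np.ndarray, GARunTrace]:
    """Run the generational GA and return (best genome ever, trace).

    Each generation keeps the ``elitism_count`` fittest individuals as clones
    (ties broken by lower population index) and refills the rest with
    offspring from roulette-selected parents via uniform crossover and
    bit-flip mutation.  With elitism active the per-generation best fitness
    is non-decreasing.
    """
    if L < 1:
        raise ValueError("genome length must be >= 1")
    streams = _spawn_streams(config.seed)
    pop = (streams["init"].random((config.population_size, L))
           < config.init_density).astype(np.uint8)
    trace = GARunTrace()
    best_genome: np.ndarray | None = None
    best_fit = -np.inf
    for _ in range(config.generations):
        fits = np.array([fitness_fn(ind) for ind in pop], dtype=float)
        # stable sort on -fitness: ties keep lower population index first
        order = np.argsort(-fits, kind="stable")
        gen_best = int(order[0])
        if fits[gen_best] > best_fit:
            best_fit = float(fits[gen_best])
            best_genome = pop[gen_best].copy()
        trace.best_fitness.append(float(fits[gen_best]))
        trace.mean_fitness.append(float(fits.mean()))
        trace.best_popcount.append(int(pop[gen_best].sum()))
        trace.best_genome.append(pop[gen_best].copy())

        next_pop = [pop[i].copy() for i in order[: config.elitism_count]]
        weights = selection_weights(fits)
        sel_rng = streams["selection"]
        while len(next_pop) < config.population_size:
            i = int(sel_rng.choice(len(fits), p=weights))
            j = int(sel_rng.choice(len(fits), p=weights))
            c1, c2 = uniform_crossover(pop[i], pop[j], config.crossover_prob,
                                       streams["crossover"])
            c1 = bitflip_mutation(c1, config.mutation_prob, streams["mutation"])
            next_pop.append(c1)
            if len(next_pop) < config.population_size:
                c2 = bitflip_mutation(c2, config.mutation_prob, streams["mutation"])
                next_pop.append(c2)
        pop = np.array(next_pop, dtype=np.uint8)
    assert best_genome is not None
    return best_genome, trace
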