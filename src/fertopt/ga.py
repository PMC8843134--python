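"""Real-coded genetic algorithm for box-constrained dose maximization.

The optimizer evolves 3-gene real chromosomes (N, K, Mg doses) inside a
bound box with roulette-wheel selection, 2-point crossover, uniform
mutation and single-individual elitism. Default operating point:
population 200, 1000 generations, crossover rate 0.7, mutation rate
0.04. Fitness is shifted to be non-negative before roulette selection,
f_i - min(f) + 0.01 * range(f), which handles negative and tied fitness
without changing the ordering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from itertools import combinations
from typing import Callable

import numpy as np

ROULETTE_EPS = 0.01


@dataclass
class GAConfig:
    population: int = 200
    generations: int = 1000
    crossover_rate: float = 0.7
    mutation_rate: float = 0.04
    bounds: tuple[tuple[float, float], ...] = (
        (0.0, 200.0),
        (0.0, 300.0),
        (0.0, 100.0),
    )
    elitism: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.crossover_rate <= 1:
            raise ValueError("crossover_rate must be in [0, 1]")
        if not 0 <= self.mutation_rate <= 1:
            raise ValueError("mutation_rate must be in [0, 1]")
        if self.population < 2:
            raise ValueError("population must be >= 2")
        if self.elitism < 0 or self.elitism >= self.population:
            raise ValueError("elitism must be in [0, population)")
        for lo, hi in self.bounds:
            if not lo < hi:
                raise ValueError("bounds must satisfy low < high per gene")

    @property
    def n_genes(self) -> int:
        return len(self.bounds)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["bounds"] = [list(b) for b in self.bounds]
        return d


@dataclass
class OptimizationResult:
    best_levels: np.ndarray
    best_value: float
    history_best: np.ndarray = field(repr=False)
    history_mean: np.ndarray = field(repr=False)
    evaluations: int = 0
    config: dict = field(default_factory=dict)
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "best_levels": self.best_levels.tolist(),
            "best_value": float(self.best_value),
            "history_best": self.history_best.tolist(),
            "history_mean": self.history_mean.tolist(),
            "evaluations": int(self.evaluations),
            "config": self.config,
            "seed": int(self.seed),
        }


def init_population(config: GAConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """Uniform random population inside the bound box."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    b = np.asarray(config.bounds, dtype=float)
    return rng.uniform(b[:, 0], b[:, 1], size=(config.population, config.n_genes))


def _selection_probs(fitness: np.ndarray) -> np.ndarray:
    f = np.asarray(fitness, dtype=float)
    spread = f.max() - f.min()
    w = f - f.min() + ROULETTE_EPS * spread
    if w.sum() <= 0:  # all fitness identical
        return np.full(len(f), 1.0 / len(f))
    return w / w.sum()


def roulette_select(population, fitness, rng: np.random.Generator) -> int:
    """Draw one parent index with probability proportional to shifted fitness."""
    population = np.asarray(population)
    if len(population) == 0:
        raise ValueError("cannot select from an empty population")
    if not np.all(np.isfinite(fitness)):
        raise ValueError("fitness must be finite for selection")
    return int(rng.choice(len(population), p=_selection_probs(fitness)))


def two_point_crossover(parent_a, parent_b, p_c: float, rng: np.random.Generator):
    """Exchange the segment between two cut points with probability ``p_c``.

    Cut pairs (i, j), i < j, are drawn uniformly from the gene boundaries
    {1, ..., L}; genes at positions [i, j) are swapped. For a 3-gene
    chromosome the possible pairs are (1,2), (1,3) and (2,3).
    """
    a = np.array(parent_a, dtype=float)
    b = np.array(parent_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("parents must be equal-length chromosomes of length >= 2")
    if rng.random() < p_c:
        pairs = list(combinations(range(1, len(a) + 1), 2))
        i, j = pairs[rng.integers(len(pairs))]
        a[i:j], b[i:j] = b[i:j].copy(), a[i:j].copy()
    return a, b


def uniform_mutation(individual, p_m: float, bounds, rng: np.random.Generator) -> np.ndarray:
    """Redraw each gene uniformly within its bounds with probability ``p_m``."""
    x = np.array(individual, dtype=float)
    b = np.asarray(bounds, dtype=float)
    mask = rng.random(len(x)) < p_m
    if mask.any():
        x[mask] = rng.uniform(b[mask, 0], b[mask, 1])
    return x


def _evaluate(objective: Callable, population: np.ndarray) -> np.ndarray:
    """Batch-evaluate the objective; fall back to a per-row loop."""
    try:
        vals = np.asarray(objective(population), dtype=float)
        if vals.shape != (len(population),):
            raise TypeError
    except (TypeError, ValueError):
        vals = np.array([float(objective(ind)) for ind in population])
    bad = ~np.isfinite(vals)
    if bad.any():
        warnings.warn(f"{bad.sum()} non-finite objective values set to worst")
        worst = vals[~bad].min() if (~bad).any() else 0.0
        vals[bad] = worst - 1.0
    return vals


def optimize(objective: Callable, config: GAConfig) -> OptimizationResult:
    """Maximize ``objective`` over the bound box.

    ``objective`` may accept a single (3,) chromosome or, for speed, a
    whole (m, 3) population returning (m,) values. With ``elitism >= 1``
    the running best is carried over each generation, so the best-fitness
    history is non-decreasing and the result is the best individual ever
    evaluated.
    """
    rng = np.random.default_rng(config.seed)
    pop = init_population(config, rng)
    fitness = _evaluate(objective, pop)
    evaluations = len(pop)

    best_hist = np.empty(config.generations)
    mean_hist = np.empty(config.generations)
    best_idx = int(np.argmax(fitness))
    best_ever = pop[best_idx].copy()
    best_val = float(fitness[best_idx])

    for gen in range(config.generations):
        best_hist[gen] = best_val
        mean_hist[gen] = float(fitness.mean())

        children = []
        if config.elitism:
            elite = np.argsort(fitness)[::-1][: config.elitism]
            children.extend(pop[elite].copy())
        probs = _selection_probs(fitness)
        while len(children) < config.population:
            ia, ib = rng.choice(len(pop), size=2, p=probs)
            ca, cb = two_point_crossover(pop[ia], pop[ib], config.crossover_rate, rng)
            ca = uniform_mutation(ca, config.mutation_rate, config.bounds, rng)
            children.append(ca)
            if len(children) < config.population:
                cb = uniform_mutation(cb, config.mutation_rate, config.bounds, rng)
                children.append(cb)
        pop = np.asarray(children)
        fitness = _evaluate(objective, pop)
        evaluations += len(pop)
        gen_best = int(np.argmax(fitness))
        if fitness[gen_best] > best_val:
            best_val = float(fitness[gen_best])
            best_ever = pop[gen_best].copy()

    return OptimizationResult(
        best_levels=best_ever,
        best_value=best_val,
        history_best=best_hist,
        history_mean=mean_hist,
        evaluations=evaluations,
        config=config.to_dict(),
        seed=config.seed,
    )
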