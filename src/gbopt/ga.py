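"""Real-coded genetic algorithm maximizing a fitness function over box bounds.

Used here to search the trained yield surrogate for the best reaction
conditions: genomes are 4-vectors (temperature, geniposide dose, glycine
dose, time) constrained to the experimental box.  Selection is
fitness-proportionate (roulette wheel) after shifting fitnesses to be
non-negative, recombination is single-point crossover, and mutation resamples
genes uniformly within their bounds.  One elite individual is carried over
unchanged each generation, which makes the best-fitness history monotone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_SHIFT_EPS = 1e-12  # keeps roulette weights strictly positive


class FitnessError(RuntimeError):
    """Fitness function returned a non-finite value."""


@dataclass
class GAConfig:
    """Search settings; defaults are the reference study's published choices."""

    population: int = 20
    generations: int = 100
    crossover_prob: float = 0.75
    mutation_prob: float = 0.05
    lower_bounds: tuple[float, ...] = (40.0, 240.0, 2.0, 5.0)
    upper_bounds: tuple[float, ...] = (100.0, 480.0, 14.0, 180.0)
    elitism: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        lo = np.asarray(self.lower_bounds, dtype=float)
        hi = np.asarray(self.upper_bounds, dtype=float)
        if lo.shape != hi.shape or np.any(lo >= hi):
            raise ValueError("lower bounds must be strictly below upper bounds")
        for p in (self.crossover_prob, self.mutation_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.population < 2:
            raise ValueError("population must be at least 2")
        if self.generations < 0 or self.elitism < 0:
            raise ValueError("generations and elitism must be non-negative")

    @property
    def n_genes(self) -> int:
        return len(self.lower_bounds)


@dataclass
class OptimizationResult:
    """Best condition vector found, its predicted fitness, and the trace."""

    best_x: np.ndarray
    best_fitness: float
    history: list[float] = field(default_factory=list)


def roulette_select(
    fitness: np.ndarray, count: int, rng: np.random.Generator
) -> np.ndarray:
    """Sample ``count`` indices with replacement, P(i) ∝ f(i) − min f + ε."""
    fitness = np.asarray(fitness, dtype=float)
    if fitness.size == 0:
        raise ValueError("empty population")
    if count < 1:
        raise ValueError("count must be >= 1")
    if not np.all(np.isfinite(fitness)):
        raise FitnessError("non-finite fitness in roulette selection")
    w = fitness - fitness.min() + _SHIFT_EPS
    return rng.choice(fitness.size, size=count, replace=True, p=w / w.sum())


def single_point_crossover(
    parent_a: np.ndarray, parent_b: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Swap tails after a cut drawn uniformly from the interior positions."""
    a = np.asarray(parent_a, dtype=float)
    b = np.asarray(parent_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("parents must have equal length")
    if a.size < 2:
        raise ValueError("genomes must have at least 2 genes")
    cut = int(rng.integers(1, a.size))
    child_a = np.concatenate([a[:cut], b[cut:]])
    child_b = np.concatenate([b[:cut], a[cut:]])
    return child_a, child_b


def mutate(genome: np.ndarray, config: GAConfig, rng: np.random.Generator) -> np.ndarray:
    """Resample each gene uniformly within its bounds with prob ``mutation_prob``."""
    lo = np.asarray(config.lower_bounds, dtype=float)
    hi = np.asarray(config.upper_bounds, dtype=float)
    out = np.asarray(genome, dtype=float).copy()
    mask = rng.random(out.size) < config.mutation_prob
    if mask.any():
        out[mask] = rng.uniform(lo[mask], hi[mask])
    return out


def _evaluate(fitness_fn, population: np.ndarray) -> np.ndarray:
    vals = np.asarray([fitness_fn(x) for x in population], dtype=float)
    if not np.all(np.isfinite(vals)):
        bad = population[int(np.argmax(~np.isfinite(vals)))]
        raise FitnessError(f"fitness returned a non-finite value at x = {bad}")
    return vals


def run_ga(fitness_fn, config: GAConfig | None = None) -> OptimizationResult:
    """Maximize ``fitness_fn`` over the box; same seed ⇒ same result.

    The initial population is uniform within the bounds.  Each generation:
    the ``elitism`` best individuals are carried over unchanged, the rest of
    the offspring come from roulette-selected parents recombined with
    probability ``crossover_prob`` and mutated gene-wise.  Returns the best
    individual ever evaluated.
    """
    config = config or GAConfig()
    rng = np.random.default_rng(config.seed)
    lo = np.asarray(config.lower_bounds, dtype=float)
    hi = np.asarray(config.upper_bounds, dtype=float)
    pop = rng.uniform(lo, hi, size=(config.population, config.n_genes))
    fit = _evaluate(fitness_fn, pop)

    best_i = int(np.argmax(fit))
    best_x, best_fit = pop[best_i].copy(), float(fit[best_i])
    history = [best_fit]

    for _ in range(config.generations):
        order = np.argsort(-fit, kind="stable")
        elites = pop[order[: config.elitism]].copy()
        n_offspring = config.population - len(elites)
        children: list[np.ndarray] = []
        while len(children) < n_offspring:
            ia, ib = roulette_select(fit, 2, rng)
            pa, pb = pop[ia].copy(), pop[ib].copy()
            if rng.random() < config.crossover_prob:
                pa, pb = single_point_crossover(pa, pb, rng)
            children.append(mutate(pa, config, rng))
            if len(children) < n_offspring:
                children.append(mutate(pb, config, rng))
        pop = np.vstack([elites] + children) if len(elites) else np.vstack(children)
        fit = _evaluate(fitness_fn, pop)
        gen_best = int(np.argmax(fit))
        if fit[gen_best] > best_fit:
            best_x, best_fit = pop[gen_best].copy(), float(fit[gen_best])
        history.append(float(fit[gen_best]))

    return OptimizationResult(best_x=best_x, best_fitness=best_fit, history=history)
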