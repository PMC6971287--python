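"""Evolutionary optimizer for Gaussian mixture fitting.

A population of candidate mixtures (flat parameter vectors) is evolved for a
fixed number of generations: evaluate fitness, build the next generation by
rank-weighted tournament selection (with the top few individuals carried
over unchanged), mutate a random subset by redrawing a random parameter slot
uniformly within its bounds, then recombine random disjoint pairs by convex
averaging with a shared uniform blend weight.

Fitness is the negated convex combination of a rescaled chi-square
distribution error and the mode-overlap error:

    fitness = -( t * chi2/(chi2 + B) + (1 - t) * overlap ),

where t is the overlap tolerance in (0, 1]. t = 1 is pure (rescaled)
chi-square optimization; lowering t trades goodness of fit for mode
separation. The rescaling chi2/(chi2 + B) maps the unbounded chi-square onto
[0, 1) so the two terms are commensurable.

All randomness flows through one numpy Generator (PCG64) seeded from the
config, in a fixed order (initialization, then per generation: selection,
mutation, recombination), so a run is a pure function of (data, M, config).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

from .fit_metrics import BinnedSample, _chi_square, _overlap_components, bin_data, default_bin_count
from .gmm_core import MixtureModel

__all__ = [
    "ParameterBounds",
    "Individual",
    "EvolutionConfig",
    "FitResult",
    "init_population",
    "fitness",
    "tournament_select",
    "mutate",
    "recombine",
    "distribution_optimization",
]


@dataclass(frozen=True)
class ParameterBounds:
    """Search box for the GA: means and sds bounded, weights always in [0, 1]."""

    mean_min: float
    mean_max: float
    sd_min: float
    sd_max: float

    def __post_init__(self) -> None:
        if not self.mean_min < self.mean_max:
            raise ValueError("mean_min must be below mean_max")
        if not (0 < self.sd_min < self.sd_max):
            raise ValueError("need 0 < sd_min < sd_max")

    @classmethod
    def from_data(cls, data) -> "ParameterBounds":
        """Default box: means within the data range, sds in [range/1000, range]."""
        data = np.asarray(data, dtype=float)
        lo, hi = float(data.min()), float(data.max())
        rng = hi - lo
        if rng <= 0:
            raise ValueError("data range must be positive")
        return cls(mean_min=lo, mean_max=hi, sd_min=rng / 1000.0, sd_max=rng)


class Individual:
    """A candidate mixture as a flat vector (mu_1..mu_M, sd_1..sd_M, w_1..w_M).

    Weights are stored normalized (sum 1). `fitness` caches the evaluated
    fitness and is None when the vector has changed since evaluation.
    """

    __slots__ = ("vector", "n_components", "fitness")

    def __init__(self, vector: np.ndarray, n_components: int, fitness: Optional[float] = None):
        self.vector = np.asarray(vector, dtype=float)
        self.n_components = int(n_components)
        if self.vector.shape != (3 * self.n_components,):
            raise ValueError("parameter vector must have length 3M")
        self.fitness = fitness

    @property
    def means(self) -> np.ndarray:
        return self.vector[: self.n_components]

    @property
    def sds(self) -> np.ndarray:
        return self.vector[self.n_components: 2 * self.n_components]

    @property
    def weights(self) -> np.ndarray:
        return self.vector[2 * self.n_components:]

    def copy(self) -> "Individual":
        return Individual(self.vector.copy(), self.n_components, self.fitness)

    def decode(self) -> MixtureModel:
        """Canonical MixtureModel (ascending means, weights renormalized)."""
        return MixtureModel.from_arrays(
            self.means, self.sds, self.weights, normalize=True
        )


@dataclass(frozen=True)
class EvolutionConfig:
    """Hyperparameters of one optimization run.

    mutation_prob is the per-individual probability of mutation in each
    generation; recombination_fraction is the share of the population paired
    off for crossover. overlap_tolerance = 1 means pure chi-square fitting.
    """

    population_size: int = 100
    iterations: int = 300
    mutation_prob: float = 0.1
    tournament_size: int = 3
    elitism_count: int = 5
    recombination_fraction: float = 0.8
    overlap_tolerance: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be at least 2")
        if self.iterations < 1:
            raise ValueError("iterations must be positive")
        if not (0.0 <= self.mutation_prob <= 1.0):
            raise ValueError("mutation_prob must lie in [0, 1]")
        if self.tournament_size < 2:
            raise ValueError("tournament_size must be at least 2")
        if not (0 <= self.elitism_count < self.population_size):
            raise ValueError("elitism_count must be below population_size")
        if not (0.0 <= self.recombination_fraction <= 1.0):
            raise ValueError("recombination_fraction must lie in [0, 1]")
        if not (0.0 < self.overlap_tolerance <= 1.0):
            raise ValueError("overlap_tolerance must lie in (0, 1]")


@dataclass(frozen=True)
class FitResult:
    """Outcome of a run: the best mixture, its errors, and reproducibility info."""

    model: MixtureModel
    chi_square: float
    overlap: float
    fitness: float
    fitness_trace: tuple[float, ...]
    seed: int
    config: EvolutionConfig
    n_bins: int


def _canonical_vector(vec: np.ndarray, m: int) -> np.ndarray:
    """Sort the component triples by ascending mean, in place slot-wise.

    Keeping every individual's slots in mean order aligns homologous
    components across the population, so that arithmetic crossover blends
    like with like instead of averaging unrelated modes (label switching
    would otherwise collapse the population toward a single central blob).
    The decoded mixture is unchanged.
    """
    order = np.argsort(vec[:m], kind="stable")
    out = np.empty_like(vec)
    out[:m] = vec[:m][order]
    out[m: 2 * m] = vec[m: 2 * m][order]
    out[2 * m:] = vec[2 * m:][order]
    return out


def init_population(
    bounds: ParameterBounds, n_components: int, size: int, rng: np.random.Generator
) -> list[Individual]:
    """Uniform draws within the bounds; weights drawn on [0,1] and normalized."""
    if size < 2:
        raise ValueError("population size must be at least 2")
    if n_components < 2:
        raise ValueError("need at least two components")
    pop = []
    for _ in range(size):
        means = rng.uniform(bounds.mean_min, bounds.mean_max, n_components)
        sds = rng.uniform(bounds.sd_min, bounds.sd_max, n_components)
        weights = rng.uniform(0.0, 1.0, n_components)
        weights = weights / weights.sum()
        vec = _canonical_vector(np.concatenate([means, sds, weights]), n_components)
        pop.append(Individual(vec, n_components))
    return pop


def _scaled_chi_square(chi2: float, n_bins: int) -> float:
    return chi2 / (chi2 + n_bins)


def default_combine(scaled_chi2: float, overlap: float, tolerance: float) -> float:
    """Convex error blend; its negation is the fitness."""
    return tolerance * scaled_chi2 + (1.0 - tolerance) * overlap


def fitness(
    ind: Individual,
    binned: BinnedSample,
    data,
    cfg: EvolutionConfig,
    combine: Callable[[float, float, float], float] = default_combine,
) -> float:
    """Negated blended error; cached on the individual."""
    if ind.fitness is not None:
        return ind.fitness
    data = np.asarray(data, dtype=float)
    w = ind.weights / ind.weights.sum()
    chi2 = _chi_square(
        binned.edges, binned.observed, binned.n_total, ind.means, ind.sds, w
    )
    if cfg.overlap_tolerance < 1.0:
        overlap = float(_overlap_components(data, ind.means, ind.sds, w).max())
    else:
        overlap = 0.0  # unused in the blend when t = 1
    value = -combine(_scaled_chi_square(chi2, binned.n_bins), overlap, cfg.overlap_tolerance)
    ind.fitness = value
    return value


def tournament_select(
    population: Sequence[Individual], rng: np.random.Generator, cfg: EvolutionConfig
) -> Individual:
    """Rank-weighted tournament: draw entrants uniformly with replacement, then
    pick a winner with probability proportional to its fitness rank within the
    tournament (best rank = tournament size, worst = 1)."""
    n = len(population)
    if n == 0:
        raise ValueError("cannot select from an empty population")
    if n == 1:
        return population[0]
    k = cfg.tournament_size
    entrants = rng.integers(0, n, size=k)
    fits = np.array([population[i].fitness for i in entrants], dtype=float)
    order = np.argsort(fits, kind="stable")  # ascending: worst first
    weights = np.arange(1, k + 1, dtype=float)  # rank weight by sorted position
    probs = weights / weights.sum()
    winner_pos = rng.choice(k, p=probs)
    return population[entrants[order[winner_pos]]]


def mutate(
    ind: Individual,
    bounds: ParameterBounds,
    rng: np.random.Generator,
    n_slots: Optional[int] = 1,
) -> Individual:
    """Uniform random mutation: redraw parameter slots within their bounds.

    By default one uniformly chosen slot is redrawn (the classic real-coded
    uniform mutation; redrawing many slots at once is too disruptive for the
    optimizer to refine solutions at the default budget). Pass n_slots to
    redraw a fixed number of distinct slots, or None to draw the count
    uniformly from {1..3M}. Weights are renormalized afterwards and the
    fitness cache is invalidated.
    """
    m = ind.n_components
    p = 3 * m
    u = int(rng.integers(1, p + 1)) if n_slots is None else int(n_slots)
    if not (1 <= u <= p):
        raise ValueError(f"n_slots must lie in [1, {p}]")
    slots = rng.choice(p, size=u, replace=False)
    vec = ind.vector.copy()
    touched_weights = False
    for s in slots:
        if s < m:
            vec[s] = rng.uniform(bounds.mean_min, bounds.mean_max)
        elif s < 2 * m:
            vec[s] = rng.uniform(bounds.sd_min, bounds.sd_max)
        else:
            vec[s] = rng.uniform(0.0, 1.0)
            touched_weights = True
    if touched_weights:
        vec[2 * m:] = vec[2 * m:] / vec[2 * m:].sum()
    return Individual(_canonical_vector(vec, m), m)


def recombine(
    p1: Individual, p2: Individual, rng: np.random.Generator
) -> tuple[Individual, Individual]:
    """Arithmetic crossover: children are convex combinations of the parents
    with one shared uniform blend weight, c1 = a p1 + (1-a) p2 and
    c2 = (1-a) p1 + a p2."""
    if p1.n_components != p2.n_components:
        raise ValueError("parents must have the same number of components")
    a = rng.uniform()
    v1 = a * p1.vector + (1.0 - a) * p2.vector
    v2 = (1.0 - a) * p1.vector + a * p2.vector
    m = p1.n_components
    return (
        Individual(_canonical_vector(v1, m), m),
        Individual(_canonical_vector(v2, m), m),
    )


def distribution_optimization(
    data,
    n_components: int,
    cfg: EvolutionConfig = EvolutionConfig(),
    *,
    n_bins: Optional[int] = None,
    bounds: Optional[ParameterBounds] = None,
    combine: Callable[[float, float, float], float] = default_combine,
    monitor: Optional[Callable[[int, float], None]] = None,
    inspect: Optional[Callable[[int, list[Individual], Individual], None]] = None,
) -> FitResult:
    """Fit an n_components Gaussian mixture by evolutionary search.

    Parameters
    ----------
    data
        One-dimensional sample.
    n_components
        Number of mixture components M >= 2.
    cfg
        Evolution hyperparameters, including the seed that makes the run
        reproducible.
    n_bins
        Bin count for the chi-square error; defaults to the sd-derived rule.
    bounds
        Search box; defaults to :meth:`ParameterBounds.from_data`.
    combine
        Error blend combining rescaled chi-square and overlap; injectable.
    monitor
        Called as monitor(generation, best_fitness) after every generation.
    inspect
        Called as inspect(generation, population, best_ever) after every
        generation; intended for invariant checking.
    """
    data = np.asarray(data, dtype=float)
    if n_components < 2:
        raise ValueError("need at least two components (use em_fit for M = 1)")
    if data.size < 3 * n_components:
        raise ValueError(
            f"need at least {3 * n_components} points to fit {n_components} components"
        )
    rng = np.random.default_rng(cfg.seed)
    if bounds is None:
        bounds = ParameterBounds.from_data(data)
    if n_bins is None:
        n_bins = default_bin_count(data)
    binned = bin_data(data, n_bins)

    def evaluate(pop: list[Individual]) -> None:
        for ind in pop:
            fitness(ind, binned, data, cfg, combine)

    population = init_population(bounds, n_components, cfg.population_size, rng)
    evaluate(population)
    best = max(population, key=lambda i: i.fitness).copy()
    trace: list[float] = []

    n_elite = cfg.elitism_count
    for gen in range(cfg.iterations):
        # selection: elites pass through untouched, the rest via tournaments
        elites = sorted(population, key=lambda i: i.fitness, reverse=True)[:n_elite]
        next_pop = [e.copy() for e in elites]
        while len(next_pop) < cfg.population_size:
            next_pop.append(tournament_select(population, rng, cfg).copy())

        # mutation of a random subset of the non-elite slots
        for i in range(n_elite, cfg.population_size):
            if rng.uniform() < cfg.mutation_prob:
                next_pop[i] = mutate(next_pop[i], bounds, rng)

        # recombination of disjoint random non-elite pairs
        free = np.arange(n_elite, cfg.population_size)
        perm = rng.permutation(free)
        n_pairs = int(cfg.recombination_fraction * free.size) // 2
        for j in range(n_pairs):
            i1, i2 = perm[2 * j], perm[2 * j + 1]
            next_pop[i1], next_pop[i2] = recombine(next_pop[i1], next_pop[i2], rng)

        population = next_pop
        evaluate(population)
        gen_best = max(population, key=lambda i: i.fitness)
        if gen_best.fitness > best.fitness:
            best = gen_best.copy()
        trace.append(best.fitness)
        if monitor is not None:
            monitor(gen, best.fitness)
        if inspect is not None:
            inspect(gen, population, best)

    model = best.decode()
    w = best.weights / best.weights.sum()
    chi2 = _chi_square(binned.edges, binned.observed, binned.n_total, best.means, best.sds, w)
    overlap = float(_overlap_components(data, best.means, best.sds, w).max())
    return FitResult(
        model=model,
        chi_square=chi2,
        overlap=overlap,
        fitness=best.fitness,
        fitness_trace=tuple(trace),
        seed=cfg.seed,
        config=cfg,
        n_bins=n_bins,
    )
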