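"""Evolutionary optimizer: operators, invariants, seeded reproducibility."""

import itertools

import numpy as np
import pytest

from distopt import (
    EvolutionConfig,
    ParameterBounds,
    distribution_optimization,
)
from distopt.evolution import (
    Individual,
    _canonical_vector,
    fitness,
    init_population,
    mutate,
    recombine,
    tournament_select,
)
from distopt.fit_metrics import bin_data, chi_square_error, overlap_error

BOUNDS = ParameterBounds(mean_min=-2.0, mean_max=12.0, sd_min=0.05, sd_max=10.0)

SMALL = dict(population_size=24, iterations=40)


class FixedUniformRng:
    """Stub generator whose uniform() returns a preset blend weight."""

    def __init__(self, value):
        self.value = value

    def uniform(self, *a, **k):
        return self.value


def make_individual(means, sds, weights):
    vec = np.concatenate([means, sds, np.asarray(weights) / np.sum(weights)])
    return Individual(_canonical_vector(vec, len(means)), len(means))


class TestBoundsAndInit:
    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            ParameterBounds(1.0, 0.0, 0.1, 1.0)
        with pytest.raises(ValueError):
            ParameterBounds(0.0, 1.0, 0.5, 0.1)

    def test_from_data_box(self):
        b = ParameterBounds.from_data([0.0, 10.0, 5.0])
        assert (b.mean_min, b.mean_max) == (0.0, 10.0)
        assert b.sd_min == pytest.approx(0.01)
        assert b.sd_max == pytest.approx(10.0)

    def test_population_respects_invariants(self, rng):
        pop = init_population(BOUNDS, 3, 50, rng)
        assert len(pop) == 50
        for ind in pop:
            assert np.all(ind.means >= BOUNDS.mean_min) and np.all(ind.means <= BOUNDS.mean_max)
            assert np.all(ind.sds >= BOUNDS.sd_min) and np.all(ind.sds <= BOUNDS.sd_max)
            assert ind.weights.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.all(np.diff(ind.means) >= 0)

    def test_degenerate_mean_bounds_concentrate(self, rng):
        tight = ParameterBounds(5.0, 5.0 + 1e-12, 0.1, 1.0)
        pop = init_population(tight, 2, 10, rng)
        for ind in pop:
            np.testing.assert_allclose(ind.means, 5.0, atol=1e-9)

    def test_mean_draws_are_uniform(self, rng):
        pop = init_population(BOUNDS, 2, 5000, rng)
        draws = np.concatenate([ind.means for ind in pop])
        center = (BOUNDS.mean_min + BOUNDS.mean_max) / 2
        half_width = (BOUNDS.mean_max - BOUNDS.mean_min) / 2
        se = half_width / np.sqrt(3 * draws.size)
        assert abs(draws.mean() - center) < 3 * se


class TestFitness:
    def test_pure_chi_square_preserves_ordering(self, rng):
        data = rng.normal(5, 2, 300)
        binned = bin_data(data, 10)
        cfg = EvolutionConfig(seed=0, overlap_tolerance=1.0)
        a = make_individual([4.9, 5.1], [2.0, 2.0], [0.5, 0.5])
        b = make_individual([0.0, 11.0], [0.1, 0.1], [0.5, 0.5])
        fa, fb = fitness(a, binned, data, cfg), fitness(b, binned, data, cfg)
        chi_a = chi_square_error(binned, a.decode())
        chi_b = chi_square_error(binned, b.decode())
        assert (fa > fb) == (chi_a < chi_b)

    def test_blend_matches_arithmetic_recomputation(self, rng):
        data = rng.normal(3, 2, 200)
        binned = bin_data(data, 8)
        cfg = EvolutionConfig(seed=0, overlap_tolerance=0.5)
        for ind in [
            make_individual([1.0, 6.0], [1.0, 1.5], [0.5, 0.5]),
            make_individual([2.5, 3.5], [2.0, 2.0], [0.3, 0.7]),
        ]:
            chi = chi_square_error(binned, ind.decode())
            ov = overlap_error(data, ind.decode())
            expected = -(0.5 * chi / (chi + binned.n_bins) + 0.5 * ov)
            assert fitness(ind, binned, data, cfg) == pytest.approx(expected, rel=1e-12)

    def test_fitness_cached(self, rng):
        data = rng.normal(0, 1, 100)
        binned = bin_data(data, 5)
        cfg = EvolutionConfig(seed=0)
        ind = make_individual([-1.0, 1.0], [1.0, 1.0], [0.5, 0.5])
        v = fitness(ind, binned, data, cfg)
        assert ind.fitness == v


class TestTournament:
    def test_single_individual_population(self, rng):
        ind = make_individual([0.0, 1.0], [1.0, 1.0], [0.5, 0.5])
        ind.fitness = -0.5
        assert tournament_select([ind], rng, EvolutionConfig(seed=0)) is ind

    def test_best_beats_worst(self, rng):
        pop = []
        for i in range(10):
            ind = make_individual([0.0, 1.0], [1.0, 1.0], [0.5, 0.5])
            ind.fitness = -float(i)
            pop.append(ind)
        cfg = EvolutionConfig(seed=0)
        wins = np.zeros(10)
        for _ in range(5000):
            winner = tournament_select(pop, rng, cfg)
            wins[int(-winner.fitness)] += 1
        assert wins[0] > wins[9]

    def test_win_frequencies_match_enumeration(self, rng):
        """Size-3 tournament over a size-3 population vs exact combinatorics."""
        pop = []
        fits = [-3.0, -2.0, -1.0]
        for f in fits:
            ind = make_individual([0.0, 1.0], [1.0, 1.0], [0.5, 0.5])
            ind.fitness = f
            pop.append(ind)
        cfg = EvolutionConfig(seed=0, tournament_size=3)

        # oracle: all 27 equally likely entrant tuples; within each, stable
        # ascending sort by fitness, win probability proportional to 1,2,3
        rank_w = np.array([1.0, 2.0, 3.0])
        rank_w /= rank_w.sum()
        exact = np.zeros(3)
        for tup in itertools.product(range(3), repeat=3):
            order = sorted(range(3), key=lambda i: fits[tup[i]])
            for pos, slot in enumerate(order):
                exact[tup[slot]] += rank_w[pos] / 27.0

        n = 50_000
        counts = np.zeros(3)
        for _ in range(n):
            winner = tournament_select(pop, rng, cfg)
            counts[pop.index(winner)] += 1
        freq = counts / n
        sigma = np.sqrt(exact * (1 - exact) / n)
        assert np.all(np.abs(freq - exact) < 3.5 * sigma)

    def test_empty_population_rejected(self, rng):
        with pytest.raises(ValueError):
            tournament_select([], rng, EvolutionConfig(seed=0))


class TestMutateRecombine:
    def test_mutation_respects_bounds_and_normalization(self, rng):
        ind = make_individual([0.0, 5.0, 10.0], [1.0, 1.0, 1.0], [1, 1, 1])
        for _ in range(100):
            out = mutate(ind, BOUNDS, rng)
            assert out.fitness is None
            assert np.all(out.means >= BOUNDS.mean_min) and np.all(out.means <= BOUNDS.mean_max)
            assert np.all(out.sds >= BOUNDS.sd_min) and np.all(out.sds <= BOUNDS.sd_max)
            assert out.weights.sum() == pytest.approx(1.0, abs=1e-12)

    def test_full_redraw_matches_init_distribution(self, rng):
        """Redrawing every slot is distributed like a fresh init draw."""
        ind = make_individual([0.0, 5.0], [1.0, 1.0], [0.5, 0.5])
        redraws = np.array([mutate(ind, BOUNDS, rng, n_slots=6).means for _ in range(4000)])
        center = (BOUNDS.mean_min + BOUNDS.mean_max) / 2
        half_width = (BOUNDS.mean_max - BOUNDS.mean_min) / 2
        se = half_width / np.sqrt(3 * redraws.size)
        assert abs(redraws.mean() - center) < 3 * se

    def test_single_slot_mutation_changes_one_parameter(self, rng):
        ind = make_individual([0.0, 5.0, 10.0], [1.0, 2.0, 3.0], [0.2, 0.3, 0.5])
        for _ in range(50):
            out = mutate(ind, BOUNDS, rng, n_slots=1)
            diff_means = np.setdiff1d(out.means, ind.means).size
            diff_sds = np.setdiff1d(out.sds, ind.sds).size
            diff_w = np.setdiff1d(out.weights, ind.weights).size
            # one block changed (weights count as one slot despite renormalization)
            assert (diff_means > 0) + (diff_sds > 0) + (diff_w > 0) == 1
            assert diff_means <= 1 and diff_sds <= 1

    def test_midpoint_blend(self):
        p1 = make_individual([0.0, 4.0], [1.0, 2.0], [0.5, 0.5])
        p2 = make_individual([2.0, 6.0], [2.0, 1.0], [0.3, 0.7])
        c1, c2 = recombine(p1, p2, FixedUniformRng(0.5))
        np.testing.assert_allclose(c1.vector, (p1.vector + p2.vector) / 2)
        np.testing.assert_allclose(c2.vector, (p1.vector + p2.vector) / 2)

    def test_unit_blend_returns_parents(self):
        p1 = make_individual([0.0, 4.0], [1.0, 2.0], [0.5, 0.5])
        p2 = make_individual([2.0, 6.0], [2.0, 1.0], [0.3, 0.7])
        c1, c2 = recombine(p1, p2, FixedUniformRng(1.0))
        np.testing.assert_allclose(c1.vector, p1.vector)
        np.testing.assert_allclose(c2.vector, p2.vector)

    def test_children_conserve_parent_sum(self, rng):
        p1 = make_individual([0.0, 4.0, 9.0], [1.0, 2.0, 0.5], [1, 2, 3])
        p2 = make_individual([1.0, 5.0, 8.0], [2.0, 1.0, 1.5], [3, 2, 1])
        for _ in range(20):
            c1, c2 = recombine(p1, p2, rng)
            np.testing.assert_allclose(c1.vector + c2.vector, p1.vector + p2.vector, atol=1e-12)

    def test_mismatched_dimensions_rejected(self, rng):
        p1 = make_individual([0.0, 4.0], [1.0, 2.0], [0.5, 0.5])
        p2 = make_individual([0.0, 4.0, 8.0], [1.0, 2.0, 1.0], [1, 1, 1])
        with pytest.raises(ValueError):
            recombine(p1, p2, rng)


class TestOptimizer:
    def test_seeded_runs_are_bit_identical(self, scenario_a_data):
        cfg = EvolutionConfig(seed=7, **SMALL)
        r1 = distribution_optimization(scenario_a_data, 3, cfg)
        r2 = distribution_optimization(scenario_a_data, 3, cfg)
        assert r1.fitness_trace == r2.fitness_trace
        np.testing.assert_array_equal(r1.model.means, r2.model.means)
        np.testing.assert_array_equal(r1.model.sds, r2.model.sds)
        np.testing.assert_array_equal(r1.model.weights, r2.model.weights)
        assert r1.chi_square == r2.chi_square

    def test_best_fitness_trace_non_decreasing(self, scenario_a_data):
        r = distribution_optimization(
            scenario_a_data, 3, EvolutionConfig(seed=3, **SMALL)
        )
        trace = np.array(r.fitness_trace)
        assert np.all(np.diff(trace) >= 0)
        assert len(trace) == SMALL["iterations"]

    def test_population_invariants_every_generation(self, scenario_a_data):
        bounds = ParameterBounds.from_data(scenario_a_data)
        seen = []

        def check(gen, population, best):
            seen.append(gen)
            assert len(population) == 24
            for ind in population:
                assert np.all(ind.means >= bounds.mean_min - 1e-12)
                assert np.all(ind.means <= bounds.mean_max + 1e-12)
                assert np.all(ind.sds >= bounds.sd_min - 1e-12)
                assert np.all(ind.sds <= bounds.sd_max + 1e-12)
                assert abs(ind.weights.sum() - 1.0) < 1e-9

        distribution_optimization(
            scenario_a_data, 3, EvolutionConfig(seed=5, **SMALL), inspect=check
        )
        assert seen == list(range(SMALL["iterations"]))

    def test_between_seed_variability_is_nonzero(self, scenario_a_data):
        means = [
            distribution_optimization(
                scenario_a_data, 3, EvolutionConfig(seed=s, **SMALL)
            ).model.means
            for s in (1, 2, 3)
        ]
        assert np.std(np.stack(means), axis=0).max() > 0

    def test_input_validation(self, scenario_a_data):
        with pytest.raises(ValueError):
            distribution_optimization(scenario_a_data, 1, EvolutionConfig(seed=0))
        with pytest.raises(ValueError):
            distribution_optimization(scenario_a_data[:5], 2, EvolutionConfig(seed=0))
        with pytest.raises(ValueError):
            EvolutionConfig(overlap_tolerance=0.0)
        with pytest.raises(ValueError):
            EvolutionConfig(elitism_count=200, population_size=100)
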