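"""Unit and property tests for the spatial individual-based simulator."""

import numpy as np
import pytest
from scipy.stats import norm

from sigmanet import (SimParams, choose_mate, effective_sigma, inbreeding_Ne,
                      init_population, local_density, reproduce,
                      run_spatial_epoch, step, survival_probability,
                      expected_natal_displacement_sq)
from sigmanet._kernels import grid_density_and_mates

from conftest import make_pop


class TestSurvival:
    @pytest.mark.parametrize("K", [0.1, 1.0, 5.0, 40.0])
    def test_empty_neighbourhood_gives_ceiling(self, K):
        assert survival_probability(0.0, K, 4.0, edge_distance=10.0, sigma_c=1.0) == 0.95

    def test_half_at_carrying_scale(self):
        K, L = 5.0, 4.0
        assert survival_probability(K * (1 + L), K, L, 10.0, 1.0) == pytest.approx(0.5)

    def test_edge_zero_kills(self):
        assert survival_probability(0.0, 5.0, 4.0, edge_distance=0.0, sigma_c=1.0) == 0.0

    def test_edge_factor_is_sqrt(self):
        p = survival_probability(0.0, 5.0, 4.0, edge_distance=0.25, sigma_c=1.0)
        assert p == pytest.approx(0.95 * 0.5)

    def test_never_exceeds_ceiling(self):
        for n in np.linspace(0, 100, 23):
            assert survival_probability(n, 2.0, 4.0, 50.0, 1.0) <= 0.95

    def test_negative_density_rejected(self):
        with pytest.raises(ValueError):
            survival_probability(-0.1, 5.0, 4.0, 1.0, 1.0)


class TestLocalDensity:
    def test_isolated_individual(self):
        pop = make_pop([(5, 5)])
        assert local_density(pop, 0, sigma_c=1.0) == 0.0

    def test_single_neighbour_at_sigma(self):
        pop = make_pop([(5, 5), (6, 5)])
        assert local_density(pop, 0, 1.0) == pytest.approx(norm.pdf(1.0), abs=1e-5)
        assert local_density(pop, 0, 1.0) == pytest.approx(0.24197, abs=1e-4)

    def test_cutoff_at_three_sigma(self):
        pop = make_pop([(1, 5), (4.5, 5)])
        assert local_density(pop, 0, 1.0) == 0.0

    def test_translation_invariance_in_interior(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(3, 6, size=(20, 2))
        pop_a = make_pop(pts, W=10)
        pop_b = make_pop(pts + 1.0, W=10)
        for i in range(20):
            assert local_density(pop_a, i, 0.5) == pytest.approx(
                local_density(pop_b, i, 0.5), rel=1e-12)


class TestMateChoice:
    def test_single_candidate_always_chosen(self):
        pop = make_pop([(5, 5), (6, 5)])
        rng = np.random.default_rng(0)
        for _ in range(10):
            assert choose_mate(pop, 0, 1.0, rng).id == 1

    def test_out_of_range_candidate_gives_none(self):
        pop = make_pop([(1, 5), (5.2, 5)])  # distance 4.2 > 3*sigma_m
        rng = np.random.default_rng(0)
        assert choose_mate(pop, 0, 1.0, rng) is None

    def test_two_equidistant_candidates_equal_probability(self):
        pop = make_pop([(5, 5), (4, 5), (6, 5)])
        rng = np.random.default_rng(1)
        picks = np.array([choose_mate(pop, 0, 1.0, rng).id for _ in range(10_000)])
        frac = np.mean(picks == 1)
        assert abs(frac - 0.5) < 0.02  # ~4 MC sigma

    def test_grid_mate_draw_matches_gaussian_weights(self):
        # one mother with two candidates at different distances: the grid
        # kernel's threshold draw must reproduce the Gaussian weighting
        x = np.array([5.0, 6.0, 3.0])
        y = np.array([5.0, 5.0, 5.0])
        sigma = 1.0
        w1 = np.exp(-0.5 * 1.0**2 / sigma**2)
        w2 = np.exp(-0.5 * 2.0**2 / sigma**2)
        rng = np.random.default_rng(3)
        u = rng.uniform(size=(5000, 3))
        picks = []
        for uu in u:
            _, mate = grid_density_and_mates(x, y, 10.0, sigma, sigma,
                                             np.array([True, False, False]), uu)
            picks.append(mate[0])
        frac = np.mean(np.asarray(picks) == 1)
        expect = w1 / (w1 + w2)
        assert abs(frac - expect) < 0.02

    def test_grid_density_matches_brute_force(self):
        rng = np.random.default_rng(5)
        n, W, sc = 300, 7.0, 0.8
        x, y = rng.uniform(0, W, n), rng.uniform(0, W, n)
        dens, _ = grid_density_and_mates(x, y, W, sc, sc, np.zeros(n, bool),
                                         np.zeros(n))
        d2 = (x[:, None] - x[None, :]) ** 2 + (y[:, None] - y[None, :]) ** 2
        mask = (d2 <= 9 * sc**2) & ~np.eye(n, dtype=bool)
        brute = (np.exp(-d2 / (2 * sc**2)) * mask).sum(axis=1)
        np.testing.assert_allclose(dens, brute, rtol=0, atol=1e-9)


def _truncate(pop, n):
    """Drop rows beyond the first n (keeps repeated-mating tests O(n))."""
    for name in ("x", "y", "natal_d2", "birth_step", "death_step",
                 "mother", "father", "f", "alive"):
        setattr(pop, name, getattr(pop, name)[:n])


class TestReproduce:
    def test_offspring_count_poisson_pmf(self):
        pop = make_pop([(5, 5), (6, 5)], L=4.0)
        rng = np.random.default_rng(0)
        zero = 0
        for _ in range(100_000):
            zero += len(reproduce(pop, 0, 1, pop.params, rng)) == 0
            _truncate(pop, 2)
        assert abs(zero / 100_000 - np.exp(-0.25)) < 0.005

    def test_dispersal_variance_matches_kernel(self):
        pop = make_pop([(25, 25), (26, 25)], W=50.0, sigma_f=1.3, L=1.0)
        rng = np.random.default_rng(1)
        xs = []
        for _ in range(110_000):
            reproduce(pop, 0, 1, pop.params, rng)
            xs.extend(pop.x[2:] - 25.0)
            _truncate(pop, 2)
        xs = np.asarray(xs)
        assert xs.size > 100_000
        assert abs(xs.var() / 1.3**2 - 1.0) < 0.02

    def test_boundary_rejection(self):
        pop = make_pop([(0.01, 5.0), (0.5, 5.0)], W=10.0, sigma_f=2.0, L=1.0)
        rng = np.random.default_rng(2)
        for _ in range(3000):
            reproduce(pop, 0, 1, pop.params, rng)
        born = pop.size - 2
        assert 0 < born < 3000  # some proposals rejected
        assert np.all((pop.x >= 0) & (pop.x <= 10) & (pop.y >= 0) & (pop.y <= 10))

    def test_selfing_rejected(self):
        pop = make_pop([(5, 5), (6, 5)])
        with pytest.raises(ValueError):
            reproduce(pop, 0, 0, pop.params, np.random.default_rng(0))

    def test_pedigree_links_and_f_counts(self):
        pop = make_pop([(5, 5), (6, 5)], L=1.0)
        rng = np.random.default_rng(3)
        total = 0
        for _ in range(200):
            total += len(reproduce(pop, 0, 1, pop.params, rng))
        assert pop.f[0] == total and pop.f[1] == total
        assert np.all(pop.mother[2:] == 0) and np.all(pop.father[2:] == 1)


class TestStepAndEpoch:
    def test_individuals_stay_inside_habitat(self, equilibrium_pop):
        pop = equilibrium_pop
        W = pop.params.W
        assert np.all((pop.x >= 0) & (pop.x <= W) & (pop.y >= 0) & (pop.y <= W))

    def test_census_trace_bookkeeping(self, equilibrium_pop):
        pop = equilibrium_pop
        assert len(pop.census_trace) == pop.time + 1
        assert pop.census_trace[-1] == pop.census

    def test_pedigree_conservation(self, equilibrium_pop):
        pop = equilibrium_pop
        non_founders = int((pop.mother >= 0).sum())
        # each birth adds one to the mother's and one to the father's count
        assert int(pop.f.sum()) == 2 * non_founders
        has_mother = pop.mother >= 0
        has_father = pop.father >= 0
        assert np.array_equal(has_mother, has_father)

    def test_extinction_is_flagged_not_raised(self):
        # habitat far smaller than the kernels: edge penalty plus offspring
        # lost over the boundary drive the population extinct
        params = SimParams(sigma_f=1.0, sigma_m=1.0, sigma_c=1.0, K=5.0,
                           W=0.5, T_spatial=50, seed=0)
        pop = run_spatial_epoch(params, n0=20)
        assert pop.extinct_at is not None
        assert pop.census == 0

    def test_habitat_mask_confines_population(self):
        # circular habitat carved out of the square: nobody may leave it
        def disc(x, y):
            return (x - 5.0) ** 2 + (y - 5.0) ** 2 <= 16.0

        params = SimParams(sigma_f=0.8, sigma_m=0.8, sigma_c=0.8, K=5, W=10,
                           T_spatial=30, habitat_mask=disc, seed=9)
        pop = run_spatial_epoch(params, n0=300)
        assert pop.extinct_at is None
        assert np.all(disc(pop.x, pop.y))

    def test_zero_steps_returns_founders(self):
        params = SimParams(sigma_f=1, sigma_m=1, sigma_c=1, K=5, W=10,
                           T_spatial=0, seed=3)
        pop = run_spatial_epoch(params, n0=50)
        assert pop.size == 50 and pop.census == 50 and pop.time == 0

    def test_fixed_seed_reproduces_census_trace(self):
        params = SimParams(sigma_f=0.8, sigma_m=0.8, sigma_c=0.8, K=4, W=8,
                           T_spatial=40, seed=17)
        a = run_spatial_epoch(params)
        b = run_spatial_epoch(params)
        assert a.census_trace == b.census_trace
        np.testing.assert_array_equal(a.x, b.x)
        np.testing.assert_array_equal(a.f, b.f)

    def test_census_equilibrium_near_K_W2(self):
        params = SimParams(sigma_f=0.8, sigma_m=0.8, sigma_c=0.8, K=5, W=12,
                           T_spatial=100, seed=5)
        pop = run_spatial_epoch(params)
        mean_census = np.mean(pop.census_trace[50:])
        assert 0.5 * 5 * 12**2 <= mean_census <= 2.0 * 5 * 12**2

    def test_doubling_K_raises_equilibrium_census(self):
        wins = 0
        for s in range(10):
            censuses = []
            for K in (2.0, 4.0):
                params = SimParams(sigma_f=0.7, sigma_m=0.7, sigma_c=0.7, K=K,
                                   W=8, T_spatial=60, seed=100 + s)
                pop = run_spatial_epoch(params)
                censuses.append(np.mean(pop.census_trace[30:]))
            wins += censuses[1] > censuses[0]
        assert wins >= 9


class TestEffectiveSigma:
    def test_constant_displacement_recovers_sqrt(self):
        pop = make_pop([(5, 5)] * 4)
        pop.natal_d2 = np.array([np.nan, 2.25, 2.25, 2.25])
        pop.f = np.array([7, 1, 2, 3])
        assert effective_sigma(pop) == pytest.approx(1.5)

    def test_zero_weight_individuals_ignored(self):
        pop = make_pop([(5, 5)] * 4)
        pop.natal_d2 = np.array([np.nan, 4.0, 100.0, 4.0])
        pop.f = np.array([3, 2, 0, 1])
        assert effective_sigma(pop) == pytest.approx(2.0)

    def test_no_births_is_an_error(self):
        pop = make_pop([(5, 5), (6, 5)])
        with pytest.raises(ValueError):
            effective_sigma(pop)

    def test_analytic_natal_displacement(self):
        assert expected_natal_displacement_sq(1.0, 1.0) == pytest.approx(1.5)
        assert expected_natal_displacement_sq(2.0, 2.0) == pytest.approx(6.0)
        assert expected_natal_displacement_sq(1.0, 0.5) == pytest.approx(1.125)


class TestInbreedingNe:
    def test_poisson_like_variance(self):
        assert inbreeding_Ne(100, [1, 3] * 50) == pytest.approx(
            (100 * 2 - 2) / (2 - 1 + 1 / 2))
        # closed form with kbar=2, Vk=2: (200-2)/2 = 99
        k = np.array([0, 2, 2, 4] * 25)  # mean 2, var 2
        assert inbreeding_Ne(100, k) == pytest.approx(99.0)

    def test_equal_family_sizes_double(self):
        assert inbreeding_Ne(100, [2] * 60) == pytest.approx(198.0)

    def test_monotone_decreasing_in_variance(self):
        vals = []
        for spread in (0, 1, 2, 3):
            k = np.array([2 - spread, 2 + spread] * 30, dtype=float)
            vals.append(inbreeding_Ne(100, k))
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_degenerate_inputs_error(self):
        with pytest.raises(ValueError):
            inbreeding_Ne(100, [0, 0, 0])
        with pytest.raises(ValueError):
            inbreeding_Ne(100, [])
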