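"""Unit and property tests for the continuous GGO optimizer."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from greylag.ggo import (
    EXPLOITATION,
    EXPLORATION,
    Agent,
    GGOConfig,
    Population,
    UpdateDraws,
    a_schedule,
    draw_coefficients,
    exploit_flock,
    exploit_sentries,
    explore_leader,
    explore_paddles,
    explore_spiral,
    mutate,
    r1_schedule,
    resize_groups,
    run_ggo,
    z_schedule,
)


def make_draws(d=1, **overrides):
    base = dict(
        r1=np.zeros(d), r2=np.zeros(d), r3=0.0, r4=0.0, r5=0.0, l=0.0,
        w1=0.0, w2=0.0, w3=0.0, w4=0.0, A=np.zeros(d), C=np.zeros(d), a=0.0,
    )
    base.update(overrides)
    for key in ("r1", "r2", "A", "C"):
        base[key] = np.atleast_1d(np.asarray(base[key], dtype=float))
    return UpdateDraws(**base)


WIDE = np.array([-1e9]), np.array([1e9])


class TestSchedules:
    @pytest.mark.parametrize("t,t_max,expected", [
        (0, 100, 1.0), (100, 100, 0.0), (5, 10, 0.75),
    ])
    def test_z_values(self, t, t_max, expected):
        assert z_schedule(t, t_max) == pytest.approx(expected)

    @pytest.mark.parametrize("t,t_max,c,expected", [
        (0, 10, 2.0, 2.0), (10, 10, 2.0, 0.0), (3, 10, 1.0, 0.7),
    ])
    def test_r1_values(self, t, t_max, c, expected):
        assert r1_schedule(t, t_max, c) == pytest.approx(expected)

    def test_out_of_range_iteration_rejected(self):
        with pytest.raises(ValueError):
            z_schedule(11, 10)
        with pytest.raises(ValueError):
            r1_schedule(-1, 10, 2.0)
        with pytest.raises(ValueError):
            r1_schedule(1, 0, 2.0)

    @given(st.integers(1, 1000))
    @settings(deadline=None)
    def test_z_monotone_decreasing_and_bounded(self, t_max):
        values = [z_schedule(t, t_max) for t in range(t_max + 1)]
        assert values[0] == 1.0 and values[-1] == 0.0
        assert all(u > v for u, v in zip(values, values[1:]))
        assert all(0.0 <= v <= 1.0 for v in values)

    def test_a_linear_endpoints(self):
        assert a_schedule(0, 10) == 2.0
        assert a_schedule(10, 10) == 0.0
        assert a_schedule(5, 10) == pytest.approx(1.0)


class TestDrawCoefficients:
    def test_identities_hold(self):
        cfg = GGOConfig(bounds=((0, 1),) * 3, seed=0)
        rng = np.random.default_rng(7)
        draws = draw_coefficients(1.3, rng, cfg)
        np.testing.assert_allclose(draws.A, 2 * 1.3 * draws.r1 - 1.3)
        np.testing.assert_allclose(draws.C, 2 * draws.r2)
        assert np.all(np.abs(draws.A) <= 2 * 1.3 + 1e-12)
        assert -1.0 <= draws.l <= 1.0
        for w in (draws.w1, draws.w2, draws.w3, draws.w4):
            assert cfg.w_low <= w <= cfg.w_high

    def test_degenerate_a_gives_zero_A(self):
        cfg = GGOConfig(seed=0)
        draws = draw_coefficients(0.0, np.random.default_rng(0), cfg)
        np.testing.assert_allclose(draws.A, 0.0)


class TestPositionUpdates:
    def test_leader_update_with_zero_A_returns_leader(self):
        draws = make_draws(A=[0.0], C=[1.0])
        out = explore_leader(np.array([0.3]), np.array([0.9]), draws, *WIDE)
        np.testing.assert_allclose(out, [0.9])

    def test_leader_update_closed_form(self):
        # X* - A*|C*X* - X| = 1 - 0.5*|1*1 - 0| = 0.5
        draws = make_draws(A=[0.5], C=[1.0])
        out = explore_leader(np.array([0.0]), np.array([1.0]), draws, *WIDE)
        np.testing.assert_allclose(out, [0.5])

    def test_leader_update_dimension_mismatch(self):
        with pytest.raises(ValueError):
            explore_leader(np.zeros(2), np.zeros(3), make_draws(2), *WIDE)

    def test_paddles_coincident_fixed_point(self):
        p = np.array([0.0])
        out = explore_paddles(p, p, p, p, 0.5, make_draws(w1=1, w2=1, w3=1), *WIDE)
        np.testing.assert_allclose(out, [0.0])

    def test_paddles_z_one_drops_third_term(self):
        draws = make_draws(w1=1.0, w2=1.0, w3=5.0)
        out = explore_paddles(np.array([9.0]), np.array([1.0]), np.array([2.0]),
                              np.array([0.5]), 1.0, draws, *WIDE)
        np.testing.assert_allclose(out, [2.5])

    def test_paddles_z_zero_drops_second_term(self):
        draws = make_draws(w1=1.0, w2=5.0, w3=2.0)
        out = explore_paddles(np.array([1.0]), np.array([0.5]), np.array([7.0]),
                              np.array([7.0]), 0.0, draws, *WIDE)
        np.testing.assert_allclose(out, [1.5])

    def test_spiral_at_leader_reduces_to_leader_term(self):
        draws = make_draws(w1=0.5, w4=3.0, r4=0.5, r5=0.5, l=0.25)
        out = explore_spiral(np.array([2.0]), np.array([2.0]), draws, 1.0, *WIDE)
        # first term vanishes; 2*w1*(r4+r5)*leader = 2*0.5*1*2 = 2
        np.testing.assert_allclose(out, [2.0])

    def test_spiral_closed_form_l_zero(self):
        draws = make_draws(w1=0.0, w4=1.0, l=0.0)
        out = explore_spiral(np.array([0.0]), np.array([1.0]), draws, 1.0, *WIDE)
        np.testing.assert_allclose(out, [1.0])  # 1*|1-0|*e^0*cos0

    def test_sentries_mean_of_sentry_positions_when_A_zero(self):
        x = np.array([0.0])
        pairs = [(np.zeros(1), np.ones(1))] * 3
        out = exploit_sentries(x, np.array([1.0]), np.array([2.0]), np.array([3.0]),
                               a=0.0, rng=np.random.default_rng(0),
                               lower=WIDE[0], upper=WIDE[1],
                               coefficient_draws=pairs)
        np.testing.assert_allclose(out, [2.0])

    def test_sentries_zero_distance_fixed_point(self):
        s = np.array([1.0])
        pairs = [(np.array([0.7]), np.ones(1))] * 3
        out = exploit_sentries(s, s, s, s, a=1.0, rng=np.random.default_rng(0),
                               lower=WIDE[0], upper=WIDE[1], coefficient_draws=pairs)
        np.testing.assert_allclose(out, [1.0])

    def test_flock_closed_form(self):
        out = exploit_flock(np.array([1.0]), np.array([0.0]), z=1.0, w=1.0,
                            d_step=np.array([0.5]), lower=WIDE[0], upper=WIDE[1])
        np.testing.assert_allclose(out, [2.0])

    def test_flock_zero_step_or_coincident_is_identity(self):
        x = np.array([1.0])
        out = exploit_flock(x, x, 0.7, 1.3, np.array([0.9]), *WIDE)
        np.testing.assert_allclose(out, x)
        out = exploit_flock(x, np.array([-4.0]), 0.7, 1.3, np.zeros(1), *WIDE)
        np.testing.assert_allclose(out, x)

    def test_updates_respect_bounds(self):
        lower, upper = np.array([0.0]), np.array([1.0])
        draws = make_draws(A=[50.0], C=[1.0])
        out = explore_leader(np.array([0.0]), np.array([1.0]), draws, lower, upper)
        assert 0.0 <= out[0] <= 1.0


class TestGroupDynamics:
    def make_pop(self, n1, n2, stagnation=0):
        agents = [Agent(np.zeros(1), float(i)) for i in range(n1 + n2)]
        for i, ag in enumerate(agents):
            ag.group_tag = EXPLORATION if i < n1 else EXPLOITATION
        leader = Agent(np.zeros(1), 0.0)
        return Population(agents, leader, n1, n2, stagnation_counter=stagnation)

    def test_normal_iteration_shifts_toward_exploitation(self):
        pop = self.make_pop(4, 6)
        resize_groups(pop, GGOConfig(population_size=10), np.random.default_rng(0))
        assert (pop.n1, pop.n2) == (3, 7)

    def test_stagnation_reverses_shift_and_resets_counter(self):
        pop = self.make_pop(2, 8, stagnation=3)
        resize_groups(pop, GGOConfig(population_size=10), np.random.default_rng(0))
        assert (pop.n1, pop.n2) == (3, 7)
        assert pop.stagnation_counter == 0

    def test_min_group_size_floor(self):
        pop = self.make_pop(1, 9)
        resize_groups(pop, GGOConfig(population_size=10), np.random.default_rng(0))
        assert (pop.n1, pop.n2) == (1, 9)

    def test_tags_match_group_sizes_after_resize(self):
        pop = self.make_pop(5, 5)
        resize_groups(pop, GGOConfig(population_size=10), np.random.default_rng(1))
        tags = [ag.group_tag for ag in pop.agents]
        assert tags.count(EXPLORATION) == pop.n1
        assert tags.count(EXPLOITATION) == pop.n2
        assert pop.n1 + pop.n2 == 10


class TestMutation:
    def test_rate_zero_is_identity(self):
        x = np.linspace(0, 1, 5)
        out = mutate(x, 0.0, np.random.default_rng(0), np.zeros(5), np.ones(5))
        np.testing.assert_array_equal(out, x)

    def test_rate_one_redraws_everything_reproducibly(self):
        x = np.full(8, 0.5)
        lower, upper = np.zeros(8), np.ones(8)
        out1 = mutate(x, 1.0, np.random.default_rng(42), lower, upper)
        out2 = mutate(x, 1.0, np.random.default_rng(42), lower, upper)
        np.testing.assert_array_equal(out1, out2)
        assert np.all((out1 >= 0) & (out1 <= 1))
        assert not np.array_equal(out1, x)

    def test_mutated_fraction_near_rate(self):
        x = np.full(1000, 0.5)
        out = mutate(x, 0.5, np.random.default_rng(3), np.zeros(1000), np.ones(1000))
        frac = np.mean(out != x)
        assert 0.45 <= frac <= 0.55


class TestRunGGO:
    def test_constant_objective(self):
        cfg = GGOConfig(population_size=6, max_iterations=10,
                        bounds=((0, 1),), seed=0)
        result = run_ggo(lambda x: 7.0, cfg)
        assert result.best_fitness == 7.0
        np.testing.assert_array_equal(result.fitness_trace, np.full(10, 7.0))

    def test_sphere_convergence_median_over_seeds(self):
        finals = []
        for seed in range(10):
            cfg = GGOConfig(population_size=20, max_iterations=200,
                            bounds=((-5, 5), (-5, 5)), seed=seed)
            finals.append(run_ggo(lambda x: float(np.sum(x**2)), cfg).best_fitness)
        assert np.median(finals) <= 1e-2

    def test_1d_quadratic_minimizer_recovered(self):
        cfg = GGOConfig(population_size=20, max_iterations=100,
                        bounds=((0, 10),), seed=5)
        result = run_ggo(lambda x: float((x[0] - 3.0) ** 2), cfg)
        assert abs(result.best_position[0] - 3.0) <= 0.1

    def test_non_finite_objective_raises_with_position(self):
        cfg = GGOConfig(population_size=4, max_iterations=2, bounds=((0, 1),), seed=0)
        with pytest.raises(RuntimeError, match="non-finite"):
            run_ggo(lambda x: float("nan"), cfg)

    def test_reproducible_for_fixed_seed(self):
        cfg = GGOConfig(population_size=10, max_iterations=30,
                        bounds=((-2, 2),) * 3, seed=11)
        obj = lambda x: float(np.sum((x - 0.5) ** 2))
        r1, r2 = run_ggo(obj, cfg), run_ggo(obj, cfg)
        np.testing.assert_array_equal(r1.best_position, r2.best_position)
        np.testing.assert_array_equal(r1.fitness_trace, r2.fitness_trace)
        assert r1.group_size_trace == r2.group_size_trace

    def test_elitism_and_group_conservation_over_many_runs(self):
        """Best-so-far is non-increasing and n1+n2 is conserved for 50
        random quadratic objectives/seeds."""
        rng = np.random.default_rng(0)
        for trial in range(50):
            d = int(rng.integers(1, 4))
            centre = rng.uniform(-1, 1, d)
            cfg = GGOConfig(population_size=int(rng.integers(4, 10)),
                            max_iterations=15,
                            bounds=tuple((-2.0, 2.0) for _ in range(d)),
                            seed=int(rng.integers(0, 2**31)))
            result = run_ggo(lambda x, c=centre: float(np.sum((x - c) ** 2)), cfg)
            assert np.all(np.diff(result.fitness_trace) <= 0)
            for n1, n2 in result.group_size_trace:
                assert n1 + n2 == cfg.population_size
                assert n1 >= cfg.min_group_size and n2 >= cfg.min_group_size

    def test_doubling_budget_weakly_improves_sphere(self):
        obj = lambda x: float(np.sum(x**2))
        def median_final(t_max):
            return float(np.median([
                run_ggo(obj, GGOConfig(population_size=10, max_iterations=t_max,
                                       bounds=((-5, 5),) * 2, seed=s)).best_fitness
                for s in range(10)
            ]))
        assert median_final(80) <= median_final(40) * (1 + 1e-9)

    def test_positions_stay_in_bounds(self):
        seen = []
        lo, hi = -1.5, 2.5
        def obj(x):
            seen.append(x.copy())
            return float(np.sum(x**2))
        run_ggo(obj, GGOConfig(population_size=6, max_iterations=20,
                               bounds=((lo, hi),) * 2, seed=2))
        arr = np.array(seen)
        assert arr.min() >= lo and arr.max() <= hi

    def test_initial_groups_split_evenly(self):
        cfg = GGOConfig(population_size=10, max_iterations=1, bounds=((0, 1),), seed=0)
        result = run_ggo(lambda x: float(x[0]), cfg)
        # after the first resize one agent has moved to exploitation
        assert result.group_size_trace[0] == (4, 6)


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"population_size": 3},
        {"max_iterations": 0},
        {"mutation_rate": 1.5},
        {"w_low": 2.0, "w_high": 1.0},
        {"bounds": ((1.0, 1.0),)},
        {"population_size": 4, "min_group_size": 3},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            GGOConfig(**kwargs)
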