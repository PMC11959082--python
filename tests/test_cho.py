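"""Unit and property tests of the CHO metaheuristic."""

import numpy as np
import pytest

from nodulekit.cho import (Bounds, CHOConfig, CHOOptimizer, boundary_step,
                           differential_fitness, exploitation_step,
                           exploration_step, init_swarm, local_effect,
                           optimize, time_control)


def sphere(x):
    return -float(np.sum(np.asarray(x) ** 2))


class TestBounds:
    def test_rejects_inverted_bounds(self):
        with pytest.raises(ValueError):
            Bounds(np.array([0.0, 1.0]), np.array([1.0, 0.5]))

    def test_cube_span(self):
        b = Bounds.cube(-2, 3, 4)
        assert b.dim == 4
        assert np.allclose(b.span, 5.0)


class TestInitSwarm:
    def test_positions_within_bounds_and_previous_equal(self):
        bounds = Bounds.cube(0, 1, 3)
        state = init_swarm(bounds, CHOConfig(pop_size=5, seed=1), sphere)
        assert state.positions.shape == (5, 3)
        assert np.all(state.positions >= 0) and np.all(state.positions <= 1)
        assert np.array_equal(state.positions, state.previous_positions)

    def test_best_fitness_analytic_range(self):
        bounds = Bounds.cube(-1, 1, 2)
        state = init_swarm(bounds, CHOConfig(pop_size=8, seed=2), sphere)
        assert -2.0 <= state.best_fitness <= 0.0
        assert state.best_fitness == state.fitnesses.max()
        assert state.worst_fitness == state.fitnesses.min()

    def test_same_seed_identical(self):
        bounds = Bounds.cube(0, 1, 3)
        a = init_swarm(bounds, CHOConfig(pop_size=5, seed=9), sphere)
        b = init_swarm(bounds, CHOConfig(pop_size=5, seed=9), sphere)
        assert np.array_equal(a.positions, b.positions)

    def test_non_finite_objective_rejected(self):
        bounds = Bounds.cube(0, 1, 2)
        with pytest.raises(ValueError, match="invalid objective"):
            init_swarm(bounds, CHOConfig(pop_size=4, seed=0),
                       lambda x: float("nan"))


class TestTimeControl:
    def test_zero_at_final_iteration(self, rng):
        for _ in range(20):
            assert time_control(50, 50, rng) == 0.0

    def test_bounded_by_one_at_start_of_long_run(self, rng):
        vals = [time_control(1, 10**6, rng) for _ in range(100)]
        assert all(0.0 <= v <= 1.0 for v in vals)

    def test_overflow_raises(self, rng):
        with pytest.raises(ValueError, match="iteration overflow"):
            time_control(51, 50, rng)

    def test_halfway_values_confined_to_half_interval(self, rng):
        # brute-force sampling: at t = t_max/2 the envelope is 1/2
        vals = np.array([time_control(50, 100, rng) for _ in range(10_000)])
        assert vals.min() >= 0.0 and vals.max() <= 0.5
        assert vals.max() > 0.45  # the envelope is actually attained


class TestDifferentialFitness:
    def test_identity_and_subtraction(self):
        assert differential_fitness(0.9, 0.9) == 0.0
        assert differential_fitness(0.8, 0.9) == pytest.approx(-0.1)

    def test_nonpositive_under_elitist_best(self):
        bounds = Bounds.cube(-3, 3, 4)
        state = init_swarm(bounds, CHOConfig(pop_size=12, seed=5), sphere)
        alphas = [differential_fitness(f, state.best_fitness)
                  for f in state.fitnesses]
        assert all(a <= 0 for a in alphas)


class TestExplorationStep:
    def test_zeroed_coefficients_halve_position(self):
        # VF = 0, inertia 0, r3 -> ~0, trial scale 0: update reduces to B/2
        config = CHOConfig(pop_size=3, seed=0, foraging_speed=0.0,
                           inertia_start=1e-12, inertia_end=1e-12,
                           recursive_low=1e-12, recursive_high=1e-9,
                           trial_factor_scale=0.0)
        bounds = Bounds.cube(-1, 1, 2)
        state = init_swarm(bounds, config, sphere)
        state.iteration = 1
        out = exploration_step(state, 0, config, np.random.default_rng(0))
        assert np.allclose(out, state.positions[0] / 2, atol=1e-8)

    def test_collapsed_swarm_matches_symbolic_expansion(self):
        # all members at P, inertia 1, trial scale 0:
        # B' = VF*0 + P + (P + r3*(P - 0))/2 = P*(3 + r3)/2
        config = CHOConfig(pop_size=4, seed=0, inertia_start=1.0,
                           inertia_end=1.0, trial_factor_scale=0.0)
        bounds = Bounds.cube(-5, 5, 3)
        state = init_swarm(bounds, config, sphere)
        P = np.array([0.5, -1.0, 2.0])
        state.positions[:] = P
        state.previous_positions[:] = P
        state.fitnesses[:] = sphere(P)
        state.best_position = P.copy()
        state.best_fitness = sphere(P)
        state.iteration = 1
        # replicate the documented draw order (r3 first, then a)
        probe = np.random.default_rng(7)
        r3 = probe.uniform(config.recursive_low, config.recursive_high)
        out = exploration_step(state, 0, config, np.random.default_rng(7))
        assert np.allclose(out, P * (3 + r3) / 2)

    def test_fixed_seed_repeatable(self):
        config = CHOConfig(pop_size=4, seed=3)
        bounds = Bounds.cube(-1, 1, 2)
        state = init_swarm(bounds, config, sphere)
        state.iteration = 1
        a = exploration_step(state, 1, config, np.random.default_rng(11))
        b = exploration_step(state, 1, config, np.random.default_rng(11))
        assert np.array_equal(a, b)


class TestLocalEffect:
    def test_flat_swarm_yields_zero(self):
        config = CHOConfig(pop_size=3, seed=0)
        state = init_swarm(Bounds.cube(-1, 1, 2), config, lambda x: 1.0)
        assert np.array_equal(local_effect(state, 0, config), np.zeros(2))

    def test_stationary_member_contributes_nothing(self):
        config = CHOConfig(pop_size=3, seed=1)
        state = init_swarm(Bounds.cube(-1, 1, 2), config, sphere)
        # members identical to their previous positions: displacement is zero,
        # so only the fitness-change numerators could contribute - and they
        # are zero too
        state.previous_fitnesses = state.fitnesses.copy()
        assert np.allclose(local_effect(state, 0, config), 0.0)

    def test_hand_summed_three_member_swarm(self):
        config = CHOConfig(pop_size=3, seed=0, epsilon=1e-10)
        state = init_swarm(Bounds.cube(-10, 10, 2), config, sphere)
        state.positions = np.array([[1.0, 0.0], [0.0, 2.0], [1.0, 1.0]])
        state.previous_positions = np.array([[2.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        state.fitnesses = np.array([0.5, 0.9, 0.2])
        state.previous_fitnesses = np.array([0.4, 0.95, 0.2])
        state.best_fitness = 0.9
        state.worst_fitness = 0.2
        expected = np.zeros(2)
        for j in range(3):
            fhat = (state.fitnesses[j] - state.previous_fitnesses[j]) / (0.2 - 0.9)
            num = state.previous_positions[j] - state.positions[j]
            den = (np.linalg.norm(state.previous_positions[j])
                   + np.linalg.norm(state.positions[j]) + config.epsilon)
            expected += fhat * num / den
        assert np.allclose(local_effect(state, 0, config), expected)


class TestExploitationStep:
    @staticmethod
    def _flat_state(config, bounds):
        state = init_swarm(bounds, config, lambda x: 1.0)  # flat fitness
        state.iteration = 1
        return state

    def test_identity_when_all_terms_vanish(self):
        config = CHOConfig(pop_size=3, seed=0, sensitive_factor=0.0,
                           inertia_start=1e-12, inertia_end=1e-12)
        bounds = Bounds.cube(-1, 1, 2)
        state = self._flat_state(config, bounds)
        out = exploitation_step(state, 0, config, np.random.default_rng(0), bounds)
        assert np.allclose(out, state.positions[0], atol=1e-10)

    def test_inertia_two_adds_previous_position(self):
        config = CHOConfig(pop_size=3, seed=0, sensitive_factor=0.0,
                           inertia_start=2.0, inertia_end=2.0)
        bounds = Bounds.cube(-1, 1, 2)
        state = self._flat_state(config, bounds)
        state.previous_positions = state.positions + 0.1
        out = exploitation_step(state, 0, config, np.random.default_rng(0), bounds)
        assert np.allclose(out, state.positions[0] + state.previous_positions[0])

    def test_matches_term_by_term_oracle(self):
        from nodulekit.cho import local_effect as le, target_effect as te

        config = CHOConfig(pop_size=4, seed=2, t_max=10)
        bounds = Bounds.cube(-2, 2, 3)
        state = init_swarm(bounds, config, sphere)
        state.previous_positions = state.positions + 0.05
        state.previous_fitnesses = np.array(
            [sphere(p) for p in state.previous_positions])
        state.iteration = 4

        probe = np.random.default_rng(99)
        r4 = probe.uniform(size=3)
        w = config.inertia(4)
        damp = 1 - 4 / 10
        phi = le(state, 1, config) + te(state, 1, config)
        expected = (state.positions[1]
                    + config.sensitive_factor * r4 * bounds.span * damp
                    + (state.best_position * phi
                       + w * state.previous_positions[1]) / 2)
        out = exploitation_step(state, 1, config, np.random.default_rng(99), bounds)
        assert np.allclose(out, expected)


class TestBoundaryStep:
    def test_in_bounds_unchanged(self, rng):
        bounds = Bounds.cube(0, 1, 3)
        config = CHOConfig(diffusion_max=0.0)
        p = np.array([0.2, 0.5, 0.99])
        assert np.array_equal(boundary_step(p, bounds, config, rng), p)

    def test_wrap_rule_first_branch(self, rng):
        # overshoot above re-enters from the lower face by the overshoot
        bounds = Bounds.cube(0, 1, 1)
        config = CHOConfig(diffusion_max=0.0)
        out = boundary_step(np.array([1.2]), bounds, config, rng)
        assert np.allclose(out, [0.2])

    def test_wrap_rule_second_branch(self, rng):
        bounds = Bounds.cube(0, 1, 1)
        config = CHOConfig(diffusion_max=0.0)
        out = boundary_step(np.array([-0.3]), bounds, config, rng)
        assert np.allclose(out, [0.7])

    def test_always_contained_after_repair(self, rng):
        bounds = Bounds.cube(-1, 2, 4)
        config = CHOConfig(diffusion_max=0.5)
        for _ in range(2000):
            p = rng.uniform(-20, 20, size=4)
            out = boundary_step(p, bounds, config, rng)
            assert np.all(out >= bounds.lower) and np.all(out <= bounds.upper)


class TestOptimize:
    def test_history_monotone_and_positions_contained(self):
        bounds = Bounds.cube(-5, 5, 3)
        config = CHOConfig(pop_size=10, t_max=40, seed=4)
        contained = []
        result = optimize(
            sphere, bounds, config,
            callback=lambda s: contained.append(
                bool(np.all(s.positions >= bounds.lower)
                     and np.all(s.positions <= bounds.upper))),
        )
        assert np.all(np.diff(result.history) >= 0)
        assert len(contained) == 40 and all(contained)

    def test_single_iteration_budget(self):
        bounds = Bounds.cube(-1, 1, 2)
        result = optimize(sphere, bounds, CHOConfig(pop_size=5, t_max=1, seed=0))
        assert result.history.shape == (1,)
        assert result.best_fitness == result.history[0]

    def test_constant_objective(self):
        bounds = Bounds.cube(0, 1, 2)
        result = optimize(lambda x: 3.25, bounds,
                          CHOConfig(pop_size=5, t_max=10, seed=0))
        assert result.best_fitness == 3.25

    def test_bit_reproducible_trajectory(self):
        bounds = Bounds.cube(-5, 5, 4)
        config = CHOConfig(pop_size=8, t_max=30, seed=13)
        a = optimize(sphere, bounds, config)
        b = optimize(sphere, bounds, config)
        assert np.array_equal(a.history, b.history)
        assert np.array_equal(a.best_position, b.best_position)

    def test_non_finite_candidates_kept_out(self):
        # objective undefined outside the unit disk: those candidates are
        # rejected and the member keeps its previous (finite) position
        def partial(x):
            r2 = float(np.sum(x**2))
            return -r2 if r2 <= 1.0 else float("nan")

        bounds = Bounds.cube(-0.9, 0.9, 2)
        result = optimize(partial, bounds, CHOConfig(pop_size=6, t_max=25, seed=3))
        assert np.isfinite(result.best_fitness)
        assert np.all(np.isfinite(result.state.fitnesses))

    def test_optimizer_wrapper_writes_trace(self, tmp_path):
        path = tmp_path / "trace.csv"
        opt = CHOOptimizer(pop_size=5, t_max=6, seed=0)
        opt.optimize(sphere, Bounds.cube(-1, 1, 2), trace_path=path)
        lines = path.read_text().strip().splitlines()
        assert lines[0] == "iteration,best_fitness,mean_fitness"
        assert len(lines) == 7

    def test_rejects_unknown_config_field(self):
        with pytest.raises(TypeError):
            CHOOptimizer(bogus=1)


class TestBoundaryProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    vec = st.lists(st.floats(-1e6, 1e6, allow_nan=False, allow_infinity=False),
                   min_size=3, max_size=3)

    @given(vec)
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_repair_always_lands_inside_bounds(self, vals):
        bounds = Bounds.cube(-2.0, 3.0, 3)
        config = CHOConfig(diffusion_max=0.01)
        rng = np.random.default_rng(0)
        out = boundary_step(np.array(vals), bounds, config, rng)
        assert np.all(out >= bounds.lower) and np.all(out <= bounds.upper)
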