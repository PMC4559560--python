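"""Unit and property tests for GA / PSO / BFO / BFPSO and their primitives."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecgbbb.swarm_optimizers import (
    Agent,
    SwarmConfig,
    SwarmState,
    bfo_optimize,
    bfpso_optimize,
    chemotaxis_move,
    elimination_dispersal,
    ga_optimize,
    pso_optimize,
    pso_position_update,
    pso_velocity_update,
    reproduction,
    rosenbrock,
    sphere,
    tumble_direction,
)


class _OnesRng:
    """Stub stream returning 1.0 everywhere (forces phi1 = phi2 = 1)."""

    def random(self, n=None):
        return np.ones(n) if n is not None else 1.0


def _state(agents, seed=0):
    return SwarmState(agents=agents, rng=np.random.default_rng(seed))


class TestObjectives:
    @pytest.mark.parametrize(
        "x, expected",
        [((1.0, 1.0, 1.0), 0.0), ((0.0, 0.0), 1.0), ((-1.0, 1.0), 4.0)],
    )
    def test_rosenbrock_hand_values(self, x, expected):
        assert rosenbrock(np.array(x)) == pytest.approx(expected)

    def test_rosenbrock_rejects_1d(self):
        with pytest.raises(ValueError):
            rosenbrock(np.array([2.0]))

    @given(st.lists(st.floats(-5, 5), min_size=2, max_size=6))
    @settings(deadline=None, max_examples=50)
    def test_rosenbrock_nonnegative(self, coords):
        assert rosenbrock(np.array(coords)) >= 0.0


class TestPsoUpdates:
    def test_pure_inertia(self):
        v = pso_velocity_update(np.array([2.0, -2.0]), np.zeros(2), np.zeros(2),
                                np.zeros(2), 0.5, 0.0, 0.0, np.random.default_rng(0))
        assert np.allclose(v, [1.0, -1.0])

    def test_zero_attraction_when_at_both_bests(self):
        x = np.array([1.5, -0.5])
        v = pso_velocity_update(np.array([0.3, 0.7]), x, x.copy(), x.copy(),
                                0.5, 2.0, 2.0, np.random.default_rng(1))
        assert np.allclose(v, 0.5 * np.array([0.3, 0.7]))

    def test_forced_phi_hand_value(self):
        """x=0, v=1, pbest=2, gbest=4, w=0.5, c1=c2=1, phi=1 -> v'=6.5, x'=6.5."""
        v = pso_velocity_update(np.array([1.0]), np.array([0.0]), np.array([2.0]),
                                np.array([4.0]), 0.5, 1.0, 1.0, _OnesRng())
        assert v[0] == pytest.approx(6.5)
        x, v2 = pso_position_update(np.array([0.0]), v, np.array([-10.0]), np.array([10.0]))
        assert x[0] == pytest.approx(6.5) and v2[0] == pytest.approx(6.5)

    def test_velocity_clamped_elementwise(self):
        v = pso_velocity_update(np.array([100.0, -100.0]), np.zeros(2), np.zeros(2),
                                np.zeros(2), 1.0, 0.0, 0.0, np.random.default_rng(0),
                                clamp=np.array([2.0, 2.0]))
        assert np.allclose(v, [2.0, -2.0])

    def test_position_clip_zeroes_velocity_on_hit_dimension(self):
        x, v = pso_position_update(np.array([4.9, 0.0]), np.array([1.0, 1.0]),
                                   np.array([-5.0, -5.0]), np.array([5.0, 5.0]))
        assert np.allclose(x, [5.0, 1.0])
        assert v[0] == 0.0 and v[1] == 1.0


class TestTumbleDirection:
    def test_unit_norm(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            assert np.linalg.norm(tumble_direction(5, rng)) == pytest.approx(1.0, abs=1e-12)

    def test_1d_gives_plus_minus_one(self):
        rng = np.random.default_rng(4)
        draws = {float(tumble_direction(1, rng)[0]) for _ in range(50)}
        assert draws <= {-1.0, 1.0} and len(draws) == 2

    def test_directional_symmetry_monte_carlo(self):
        rng = np.random.default_rng(5)
        mean = np.mean([tumble_direction(2, rng) for _ in range(10_000)], axis=0)
        assert np.linalg.norm(mean) < 0.05


class TestChemotaxis:
    def test_swims_to_origin_with_forced_direction(self):
        """Distance objective, start (1,0), direction (-1,0), C=0.25, Ns=4."""
        evals = []

        def objective(x):
            evals.append(x.copy())
            return float(np.linalg.norm(x))

        agent = Agent(position=np.array([1.0, 0.0]), velocity=np.zeros(2), fitness=1.0)
        state = _state([agent])
        chemotaxis_move(agent, objective, np.array([0.25, 0.25]), 4,
                        state.rng, np.array([-5.0, -5.0]), np.array([5.0, 5.0]),
                        state, direction=np.array([-1.0, 0.0]))
        assert np.allclose(agent.position, [0.0, 0.0])
        improving = sum(1 for e in evals if np.linalg.norm(e) < 1.0 + 1e-12)
        assert improving >= 4 and agent.fitness == pytest.approx(0.0)

    def test_single_tumble_has_step_length_c(self):
        agent = Agent(position=np.zeros(3), velocity=np.zeros(3), fitness=0.0)
        state = _state([agent], seed=9)
        chemotaxis_move(agent, sphere, np.full(3, 0.7), 0, state.rng,
                        np.full(3, -10.0), np.full(3, 10.0), state)
        assert np.linalg.norm(agent.position) == pytest.approx(0.7)
        assert state.evaluations == 1

    def test_constant_objective_takes_tumble_but_no_swim_moves(self):
        agent = Agent(position=np.zeros(2), velocity=np.zeros(2), fitness=5.0)
        state = _state([agent], seed=2)
        chemotaxis_move(agent, lambda x: 5.0, np.full(2, 0.5), 3, state.rng,
                        np.full(2, -10.0), np.full(2, 10.0), state)
        assert np.linalg.norm(agent.position) == pytest.approx(0.5)  # tumble only

    def test_nonfinite_objective_raises(self):
        agent = Agent(position=np.zeros(2), velocity=np.zeros(2), fitness=0.0)
        state = _state([agent])
        with pytest.raises(ValueError, match="non-finite"):
            chemotaxis_move(agent, lambda x: float("nan"), np.full(2, 0.1), 0,
                            state.rng, np.full(2, -1.0), np.full(2, 1.0), state)


class TestReproductionAndDispersal:
    def _agents(self, healths):
        return [Agent(position=np.array([float(i)]), velocity=np.zeros(1), health=h)
                for i, h in enumerate(healths)]

    def test_healthier_half_survives_and_duplicates(self):
        state = _state(self._agents([3.0, 1.0, 4.0, 2.0]))
        reproduction(state)
        positions = sorted(float(a.position[0]) for a in state.agents)
        assert positions == [1.0, 1.0, 3.0, 3.0]  # agents with health 1 and 2
        assert len(state.agents) == 4
        assert all(a.health == 0.0 for a in state.agents)

    def test_ties_keep_first_agents(self):
        state = _state(self._agents([1.0, 1.0, 1.0, 1.0]))
        reproduction(state)
        assert sorted(float(a.position[0]) for a in state.agents) == [0.0, 0.0, 1.0, 1.0]

    def test_odd_population_rejected(self):
        state = _state(self._agents([1.0, 2.0, 3.0]))
        with pytest.raises(ValueError):
            reproduction(state)

    def test_dispersal_ped_zero_is_identity(self):
        state = _state(self._agents([1.0, 2.0]))
        before = [a.position.copy() for a in state.agents]
        elimination_dispersal(state, 0.0, state.rng, np.array([-5.0]), np.array([5.0]))
        assert all(np.array_equal(b, a.position) for b, a in zip(before, state.agents))

    def test_dispersal_ped_one_redraws_all_inside_bounds(self):
        state = _state(self._agents([1.0, 2.0, 3.0, 4.0]), seed=11)
        elimination_dispersal(state, 1.0, state.rng, np.array([10.0]), np.array([20.0]))
        assert all(10.0 <= a.position[0] <= 20.0 for a in state.agents)

    def test_dispersal_count_within_binomial_envelope(self):
        from scipy.stats import binom

        state = _state(self._agents([0.0] * 400), seed=12)
        before = [a.position.copy() for a in state.agents]
        elimination_dispersal(state, 0.25, state.rng, np.array([-5.0]), np.array([5.0]))
        moved = sum(not np.array_equal(b, a.position) for b, a in zip(before, state.agents))
        assert binom.ppf(0.005, 400, 0.25) <= moved <= binom.ppf(0.995, 400, 0.25)


BUDGET_CFG = dict(population=20, dims=2, lo=-5.0, hi=5.0, n_chemotactic=30,
                  swim_length=4, n_reproduction=4, n_elimination=2)


class TestOptimizers:
    @pytest.mark.parametrize("optimize", [bfo_optimize, bfpso_optimize])
    def test_bfo_family_sphere_converges_and_is_deterministic(self, optimize):
        cfg = SwarmConfig(seed=7, **BUDGET_CFG)
        _, best, state = optimize(sphere, cfg)
        assert best < 1e-1
        _, best2, state2 = optimize(sphere, SwarmConfig(seed=7, **BUDGET_CFG))
        assert best == best2 and state.trace == state2.trace

    def test_bfo_budget_bound(self):
        cfg = SwarmConfig(seed=7, **BUDGET_CFG)
        _, _, state = bfo_optimize(sphere, cfg)
        s, nc, ns = cfg.population, cfg.n_chemotactic, cfg.swim_length
        assert state.evaluations <= s * nc * (ns + 1) * cfg.n_reproduction * cfg.n_elimination

    def test_bfpso_rosenbrock_2d(self):
        cfg = SwarmConfig(population=30, dims=2, lo=-5.0, hi=5.0, n_chemotactic=50,
                          n_reproduction=4, n_elimination=2, seed=7)
        _, best, _ = bfpso_optimize(rosenbrock, cfg)
        assert best < 1e-1

    def test_pso_sphere_high_precision(self):
        cfg = SwarmConfig(population=20, dims=2, lo=-5.0, hi=5.0, n_iterations=100, seed=5)
        _, best, state = pso_optimize(sphere, cfg)
        assert best < 1e-3
        _, best2, state2 = pso_optimize(sphere, SwarmConfig(population=20, dims=2, lo=-5.0,
                                                            hi=5.0, n_iterations=100, seed=5))
        assert best == best2 and state.trace == state2.trace

    def test_pso_frozen_when_all_coefficients_zero(self):
        cfg = SwarmConfig(population=10, dims=2, lo=-5.0, hi=5.0, n_iterations=20,
                          omega_start=1e-9, omega_end=1e-9, c1=0.0, c2=0.0, seed=1)
        _, _, state = pso_optimize(sphere, cfg)
        assert len(set(state.trace)) == 1  # trace constant after init

    def test_ga_sphere_converges(self):
        cfg = SwarmConfig(population=30, dims=2, lo=-5.0, hi=5.0, n_iterations=50, seed=3)
        _, best, _ = ga_optimize(sphere, cfg)
        assert best < 1e-1

    def test_ga_without_variation_keeps_initial_best(self):
        cfg = SwarmConfig(population=10, dims=3, lo=-5.0, hi=5.0, n_iterations=30,
                          crossover_rate=0.0, mutation_rate=0.0, seed=2)
        _, best, state = ga_optimize(sphere, cfg)
        assert best == state.trace[0]  # no variation: cannot beat the initial best

    @pytest.mark.parametrize("optimize", [ga_optimize, pso_optimize, bfo_optimize, bfpso_optimize])
    def test_trace_nonincreasing_and_position_feasible(self, optimize):
        cfg = SwarmConfig(population=12, dims=3, lo=-2.0, hi=3.0, n_chemotactic=10,
                          n_reproduction=2, n_elimination=2, n_iterations=20, seed=13)
        pos, best, state = optimize(rosenbrock, cfg)
        assert all(a >= b for a, b in zip(state.trace, state.trace[1:]))
        assert np.all(pos >= cfg.lo) and np.all(pos <= cfg.hi)
        assert len(state.agents) == 12  # population conserved
        assert best == state.trace[-1]

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SwarmConfig(population=7)  # odd
        with pytest.raises(ValueError):
            SwarmConfig(lo=5.0, hi=-5.0)
        with pytest.raises(ValueError):
            SwarmConfig(p_eliminate=1.5)
        with pytest.raises(ValueError):
            SwarmConfig(omega_start=2.0)
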