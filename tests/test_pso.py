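"""Swarm optimizer: schedules, neighbor pruning, projection, convergence."""

import numpy as np
import pytest

from cellsqueeze3d import (
    NucleusObservation,
    SwarmConfig,
    build_neighbor_sets,
    initialize_swarm,
    optimize,
    schedule_at,
    step,
)
from cellsqueeze3d.pso import _Problem, genetic_perturbation


def brute_neighbor_sets(centers, R, tau_factor=2.0):
    tau = tau_factor * max(R)
    n = len(centers)
    sets = [set() for _ in range(n)]
    for i in range(n):
        for j in range(n):
            if i != j and np.linalg.norm(np.asarray(centers[i]) - np.asarray(centers[j])) <= tau:
                sets[i].add(j)
    return sets


class TestSchedule:
    def test_endpoints_match_published_table(self):
        config = SwarmConfig(T=120)
        s0 = schedule_at(0, config)
        sT = schedule_at(119, config)
        assert (s0.w, s0.c1, s0.c2) == pytest.approx((0.9, 2.5, 1.0))
        assert (sT.w, sT.c1, sT.c2) == pytest.approx((0.4, 1.0, 2.6))

    def test_linear_midpoint(self):
        config = SwarmConfig(T=121)  # odd horizon: exact midpoint exists
        s = schedule_at(60, config)
        assert (s.w, s.c1, s.c2) == pytest.approx((0.65, 1.75, 1.8))

    def test_out_of_range_rejected(self):
        config = SwarmConfig(T=10)
        with pytest.raises(ValueError):
            schedule_at(10, config)
        with pytest.raises(ValueError):
            schedule_at(-1, config)

    def test_monotone_schedules(self):
        config = SwarmConfig(T=50)
        vals = [schedule_at(t, config) for t in range(50)]
        assert all(a.w >= b.w for a, b in zip(vals, vals[1:]))
        assert all(a.c1 >= b.c1 for a, b in zip(vals, vals[1:]))
        assert all(a.c2 <= b.c2 for a, b in zip(vals, vals[1:]))


class TestNeighborSets:
    def test_far_pair_has_empty_sets(self):
        centers = np.array([[0.0, 0, 0], [100.0, 0, 0]])
        sets = build_neighbor_sets(centers, [3.0, 3.0])
        assert sets == [set(), set()]

    def test_collinear_chain(self):
        # threshold tau = 2 * 5 = 10; spacing tau/2 = 5
        centers = np.array([[0.0, 0, 0], [5.0, 0, 0], [10.0, 0, 0]])
        sets = build_neighbor_sets(centers, [5.0, 5.0, 5.0])
        assert sets[1] == {0, 2}
        assert 1 in sets[0] and 1 in sets[2]

    def test_matches_brute_force(self):
        rng = np.random.default_rng(3)
        for n in (2, 10, 50, 150):
            centers = rng.uniform(0, 60, size=(n, 3))
            R = rng.uniform(3, 9, size=n)
            got = build_neighbor_sets(centers, R)
            want = brute_neighbor_sets(centers, R)
            assert got == want

    def test_empty_input(self):
        assert build_neighbor_sets(np.empty((0, 3)), []) == []


class TestInitialization:
    def test_positions_inside_box(self, small_tissue):
        config = small_tissue.config(n_swarm=8, seed=5)
        problem = _Problem(small_tissue.observations, config)
        state = initialize_swarm(small_tissue.observations, config)
        for p in state.particles:
            assert np.all(p.position >= problem.lower - 1e-12)
            assert np.all(p.position <= problem.upper + 1e-12)
            assert np.all(p.velocity == 0.0)

    def test_same_seed_identical_swarms(self, small_tissue):
        config = small_tissue.config(n_swarm=6, seed=11)
        a = initialize_swarm(small_tissue.observations, config)
        b = initialize_swarm(small_tissue.observations, config)
        for pa, pb in zip(a.particles, b.particles):
            np.testing.assert_array_equal(pa.position, pb.position)
        assert a.gbest_loss == b.gbest_loss

    def test_jitter_separates_coincident_nuclei(self):
        """Depth redraws resolve a 2D-coincident pair in >= 95% of particles."""
        obs = [
            NucleusObservation(id=1, x=10.0, y=10.0, r_nuc=4.0),
            NucleusObservation(id=2, x=10.0, y=10.0, r_nuc=4.0),
        ]
        config = SwarmConfig(n_swarm=1000, seed=2)
        state = initialize_swarm(obs, config)
        ok = sum(abs(p.position[0] - p.position[1]) >= 8.0 for p in state.particles)
        assert ok >= 950

    def test_pbest_consistency(self, small_tissue):
        config = small_tissue.config(n_swarm=5, seed=1)
        problem = _Problem(small_tissue.observations, config)
        state = initialize_swarm(small_tissue.observations, config)
        for p in state.particles:
            assert p.pbest_loss == problem.evaluate(p.pbest_position).L


class TestStep:
    def test_fixed_point(self, small_tissue):
        """Zero velocity at the common best position is a fixed point."""
        config = small_tissue.config(n_swarm=4, seed=3)
        rng = np.random.default_rng(0)
        state = initialize_swarm(small_tissue.observations, config, rng)
        for p in state.particles:
            p.position = state.gbest_position.copy()
            p.velocity[:] = 0.0
            p.pbest_position = state.gbest_position.copy()
            p.pbest_loss = state.gbest_loss
        before = state.gbest_position.copy()
        step(state, small_tissue.observations, config, rng)
        for p in state.particles:
            np.testing.assert_allclose(p.position, before)
        assert state.gbest_loss == state.trace[-1].L

    def test_gbest_never_increases(self, small_tissue):
        config = small_tissue.config(n_swarm=8, T=20, seed=9)
        rng = np.random.default_rng(9)
        state = initialize_swarm(small_tissue.observations, config, rng)
        prev = state.gbest_loss
        for _ in range(config.T):
            step(state, small_tissue.observations, config, rng)
            assert state.gbest_loss <= prev
            prev = state.gbest_loss

    def test_projection_clips_to_box(self, small_tissue):
        config = small_tissue.config(n_swarm=4, seed=13)
        problem = _Problem(small_tissue.observations, config)
        rng = np.random.default_rng(13)
        state = initialize_swarm(small_tissue.observations, config, rng)
        # force velocities that push far outside the box
        for p in state.particles:
            p.velocity = problem.width * 10.0
        step(state, problem, config, rng)
        for p in state.particles:
            assert np.all(p.position >= problem.lower)
            assert np.all(p.position <= problem.upper)


class TestGeneticPerturbation:
    def test_disabled_is_identity(self, small_tissue):
        config = small_tissue.config(n_swarm=8, seed=1, ga_enabled=False)
        rng = np.random.default_rng(1)
        state = initialize_swarm(small_tissue.observations, config, rng)
        positions = [p.position.copy() for p in state.particles]
        genetic_perturbation(state, small_tissue.observations, config, rng)
        for p, q in zip(state.particles, positions):
            np.testing.assert_array_equal(p.position, q)

    def test_projected_and_gbest_preserved(self, small_tissue):
        config = small_tissue.config(n_swarm=12, seed=4, ga_enabled=True)
        problem = _Problem(small_tissue.observations, config)
        rng = np.random.default_rng(4)
        state = initialize_swarm(small_tissue.observations, config, rng)
        for s in range(20):
            before = state.gbest_loss
            genetic_perturbation(state, problem, config, rng)
            assert state.gbest_loss <= before
            for p in state.particles:
                assert np.all(p.position >= problem.lower - 1e-12)
                assert np.all(p.position <= problem.upper + 1e-12)


class TestOptimize:
    def test_single_nucleus_is_feasible_at_init(self):
        obs = [NucleusObservation(id=1, x=5.0, y=5.0, r_nuc=4.0)]
        config = SwarmConfig(n_swarm=5, T=5, seed=0)
        cells, bd, trace = optimize(obs, config)
        assert bd.L == 0.0
        assert len(trace) == 5

    def test_free_field_limit(self):
        """Widely spaced nuclei: initialization is already feasible."""
        obs = [
            NucleusObservation(id=k, x=100.0 * k, y=0.0, r_nuc=4.0) for k in range(1, 5)
        ]
        config = SwarmConfig(n_swarm=6, T=4, seed=1)
        cells, bd, trace = optimize(obs, config)
        assert trace[0] == 0.0 and bd.L == 0.0

    def test_deterministic_under_seed(self, small_tissue, fast_config):
        config = small_tissue.config(n_swarm=10, T=15, seed=21)
        a_cells, a_bd, a_trace = optimize(small_tissue.observations, config)
        b_cells, b_bd, b_trace = optimize(small_tissue.observations, config)
        assert a_trace == b_trace
        for ca, cb in zip(a_cells, b_cells):
            assert (ca.z, ca.R) == (cb.z, cb.R)

    def test_trace_monotone_across_seeds(self, small_tissue):
        for seed in range(20):
            config = small_tissue.config(n_swarm=8, T=12, seed=seed)
            _, _, trace = optimize(small_tissue.observations, config)
            assert len(trace) == 12
            assert all(a >= b for a, b in zip(trace, trace[1:]))

    def test_recovery_reduces_or_preserves_feasibility(self, small_tissue):
        """Final loss is 0 when initialization is feasible, else far below
        the initial median particle loss."""
        finals, initials = [], []
        for seed in range(10):
            config = small_tissue.config(n_swarm=10, T=20, seed=seed)
            state = initialize_swarm(small_tissue.observations, config)
            initials.append(float(np.median([p.pbest_loss for p in state.particles])))
            _, bd, _ = optimize(small_tissue.observations, config)
            finals.append(bd.L)
        med_final = float(np.median(finals))
        med_init = float(np.median(initials))
        if med_init == 0.0:
            assert med_final == 0.0
        else:
            assert med_final < 1e-3 * med_init

    def test_requires_observations(self):
        with pytest.raises(ValueError):
            optimize([], SwarmConfig())

    def test_duplicate_ids_rejected(self):
        obs = [
            NucleusObservation(id=1, x=0.0, y=0.0, r_nuc=3.0),
            NucleusObservation(id=1, x=50.0, y=0.0, r_nuc=3.0),
        ]
        with pytest.raises(ValueError):
            optimize(obs, SwarmConfig(n_swarm=4, T=2))
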