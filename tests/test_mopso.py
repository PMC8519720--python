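"""Swarm mechanics: index mapping, velocity schedule, archive, termination."""

import numpy as np
import pytest

from psoimpute.data import ChainOrder, VariableSchema
from psoimpute.errors import OptimizationFailureError
from psoimpute.mopso import (ParetoArchive, Particle, SwarmConfig, check_termination,
                             decode, dominates, final_select, init_swarm, map_index,
                             optimize, swarm_diameter, termination_state,
                             update_velocity, vmax_schedule)

SCHEMA_2 = (
    VariableSchema("d", "discrete"),
    VariableSchema("c", "continuous"),
    VariableSchema("y", "discrete", "dependent"),
)
ORDER_2 = ChainOrder(("d", "c"))


class TestMapIndex:
    @pytest.mark.parametrize("x,n,expected", [
        (0.0, 18, 1),
        (1.0, 18, 18),
        (0.75, 18, 14),   # the 9-NN anchor of the discrete pool
        (0.60, 9, 6),
        (0.999, 9, 9),
    ])
    def test_pinned_values(self, x, n, expected):
        assert map_index(x, n) == expected

    def test_domain_error(self):
        with pytest.raises(ValueError):
            map_index(1.2, 18)

    def test_surjective_monotone_equal_partition(self):
        for n in (1, 2, 9, 18):
            grid = np.linspace(0, 1, 1801)
            idx = [map_index(float(x), n) for x in grid]
            assert set(idx) == set(range(1, n + 1))
            assert all(a <= b for a, b in zip(idx, idx[1:]))


class TestDecode:
    def test_all_zero_position_selects_first_algorithms(self):
        a = decode(np.zeros(2), ORDER_2, SCHEMA_2)
        assert a.index_tuple() == (1, 1)

    def test_mixed_position(self):
        a = decode(np.array([0.75, 0.60]), ORDER_2, SCHEMA_2)
        assert a.index_tuple() == (14, 6)
        assert a.spec_for("d").label == "9-NN"


class TestSwarmBasics:
    def test_default_swarm_has_100_uniform_particles(self):
        swarm = init_swarm(SwarmConfig(seed=1), 3)
        assert len(swarm) == 100
        pos = np.concatenate([p.position for p in swarm])
        assert ((0 <= pos) & (pos <= 1)).all()
        assert all(np.all(p.velocity == 0) for p in swarm)

    def test_same_seed_reproduces_swarm(self):
        a = init_swarm(SwarmConfig(seed=5), 4)
        b = init_swarm(SwarmConfig(seed=5), 4)
        assert all(np.array_equal(x.position, y.position) for x, y in zip(a, b))

    def test_uniform_component_mean(self):
        swarm = init_swarm(SwarmConfig(n_particles=2500, seed=2), 4)
        pos = np.concatenate([p.position for p in swarm])
        assert 0.47 <= pos.mean() <= 0.53

    @pytest.mark.parametrize("gen,delta", [(0, 1.0), (1, 0.9), (2, 0.81)])
    def test_delta_schedule(self, gen, delta):
        v = vmax_schedule(gen, SwarmConfig(), [(0.0, 1.0)] * 3)
        assert v == pytest.approx([delta] * 3)

    def test_velocity_zero_attraction(self):
        p = Particle(np.array([0.5]), np.array([0.2]), np.array([0.5]))
        v = update_velocity(p, np.array([0.5]), SwarmConfig(), np.array([1.0]),
                            np.random.default_rng(0))
        assert v[0] == pytest.approx(0.2)

    def test_velocity_clamped_symmetrically(self):
        cfg = SwarmConfig(c1=10.0, c2=10.0)
        p_up = Particle(np.array([0.0]), np.array([0.9]), np.array([1.0]))
        v = update_velocity(p_up, np.array([1.0]), cfg, np.array([0.5]),
                            np.random.default_rng(1))
        assert v[0] == pytest.approx(0.5)
        p_dn = Particle(np.array([1.0]), np.array([-0.9]), np.array([0.0]))
        v = update_velocity(p_dn, np.array([0.0]), cfg, np.array([0.5]),
                            np.random.default_rng(1))
        assert v[0] == pytest.approx(-0.5)


def brute_force_front(stream):
    return {
        tuple(o) for _, o in stream
        if not any(dominates(tuple(other), tuple(o)) for _, other in stream)
    }


class TestParetoArchive:
    def test_strict_domination_replaces(self):
        arch = ParetoArchive()
        arch.add(np.array([0.1]), (0.2, 0.3))
        arch.add(np.array([0.2]), (0.1, 0.1))
        assert [m.objectives for m in arch.members] == [(0.1, 0.1)]

    def test_mutual_nondomination_keeps_both(self):
        arch = ParetoArchive()
        arch.add(np.array([0.1]), (0.1, 0.4))
        arch.add(np.array([0.2]), (0.4, 0.1))
        assert len(arch) == 2

    def test_matches_bruteforce_filter_on_random_streams(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            stream = [(rng.uniform(size=2), tuple(rng.uniform(size=2))) for _ in range(200)]
            arch = ParetoArchive(capacity=None)
            for pos, obj in stream:
                arch.add(pos, obj)
            assert {m.objectives for m in arch.members} == brute_force_front(stream)

    def test_capacity_pruning_keeps_boundary_members(self):
        arch = ParetoArchive(capacity=5)
        for i in range(50):
            t = i / 49
            arch.add(np.array([t]), (t, 1 - t))
        assert len(arch) == 5
        objs = {m.objectives for m in arch.members}
        assert (0.0, 1.0) in objs and (1.0, 0.0) in objs


class TestTermination:
    def test_collapsed_swarm_terminates(self):
        particles = [Particle(np.array([0.3, 0.3]), np.zeros(2), np.zeros(2))
                     for _ in range(5)]
        state = termination_state(particles, np.array([0.3, 0.3]), diameter0=1.0)
        assert state.rmax == 0.0
        assert check_termination(state, SwarmConfig(), generation=1)

    def test_large_rnorm_continues(self):
        particles = [Particle(np.array([0.0]), np.zeros(1), np.zeros(1)),
                     Particle(np.array([1.0]), np.zeros(1), np.zeros(1))]
        state = termination_state(particles, np.array([0.5]), diameter0=1.0)
        assert state.rnorm == pytest.approx(0.5)
        assert not check_termination(state, SwarmConfig(max_generations=50), generation=1)

    def test_rmax_matches_enumeration(self):
        rng = np.random.default_rng(3)
        particles = [Particle(rng.uniform(size=3), np.zeros(3), np.zeros(3))
                     for _ in range(5)]
        leader = rng.uniform(size=3)
        state = termination_state(particles, leader, diameter0=2.0)
        expected = max(np.linalg.norm(p.position - leader) for p in particles)
        assert state.rmax == pytest.approx(expected)

    def test_degenerate_initial_swarm(self):
        state = termination_state(
            [Particle(np.zeros(2), np.zeros(2), np.zeros(2))], np.zeros(2), diameter0=0.0)
        assert check_termination(state, SwarmConfig(), generation=0)


class TestFinalSelect:
    def _archive(self, positions):
        arch = ParetoArchive()
        for i, pos in enumerate(positions):
            arch.add(np.asarray(pos), (float(i), float(len(positions) - i)))
        return arch

    def test_singleton_archive(self):
        arch = self._archive([[0.1, 0.1]])
        a, acc = final_select(arch, lambda _: 70.0, ORDER_2, SCHEMA_2, seed=0)
        assert acc == 70.0

    def test_argmax_accuracy(self):
        arch = self._archive([[0.05, 0.05], [0.5, 0.5], [0.95, 0.95]])
        scores = {(1, 1): 70.0, (10, 5): 72.5, (18, 9): 71.0}
        a, acc = final_select(arch, lambda x: scores[x.index_tuple()],
                              ORDER_2, SCHEMA_2, seed=0)
        assert a.index_tuple() == (10, 5)
        assert acc == 72.5

    def test_tie_broken_uniformly(self):
        arch = self._archive([[0.05, 0.05], [0.95, 0.95]])
        picks = {(1, 1): 0, (18, 9): 0}
        for seed in range(1000):
            a, _ = final_select(arch, lambda _: 72.5, ORDER_2, SCHEMA_2, seed=seed)
            picks[a.index_tuple()] += 1
        assert abs(picks[(1, 1)] - 500) <= 60

    def test_empty_archive_raises(self):
        with pytest.raises(OptimizationFailureError):
            final_select(ParetoArchive(), lambda _: 0.0, ORDER_2, SCHEMA_2)


class TestOptimizeLoop:
    @staticmethod
    def mock_fitness(assignment):
        # conflicting objectives over the decoded indices: pulls the front
        # toward opposite pool corners
        i, j = assignment.index_tuple()
        return (i / 18 + 0.1 * j / 9, (18 - i) / 18 + 0.1 * (9 - j) / 9)

    def test_invariants_and_trace(self):
        cfg = SwarmConfig(n_particles=12, max_generations=8, seed=9)
        res = optimize(self.mock_fitness, ORDER_2, SCHEMA_2, cfg)
        assert 1 <= res.n_generations <= 8
        assert len(res.trace) == res.n_generations
        assert all(t["archive_size"] >= 1 for t in res.trace)
        objs = [tuple(m.objectives) for m in res.archive.members]
        assert not any(dominates(a, b) for a in objs for b in objs if a != b)

    def test_deterministic_under_seed(self):
        cfg = SwarmConfig(n_particles=10, max_generations=5, seed=4)
        r1 = optimize(self.mock_fitness, ORDER_2, SCHEMA_2, cfg)
        r2 = optimize(self.mock_fitness, ORDER_2, SCHEMA_2, cfg)
        assert sorted(m.objectives for m in r1.archive.members) == \
               sorted(m.objectives for m in r2.archive.members)


def test_swarm_diameter_brute_force():
    rng = np.random.default_rng(8)
    pts = rng.uniform(size=(6, 3))
    expected = max(np.linalg.norm(pts[i] - pts[j])
                   for i in range(6) for j in range(i + 1, 6))
    assert swarm_diameter(pts) == pytest.approx(expected)
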