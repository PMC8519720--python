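"""Multiobjective particle swarm search over imputation-algorithm assignments.

Particles live in the continuous unit cube [0, 1]^n, one dimension per chain
variable.  A component x is decoded to a 1-based pool index by
``min(n_pool, floor(x * n_pool) + 1)``, so the cube is partitioned into
equal cells covering the whole registry.  The two minimized objectives are
the mean absolute changes in classification sensitivity and specificity
caused by simulated amputation + imputation (see :mod:`psoimpute.fitness`).

Velocity update (no inertia weight beyond the unit carry-over term)::

    v' = v + c1 r1 (pbest - x) + c2 r2 (leader - x),   |v'_j| <= vmax_j

with the velocity cap shrinking geometrically, vmax_j = delta * range_j,
delta = 0.9^generation.  Nondominated solutions accumulate in a bounded
Pareto archive pruned by crowding distance; per-particle leaders are drawn
uniformly from the archive.  The run stops when the swarm has collapsed
onto its leader: R_norm = R_max / diameter(S0) falls below a threshold,
where R_max is the largest particle-to-leader distance and diameter(S0) the
initial swarm diameter.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .data import ChainOrder, VariableSchema
from .errors import ConfigurationError, OptimizationFailureError
from .pool import ChainAssignment, make_assignment, registry

logger = logging.getLogger(__name__)

Objectives = tuple[float, float]


@dataclass
class SwarmConfig:
    """Swarm hyperparameters; defaults follow standard PSO practice where a
    value is not otherwise fixed (100 particles, delta halving by 0.9/gen)."""

    n_particles: int = 100
    c1: float = 2.0
    c2: float = 2.0
    inertia: float = 1.0
    delta0: float = 1.0
    delta_decay: float = 0.9
    max_generations: int = 50
    rnorm_threshold: float = 0.01
    archive_capacity: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_particles < 2:
            raise ConfigurationError("need at least 2 particles")
        if self.c1 <= 0 or self.c2 <= 0:
            raise ConfigurationError("c1 and c2 must be positive")
        if not (0 < self.delta_decay < 1):
            raise ConfigurationError("delta_decay must lie in (0, 1)")


@dataclass
class Particle:
    position: np.ndarray
    velocity: np.ndarray
    pbest_position: np.ndarray
    pbest_fitness: Objectives | None = None
    fitness: Objectives | None = None


def dominates(a: Objectives, b: Objectives) -> bool:
    """Strict Pareto dominance for minimized objective pairs."""
    return a[0] <= b[0] and a[1] <= b[1] and (a[0] < b[0] or a[1] < b[1])


# -- index mapping -------------------------------------------------------------


def map_index(x: float, n: int) -> int:
    """Map a continuous value in [0, 1] to a pool index in 1..n.

    ``min(n, floor(x * n) + 1)``: surjective, non-decreasing, and an equal
    partition of the unit interval.  Positions are clamped before mapping,
    so an out-of-domain x signals an internal bug.
    """
    if not (0 <= x <= 1):
        raise ValueError(f"map_index domain is [0, 1], got {x}")
    if n < 1:
        raise ValueError("pool size must be >= 1")
    return min(n, int(math.floor(x * n)) + 1)


def decode(position: np.ndarray, order: ChainOrder,
           schema: Sequence[VariableSchema]) -> ChainAssignment:
    """Decode a particle position into a chain assignment."""
    smap = {v.name: v for v in schema}
    if len(position) != len(order):
        raise ConfigurationError("position length must equal the chain length")
    indices = []
    for x, name in zip(position, order):
        pool_n = len(registry(smap[name].vtype))
        indices.append(map_index(float(x), pool_n))
    return make_assignment(order, schema, indices)


# -- swarm mechanics -----------------------------------------------------------


def init_swarm(cfg: SwarmConfig, n_dims: int) -> list[Particle]:
    """Uniform-random initial swarm with zero velocities (seeded)."""
    if n_dims < 1:
        raise ConfigurationError("need at least one chain variable")
    rng = np.random.default_rng(cfg.seed)
    particles = []
    for _ in range(cfg.n_particles):
        pos = rng.uniform(0.0, 1.0, size=n_dims)
        particles.append(Particle(pos, np.zeros(n_dims), pos.copy()))
    return particles


def vmax_schedule(generation: int, cfg: SwarmConfig,
                  bounds: Sequence[tuple[float, float]]) -> np.ndarray:
    """Velocity cap per dimension: delta(gen) * (max - min), delta = 0.9^gen."""
    if generation < 0:
        raise ConfigurationError("generation must be >= 0")
    delta = cfg.delta0 * cfg.delta_decay ** generation
    return np.asarray([delta * (hi - lo) for lo, hi in bounds])


def update_velocity(p: Particle, leader: np.ndarray, cfg: SwarmConfig,
                    vmax: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One velocity update with symmetric clamping to +/- vmax."""
    r1 = rng.uniform(size=len(p.position))
    r2 = rng.uniform(size=len(p.position))
    v = (cfg.inertia * p.velocity
         + cfg.c1 * r1 * (p.pbest_position - p.position)
         + cfg.c2 * r2 * (leader - p.position))
    return np.clip(v, -vmax, vmax)


# -- Pareto archive ------------------------------------------------------------


@dataclass
class ArchiveEntry:
    position: np.ndarray
    objectives: Objectives


class ParetoArchive:
    """Bounded set of mutually nondominated solutions.

    Insertion keeps the nondomination invariant; overflow beyond capacity is
    pruned by removing the most crowded member (smallest crowding distance
    on the two objectives, boundary members protected).
    """

    def __init__(self, capacity: int | None = 100):
        self.capacity = capacity
        self.members: list[ArchiveEntry] = []

    def __len__(self) -> int:
        return len(self.members)

    def add(self, position: np.ndarray, objectives: Objectives) -> bool:
        if not all(np.isfinite(objectives)):
            raise ConfigurationError("archive objectives must be finite")
        objectives = (float(objectives[0]), float(objectives[1]))
        for m in self.members:
            if dominates(m.objectives, objectives) or m.objectives == objectives:
                return False
        self.members = [m for m in self.members if not dominates(objectives, m.objectives)]
        self.members.append(ArchiveEntry(np.asarray(position, dtype=float).copy(), objectives))
        if self.capacity is not None and len(self.members) > self.capacity:
            self._prune()
        return True

    def _crowding(self) -> np.ndarray:
        objs = np.asarray([m.objectives for m in self.members])
        n = len(objs)
        dist = np.zeros(n)
        for j in range(objs.shape[1]):
            order = np.argsort(objs[:, j], kind="stable")
            rng_j = objs[order[-1], j] - objs[order[0], j]
            dist[order[0]] = dist[order[-1]] = np.inf
            if rng_j > 0:
                for k in range(1, n - 1):
                    dist[order[k]] += (objs[order[k + 1], j] - objs[order[k - 1], j]) / rng_j
        return dist

    def _prune(self) -> None:
        while len(self.members) > self.capacity:
            dist = self._crowding()
            self.members.pop(int(np.argmin(dist)))

    def representative(self) -> ArchiveEntry:
        """Deterministic leader for termination: smallest objective sum."""
        if not self.members:
            raise OptimizationFailureError("empty archive")
        return min(self.members, key=lambda m: (m.objectives[0] + m.objectives[1], m.objectives))


# -- termination ---------------------------------------------------------------


@dataclass
class TerminationState:
    diameter0: float
    rmax: float
    n_s: int

    @property
    def rnorm(self) -> float:
        return self.rmax / self.diameter0 if self.diameter0 > 0 else 0.0


def swarm_diameter(positions: np.ndarray) -> float:
    """Maximum pairwise Euclidean distance."""
    d = 0.0
    for i in range(len(positions)):
        diff = positions[i + 1:] - positions[i]
        if len(diff):
            d = max(d, float(np.sqrt((diff ** 2).sum(axis=1)).max()))
    return d


def termination_state(particles: Sequence[Particle], leader: np.ndarray,
                      diameter0: float) -> TerminationState:
    rmax = max(float(np.linalg.norm(p.position - leader)) for p in particles)
    return TerminationState(diameter0=diameter0, rmax=rmax, n_s=len(particles))


def check_termination(state: TerminationState, cfg: SwarmConfig, generation: int) -> bool:
    """Stop when the normalized swarm radius collapses or the budget runs out."""
    if state.diameter0 == 0:
        logger.warning("degenerate initial swarm (zero diameter): terminating immediately")
        return True
    return state.rnorm < cfg.rnorm_threshold or generation >= cfg.max_generations


# -- main loop -----------------------------------------------------------------


@dataclass
class MopsoResult:
    archive: ParetoArchive
    trace: list[dict]
    n_generations: int
    order: ChainOrder


def optimize(
    fitness_fn: Callable[[ChainAssignment], Objectives],
    order: ChainOrder,
    schema: Sequence[VariableSchema],
    cfg: SwarmConfig,
) -> MopsoResult:
    """Run the swarm search; ``fitness_fn`` maps an assignment to the two
    minimized objectives (Δsensitivity, Δspecificity)."""
    n_dims = len(order)
    swarm = init_swarm(cfg, n_dims)
    rng = np.random.default_rng((cfg.seed << 1) ^ 0x5EED)
    diameter0 = swarm_diameter(np.asarray([p.position for p in swarm]))
    archive = ParetoArchive(cfg.archive_capacity)
    bounds = [(0.0, 1.0)] * n_dims
    trace: list[dict] = []
    generation = 0
    while True:
        for p in swarm:
            fit = fitness_fn(decode(p.position, order, schema))
            p.fitness = (float(fit[0]), float(fit[1]))
            if p.pbest_fitness is None or dominates(p.fitness, p.pbest_fitness):
                p.pbest_fitness = p.fitness
                p.pbest_position = p.position.copy()
            archive.add(p.position, p.fitness)
        leader = archive.representative()
        state = termination_state(swarm, leader.position, diameter0)
        trace.append({
            "generation": generation,
            "best_objectives": list(leader.objectives),
            "rnorm": state.rnorm,
            "archive_size": len(archive),
        })
        if check_termination(state, cfg, generation + 1):
            break
        vmax = vmax_schedule(generation, cfg, bounds)
        for p in swarm:
            guide = archive.members[rng.integers(len(archive))]
            p.velocity = update_velocity(p, guide.position, cfg, vmax, rng)
            p.position = np.clip(p.position + p.velocity, 0.0, 1.0)
        generation += 1
    return MopsoResult(archive=archive, trace=trace, n_generations=generation + 1, order=order)


def final_select(
    archive: ParetoArchive,
    accuracy_fn: Callable[[ChainAssignment], float],
    order: ChainOrder,
    schema: Sequence[VariableSchema],
    seed: int = 0,
) -> tuple[ChainAssignment, float]:
    """Score every archive member's assignment for classification accuracy
    and return the argmax; exact ties are broken uniformly at random."""
    if not archive.members:
        raise OptimizationFailureError("empty archive: nothing to select from")
    scored: dict[tuple[int, ...], tuple[ChainAssignment, float]] = {}
    for m in archive.members:
        assignment = decode(m.position, order, schema)
        key = assignment.index_tuple()
        if key not in scored:
            scored[key] = (assignment, float(accuracy_fn(assignment)))
    best_acc = max(acc for _, acc in scored.values())
    ties = [a for a, acc in scored.values() if acc == best_acc]
    rng = np.random.default_rng(seed)
    return ties[int(rng.integers(len(ties)))], best_acc
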