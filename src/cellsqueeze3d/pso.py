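"""Hybrid particle-swarm engine for the 2D-to-3D reconstruction problem.

A particle encodes a full candidate reconstruction as a vector of length
2N laid out as ``(z_1..z_N, R_1..R_N)``.  Velocities follow the classic
inertia + cognitive + social update with per-coordinate uniform random
factors; positions are projected onto the feasible box after every move,
so the radius and depth penalties vanish by construction and the search
effort goes entirely into resolving 3D overlaps.

Coefficient schedules are linear: inertia decays (exploration ->
exploitation) while the cognitive weight decays and the social weight
grows, shifting the swarm from individual search to global convergence.
An optional genetic perturbation (uniform crossover of personal bests
plus Gaussian mutation, applied periodically to the worst quartile) is
available but off by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Sequence, Set, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .core import (
    CellEstimate,
    NucleusObservation,
    PenaltyBreakdown,
    SwarmConfig,
    observations_to_arrays,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Particle",
    "SwarmState",
    "ScheduleValues",
    "build_neighbor_sets",
    "initialize_swarm",
    "schedule_at",
    "step",
    "genetic_perturbation",
    "optimize",
]


@dataclass
class Particle:
    """Candidate solution: position/velocity in R^2N plus personal best."""

    position: np.ndarray
    velocity: np.ndarray
    pbest_position: np.ndarray
    pbest_loss: float
    pbest_breakdown: PenaltyBreakdown


@dataclass
class SwarmState:
    """The whole swarm plus the global best and the loss trace."""

    particles: List[Particle]
    gbest_position: np.ndarray
    gbest_loss: float
    gbest_breakdown: PenaltyBreakdown
    iteration: int = 0
    trace: List[PenaltyBreakdown] = field(default_factory=list)

    @property
    def loss_trace(self) -> List[float]:
        return [b.L for b in self.trace]


@dataclass(frozen=True)
class ScheduleValues:
    w: float
    c1: float
    c2: float


class _Problem:
    """Precomputed arrays and the fast loss evaluator for one patch."""

    def __init__(self, observations: Sequence[NucleusObservation], config: SwarmConfig):
        if len(observations) < 1:
            raise ValueError("at least one observation is required")
        self.config = config
        self.ids, self.x, self.y, self.r_nuc = observations_to_arrays(observations)
        if len(np.unique(self.ids)) != len(self.ids):
            raise ValueError("observation ids must be unique within a patch")
        self.n = len(self.ids)
        self.lower = np.concatenate(
            [np.full(self.n, config.z_min), config.alpha * self.r_nuc]
        )
        self.upper = np.concatenate(
            [np.full(self.n, config.z_max), config.beta * self.r_nuc]
        )
        self.width = self.upper - self.lower
        self.vmax = 0.5 * self.width  # velocity clamp, prevents divergence
        # 2D-close pairs: candidates for the initialization z-jitter
        xy_tree = cKDTree(np.column_stack([self.x, self.y]))
        cand = xy_tree.query_pairs(2.0 * self.r_nuc.max(), output_type="ndarray")
        if len(cand):
            d2 = np.linalg.norm(
                np.column_stack([self.x, self.y])[cand[:, 0]]
                - np.column_stack([self.x, self.y])[cand[:, 1]],
                axis=1,
            )
            rsum = self.r_nuc[cand[:, 0]] + self.r_nuc[cand[:, 1]]
            self.close_pairs = cand[d2 < rsum]
        else:
            self.close_pairs = np.empty((0, 2), dtype=int)

    def evaluate(self, position: np.ndarray) -> PenaltyBreakdown:
        cfg = self.config
        n = self.n
        z = position[:n]
        R = position[n:]
        P_R = float(
            np.maximum(0.0, cfg.alpha * self.r_nuc - R).sum()
            + np.maximum(0.0, R - cfg.beta * self.r_nuc).sum()
        )
        P_Z = float(
            np.maximum(0.0, cfg.z_min - z).sum() + np.maximum(0.0, z - cfg.z_max).sum()
        )
        centers = np.column_stack([self.x, self.y, z])
        tau = cfg.neighbor_tau_factor * float(R.max())
        pairs = cKDTree(centers).query_pairs(tau, output_type="ndarray")
        if len(pairs):
            d = np.linalg.norm(centers[pairs[:, 0]] - centers[pairs[:, 1]], axis=1)
            rsum = self.r_nuc[pairs[:, 0]] + self.r_nuc[pairs[:, 1]]
            # x2: ordered-pair summation counts each unordered pair twice
            P_O = 2.0 * float(np.maximum(0.0, rsum - d).sum())
        else:
            P_O = 0.0
        bd = PenaltyBreakdown.compose(P_R, P_Z, P_O, cfg)
        if not np.isfinite(bd.L):
            raise FloatingPointError(
                f"non-finite loss (P_R={P_R}, P_Z={P_Z}, P_O={P_O}); "
                f"position range [{position.min()}, {position.max()}]"
            )
        return bd

    def decode(self, position: np.ndarray) -> List[CellEstimate]:
        n = self.n
        return [
            CellEstimate(
                id=int(self.ids[i]),
                x=float(self.x[i]),
                y=float(self.y[i]),
                z=float(position[i]),
                R=float(position[n + i]),
            )
            for i in range(n)
        ]


def build_neighbor_sets(
    centers: Sequence[CellEstimate] | np.ndarray,
    current_R: Sequence[float],
    tau_factor: float = 2.0,
) -> List[Set[int]]:
    """KD-tree neighbor pruning: ``N_i = {j != i : ||c_i - c_j|| <= tau}``.

    The threshold is ``tau = tau_factor * max_i R_i`` (the published choice
    is twice the largest current cell radius).  Sets are symmetric by
    construction.
    """
    if isinstance(centers, np.ndarray):
        pts = np.asarray(centers, dtype=float)
    else:
        pts = np.array([[c.x, c.y, c.z] for c in centers], dtype=float)
    n = len(pts)
    sets: List[Set[int]] = [set() for _ in range(n)]
    if n == 0:
        return sets
    R = np.asarray(current_R, dtype=float)
    if np.any(R <= 0):
        raise ValueError("current_R must be positive elementwise")
    tau = tau_factor * float(R.max())
    pairs = cKDTree(pts).query_pairs(tau, output_type="ndarray")
    for i, j in pairs:
        sets[i].add(int(j))
        sets[j].add(int(i))
    return sets


def schedule_at(t: int, config: SwarmConfig) -> ScheduleValues:
    """Linear interpolation of (w, c1, c2) over iterations 0 .. T-1."""
    if not 0 <= t < config.T:
        raise ValueError(f"iteration {t} out of range [0, {config.T})")
    f = 0.0 if config.T == 1 else t / (config.T - 1)
    return ScheduleValues(
        w=config.w_start + f * (config.w_end - config.w_start),
        c1=config.c1_start + f * (config.c1_end - config.c1_start),
        c2=config.c2_start + f * (config.c2_end - config.c2_start),
    )


def _jitter_z(problem: _Problem, z: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Redraw depths of 2D-overlapping pairs until 3D-separated (or cap)."""
    cfg = problem.config
    pairs = problem.close_pairs
    if len(pairs) == 0:
        return z
    i, j = pairs[:, 0], pairs[:, 1]
    dx = problem.x[i] - problem.x[j]
    dy = problem.y[i] - problem.y[j]
    d2_sq = dx * dx + dy * dy
    rsum = problem.r_nuc[i] + problem.r_nuc[j]
    for _ in range(cfg.init_retry_cap):
        dz = z[i] - z[j]
        bad = (d2_sq + dz * dz) < rsum * rsum
        if not bad.any():
            return z
        redraw = np.unique(np.concatenate([i[bad], j[bad]]))
        z[redraw] = rng.uniform(cfg.z_min, cfg.z_max, size=len(redraw))
    logger.warning(
        "initialization jitter cap reached; %d pair(s) remain 3D-overlapping "
        "(the overlap penalty will drive repair)",
        int(bad.sum()),
    )
    return z


def initialize_swarm(
    observations: Sequence[NucleusObservation],
    config: SwarmConfig,
    rng: np.random.Generator | None = None,
) -> SwarmState:
    """Draw the initial swarm from the feasible box.

    Per particle: ``z ~ U(z_min, z_max)`` and ``R_i ~ U(alpha*r_i, beta*r_i)``;
    depths of pairs whose 2D centroid distance is below the sum of their
    nuclear radii are then redrawn until the pair is separated in 3D (up to
    a retry cap).  Velocities start at zero and each particle's personal
    best is its initial position.
    """
    problem = _Problem(observations, config)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    particles: List[Particle] = []
    for _ in range(config.n_swarm):
        z = rng.uniform(config.z_min, config.z_max, size=problem.n)
        R = rng.uniform(problem.lower[problem.n :], problem.upper[problem.n :])
        z = _jitter_z(problem, z, rng)
        position = np.concatenate([z, R])
        bd = problem.evaluate(position)
        particles.append(
            Particle(
                position=position,
                velocity=np.zeros_like(position),
                pbest_position=position.copy(),
                pbest_loss=bd.L,
                pbest_breakdown=bd,
            )
        )
    best = min(range(len(particles)), key=lambda k: particles[k].pbest_loss)
    return SwarmState(
        particles=particles,
        gbest_position=particles[best].pbest_position.copy(),
        gbest_loss=particles[best].pbest_loss,
        gbest_breakdown=particles[best].pbest_breakdown,
        iteration=0,
        trace=[],
    )


def step(
    state: SwarmState,
    observations: Sequence[NucleusObservation] | _Problem,
    config: SwarmConfig,
    rng: np.random.Generator,
) -> SwarmState:
    """One synchronous swarm iteration (velocity, move, project, rescore).

    The position update is clipped coordinatewise onto the feasible box;
    the velocity component of any clipped coordinate is zeroed to avoid
    boundary oscillation.  Personal and global bests use a strict (<)
    improvement rule (ties keep the incumbent), so the global-best loss
    trace is non-increasing and, once a feasible configuration is found,
    the reported solution is stable.
    """
    problem = observations if isinstance(observations, _Problem) else _Problem(observations, config)
    sched = schedule_at(min(state.iteration, config.T - 1), config)
    dim = 2 * problem.n
    for p in state.particles:
        r1 = rng.uniform(size=dim)
        r2 = rng.uniform(size=dim)
        v = (
            sched.w * p.velocity
            + sched.c1 * r1 * (p.pbest_position - p.position)
            + sched.c2 * r2 * (state.gbest_position - p.position)
        )
        v = np.clip(v, -problem.vmax, problem.vmax)
        raw = p.position + v
        new = np.clip(raw, problem.lower, problem.upper)
        v[raw != new] = 0.0
        p.position = new
        p.velocity = v
        bd = problem.evaluate(new)
        if bd.L < p.pbest_loss:
            p.pbest_loss = bd.L
            p.pbest_breakdown = bd
            p.pbest_position = new.copy()
        if bd.L < state.gbest_loss:
            state.gbest_loss = bd.L
            state.gbest_breakdown = bd
            state.gbest_position = new.copy()
    state.iteration += 1
    state.trace.append(state.gbest_breakdown)
    return state


def genetic_perturbation(
    state: SwarmState,
    observations: Sequence[NucleusObservation] | _Problem,
    config: SwarmConfig,
    rng: np.random.Generator,
) -> SwarmState:
    """Replace the worst-quartile particles by crossover of personal bests.

    Each replacement position is a uniform crossover of two distinct random
    personal-best vectors plus Gaussian mutation (sigma = 5% of each
    coordinate's box width), projected back onto the box.  Personal bests
    are retained, so the global best can never be lost.
    """
    if not config.ga_enabled:
        return state
    n_part = len(state.particles)
    if n_part < 4:
        logger.info("genetic perturbation skipped: swarm smaller than 4")
        return state
    problem = observations if isinstance(observations, _Problem) else _Problem(observations, config)
    order = sorted(range(n_part), key=lambda k: state.particles[k].pbest_loss)
    worst = order[-(n_part // 4):]
    for k in worst:
        a, b = rng.choice(n_part, size=2, replace=False)
        mask = rng.uniform(size=2 * problem.n) < 0.5
        child = np.where(
            mask,
            state.particles[a].pbest_position,
            state.particles[b].pbest_position,
        )
        child = child + rng.normal(0.0, 0.05 * problem.width)
        child = np.clip(child, problem.lower, problem.upper)
        p = state.particles[k]
        p.position = child
        p.velocity = np.zeros_like(child)
        bd = problem.evaluate(child)
        if bd.L < p.pbest_loss:
            p.pbest_loss = bd.L
            p.pbest_breakdown = bd
            p.pbest_position = child.copy()
    return state


def optimize(
    observations: Sequence[NucleusObservation],
    config: SwarmConfig,
) -> Tuple[List[CellEstimate], PenaltyBreakdown, List[float]]:
    """Full reconstruction: initialize, iterate T steps, decode the best.

    Returns the decoded cells, the penalty breakdown of the global best and
    the per-iteration global-best loss trace (length T).  Deterministic for
    a fixed ``config.seed``.
    """
    problem = _Problem(observations, config)
    rng = np.random.default_rng(config.seed)
    state = initialize_swarm(observations, config, rng)
    for t in range(config.T):
        step(state, problem, config, rng)
        if config.ga_enabled and (t + 1) % config.ga_period == 0:
            genetic_perturbation(state, problem, config, rng)
    cells = problem.decode(state.gbest_position)
    return cells, state.gbest_breakdown, state.loss_trace
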