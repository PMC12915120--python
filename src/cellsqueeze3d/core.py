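"""Domain types, penalty functions and the composite reconstruction loss.

The model treats every cell as a sphere whose (x, y) center and nuclear
radius ``r_nuc`` are observed in the 2D section, while the depth ``z`` and
the whole-cell radius ``R`` are unknown.  Feasibility of a candidate
reconstruction is scored by three hinge penalties:

* a radius-bound penalty keeping ``R`` inside the biologically plausible
  band ``[alpha * r_nuc, beta * r_nuc]``;
* a depth penalty keeping ``z`` inside the slab ``[z_min, z_max]``;
* a non-interpenetration penalty requiring the 3D center distance of
  adjacent cells to exceed the sum of their *nuclear* radii.

The total loss is the weighted sum of the three penalties and is zero
exactly when the configuration satisfies every constraint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Set

import numpy as np

__all__ = [
    "NucleusObservation",
    "CellEstimate",
    "SwarmConfig",
    "PenaltyBreakdown",
    "radius_penalty",
    "z_penalty",
    "overlap_penalty",
    "total_loss",
]


@dataclass(frozen=True)
class NucleusObservation:
    """One detected nucleus: 2D centroid and nuclear radius.

    All lengths share one unit (pixels by default; any micron conversion
    happens at I/O time).
    """

    id: int
    x: float
    y: float
    r_nuc: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.r_nuc) or self.r_nuc <= 0:
            raise ValueError(f"nucleus {self.id}: r_nuc must be positive, got {self.r_nuc}")


@dataclass(frozen=True)
class CellEstimate:
    """One reconstructed cell: 3D center and whole-cell radius.

    ``x`` and ``y`` are copied verbatim from the source observation and are
    never optimized; only ``z`` and ``R`` are free.
    """

    id: int
    x: float
    y: float
    z: float
    R: float

    @property
    def center(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass
class SwarmConfig:
    """All algorithm parameters plus run controls.

    Defaults follow the published parameter table: radius-ratio band
    [1.5, 2.5], slab depth 50, penalty weights (5e4, 1e4, 1e6), linearly
    scheduled inertia 0.9 -> 0.4, cognitive coefficient 2.5 -> 1.0 and
    social coefficient 1.0 -> 2.6, swarm size 50, 120 iterations.
    """

    alpha: float = 1.5
    beta: float = 2.5
    z_min: float = 0.0
    z_max: float = 50.0
    lambda_R: float = 5e4
    lambda_Z: float = 1e4
    lambda_O: float = 1e6
    w_start: float = 0.9
    w_end: float = 0.4
    c1_start: float = 2.5
    c1_end: float = 1.0
    c2_start: float = 1.0
    c2_end: float = 2.6
    n_swarm: int = 50
    T: int = 120
    seed: int = 0
    ga_enabled: bool = False
    ga_period: int = 20
    neighbor_tau_factor: float = 2.0
    init_retry_cap: int = 50

    def __post_init__(self) -> None:
        if not self.alpha < self.beta:
            raise ValueError(f"alpha ({self.alpha}) must be < beta ({self.beta})")
        if not self.z_min < self.z_max:
            raise ValueError(f"z_min ({self.z_min}) must be < z_max ({self.z_max})")
        for name in ("lambda_R", "lambda_Z", "lambda_O"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_swarm < 2:
            raise ValueError("n_swarm must be >= 2")
        if self.T < 1:
            raise ValueError("T must be >= 1")


@dataclass(frozen=True)
class PenaltyBreakdown:
    """The three penalty components and their weighted sum L."""

    P_R: float
    P_Z: float
    P_O: float
    L: float

    @classmethod
    def compose(cls, P_R: float, P_Z: float, P_O: float, config: SwarmConfig) -> "PenaltyBreakdown":
        L = config.lambda_R * P_R + config.lambda_Z * P_Z + config.lambda_O * P_O
        return cls(P_R=float(P_R), P_Z=float(P_Z), P_O=float(P_O), L=float(L))


def _as_array(v: Sequence[float]) -> np.ndarray:
    return np.asarray(v, dtype=float)


def radius_penalty(r_nuc: Sequence[float], R: Sequence[float], alpha: float, beta: float) -> float:
    """Hinge penalty for cell radii outside ``[alpha*r_nuc, beta*r_nuc]``.

    Returns ``sum_i max(0, alpha*r_i - R_i) + sum_i max(0, R_i - beta*r_i)``;
    zero iff every radius lies in its band (bounds inclusive).
    """
    r_nuc = _as_array(r_nuc)
    R = _as_array(R)
    if r_nuc.shape != R.shape:
        raise ValueError(f"length mismatch: r_nuc has {r_nuc.shape}, R has {R.shape}")
    if np.any(r_nuc <= 0):
        raise ValueError("r_nuc must be positive elementwise")
    low = np.maximum(0.0, alpha * r_nuc - R)
    high = np.maximum(0.0, R - beta * r_nuc)
    return float(low.sum() + high.sum())


def z_penalty(z: Sequence[float], z_min: float, z_max: float) -> float:
    """Hinge penalty for depths outside the slab ``[z_min, z_max]``."""
    if z_min >= z_max:
        raise ValueError(f"z_min ({z_min}) must be < z_max ({z_max})")
    z = _as_array(z)
    below = np.maximum(0.0, z_min - z)
    above = np.maximum(0.0, z - z_max)
    return float(below.sum() + above.sum())


def _centers_of(cells: Sequence[CellEstimate] | np.ndarray) -> np.ndarray:
    if isinstance(cells, np.ndarray):
        centers = np.asarray(cells, dtype=float)
        if centers.ndim != 2 or centers.shape[1] != 3:
            raise ValueError("centers array must have shape (n, 3)")
        return centers
    return np.array([[c.x, c.y, c.z] for c in cells], dtype=float)


def overlap_penalty(
    cells: Sequence[CellEstimate] | np.ndarray,
    r_nuc: Sequence[float],
    neighbors: Sequence[Set[int]] | Dict[int, Set[int]],
) -> float:
    """Non-interpenetration penalty over the given adjacency sets.

    ``sum_i sum_{j in N_i} max(0, (r_i + r_j) - ||c_i - c_j||)`` with
    *nuclear* radii setting the minimum center distance.  With symmetric
    neighbor sets every violating unordered pair is counted twice (ordered
    i, j-in-N_i summation); this convention only rescales the overlap
    weight and is kept deliberately.
    """
    centers = _centers_of(cells)
    r_nuc = _as_array(r_nuc)
    n = len(centers)
    if len(r_nuc) != n:
        raise ValueError("r_nuc length must match number of cells")
    total = 0.0
    for i in range(n):
        nbrs = neighbors[i]
        if not nbrs:
            continue
        js = np.fromiter(nbrs, dtype=int)
        if np.any((js < 0) | (js >= n)) or np.any(js == i):
            raise IndexError(f"invalid neighbor index for cell {i}")
        d = np.linalg.norm(centers[js] - centers[i], axis=1)
        total += float(np.maximum(0.0, (r_nuc[i] + r_nuc[js]) - d).sum())
    return total


def all_pairs_neighbors(n: int) -> List[Set[int]]:
    """Complete adjacency: every other index is a neighbor."""
    full = set(range(n))
    return [full - {i} for i in range(n)]


def total_loss(
    cells: Sequence[CellEstimate],
    observations: Sequence[NucleusObservation],
    config: SwarmConfig,
    neighbors: Sequence[Set[int]] | None = None,
) -> PenaltyBreakdown:
    """Composite loss ``L = lambda_R*P_R + lambda_Z*P_Z + lambda_O*P_O``.

    Cells and observations must align by id.  ``neighbors`` defaults to the
    complete graph, which is exact (the KD-tree pruning used inside the
    optimizer is an accelerator, not a different objective).
    """
    if len(cells) != len(observations):
        raise ValueError("cells and observations must have equal length")
    for c, o in zip(cells, observations):
        if c.id != o.id:
            raise ValueError(f"id mismatch: cell {c.id} vs observation {o.id}")
    r_nuc = np.array([o.r_nuc for o in observations], dtype=float)
    R = np.array([c.R for c in cells], dtype=float)
    z = np.array([c.z for c in cells], dtype=float)
    if neighbors is None:
        neighbors = all_pairs_neighbors(len(cells))
    P_R = radius_penalty(r_nuc, R, config.alpha, config.beta)
    P_Z = z_penalty(z, config.z_min, config.z_max)
    P_O = overlap_penalty(cells, r_nuc, neighbors)
    return PenaltyBreakdown.compose(P_R, P_Z, P_O, config)


def observations_to_arrays(observations: Sequence[NucleusObservation]):
    """Split observations into (ids, x, y, r_nuc) float arrays (ids int)."""
    ids = np.array([o.id for o in observations], dtype=int)
    x = np.array([o.x for o in observations], dtype=float)
    y = np.array([o.y for o in observations], dtype=float)
    r = np.array([o.r_nuc for o in observations], dtype=float)
    return ids, x, y, r
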