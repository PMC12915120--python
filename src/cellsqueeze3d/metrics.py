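"""Morphometric validation statistics for reconstructed cell populations.

The central quantity is the nuclear-to-cytoplasmic (N/C) ratio, here the
ratio of nuclear radius to whole-cell radius ``r_nuc / R``.  Under the
radius-band constraint ``R in [alpha*r_nuc, beta*r_nuc]`` every ratio lies
in ``[1/beta, 1/alpha]`` (with the defaults, [0.4, 2/3]).  Per-patch
heterogeneity is summarized by the Shannon entropy of the binned ratio
distribution, and reconstructions are validated against a null model that
draws cell radii uniformly from the same band without any optimization,
using the two-sample Kolmogorov-Smirnov test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import kolmogorov

from .core import CellEstimate, NucleusObservation, SwarmConfig

__all__ = [
    "NCDistribution",
    "EntropySummary",
    "nc_ratio",
    "nc_entropy",
    "random_baseline",
    "ks_two_sample",
    "validate_against_random",
]


@dataclass(frozen=True)
class NCDistribution:
    """Per-cell N/C ratios of one patch."""

    values: np.ndarray
    patch_id: str | None = None


@dataclass(frozen=True)
class EntropySummary:
    H: float
    n_cells: int
    n_bins: int
    bin_edges: np.ndarray


def nc_ratio(
    observations: Sequence[NucleusObservation],
    cells: Sequence[CellEstimate],
    patch_id: str | None = None,
) -> NCDistribution:
    """N/C ratio per cell: nuclear radius over whole-cell radius."""
    if len(observations) != len(cells):
        raise ValueError("observations and cells must have equal length")
    by_id = {o.id: o for o in observations}
    values = np.empty(len(cells))
    for k, c in enumerate(cells):
        if c.id not in by_id:
            raise ValueError(f"cell id {c.id} has no matching observation")
        if c.R <= 0:
            raise ValueError(f"cell {c.id}: R must be positive, got {c.R}")
        values[k] = by_id[c.id].r_nuc / c.R
    return NCDistribution(values=values, patch_id=patch_id)


def nc_entropy(
    dist: NCDistribution | Sequence[float],
    n_bins: int = 20,
    value_range: Tuple[float, float] = (0.4, 2.0 / 3.0),
) -> EntropySummary:
    """Shannon entropy (nats) of the binned N/C ratio distribution.

    The histogram uses ``n_bins`` equal bins over a fixed range (default
    the feasible band [1/beta, 1/alpha] = [0.4, 2/3]) so entropies are
    comparable across patches; values outside the range are clipped into
    the edge bins.  ``H = -sum p_b ln p_b`` with ``0 ln 0 = 0``, hence
    ``0 <= H <= ln(n_bins)``.
    """
    values = dist.values if isinstance(dist, NCDistribution) else np.asarray(dist, dtype=float)
    if len(values) == 0:
        raise ValueError("cannot compute entropy of an empty distribution")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    lo, hi = value_range
    edges = np.linspace(lo, hi, n_bins + 1)
    clipped = np.clip(values, lo, hi)
    counts, _ = np.histogram(clipped, bins=edges)
    p = counts / counts.sum()
    nz = p[p > 0]
    H = float(-(nz * np.log(nz)).sum())
    return EntropySummary(H=H, n_cells=len(values), n_bins=n_bins, bin_edges=edges)


def random_baseline(
    observations: Sequence[NucleusObservation],
    config: SwarmConfig,
    rng: np.random.Generator | int | None = None,
) -> List[CellEstimate]:
    """Null model: draw z and R uniformly from the feasible box, no search.

    ``R_i ~ U(alpha*r_i, beta*r_i)`` and ``z_i ~ U(z_min, z_max)``,
    independently per cell; reproducible for a fixed seed.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    cells = []
    for o in observations:
        cells.append(
            CellEstimate(
                id=o.id,
                x=o.x,
                y=o.y,
                z=float(rng.uniform(config.z_min, config.z_max)),
                R=float(rng.uniform(config.alpha * o.r_nuc, config.beta * o.r_nuc)),
            )
        )
    return cells


def ks_two_sample(a: Sequence[float], b: Sequence[float]) -> Tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test: (D, asymptotic two-sided p).

    ``D = sup_x |ECDF_a(x) - ECDF_b(x)|`` evaluated exactly over all sample
    breakpoints; the p-value comes from the asymptotic Kolmogorov
    distribution at ``sqrt(n_eff) * D`` with effective size
    ``n_eff = n_a n_b / (n_a + n_b)``.
    """
    a = np.sort(np.asarray(a, dtype=float))
    b = np.sort(np.asarray(b, dtype=float))
    na, nb = len(a), len(b)
    if na == 0 or nb == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    cdf_a = np.searchsorted(a, pooled, side="right") / na
    cdf_b = np.searchsorted(b, pooled, side="right") / nb
    D = float(np.max(np.abs(cdf_a - cdf_b)))
    n_eff = na * nb / (na + nb)
    p = float(kolmogorov(np.sqrt(n_eff) * D))
    return D, min(p, 1.0)


def validate_against_random(
    patches: Sequence[Tuple[Sequence[NucleusObservation], Sequence[CellEstimate]]],
    config: SwarmConfig,
    n_reps: int = 10,
    seed: int | None = None,
    n_bins: int = 20,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Compare optimized reconstructions with the random-radius null model.

    ``patches`` is a sequence of (observations, optimized cells) pairs, one
    per image patch.  For each patch the per-patch median N/C ratio and the
    per-patch N/C entropy are computed for the optimized cells and for
    ``n_reps`` independent random baselines.  Both summaries are compared
    across patches with the two-sided KS test.

    Returns ``(report, cdf_table)``: the report has one row per summary
    (``median_nc`` and ``entropy``) with D, p and sample sizes; the CDF
    table lists the pooled sorted values with their empirical CDFs for both
    arms, ready for plotting.
    """
    if len(patches) == 0:
        raise ValueError("at least one patch is required")
    rng = np.random.default_rng(seed)
    lo, hi = 1.0 / config.beta, 1.0 / config.alpha
    opt_median, opt_entropy = [], []
    rnd_median, rnd_entropy = [], []
    for observations, cells in patches:
        dist = nc_ratio(observations, cells)
        opt_median.append(float(np.median(dist.values)))
        opt_entropy.append(nc_entropy(dist, n_bins=n_bins, value_range=(lo, hi)).H)
        for _ in range(n_reps):
            base = random_baseline(observations, config, rng)
            bdist = nc_ratio(observations, base)
            rnd_median.append(float(np.median(bdist.values)))
            rnd_entropy.append(nc_entropy(bdist, n_bins=n_bins, value_range=(lo, hi)).H)
    rows = []
    cdf_rows = []
    for name, opt, rnd in (
        ("median_nc", opt_median, rnd_median),
        ("entropy", opt_entropy, rnd_entropy),
    ):
        D, p = ks_two_sample(opt, rnd)
        rows.append(
            {"summary": name, "D": D, "p": p, "n_optimized": len(opt), "n_random": len(rnd)}
        )
        pooled = np.sort(np.concatenate([opt, rnd]))
        cdf_rows.append(
            pd.DataFrame(
                {
                    "summary": name,
                    "value": pooled,
                    "cdf_optimized": np.searchsorted(np.sort(opt), pooled, side="right")
                    / len(opt),
                    "cdf_random": np.searchsorted(np.sort(rnd), pooled, side="right")
                    / len(rnd),
                }
            )
        )
    return pd.DataFrame(rows), pd.concat(cdf_rows, ignore_index=True)
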