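# Methods

## Model

Each cell i is a sphere with center c_i = (x_i, y_i, z_i) and radius R_i.
The planar center and the nuclear radius r_i^nuc are measured from an
instance-labeled nuclear segmentation; z_i and R_i are free. Feasibility is
expressed through three hinge penalties — radius band
R_i ∈ [α·r_i^nuc, β·r_i^nuc], slab depth z_i ∈ [z_min, z_max], and a minimum
3D center distance of r_i^nuc + r_j^nuc between neighboring cells (nuclei
are rigid and may not interpenetrate; cytoplasm may be squeezed). The total
loss is the weighted sum L = λ_R·P_R + λ_Z·P_Z + λ_O·P_O and is zero iff the
configuration satisfies every constraint.

Two consequences of this formulation are worth stating explicitly because
they shape what the method can and cannot claim:

1. **Depth is identified only relatively.** All penalties depend on depth
   differences, so the loss is invariant under the global reflection
   z → z_max − z. Recovery metrics therefore score depth up to that
   reflection, and individual depths in sparse fields are weakly
   constrained (many feasible answers exist).
2. **Cell radii are loss-neutral inside their band.** The overlap penalty
   uses nuclear radii, so after feasibility projection the objective does
   not distinguish between values of R_i within [α·r_i^nuc, β·r_i^nuc].
   The optimizer guarantees biomechanical *plausibility* of the radii, not
   their uniqueness; distribution-level statistics (below) are the
   appropriate level of interpretation for R.

## Optimization

Particles encode (z_1..z_N, R_1..R_N) ∈ R^2N. Initialization draws
z ~ U(z_min, z_max) and R_i ~ U(α·r_i^nuc, β·r_i^nuc); pairs closer in 2D
than the sum of their nuclear radii have their depths redrawn until the pair
separates in 3D (cap 50 rounds, after which the penalty drives repair).
Velocity updates use per-coordinate uniform random factors with linear
schedules — inertia 0.9→0.4, cognitive 2.5→1.0, social 1.0→2.6 over the run
— and positions are projected onto the feasible box by per-coordinate
clipping, which makes P_R = P_Z = 0 invariantly; only the overlap term
requires search. Numerical choices, where the underlying design was open:

- **Projection**: clipping is the simplest idempotent projection; the
  velocity component of a clipped coordinate is zeroed to avoid boundary
  oscillation, and velocities are clamped to half the box width.
- **Tie-breaking**: personal/global bests update on strict improvement;
  ties keep the incumbent, so the global-best trace is non-increasing and
  reported solutions are stable.
- **Neighbor sets** are rebuilt every evaluation from the particle's own
  current geometry via a KD-tree at τ = 2·max R_i. Because
  τ ≥ 3·max r^nuc ≥ r_i^nuc + r_j^nuc, pruning can never hide a violating
  pair; the KD-tree is an accelerator, not a different objective. The
  ordered double summation counts each unordered violating pair twice;
  this deliberate convention only rescales λ_O.
- **Genetic perturbation** (off by default): every 20 iterations the worst
  quartile is replaced by uniform crossover of two random personal bests
  plus Gaussian mutation (σ = 5% of box width), projected back onto the
  box; personal bests are retained so the global best cannot be lost.
- Iteration budget defaults to 120 with a swarm of 50; both are exposed.

Units: all lengths share one unit (pixels by default). Any micron
conversion (a typical 40× scale is 0.25 µm/px) belongs at the I/O boundary.
z_min defaults to 0 and z_max to 50, matching the initialization range;
these defaults are configurable and deliberately generous relative to
nominal physical section thickness, since apparent depth ranges in stained
sections are not tightly pinned down.

## Morphometric validation

The N/C ratio of a cell is r^nuc/R; under the band constraint it lies in
[1/β, 1/α] = [0.4, 2/3]. Patch heterogeneity is the Shannon entropy (nats)
of the ratio histogram over 20 fixed bins spanning that band — the fixed
range makes entropies comparable across patches; out-of-range values are
clipped into the edge bins. The null model draws R uniformly from the same
band (and z uniformly from the slab) with no optimization. Two per-patch
summaries — median N/C and N/C entropy — are compared between arms with the
two-sample KS test: D is the exact ECDF supremum over all breakpoints, and
the two-sided p-value uses the asymptotic Kolmogorov distribution at
√(n_a·n_b/(n_a+n_b))·D. (scipy's implementation serves as an independent
cross-check in the tests, never as the implementation.)

## Synthetic tissues

The generator places spheres sequentially in a W×H×z_max slab by rejection:
nuclear radii ~ LogNormal(ln 4, 0.3) truncated to [2, 10] px (right-skewed,
as real nuclear size distributions are), cell/nucleus ratio ~ Normal(2.0,
0.25) truncated to [α, β] (typical N/C near 0.5; a uniform option exists),
centers uniform with nuclei kept inside the field; a candidate is accepted
only if its 3D distance to every accepted center is at least the sum of
nuclear radii. Every generated tissue therefore has exactly zero loss. A
density guard rejects requests whose nuclear cross-section would exceed 40%
of the field, and 10⁴ consecutive placement rejections abort with advice.
Defaults (50 cells per 512×512 px field) match the nuclear density of
moderately cellular 40× carcinoma patches (~140 cells per 1000×1000 px).

What the generator does *not* emulate: H&E color and texture, anisometric
or lobulated nuclei, sectioning artifacts (folds, tears, uneven staining),
adhesion/tension forces and extracellular matrix. Passing recovery tests
therefore demonstrate the correctness of the optimization and statistics
machinery on geometry that satisfies the model's own assumptions, not
robustness to real-tissue nuisance factors.

## Problem sizes in tests and the acceptance script

Tests run at desk scale chosen as the package's own defaults: recovery uses
50-cell tissues at the published swarm settings (swarm 50, 120 iterations);
optimizer-contract checks use swarm 30 over 60 iterations across 20 seeds;
the statistical validation uses 30 patches of 20 cells with ratio sd 0.05
against 10 null replicates per patch. The end-to-end pipeline on a 100-cell
field completes in well under a minute on one CPU.

## Known limitations

- Sparse, well-separated fields are often feasible at initialization; the
  optimizer then certifies feasibility rather than searching (the free-field
  limit). Dense fields exercise the overlap search.
- Because R is loss-neutral within its band (point 2 above), per-cell
  radius estimates carry no information beyond the band and should only be
  interpreted distributionally; the cohesion of real tissue enters through
  the observed nuclei, not through the optimizer's choice of R.
- Spherical-cell and spherical-nucleus assumptions; no soft-body
  deformation, adhesion, or ECM modeling.
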