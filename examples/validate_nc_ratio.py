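"""Statistical validation of the N/C ratio against a random null model.

Builds 30 cohesive synthetic patches (cell/nucleus radius ratio tightly
distributed, sd 0.05) and compares their per-patch median N/C ratio and
N/C entropy with those of random radius assignments drawn from the same
admissible band, using the two-sided Kolmogorov-Smirnov test.
"""

from cellsqueeze3d import SwarmConfig, TissueParams, generate_tissue, validate_against_random

patches = []
for k in range(30):
    t = generate_tissue(
        TissueParams(n_cells=20, field_size=(300.0, 300.0), ratio_sigma=0.05),
        seed=1000 + k,
    )
    patches.append((t.observations, t.truth))

report, cdf = validate_against_random(patches, SwarmConfig(), n_reps=10, seed=0)
for row in report.itertuples():
    print(f"{row.summary:>10}: D = {row.D:.3f}, p = {row.p:.3g} "
          f"({row.n_optimized} patches vs {row.n_random} null draws)")
# Small p-values mean the cohesive tissues' N/C summaries are
# distinguishable from unconstrained random radius assignment — the
# desk-scale analogue of validating reconstructed morphology against a
# stochastic null.  The cdf table holds both empirical CDFs for plotting.
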