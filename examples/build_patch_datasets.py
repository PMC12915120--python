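"""Construct the three 60x60 patch datasets used for cell classification.

From one image frame: (1) sliding-window grid tiles, (2) windows centered
on each detected nucleus, (3) cell-centric windows masked to the projected
boundary of each reconstructed cell.  A half-plane "tumor annotation"
labels each patch by its defining point.
"""

import numpy as np

from cellsqueeze3d import (
    TissueParams,
    extract_patches_cell_region,
    extract_patches_nucleus_centered,
    extract_patches_sliding,
    generate_tissue,
    label_patches,
    optimize,
    project_cells,
    render_mask,
)

tissue = generate_tissue(TissueParams(n_cells=30, field_size=(300.0, 300.0)), seed=3)
image = (render_mask(tissue) > 0).astype(np.uint8) * 200  # stand-in for an H&E frame

sliding = extract_patches_sliding(image)
centered = extract_patches_nucleus_centered(image, tissue.observations)
cells, _, _ = optimize(tissue.observations, tissue.config(n_swarm=20, T=40, seed=3))
regions = project_cells(cells, mode="shadow")
cell_centric = extract_patches_cell_region(image, regions)

print(f"sliding grid: {len(sliding)} patches "
      f"(= ceil(300/60)^2 = {int(np.ceil(300/60))**2})")
print(f"nucleus-centered: {len(centered)} patches (one per nucleus)")
print(f"cell-centric: {len(cell_centric)} patches (one per projected cell)")

tumor = np.zeros(image.shape, dtype=bool)
tumor[:, 150:] = True  # annotation: right half of the frame is tumor
labeled = label_patches(cell_centric, tumor)
n_tumor = sum(p.label for p in labeled.patches)
print(f"labels from half-plane annotation: {n_tumor} tumor / "
      f"{len(labeled) - n_tumor} non-tumor")
# Cell-centric patches zero out pixels beyond each cell's projected disk,
# so a classifier sees exactly one cell's footprint per example instead of
# arbitrary grid content.
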