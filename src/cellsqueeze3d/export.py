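"""Mesh export, plane projections and cell-centric patch construction.

Reconstructed cells are spheres ``S_i = {p : ||p - c_i|| = R_i}``; for
visualization each is tessellated as an icosphere (recursive midpoint
subdivision of an icosahedron, vertices renormalized to the sphere) and
written to ASCII PLY, which mesh tools such as MeshLab open directly.

For classification experiments three patch datasets can be built from the
same image: a sliding-window grid, fixed windows centered on each nucleus,
and cell-centric windows masked to the projected boundary of each
reconstructed cell.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Literal, Sequence, Tuple

import numpy as np

from .core import CellEstimate, NucleusObservation

__all__ = [
    "icosphere",
    "export_ply",
    "ProjectedRegion",
    "project_cells",
    "Patch",
    "PatchSet",
    "extract_patches_sliding",
    "extract_patches_nucleus_centered",
    "extract_patches_cell_region",
    "label_patches",
]


def icosphere(subdivisions: int = 2) -> Tuple[np.ndarray, np.ndarray]:
    """Unit icosphere (vertices, faces) with the given subdivision level.

    Level 0 is the icosahedron (12 vertices, 20 faces); each level splits
    every triangle in four, giving 42/80 at level 1 and 162/320 at level 2.
    """
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=float,
    )
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    faces = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ],
        dtype=int,
    )
    for _ in range(subdivisions):
        vert_list = list(verts)
        midpoint: Dict[Tuple[int, int], int] = {}

        def mid(a: int, b: int) -> int:
            key = (a, b) if a < b else (b, a)
            if key not in midpoint:
                m = vert_list[a] + vert_list[b]
                m /= np.linalg.norm(m)
                midpoint[key] = len(vert_list)
                vert_list.append(m)
            return midpoint[key]

        new_faces = []
        for a, b, c in faces:
            ab, bc, ca = mid(a, b), mid(b, c), mid(c, a)
            new_faces += [[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]]
        verts = np.array(vert_list)
        faces = np.array(new_faces, dtype=int)
    return verts, faces


def export_ply(cells: Sequence[CellEstimate], path, subdivisions: int = 2) -> None:
    """Write one icosphere per cell to an ASCII PLY file.

    Vertex positions are ``c_i + R_i * (unit sphere)``; the header vertex
    and face counts are exact multiples of the per-sphere counts.
    """
    if len(cells) == 0:
        raise ValueError("export_ply requires at least one cell")
    unit_v, unit_f = icosphere(subdivisions)
    nv, nf = len(unit_v), len(unit_f)
    path = Path(path)
    with open(path, "w", encoding="ascii", newline="\n") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"comment {len(cells)} reconstructed cells as icospheres\n")
        fh.write(f"element vertex {nv * len(cells)}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write(f"element face {nf * len(cells)}\n")
        fh.write("property list uchar int vertex_indices\n")
        fh.write("end_header\n")
        for cell in cells:
            pts = cell.center[None, :] + cell.R * unit_v
            for p in pts:
                fh.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
        for k in range(len(cells)):
            off = k * nv
            for f in unit_f:
                fh.write(f"3 {f[0] + off} {f[1] + off} {f[2] + off}\n")


@dataclass(frozen=True)
class ProjectedRegion:
    """A cell's footprint on the image plane.

    ``shadow`` mode is the orthographic silhouette (radius R); the
    ``cross_section`` mode is the slice through z = 0, with radius
    ``sqrt(R^2 - z^2)``, defined only for cells the plane actually cuts.
    """

    cell_id: int
    x: float
    y: float
    radius: float
    mode: str


def project_cells(
    cells: Sequence[CellEstimate],
    mode: Literal["shadow", "cross_section"] = "shadow",
) -> List[ProjectedRegion]:
    """Project spheres onto the imaging plane; see :class:`ProjectedRegion`."""
    if mode not in ("shadow", "cross_section"):
        raise ValueError(f"unknown projection mode: {mode!r}")
    regions = []
    for c in cells:
        if mode == "shadow":
            regions.append(ProjectedRegion(c.id, c.x, c.y, float(c.R), mode))
        else:
            if abs(c.z) <= c.R:
                r = float(np.sqrt(c.R**2 - c.z**2))
                regions.append(ProjectedRegion(c.id, c.x, c.y, r, mode))
    return regions


@dataclass
class Patch:
    """One fixed-size image window plus its provenance."""

    image: np.ndarray
    provenance: str  # sliding | nucleus_centered | cell_region
    cx: float        # defining point (window/nucleus/region center), x = col
    cy: float
    radius: float | None = None
    label: int | None = None
    cell_id: int | None = None


@dataclass
class PatchSet:
    patches: List[Patch]
    size: int
    source_shape: Tuple[int, int]

    def __len__(self) -> int:
        return len(self.patches)


def _window(image: np.ndarray, r0: int, c0: int, size: int) -> np.ndarray:
    """Crop a size x size window at (row r0, col c0), zero-padded at edges."""
    out_shape = (size, size) + image.shape[2:]
    out = np.zeros(out_shape, dtype=image.dtype)
    r1, c1 = r0 + size, c0 + size
    src_r0, src_c0 = max(r0, 0), max(c0, 0)
    src_r1, src_c1 = min(r1, image.shape[0]), min(c1, image.shape[1])
    if src_r0 < src_r1 and src_c0 < src_c1:
        out[src_r0 - r0 : src_r1 - r0, src_c0 - c0 : src_c1 - c0] = image[
            src_r0:src_r1, src_c0:src_c1
        ]
    return out


def extract_patches_sliding(image: np.ndarray, size: int = 60, stride: int = 60) -> PatchSet:
    """Row-major grid tiling from the top-left corner, zero-padded at edges."""
    image = np.asarray(image)
    H, W = image.shape[:2]
    patches = []
    for r0 in range(0, H, stride):
        for c0 in range(0, W, stride):
            patches.append(
                Patch(
                    image=_window(image, r0, c0, size),
                    provenance="sliding",
                    cx=c0 + size / 2.0,
                    cy=r0 + size / 2.0,
                )
            )
    return PatchSet(patches=patches, size=size, source_shape=(H, W))


def extract_patches_nucleus_centered(
    image: np.ndarray, observations: Sequence[NucleusObservation], size: int = 60
) -> PatchSet:
    """One window per nucleus, centered on the rounded centroid."""
    image = np.asarray(image)
    H, W = image.shape[:2]
    half = size // 2
    patches = []
    for o in observations:
        r0 = int(round(o.y)) - half
        c0 = int(round(o.x)) - half
        patches.append(
            Patch(
                image=_window(image, r0, c0, size),
                provenance="nucleus_centered",
                cx=o.x,
                cy=o.y,
                cell_id=o.id,
            )
        )
    return PatchSet(patches=patches, size=size, source_shape=(H, W))


def extract_patches_cell_region(
    image: np.ndarray, regions: Sequence[ProjectedRegion], size: int = 60
) -> PatchSet:
    """Cell-centric windows: pixels outside the projected disk are zeroed.

    The disk boundary is the reconstructed cell's projected outline, so the
    patch contains exactly one cell's footprint (regions wider than the
    window are cropped by it).
    """
    image = np.asarray(image)
    H, W = image.shape[:2]
    half = size // 2
    rows, cols = np.mgrid[0:size, 0:size]
    patches = []
    for reg in regions:
        r0 = int(round(reg.y)) - half
        c0 = int(round(reg.x)) - half
        win = _window(image, r0, c0, size).copy()
        dy = (rows + r0) - reg.y
        dx = (cols + c0) - reg.x
        mask = dx * dx + dy * dy <= reg.radius**2
        win[~mask] = 0
        patches.append(
            Patch(
                image=win,
                provenance="cell_region",
                cx=reg.x,
                cy=reg.y,
                radius=reg.radius,
                cell_id=reg.cell_id,
            )
        )
    return PatchSet(patches=patches, size=size, source_shape=(H, W))


def label_patches(patchset: PatchSet, tumor_mask: np.ndarray) -> PatchSet:
    """Label each patch tumor (1) / non-tumor (0) by its defining point.

    The defining point is the nucleus or region center (window center for
    sliding patches); a patch is tumor iff that point falls inside the
    binary annotation mask.
    """
    tumor_mask = np.asarray(tumor_mask)
    if tumor_mask.shape[:2] != patchset.source_shape:
        raise ValueError(
            f"tumor mask shape {tumor_mask.shape[:2]} does not match "
            f"source image shape {patchset.source_shape}"
        )
    labeled = []
    for p in patchset.patches:
        r = int(round(p.cy))
        c = int(round(p.cx))
        inside = (
            0 <= r < tumor_mask.shape[0]
            and 0 <= c < tumor_mask.shape[1]
            and bool(tumor_mask[r, c])
        )
        labeled.append(
            Patch(
                image=p.image,
                provenance=p.provenance,
                cx=p.cx,
                cy=p.cy,
                radius=p.radius,
                label=int(inside),
                cell_id=p.cell_id,
            )
        )
    return PatchSet(patches=labeled, size=patchset.size, source_shape=patchset.source_shape)
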