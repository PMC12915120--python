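"""Readers and writers bridging nuclear segmentations and the optimizer.

Coordinate convention: 0-based pixel indices, ``x`` = column, ``y`` = row,
centroids at pixel centers, origin at the top-left corner.  All lengths are
in pixels; callers working in microns convert at this boundary (a typical
scale is 0.25 um/px at 40x magnification).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import List, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.measure import regionprops
from skimage.segmentation import watershed

from .core import CellEstimate, NucleusObservation

logger = logging.getLogger(__name__)

__all__ = [
    "nuclei_from_mask",
    "split_binary_mask",
    "read_nuclei_csv",
    "write_nuclei_csv",
    "read_cells_csv",
    "write_cells_csv",
]

NUCLEI_COLUMNS = ["id", "x", "y", "r_nuc"]
CELL_COLUMNS = ["id", "x", "y", "r_nuc", "z", "R"]


def split_binary_mask(mask: np.ndarray, min_separation: int = 5) -> np.ndarray:
    """Split a binary nucleus mask into instances by watershed.

    Seeds are local maxima of the Euclidean distance transform separated by
    at least ``min_separation`` pixels; the watershed is flooded on the
    negated distance map restricted to the foreground.
    """
    binary = mask > 0
    if not binary.any():
        return np.zeros(mask.shape, dtype=int)
    distance = ndimage.distance_transform_edt(binary)
    peaks = peak_local_max(distance, min_distance=min_separation, labels=binary)
    markers = np.zeros(mask.shape, dtype=int)
    for k, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = k
    if markers.max() == 0:  # degenerate tiny blobs: fall back to components
        labels, _ = ndimage.label(binary)
        return labels
    return watershed(-distance, markers, mask=binary)


def nuclei_from_mask(
    mask: np.ndarray,
    split_binary: bool | str = "auto",
    min_separation: int = 5,
) -> List[NucleusObservation]:
    """Extract per-nucleus centroid and equivalent-circle radius from a mask.

    ``mask`` is a 2D integer raster with 0 = background and each positive
    label one nucleus instance.  The radius is the equivalent-circle radius
    ``sqrt(area / pi)``.  When the raster is binary (labels {0, 1}) and
    ``split_binary`` is true or "auto", a distance-transform watershed
    splits touching nuclei first.  Output is sorted by ascending label.
    """
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError(f"mask must be 2D, got shape {mask.shape}")
    if not np.issubdtype(mask.dtype, np.integer):
        if np.allclose(mask, np.round(mask)):
            mask = mask.astype(int)
        else:
            raise ValueError("mask must be an integer label raster")
    labels = np.unique(mask)
    labels = labels[labels > 0]
    if len(labels) == 0:
        logger.warning("mask contains no foreground labels")
        return []
    is_binary = len(labels) == 1 and labels[0] == 1
    if is_binary and (split_binary is True or split_binary == "auto"):
        mask = split_binary_mask(mask, min_separation=min_separation)
    observations = []
    for prop in regionprops(mask.astype(int)):
        cy, cx = prop.centroid  # (row, col) -> (y, x)
        r = float(np.sqrt(prop.area / np.pi))
        observations.append(
            NucleusObservation(id=int(prop.label), x=float(cx), y=float(cy), r_nuc=r)
        )
    observations.sort(key=lambda o: o.id)
    return observations


def _check_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    for col in required:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column '{col}'")


def _check_finite(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    values = df[list(cols)].to_numpy(dtype=float)
    bad = ~np.isfinite(values)
    if bad.any():
        row = int(np.argwhere(bad)[0][0])
        # +2: one for the header line, one for 1-based numbering
        raise ValueError(f"{path}: non-finite value at line {row + 2}")


def read_nuclei_csv(path) -> List[NucleusObservation]:
    """Read nucleus observations from CSV with columns id,x,y,r_nuc.

    Unknown columns are tolerated and ignored by the model.  Non-finite
    values and nonpositive radii are rejected with the offending line
    number (header = line 1).
    """
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    _check_columns(df, NUCLEI_COLUMNS, path)
    _check_finite(df, ["x", "y", "r_nuc"], path)
    nonpos = df.index[df["r_nuc"] <= 0]
    if len(nonpos):
        raise ValueError(f"{path}: r_nuc must be > 0 at line {int(nonpos[0]) + 2}")
    return [
        NucleusObservation(id=int(r.id), x=float(r.x), y=float(r.y), r_nuc=float(r.r_nuc))
        for r in df.itertuples()
    ]


def write_nuclei_csv(observations: Sequence[NucleusObservation], path) -> None:
    df = pd.DataFrame(
        {
            "id": [o.id for o in observations],
            "x": [o.x for o in observations],
            "y": [o.y for o in observations],
            "r_nuc": [o.r_nuc for o in observations],
        }
    )
    _write_with_header(df, path)


def read_cells_csv(path) -> List[CellEstimate]:
    """Read reconstructed cells from CSV with columns id,x,y,z,R."""
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    _check_columns(df, ["id", "x", "y", "z", "R"], path)
    _check_finite(df, ["x", "y", "z", "R"], path)
    return [
        CellEstimate(id=int(r.id), x=float(r.x), y=float(r.y), z=float(r.z), R=float(r.R))
        for r in df.itertuples()
    ]


def write_cells_csv(
    cells: Sequence[CellEstimate],
    path,
    observations: Sequence[NucleusObservation] | None = None,
) -> None:
    """Write cells to CSV; adds the r_nuc column when observations given."""
    data = {
        "id": [c.id for c in cells],
        "x": [c.x for c in cells],
        "y": [c.y for c in cells],
    }
    if observations is not None:
        by_id = {o.id: o for o in observations}
        data["r_nuc"] = [by_id[c.id].r_nuc for c in cells]
    data["z"] = [c.z for c in cells]
    data["R"] = [c.R for c in cells]
    _write_with_header(pd.DataFrame(data), path)


def _write_with_header(df: pd.DataFrame, path) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("# lengths in pixels; x = column, y = row, 0-based, pixel centers\n")
        df.to_csv(fh, index=False, float_format="%.17g")
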