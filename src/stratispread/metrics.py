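"""Landscape metrics: PLAND, NP and CONNECT.

PLAND is the percentage of the landscape covered by a class, NP the
number of patches (connected components) of that class, and CONNECT the
percentage of same-class patch pairs whose minimum cell-centre distance
is within a user threshold ("functional joinings").  All three can be
reported per class and for the landscape as a whole.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .landscape import SuitabilityClass, SuitabilityClassMap, classify_suitability
from .raster import RasterGrid

__all__ = [
    "PatchLabeling",
    "label_patches",
    "pland",
    "np_metric",
    "connect_metric",
    "whole_landscape_report",
]

_STRUCTURES = {
    4: ndimage.generate_binary_structure(2, 1),
    8: ndimage.generate_binary_structure(2, 2),
}


def _values(grid) -> np.ndarray:
    return grid.values if isinstance(grid, RasterGrid) else np.asarray(grid)


def _structure(connectivity_rule: int) -> np.ndarray:
    try:
        return _STRUCTURES[int(connectivity_rule)]
    except KeyError:
        raise ValueError(
            f"connectivity_rule must be 4 or 8, got {connectivity_rule}"
        ) from None


@dataclass
class PatchLabeling:
    """Connected-component labelling of one class (0 = background)."""

    labels: np.ndarray
    n_patches: int
    class_value: float
    connectivity_rule: int


def label_patches(grid, class_value, connectivity_rule: int = 8) -> PatchLabeling:
    """Label the patches (connected components) of ``class_value``."""
    values = _values(grid)
    mask = values == class_value
    labels, n = ndimage.label(mask, structure=_structure(connectivity_rule))
    return PatchLabeling(labels=labels, n_patches=int(n),
                         class_value=class_value,
                         connectivity_rule=int(connectivity_rule))


def pland(grid, class_value) -> float:
    """Percentage of (non-nodata) landscape area occupied by a class."""
    values = _values(grid)
    if isinstance(grid, RasterGrid):
        valid = grid.data_mask()
    else:
        valid = np.ones(values.shape, dtype=bool)
    total = int(valid.sum())
    if total == 0:
        raise ValueError("grid has no valid cells")
    return 100.0 * np.count_nonzero((values == class_value) & valid) / total


def np_metric(grid, class_value, connectivity_rule: int = 8) -> int:
    """Number of patches (NP) of a class."""
    return label_patches(grid, class_value, connectivity_rule).n_patches


def _patch_coords(labeling: PatchLabeling) -> list[np.ndarray]:
    """Cell-centre lattice coordinates of every patch, 1-indexed labels."""
    labels = labeling.labels
    coords = []
    for i in range(1, labeling.n_patches + 1):
        rr, cc = np.nonzero(labels == i)
        coords.append(np.column_stack([rr, cc]).astype(float))
    return coords


def _pairs_within(coords: list[np.ndarray], threshold_cells: float) -> int:
    """Count patch pairs whose minimum cell-centre distance is <= threshold.

    Pools all patch cells into one KD-tree and reads off the distinct
    patch-id pairs among cell pairs within the radius; equivalent to the
    all-pairs minimum-distance definition but near-linear in cells for
    small thresholds.
    """
    if len(coords) <= 1:
        return 0
    pts = np.concatenate(coords, axis=0)
    ids = np.concatenate([np.full(len(c), i) for i, c in enumerate(coords)])
    pairs = cKDTree(pts).query_pairs(r=threshold_cells, output_type="ndarray")
    if pairs.size == 0:
        return 0
    a, b = ids[pairs[:, 0]], ids[pairs[:, 1]]
    cross = a != b
    if not np.any(cross):
        return 0
    lo, hi = np.minimum(a[cross], b[cross]), np.maximum(a[cross], b[cross])
    return int(np.unique(lo * len(coords) + hi).size)


def connect_metric(
    grid,
    class_value,
    connectivity_rule: int = 8,
    threshold_distance: float = 2.0,
    cell_size: float | None = None,
) -> float:
    """CONNECT: percentage of patch pairs within a threshold distance.

    The inter-patch distance is the minimum Euclidean distance between
    cell centres of the two patches, in map units.  With n patches the
    denominator is n(n-1)/2; n <= 1 returns 0 by convention (no pairs).

    ``threshold_distance`` is in map units; ``cell_size`` defaults to
    the grid's own (1.0 for bare arrays).
    """
    if not threshold_distance > 0:
        raise ValueError(f"threshold_distance must be positive, got {threshold_distance}")
    if cell_size is None:
        cell_size = grid.cell_size if isinstance(grid, RasterGrid) else 1.0
    labeling = label_patches(grid, class_value, connectivity_rule)
    n = labeling.n_patches
    if n <= 1:
        return 0.0
    coords = _patch_coords(labeling)
    joined = _pairs_within(coords, threshold_distance / cell_size)
    return 100.0 * joined / (n * (n - 1) / 2)


_CLASS_NAMES = {
    SuitabilityClass.SUITABLE: "suitable",
    SuitabilityClass.LESS_SUITABLE: "less_suitable",
    SuitabilityClass.MARGINAL: "marginal",
}


def whole_landscape_report(
    grid,
    connect_threshold: float = 2.0,
    connectivity_rule: int = 8,
    classes=None,
) -> pd.DataFrame:
    """Per-class PLAND/NP/CONNECT plus a pooled whole-landscape row.

    ``grid`` may be a categorical grid (any values; ``classes`` defaults
    to the sorted distinct values), a :class:`SuitabilityClassMap`, or a
    survival-probability map in [0, 1], which is first classified into
    suitable / less suitable / marginal.  The ``landscape`` row pools
    every classed patch: its NP is the total patch count and its CONNECT
    considers all patch pairs regardless of class; its PLAND is 100.
    """
    if isinstance(grid, SuitabilityClassMap):
        cat = grid.grid
        names = _CLASS_NAMES
    elif isinstance(grid, RasterGrid) and np.issubdtype(grid.values.dtype, np.floating) \
            and grid.values.min() >= 0 and grid.values.max() <= 1 \
            and np.any(~np.isin(grid.values, (0.0, 1.0))):
        cat = classify_suitability(grid).grid
        names = _CLASS_NAMES
    else:
        cat = grid if isinstance(grid, RasterGrid) else RasterGrid(np.asarray(grid))
        names = None
    if classes is None:
        classes = sorted(np.unique(cat.values).tolist())
    cell_size = cat.cell_size

    rows = []
    all_coords: list[np.ndarray] = []
    for cls in classes:
        labeling = label_patches(cat, cls, connectivity_rule)
        coords = _patch_coords(labeling)
        all_coords.extend(coords)
        name = names.get(cls, str(cls)) if names else str(cls)
        rows.append(
            {
                "class": name,
                "PLAND": pland(cat, cls),
                "NP": labeling.n_patches,
                "CONNECT": _connect_from_coords(coords, connect_threshold, cell_size),
            }
        )
    rows.append(
        {
            "class": "landscape",
            "PLAND": float(sum(r["PLAND"] for r in rows)),
            "NP": int(sum(r["NP"] for r in rows)),
            "CONNECT": _connect_from_coords(all_coords, connect_threshold, cell_size),
        }
    )
    return pd.DataFrame(rows)


def _connect_from_coords(coords, threshold_distance, cell_size) -> float:
    n = len(coords)
    if n <= 1:
        return 0.0
    joined = _pairs_within(coords, threshold_distance / cell_size)
    return 100.0 * joined / (n * (n - 1) / 2)
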