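"""Seeded threshold masking ("paint with threshold").

The original workflow selected each structure interactively: the operator
painted over the target and the tool kept connected voxels whose intensity
fell inside a chosen range, ignoring disconnected in-range structures.  The
reproducible formalization here is (seed points + intensity range): the mask
is the union of 26-connected components of the in-range voxel set that
contain at least one seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from iseikit.stackio import VoxelGrid

__all__ = ["BinaryMask", "paint_threshold", "mask_volume", "CONNECTIVITY_STRUCTS"]

CONNECTIVITY_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class BinaryMask:
    """Voxels of one labeled structure, tied to a grid's geometry."""

    data: np.ndarray                      # boolean, same shape as the grid
    spacing: tuple[float, float, float]   # (z, y, x) mm
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    label: str = "structure"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError("mask must be 3D")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def indices(self) -> np.ndarray:
        """(n, 3) array of (z, y, x) voxel indices, lexicographically ordered."""
        return np.argwhere(self.data)

    def centers_mm(self) -> np.ndarray:
        """(n, 3) physical (x, y, z) centers of the masked voxels."""
        from iseikit.stackio import index_to_mm
        return index_to_mm(self.indices(), self.spacing, self.origin)


def paint_threshold(grid: VoxelGrid, seeds, intensity_range,
                    connectivity: int = 26, label: str = "structure") -> BinaryMask:
    """Select the connected in-range component(s) reachable from seed voxels.

    Parameters
    ----------
    grid : VoxelGrid
    seeds : iterable of (z, y, x) index triples
        Points the operator would have painted; each must be in bounds and
        in range.
    intensity_range : (lo, hi)
        Inclusive intensity window defining candidate voxels.
    connectivity : 6, 18 or 26
        3D neighbor connectivity; 26 matches the permissive behaviour of an
        interactive painting tool.

    Disconnected in-range voxels (non-target structures, noise speckle) are
    excluded: only components containing a seed survive.
    """
    lo, hi = intensity_range
    if lo > hi:
        raise ValueError(f"invalid intensity range [{lo}, {hi}]")
    if connectivity not in CONNECTIVITY_STRUCTS:
        raise ValueError("connectivity must be 6, 18 or 26")
    seeds = [tuple(int(c) for c in s) for s in seeds]
    if not seeds:
        raise ValueError("at least one seed is required")
    shape = grid.shape
    for s in seeds:
        if len(s) != 3 or any(c < 0 or c >= shape[i] for i, c in enumerate(s)):
            raise IndexError(f"seed {s} out of bounds for grid shape {shape}")
        v = grid.data[s]
        if not (lo <= v <= hi):
            raise ValueError(f"seed {s} has intensity {v}, outside range [{lo}, {hi}]")

    in_range = (grid.data >= lo) & (grid.data <= hi)
    labels, _ = ndimage.label(in_range, structure=CONNECTIVITY_STRUCTS[connectivity])
    keep = {labels[s] for s in seeds}
    keep.discard(0)
    mask = np.isin(labels, sorted(keep))
    return BinaryMask(mask, grid.spacing, grid.origin, label=label)


def mask_volume(mask: BinaryMask) -> float:
    """Physical volume (mm^3): voxel count times voxel volume."""
    n = mask.n_voxels
    if n == 0:
        raise ValueError("empty mask has no volume")
    return n * float(np.prod(mask.spacing))
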