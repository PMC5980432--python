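"""Single center positions for pronuclei and polar-body masks.

Each nuclear landmark (male pronucleus, female pronucleus, the polar-body
cluster — which migrates to a putative common position and is masked as one
structure) is reduced to one point: the simple arithmetic mean of the masked
voxel coordinates, axis by axis.

Two coordinate flavours are exposed.  The index-unit center is the raw mean
of the integer voxel indices (e.g. sites [3,9,7] and [5,3,7] average to
[4,6,7]).  The mm center maps voxel indices to physical voxel centers
(half-voxel convention) before averaging; downstream distances use mm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from iseikit.masking import BinaryMask
from iseikit.stackio import index_to_mm

__all__ = ["LandmarkCenter", "compute_center", "compute_centers"]


@dataclass
class LandmarkCenter:
    label: str
    index: np.ndarray     # mean voxel index, same axis order as the input sites
    mm: np.ndarray        # physical (x, y, z) center in mm
    n_voxels: int


def compute_center(mask: BinaryMask) -> LandmarkCenter:
    """Arithmetic-mean center of a landmark mask.

    Raises on an empty mask; a single-voxel mask returns that voxel.
    """
    sites = mask.indices()
    if len(sites) == 0:
        raise ValueError(f"mask '{mask.label}' is empty: no center")
    idx_center = sites.mean(axis=0)
    mm_center = index_to_mm(sites, mask.spacing, mask.origin).mean(axis=0)
    return LandmarkCenter(mask.label, idx_center, mm_center, len(sites))


def center_of_sites(sites) -> np.ndarray:
    """Arithmetic mean of raw index triples (axis-order agnostic)."""
    sites = np.asarray(sites, dtype=float)
    if sites.size == 0:
        raise ValueError("no sites")
    return sites.mean(axis=0)


def compute_centers(masks: dict[str, BinaryMask]) -> dict[str, LandmarkCenter]:
    """Centers for a set of landmark masks, keyed by label."""
    return {label: compute_center(m) for label, m in masks.items()}
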