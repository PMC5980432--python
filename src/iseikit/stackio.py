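"""Image-stack and record I/O with explicit physical spacing.

Axis convention: arrays are indexed (z, y, x) with z the slice index; all
physical coordinates in the package are (x, y, z) in mm.  The two helpers
:func:`index_to_mm` / :func:`mm_to_index` are the single conversion point.
Voxel *centers* sit at ``(index + 0.5) * spacing`` plus the grid origin.

Spacing is never defaulted silently: it must come from the caller or from a
JSON sidecar written next to the stack (``<stem>.spacing.json``, containing
``{"spacing_mm": [z, y, x]}``).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

log = logging.getLogger(__name__)

__all__ = ["VoxelGrid", "read_stack", "write_stack", "write_records",
           "index_to_mm", "mm_to_index", "RECORD_COLUMNS"]


@dataclass
class VoxelGrid:
    """A 3D intensity lattice with per-axis physical spacing.

    data : (nz, ny, nx) array
    spacing : (z, y, x) voxel pitch in mm, strictly positive
    origin : physical (x, y, z) offset of the grid corner in mm
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or self.data.size == 0:
            raise ValueError("grid must be a non-empty 3D array")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive values, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("grid intensities must be finite")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Physical volume of one voxel (mm^3)."""
        return float(np.prod(self.spacing))

    def voxel_centers_mm(self, indices: np.ndarray) -> np.ndarray:
        """(x, y, z) mm centers of (z, y, x) index triples."""
        return index_to_mm(np.asarray(indices), self.spacing, self.origin)


def index_to_mm(indices_zyx: np.ndarray, spacing, origin=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Map (z, y, x) voxel indices to physical (x, y, z) voxel-center mm."""
    idx = np.atleast_2d(np.asarray(indices_zyx, dtype=float))
    sp = np.asarray(spacing, dtype=float)          # (z, y, x)
    centers_zyx = (idx + 0.5) * sp
    xyz = centers_zyx[:, ::-1] + np.asarray(origin, dtype=float)
    return xyz if np.asarray(indices_zyx).ndim > 1 else xyz[0]


def mm_to_index(points_xyz: np.ndarray, spacing, origin=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Map physical (x, y, z) mm to fractional (z, y, x) voxel indices."""
    pts = np.atleast_2d(np.asarray(points_xyz, dtype=float)) - np.asarray(origin, dtype=float)
    zyx = pts[:, ::-1] / np.asarray(spacing, dtype=float) - 0.5
    return zyx if np.asarray(points_xyz).ndim > 1 else zyx[0]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix("").with_suffix(".spacing.json") if path.suffix else path / "spacing.json"


def read_stack(path, spacing: Sequence[float] | None = None) -> VoxelGrid:
    """Read a multi-page TIFF, or a directory of 2D TIFF slices in
    lexicographic order, into a :class:`VoxelGrid`.

    ``spacing`` is (z, y, x) in mm; if omitted it must be present in the
    JSON sidecar — there is deliberately no default of 1.
    """
    path = Path(path)
    origin = (0.0, 0.0, 0.0)
    if path.is_dir():
        pages = sorted(p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff"))
        if not pages:
            raise FileNotFoundError(f"no TIFF slices in {path}")
        slices = [tifffile.imread(p) for p in pages]
        shapes = {s.shape for s in slices}
        if len(shapes) != 1 or slices[0].ndim != 2:
            raise ValueError(f"ragged or non-2D slice shapes in {path}: {shapes}")
        data = np.stack(slices, axis=0)
        sidecar = path / "spacing.json"
    else:
        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None]
        if data.ndim != 3:
            raise ValueError(f"expected a 2D/3D TIFF, got shape {data.shape}")
        sidecar = _sidecar_path(path)

    meta = {}
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    if spacing is None:
        if "spacing_mm" not in meta:
            raise ValueError(
                f"no spacing given and no sidecar {sidecar.name}: voxel spacing "
                "(z, y, x) in mm is required, it is never defaulted")
        spacing = meta["spacing_mm"]
    if "origin_mm" in meta:
        origin = tuple(meta["origin_mm"])
    return VoxelGrid(data, tuple(spacing), origin)


def write_stack(grid: VoxelGrid, path) -> Path:
    """Write a multi-page 16-bit TIFF plus a JSON spacing sidecar.

    Intensities outside the uint16 range are clamped with a warning.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = grid.data
    if not np.issubdtype(data.dtype, np.unsignedinteger):
        if data.min() < 0 or data.max() > np.iinfo(np.uint16).max:
            log.warning("intensities outside [0, 65535] clamped on write to %s", path)
        data = np.clip(np.round(data), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    elif data.dtype != np.uint16:
        data = data.astype(np.uint16)
    tifffile.imwrite(path, data, photometric="minisblack")
    sidecar = _sidecar_path(path)
    sidecar.write_text(json.dumps({
        "spacing_mm": list(grid.spacing),
        "origin_mm": list(grid.origin),
    }))
    return path


#: stable column order of the per-egg records table
RECORD_COLUMNS = [
    "egg_id", "female_species", "male_species", "stage",
    "sperm_positioning", "pronuclei_distance",
    "arc_length", "net_length", "aspect_ratio",
    "average_curvature", "total_curvature",
    "average_torsion", "writhe",
    "n_trace_points", "flagellum_mask_voxels", "qc_flags",
]


def write_records(records, path) -> Path:
    """Write egg records to CSV, one row per egg, stable column order.

    Descriptors that are not measurable at a record's stage (the positional
    parameters vanish once pronuclei fuse and polar bodies disintegrate)
    are written as empty cells.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = [r.as_dict() if hasattr(r, "as_dict") else dict(r) for r in records]
    df = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    df.to_csv(path, index=False)
    return path
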