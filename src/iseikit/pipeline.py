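"""Per-egg measurement: masking -> landmarks -> tracing -> descriptors.

Assembles one :class:`EggRecord` per egg, honouring stage-dependent
measurability: at the pronuclear (PN) stage all seven ISEI parameters exist
(sperm positioning, pronuclei distance, arc length, net length, aspect
ratio, average curvature, total curvature); after karyogamy (2N-8N) the
pronuclei have fused and the polar bodies disintegrated, so only the five
shape descriptors remain and the two positional ones are absent, never
zero-filled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from iseikit.centerline import TraceParams, Polyline, trace
from iseikit.geometry import describe_points
from iseikit.landmarks import compute_center
from iseikit.masking import BinaryMask
from iseikit.stackio import VoxelGrid, RECORD_COLUMNS

log = logging.getLogger(__name__)

__all__ = ["EggRecord", "sperm_positioning", "pronuclei_distance",
           "measure_egg", "build_table", "STAGES", "PN_ONLY", "SHAPE_DESCRIPTORS"]

STAGES = ("PN", "2N", "4N", "8N")
PN_ONLY = ("sperm_positioning", "pronuclei_distance")
SHAPE_DESCRIPTORS = ("arc_length", "net_length", "aspect_ratio",
                     "average_curvature", "total_curvature")


@dataclass
class EggRecord:
    """One egg's annotations, descriptors and QC flags; cross written
    female-first."""

    egg_id: str
    female_species: str
    male_species: str
    stage: str
    sperm_positioning: float | None = None
    pronuclei_distance: float | None = None
    arc_length: float | None = None
    net_length: float | None = None
    aspect_ratio: float | None = None
    average_curvature: float | None = None
    total_curvature: float | None = None
    average_torsion: float | None = None
    writhe: float | None = None
    n_trace_points: int | None = None
    flagellum_mask_voxels: int | None = None
    qc_flags: str = ""

    def __post_init__(self):
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage '{self.stage}'; expected one of {STAGES}")
        if self.stage != "PN":
            for name in PN_ONLY:
                if getattr(self, name) is not None:
                    raise ValueError(f"{name} is only measurable at the PN stage, "
                                     f"but was set for a {self.stage} record")

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in RECORD_COLUMNS}


def sperm_positioning(polyline: Polyline | np.ndarray, polar_body_center) -> float:
    """Mean distance (mm) from the polar-body center to the flagellum.

    Averaged over the uniformly resampled centerline points, which makes it
    an arc-length-weighted mean distance — the formalization of using the
    distance from the polar bodies to points along the sperm as a landmark
    for where the flagellum sits within the egg.
    """
    pts = polyline.points if isinstance(polyline, Polyline) else np.asarray(polyline, float)
    c = np.asarray(polar_body_center, float)
    return float(np.linalg.norm(pts - c, axis=1).mean())


def pronuclei_distance(male_center, female_center) -> float:
    """3D Euclidean distance (mm) between the male and female pronuclei."""
    return float(np.linalg.norm(np.asarray(male_center, float)
                                - np.asarray(female_center, float)))


def measure_egg(grid: VoxelGrid, masks: dict[str, BinaryMask], annotations: dict,
                params: TraceParams | None = None,
                smoothing: float | None = None) -> EggRecord | None:
    """Measure one egg end to end; returns None (with a logged reason) when
    the flagellum mask is missing."""
    egg_id = annotations.get("egg_id", "?")
    if "flagellum" not in masks or masks["flagellum"].n_voxels == 0:
        log.warning("egg %s skipped: no flagellum mask", egg_id)
        return None
    stage = annotations["stage"]
    flags = []

    poly = trace(masks["flagellum"], params)
    if len(poly) < 10:
        flags.append("short_trace")
    desc = describe_points(poly.points, smoothing=smoothing)

    rec = EggRecord(
        egg_id=egg_id,
        female_species=annotations["female_species"],
        male_species=annotations["male_species"],
        stage=stage,
        arc_length=desc.arc_length,
        net_length=desc.net_length,
        aspect_ratio=desc.aspect_ratio,
        average_curvature=desc.average_curvature,
        total_curvature=desc.total_curvature,
        average_torsion=desc.average_torsion,
        writhe=desc.writhe,
        n_trace_points=len(poly),
        flagellum_mask_voxels=masks["flagellum"].n_voxels,
    )
    if stage == "PN":
        if "polar_bodies" in masks and masks["polar_bodies"].n_voxels:
            pb = compute_center(masks["polar_bodies"])
            rec.sperm_positioning = sperm_positioning(poly, pb.mm)
        else:
            flags.append("missing_polar_bodies")
        if all(k in masks and masks[k].n_voxels
               for k in ("male_pronucleus", "female_pronucleus")):
            m = compute_center(masks["male_pronucleus"])
            f = compute_center(masks["female_pronucleus"])
            rec.pronuclei_distance = pronuclei_distance(m.mm, f.mm)
        else:
            flags.append("missing_pronucleus")
    rec.qc_flags = ";".join(flags)
    return rec


def build_table(records) -> pd.DataFrame:
    """Long-format analysis table keyed by (cross, stage), one row per egg."""
    rows = [r.as_dict() if isinstance(r, EggRecord) else dict(r) for r in records]
    df = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    if df["egg_id"].duplicated().any():
        dupes = df.loc[df["egg_id"].duplicated(), "egg_id"].tolist()
        raise ValueError(f"duplicated egg_id(s): {dupes}")
    df["cross"] = df["female_species"].astype(str) + "x" + df["male_species"].astype(str)
    return df


def group_sizes(table: pd.DataFrame) -> pd.DataFrame:
    """Egg counts per (female, male, stage) — the design layout check."""
    if table.empty:
        return pd.DataFrame(columns=["female_species", "male_species", "stage", "n"])
    out = (table.groupby(["female_species", "male_species", "stage"], observed=True)
           .size().rename("n").reset_index())
    return out
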