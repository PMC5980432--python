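"""Iterative directed centerline tracing of a tubular voxel mask.

The flagellum mask is a curved tube of voxels, possibly passing close to or
over itself.  The tracer turns it into an ordered polyline of sub-voxel
points:

1.  Every masked voxel gets a *density score* from the number and distance
    of its masked neighbors — voxels deep inside the tube score highest.
2.  The start point is the score-weighted neighborhood centroid of the
    best-scoring voxel; the second point is the neighborhood centroid of
    the voxel maximizing ``score x distance-kernel`` around the start.
3.  Tracing then iterates: candidate voxels must lie ahead of the current
    direction (inside a forward cone — voxels behind are never considered),
    are weighted by score and by a triangular kernel around a preferred
    step distance that shrinks with the candidate's angle off the direction
    (smaller steps into turns), and the winner's neighborhood centroid
    becomes the next point.
4.  After each step the voxels between the new point and the previous one
    are *consumed* (removed from candidacy and from centroid neighborhoods),
    which is what lets the tracer pass straight through a location where the
    curve crosses over itself instead of switching onto the other branch.
5.  The whole process repeats in the opposite direction from the seed pair,
    and the two halves are joined and resampled at a uniform spacing.

Termination — an empty candidate set or a step below the minimal distance —
is a normal outcome marking the end of the tube.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from iseikit.masking import BinaryMask

log = logging.getLogger(__name__)

__all__ = ["TraceParams", "Polyline", "density_score", "find_start",
           "trace_direction", "trace", "resample_uniform"]


@dataclass
class TraceParams:
    """Tuning knobs of the tracer; lengths in mm.

    Any field left ``None`` is derived from the grid spacing when tracing
    starts (see :func:`resolve_params`): preferred step ``s0`` = 3x the
    coarsest voxel pitch, minimal step ``eps`` = 0.5x, density radius = 2x,
    and the consumption radius is estimated from the mask volume and a
    pilot trace (tube radius = sqrt(V / (pi L))).
    """

    density_radius: float | None = None     # neighborhood radius for scores/centroids
    step_distance: float | None = None      # s0, preferred step
    min_step: float | None = None           # eps, termination threshold
    cone_half_angle_deg: float = 80.0       # candidates beyond this are not considered
    weight_scale: float | None = None       # half-width of the triangular distance kernel
    gain: float = 0.5                       # step shrink per radian-fraction off-axis
    consumption_radius: float | None = None # rho, tube radius for voxel consumption
    resample_spacing: float = 0.002         # uniform output spacing
    consume: bool = True                    # disable only for ablation studies

    def resolved(self, spacing) -> "TraceParams":
        h = float(max(spacing))
        return replace(
            self,
            density_radius=self.density_radius if self.density_radius is not None else 2.0 * h,
            step_distance=self.step_distance if self.step_distance is not None else 3.0 * h,
            min_step=self.min_step if self.min_step is not None else 0.5 * h,
            weight_scale=self.weight_scale if self.weight_scale is not None else 3.0 * h,
        )


@dataclass
class Polyline:
    """Ordered 3D points (mm) with provenance."""

    points: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3 or len(self.points) < 2:
            raise ValueError("polyline needs at least two 3D points")
        if np.any(np.linalg.norm(np.diff(self.points, axis=0), axis=1) == 0):
            raise ValueError("consecutive polyline points must be distinct")

    def __len__(self):
        return len(self.points)

    @property
    def chord_length(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())


class _MaskField:
    """Masked voxel coordinates, KD-tree, density scores and consumption state."""

    def __init__(self, mask: BinaryMask, params: TraceParams):
        self.coords = mask.centers_mm()          # lexicographic (z,y,x) index order
        if len(self.coords) < 2:
            raise ValueError("mask too small to trace")
        self.tree = cKDTree(self.coords)
        self.scores = _scores_from_tree(self.coords, self.tree, params.density_radius)
        self.consumed = np.zeros(len(self.coords), dtype=bool)

    def centroid(self, i: int) -> np.ndarray:
        """Score-weighted centroid of live masked voxels near voxel i."""
        return self.centroid_at(self.coords[i])

    def centroid_at(self, point: np.ndarray) -> np.ndarray:
        idx = np.array(self.tree.query_ball_point(point, self._radius), dtype=int)
        idx = idx[~self.consumed[idx]] if len(idx) else idx
        if len(idx) == 0:
            return np.asarray(point, dtype=float)
        w = self.scores[idx] + 1e-12
        return (self.coords[idx] * w[:, None]).sum(axis=0) / w.sum()

    def consume_segment(self, a: np.ndarray, b: np.ndarray, rho: float):
        """Mark voxels within rho of the segment a->b as consumed, sparing the
        neighborhood of the new endpoint b (only voxels *between* the points)."""
        seg = b - a
        length = np.linalg.norm(seg)
        if length == 0:
            return
        n_probe = max(2, int(np.ceil(length / (0.5 * rho))) + 1)
        ts = np.linspace(0.0, max(0.0, 1.0 - rho / length), n_probe)
        hit: set[int] = set()
        for t in ts:
            hit.update(self.tree.query_ball_point(a + t * seg, rho))
        if hit:
            self.consumed[np.fromiter(hit, dtype=int)] = True


def _scores_from_tree(coords, tree, radius):
    pairs = tree.query_pairs(radius, output_type="ndarray")
    scores = np.zeros(len(coords))
    if len(pairs):
        d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
        w = 1.0 / (1.0 + d)
        np.add.at(scores, pairs[:, 0], w)
        np.add.at(scores, pairs[:, 1], w)
    return scores


def density_score(mask: BinaryMask, radius: float | None = None) -> np.ndarray:
    """Per-voxel density score, aligned with ``mask.indices()`` order.

    score(v) = sum over masked neighbors u within ``radius`` of 1/(1 + |u-v|),
    distances in mm.  An isolated voxel scores 0.
    """
    if radius is None:
        radius = 2.0 * max(mask.spacing)
    coords = mask.centers_mm()
    tree = cKDTree(coords)
    return _scores_from_tree(coords, tree, radius)


def _triangular(d, peak, width):
    return np.maximum(0.0, 1.0 - np.abs(d - peak) / width)


def find_start(mask: BinaryMask, params: TraceParams | None = None):
    """Seed pair (point 0, point 1) for the trace.

    Point 0 is the neighborhood centroid of the highest-density voxel; point 1
    the neighborhood centroid of the voxel maximizing score x triangular
    distance kernel peaked at the preferred step.  Ties resolve to the
    lexicographically smallest voxel index (argmax-first over index order).
    """
    params = (params or TraceParams()).resolved(mask.spacing)
    f = _MaskField(mask, params)
    return _find_start(f, params) + (f,)


def _find_start(f: _MaskField, params: TraceParams):
    f._radius = params.density_radius
    i0 = int(np.argmax(f.scores))
    p0 = f.centroid(i0)
    d = np.linalg.norm(f.coords - p0, axis=1)
    w = f.scores * _triangular(d, params.step_distance, params.weight_scale)
    w[d < params.min_step] = 0.0
    if not np.any(w > 0):
        raise ValueError("mask too small: no admissible second point")
    i1 = int(np.argmax(w))
    p1 = f.centroid(i1)
    return p0, p1


def _step(f: _MaskField, p_prev, p_cur, params: TraceParams):
    """One tracing step; returns the next point or None at termination."""
    direction = p_cur - p_prev
    direction = direction / np.linalg.norm(direction)
    reach = params.step_distance + params.weight_scale
    idx = np.array(f.tree.query_ball_point(p_cur, reach), dtype=int)
    if len(idx) == 0:
        return None
    idx = idx[~f.consumed[idx]]
    if len(idx) == 0:
        return None
    rel = f.coords[idx] - p_cur
    dist = np.linalg.norm(rel, axis=1)
    good = dist > 0
    idx, rel, dist = idx[good], rel[good], dist[good]
    proj = rel @ direction
    cosang = np.clip(proj / dist, -1.0, 1.0)
    theta = np.arccos(cosang)
    cone = np.deg2rad(params.cone_half_angle_deg)
    ahead = (proj > 0) & (theta <= cone)
    if not np.any(ahead):
        return None
    idx, dist, theta = idx[ahead], dist[ahead], theta[ahead]
    s_pref = params.step_distance * (1.0 - params.gain * theta / np.pi)
    w = f.scores[idx] * _triangular(dist, s_pref, params.weight_scale)
    # soft cone: alignment taper on top of the hard cutoff, so straight
    # continuation beats an oblique branch of equal density
    w *= 1.0 - theta / cone
    if not np.any(w > 0):
        return None
    winner = idx[int(np.argmax(w))]
    nxt = f.centroid_at(f.coords[winner])
    if np.linalg.norm(nxt - p_cur) < params.min_step:
        return None
    return nxt


def trace_direction(mask: BinaryMask, point0, point1,
                    params: TraceParams | None = None,
                    _field: _MaskField | None = None) -> np.ndarray:
    """Trace from the seed pair in the direction point0 -> point1.

    Returns the ordered points including the seeds.  Consumption state lives
    in the mask field, so a caller-supplied field carries it across calls.
    """
    params = (params or TraceParams()).resolved(mask.spacing)
    f = _field
    if f is None:
        f = _MaskField(mask, params)
        f._radius = params.density_radius
    rho = params.consumption_radius or max(mask.spacing)
    pts = [np.asarray(point0, float), np.asarray(point1, float)]
    if params.consume:
        f.consume_segment(pts[0], pts[1], rho)
    while True:
        nxt = _step(f, pts[-2], pts[-1], params)
        if nxt is None:
            break
        if params.consume:
            f.consume_segment(pts[-1], nxt, rho)
        pts.append(nxt)
        # a sane trace takes far fewer steps than there are tube voxels; a
        # tracer circling a self-crossing forever (e.g. with consumption
        # disabled) trips this instead of spinning
        if len(pts) > max(1000, len(f.coords)):
            raise RuntimeError("trace did not terminate: exceeded the voxel "
                               "budget (is voxel consumption disabled on a "
                               "self-crossing curve?)")
    return np.array(pts)


def trace(mask: BinaryMask, params: TraceParams | None = None) -> Polyline:
    """Full bidirectional trace of a tubular mask, resampled uniformly.

    When no consumption radius is given, a pilot trace estimates the tube
    radius as sqrt(mask volume / (pi x pilot length)) and the trace is
    re-run with that radius.
    """
    params = (params or TraceParams()).resolved(mask.spacing)
    if params.consumption_radius is None:
        pilot = replace(params, consumption_radius=max(mask.spacing))
        poly = _trace_once(mask, pilot)
        volume = mask.n_voxels * float(np.prod(mask.spacing))
        length = poly.chord_length
        rho = float(np.sqrt(volume / (np.pi * max(length, 1e-9))))
        rho = float(np.clip(rho, 0.5 * max(mask.spacing), 3.0 * max(mask.spacing)))
        params = replace(params, consumption_radius=rho)
    return _trace_once(mask, params)


def _trace_once(mask: BinaryMask, params: TraceParams) -> Polyline:
    f = _MaskField(mask, params)
    f._radius = params.density_radius
    p0, p1 = _find_start(f, params)

    forward = trace_direction(mask, p0, p1, params, _field=f)

    fb = _MaskField(mask, params)
    fb._radius = params.density_radius
    fb.scores = f.scores
    # the backward pass must not re-trace the forward direction: its seed
    # segment (the forward pass's first step) starts out consumed
    backward = trace_direction(mask, p1, p0, params, _field=fb)

    # backward = [p1, p0, b2, b3, ...]; stitch reversed tail + forward
    tail = backward[2:][::-1] if len(backward) > 2 else np.empty((0, 3))
    full = np.vstack([tail, forward])
    if len(full) < 3:
        log.warning("trace produced only %d points; mask may be degenerate", len(full))
    poly = resample_uniform(full, params.resample_spacing)
    poly.provenance = {"n_raw_points": int(len(full)),
                       "params": {k: v for k, v in params.__dict__.items()}}
    return poly


def resample_uniform(points: np.ndarray, spacing: float) -> Polyline:
    """Resample a polyline at uniform arc-length spacing, preserving endpoints.

    The final segment may be shorter than ``spacing`` (the endpoint is kept
    exactly).  If ``spacing`` exceeds the total length, the two endpoints are
    returned with a warning.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        raise ValueError("need at least two points")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    keep = np.concatenate([[True], seg > 0])
    pts = pts[keep]
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if spacing > total:
        log.warning("resample spacing %g exceeds curve length %g: endpoints only",
                    spacing, total)
        return Polyline(pts[[0, -1]])
    targets = np.arange(0.0, total, spacing)
    if total - targets[-1] > 1e-12:
        targets = np.append(targets, total)
    out = np.column_stack([np.interp(targets, s, pts[:, k]) for k in range(3)])
    return Polyline(out)
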