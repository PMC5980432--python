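"""Synthetic fertilized-egg scenes with analytic ground truth.

No real confocal data accompany the method, so validation runs on simulated
eggs: an ellipsoidal egg volume containing one tube-like labeled flagellum
curve (possibly passing over itself), one or two pronuclear blobs and a
polar-body blob, rasterized onto an anisotropic voxel lattice with additive
noise.  Every scene carries a :class:`GroundTruth` with the generating
curve's exact sample points and its shape descriptors in closed form where
the family admits them (line, circle arc, helix) and by high-resolution
quadrature on exact derivatives otherwise (figure-8, random spline).

Curve families
--------------
line          straight segment; aspect ratio exactly 1.
circle_arc    planar arc of radius r; curvature exactly 1/r, zero torsion.
helix         circular helix, radius ``a`` and pitch parameter ``b`` (the
              z-rise is ``2 pi b`` per turn); curvature a/(a^2+b^2), torsion
              b/(a^2+b^2) — positive for a right-handed helix, negated by
              ``b < 0``.
figure8       two lobes crossing once; the crossing is offset out of plane
              by ``axial_offset`` so the true curve never intersects itself
              in 3D while its rasterized tube does — the case the tracer's
              voxel-consumption rule exists for.
random_spline smooth random curve inside a bounding ellipsoid, for property
              sweeps.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import interpolate
from scipy.spatial import cKDTree

from iseikit.geometry import CurveDescriptors, writhe as gauss_writhe
from iseikit.masking import BinaryMask
from iseikit.stackio import VoxelGrid, write_stack, index_to_mm

log = logging.getLogger(__name__)

__all__ = ["CurveSpec", "SceneSpec", "Blob", "GroundTruth", "SampledCurve",
           "make_curve", "rasterize_scene", "generate_experiment", "EffectModel"]

FAMILIES = ("line", "circle_arc", "helix", "figure8", "random_spline")


@dataclass
class CurveSpec:
    """One generating curve: a family, its parameters and a rigid placement."""

    family: str
    params: dict = field(default_factory=dict)
    rotation: np.ndarray | None = None      # 3x3, applied before translation
    translation: np.ndarray | None = None   # (x, y, z) mm
    seed: int = 0                           # used by random_spline only

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown curve family '{self.family}'; choose from {FAMILIES}")
        for key in ("radius", "pitch", "turns", "arc_angle", "lobe_radius", "length"):
            if key in self.params and key != "pitch" and self.params[key] <= 0:
                raise ValueError(f"{self.family}: parameter '{key}' must be positive")


@dataclass
class SampledCurve:
    points: np.ndarray            # (n, 3), uniform in arc length, mm
    descriptors: CurveDescriptors
    spec: CurveSpec


# ---------------------------------------------------------------------------
# family definitions: position and first three derivatives w.r.t. t


def _family(spec: CurveSpec):
    p = spec.params
    fam = spec.family
    if fam == "line":
        p0 = np.asarray(p.get("start", (0.0, 0.0, 0.0)), float)
        p1 = np.asarray(p["end"], float)
        d = p1 - p0
        if np.linalg.norm(d) == 0:
            raise ValueError("line: endpoints coincide")

        def ev(t, k):
            if k == 0:
                return p0 + np.outer(t, d)
            if k == 1:
                return np.tile(d, (len(t), 1))
            return np.zeros((len(t), 3))
        return ev, (0.0, 1.0)
    if fam == "circle_arc":
        r = p["radius"]
        theta = p.get("arc_angle", 2.0 * np.pi)
        if theta <= 0:
            raise ValueError("circle_arc: arc_angle must be positive")

        def ev(t, k):
            c, s = np.cos(t), np.sin(t)
            table = {0: (r * c, r * s), 1: (-r * s, r * c),
                     2: (-r * c, -r * s), 3: (r * s, -r * c)}
            x, y = table[k]
            return np.column_stack([x, y, np.zeros_like(t)])
        return ev, (0.0, theta)
    if fam == "helix":
        a, b = p["radius"], p["pitch"]
        turns = p.get("turns", 1.0)

        def ev(t, k):
            c, s = np.cos(t), np.sin(t)
            table = {0: (a * c, a * s, b * t), 1: (-a * s, a * c, np.full_like(t, b)),
                     2: (-a * c, -a * s, np.zeros_like(t)),
                     3: (a * s, -a * c, np.zeros_like(t))}
            return np.column_stack(table[k])
        return ev, (0.0, 2.0 * np.pi * turns)
    if fam == "figure8":
        A = p["lobe_radius"]
        h = p.get("axial_offset", 0.0)
        c = p.get("lobe_aspect", 2.0)
        t0, t1 = p.get("t_range", (-0.5 * np.pi, 1.5 * np.pi - 0.6))

        def ev(t, k):
            # x = A sin t, y = (c A / 2) sin 2t, z = h cos t
            # self-crossing at t = 0 vs t = pi, separated by 2h in z
            x = {0: A * np.sin(t), 1: A * np.cos(t),
                 2: -A * np.sin(t), 3: -A * np.cos(t)}[k]
            y = {0: 0.5 * c * A * np.sin(2 * t), 1: c * A * np.cos(2 * t),
                 2: -2 * c * A * np.sin(2 * t), 3: -4 * c * A * np.cos(2 * t)}[k]
            z = {0: h * np.cos(t), 1: -h * np.sin(t),
                 2: -h * np.cos(t), 3: h * np.sin(t)}[k]
            return np.column_stack([x, y, z])
        return ev, (t0, t1)
    if fam == "random_spline":
        n_ctrl = int(p.get("n_control", 8))
        semi = np.asarray(p.get("semi_axes", (0.12, 0.05, 0.05)), float)
        rng = np.random.default_rng(spec.seed)
        # random walk of control points, kept inside the bounding ellipsoid
        ctrl = np.cumsum(rng.normal(size=(n_ctrl, 3)), axis=0)
        ctrl -= ctrl.mean(axis=0)
        scale = np.abs(ctrl / semi).max()
        ctrl = ctrl / (scale * 1.2)
        tck, _ = interpolate.splprep(ctrl.T, s=0, k=min(5, n_ctrl - 1))

        def ev(t, k):
            return np.stack(interpolate.splev(t, tck, der=k), axis=-1)
        return ev, (0.0, 1.0)
    raise ValueError(f"unknown family {fam}")


def _placed(ev, spec: CurveSpec):
    R = np.eye(3) if spec.rotation is None else np.asarray(spec.rotation, float)
    T = np.zeros(3) if spec.translation is None else np.asarray(spec.translation, float)

    def ev2(t, k):
        v = ev(np.atleast_1d(np.asarray(t, float)), k)
        v = v @ R.T
        return v + T if k == 0 else v
    return ev2


def _closed_form(spec: CurveSpec, L: float):
    """Closed-form descriptors for the families that admit them, else None."""
    p = spec.params
    if spec.family == "line":
        return dict(net=L, avg_k=0.0, total_k=0.0, avg_t=float("nan"), wr=0.0)
    if spec.family == "circle_arc":
        r, theta = p["radius"], p.get("arc_angle", 2.0 * np.pi)
        net = 2.0 * r * np.sin(min(theta, 2 * np.pi) / 2.0)
        return dict(net=abs(net), avg_k=1.0 / r, total_k=theta, avg_t=0.0, wr=0.0)
    if spec.family == "helix":
        a, b = p["radius"], p["pitch"]
        theta = 2.0 * np.pi * p.get("turns", 1.0)
        net = float(np.sqrt(2 * a * a * (1 - np.cos(theta)) + (b * theta) ** 2))
        k = a / (a * a + b * b)
        return dict(net=net, avg_k=k, total_k=k * L, avg_t=b / (a * a + b * b), wr=None)
    return None


def make_curve(spec: CurveSpec, n_samples: int = 400,
               dense: int = 8192, compute_writhe: bool = True) -> SampledCurve:
    """Sample a curve family uniformly in arc length, with its descriptors.

    Descriptors use closed forms where available; anything else (and writhe
    for non-planar families) comes from quadrature on the exact derivatives
    at ``dense`` samples and is flagged ``numerical``.  The writhe Gauss sum
    is quadratic in sample count; large cohort simulations that do not use
    writhe can skip it with ``compute_writhe=False`` (reported as NaN).
    """
    if n_samples < 50:
        raise ValueError("n_samples must be at least 50")
    ev_raw, (t0, t1) = _family(spec)
    ev = _placed(ev_raw, spec)

    t = np.linspace(t0, t1, dense)
    r1 = ev(t, 1)
    speed = np.linalg.norm(r1, axis=1)
    s_cum = np.concatenate([[0.0], np.cumsum(0.5 * (speed[1:] + speed[:-1]) * np.diff(t))])
    L = float(s_cum[-1])
    t_of_s = np.interp(np.linspace(0.0, L, n_samples), s_cum, t)
    points = ev(t_of_s, 0)

    cf = _closed_form(spec, L)
    numerical = cf is None
    if cf is None:
        r2 = ev(t, 2)
        r3 = ev(t, 3)
        cross = np.cross(r1, r2)
        cross_sq = np.einsum("ij,ij->i", cross, cross)
        kappa = np.sqrt(cross_sq) / speed**3
        total_k = float(np.trapezoid(kappa * speed, t))
        defined = kappa >= 1e-6
        tau = np.zeros(dense)
        np.divide(np.einsum("ij,ij->i", cross, r3), cross_sq, out=tau, where=defined)
        wsp = np.where(defined, speed, 0.0)
        avg_t = float(np.trapezoid(tau * wsp, t) / np.trapezoid(wsp, t)) if wsp.any() else float("nan")
        ends = ev(np.array([t0, t1]), 0)
        cf = dict(net=float(np.linalg.norm(ends[1] - ends[0])),
                  avg_k=total_k / L, total_k=total_k, avg_t=avg_t, wr=None)
    if cf["wr"] is None:
        if compute_writhe:
            t_wr = np.interp(np.linspace(0.0, L, 1025), s_cum, t)
            cf["wr"] = gauss_writhe(ev(t_wr, 0))
        else:
            cf["wr"] = float("nan")
        numerical = True

    if cf["net"] <= 0:
        raise ValueError("degenerate curve: coincident endpoints (closed curve)")
    desc = CurveDescriptors(
        arc_length=L, net_length=cf["net"], aspect_ratio=L / cf["net"],
        average_curvature=cf["avg_k"], total_curvature=cf["total_k"],
        average_torsion=cf["avg_t"], writhe=cf["wr"],
        smoothing=0.0, numerical=numerical,
    )
    return SampledCurve(points=points, descriptors=desc, spec=spec)


# ---------------------------------------------------------------------------
# scene rasterization


@dataclass
class Blob:
    kind: str                       # male_pronucleus | female_pronucleus | polar_bodies | nucleus
    center: tuple[float, float, float]
    radius: float = 0.006


@dataclass
class SceneSpec:
    """Geometry, optics stand-in and noise model of one simulated egg."""

    egg_semi_axes: tuple[float, float, float] = (0.40, 0.15, 0.15)   # (x,y,z) mm
    spacing: tuple[float, float, float] = (0.002, 0.0005, 0.0005)    # (z,y,x) mm
    tube_radius: float = 0.002
    blobs: list[Blob] = field(default_factory=list)
    background: float = 100.0
    tube_peak: float = 1000.0
    blob_peak: float = 800.0
    noise_sigma: float = 100.0      # additive Gaussian, counts; 10% of tube peak
    poisson: bool = False
    seed: int = 0
    margin: float = 0.008           # bounding-box padding around structures

    def __post_init__(self):
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive on every axis")
        for b in self.blobs:
            rel = np.asarray(b.center) / np.asarray(self.egg_semi_axes)
            if (rel**2).sum() > 1.0:
                raise ValueError(f"blob '{b.kind}' center {b.center} outside the egg ellipsoid")


@dataclass
class GroundTruth:
    """Exact geometry behind one synthetic egg."""

    curve_points: np.ndarray
    descriptors: CurveDescriptors
    landmarks: dict[str, tuple[float, float, float]]
    scene: SceneSpec | None = None
    curve_spec: CurveSpec | None = None

    def to_json(self, path):
        payload = {
            "curve_points_mm": np.asarray(self.curve_points).tolist(),
            "descriptors": self.descriptors.as_dict(),
            "landmarks_mm": {k: list(v) for k, v in self.landmarks.items()},
        }
        Path(path).write_text(json.dumps(payload))


def rasterize_scene(scene: SceneSpec, curve_points: np.ndarray,
                    descriptors: CurveDescriptors | None = None):
    """Rasterize one egg scene onto an anisotropic voxel lattice.

    Intensity = background + Gaussian tube profile around the curve
    (sigma = tube radius / 2) + Gaussian blobs at landmark centers + noise.
    Returns ``(grid, masks, ground_truth)`` where ``masks`` are the
    noise-free binary masks (tube within one tube radius; blobs within one
    blob radius), and everything is deterministic given ``scene.seed``.

    Only the bounding box of the structures (plus a margin) is rasterized;
    the grid origin records its placement inside the egg.
    """
    pts = np.asarray(curve_points, float)
    if scene.tube_radius < max(scene.spacing):
        raise ValueError("tube radius must be at least the coarsest voxel spacing "
                         "for the tube to be resolvable")
    rel = pts / np.asarray(scene.egg_semi_axes)
    bad = np.argmax((rel**2).sum(axis=1))
    if (rel[bad] ** 2).sum() > 1.0:
        raise ValueError(f"curve exits the egg ellipsoid at point {pts[bad]} (mm)")

    centers = [pts] + [np.asarray(b.center, float)[None] for b in scene.blobs]
    radii = [scene.tube_radius] + [b.radius for b in scene.blobs]
    allpts = np.vstack(centers)
    pad = max(radii) + scene.margin
    lo = allpts.min(axis=0) - pad          # (x, y, z)
    hi = allpts.max(axis=0) + pad
    sp_xyz = np.asarray(scene.spacing[::-1])
    shape_xyz = np.ceil((hi - lo) / sp_xyz).astype(int)
    nz, ny, nx = int(shape_xyz[2]), int(shape_xyz[1]), int(shape_xyz[0])
    origin = tuple(lo)

    zz, yy, xx = np.meshgrid(np.arange(nz), np.arange(ny), np.arange(nx),
                             indexing="ij", sparse=False)
    idx = np.column_stack([zz.ravel(), yy.ravel(), xx.ravel()])
    vox = index_to_mm(idx, scene.spacing, origin)

    # distance to the curve via a dense sample of it
    step = 0.5 * min(scene.spacing)
    dense = _resample_dense(pts, step)
    d_curve = cKDTree(dense).query(vox, workers=-1)[0]
    sigma_t = scene.tube_radius / 2.0
    img = scene.background + scene.tube_peak * np.exp(-0.5 * (d_curve / sigma_t) ** 2)
    masks = {"flagellum": (d_curve <= scene.tube_radius).reshape(nz, ny, nx)}

    landmarks = {}
    for b in scene.blobs:
        d = np.linalg.norm(vox - np.asarray(b.center), axis=1)
        img += scene.blob_peak * np.exp(-0.5 * (d / (b.radius / 2.0)) ** 2)
        masks[b.kind] = (d <= b.radius).reshape(nz, ny, nx)
        landmarks[b.kind] = tuple(b.center)

    rng = np.random.default_rng(scene.seed)
    if scene.poisson:
        img = rng.poisson(np.maximum(img, 0)).astype(float)
    if scene.noise_sigma > 0:
        img = img + rng.normal(0.0, scene.noise_sigma, size=img.shape)
    img = np.clip(np.round(img), 0, 65535).astype(np.uint16).reshape(nz, ny, nx)

    grid = VoxelGrid(img, scene.spacing, origin)
    bin_masks = {k: BinaryMask(m, scene.spacing, origin, label=k) for k, m in masks.items()}
    gt = GroundTruth(curve_points=pts, descriptors=descriptors,
                     landmarks=landmarks, scene=scene)
    return grid, bin_masks, gt


def _resample_dense(pts, step):
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.arange(0.0, s[-1], step)
    return np.column_stack([np.interp(targets, s, pts[:, k]) for k in range(3)])


# ---------------------------------------------------------------------------
# cohort generation


@dataclass
class EffectModel:
    """How group membership shifts the curve-generating parameters.

    ``stage_effects`` / ``cross_effects`` map a stage or (female, male)
    cross to multiplicative factors on curve parameters; ``egg_cv`` is the
    between-egg coefficient of variation applied log-normally to each
    parameter independently.  A zero/empty model is the null: every egg is
    drawn from the same distribution.
    """

    base_curve: CurveSpec = field(default_factory=lambda: CurveSpec(
        "helix", {"radius": 0.01, "pitch": 0.003, "turns": 4.5}))
    stage_effects: dict = field(default_factory=dict)
    cross_effects: dict = field(default_factory=dict)
    egg_cv: float = 0.05

    def curve_for(self, female, male, stage, rng) -> CurveSpec:
        params = dict(self.base_curve.params)
        for key, fac in self.stage_effects.get(stage, {}).items():
            params[key] = params[key] * fac
        for key, fac in self.cross_effects.get((female, male), {}).items():
            params[key] = params[key] * fac
        if self.egg_cv > 0:
            for key in params:
                params[key] = params[key] * rng.lognormal(0.0, self.egg_cv)
        return replace(self.base_curve, params=params)


def generate_experiment(design, effect_model: EffectModel | None = None,
                        base_scene: SceneSpec | None = None,
                        out_dir=None, rasterize: bool = True,
                        n_samples: int = 200, dense: int = 8192,
                        compute_writhe: bool = True, seed: int = 0):
    """Simulate a whole cohort: one egg per design row replicate.

    Parameters
    ----------
    design : iterable of (female, male, stage, n_eggs)
        The cross-by-stage layout, female species listed first.
    effect_model : EffectModel
        Group-level parameter shifts plus between-egg variability.
    base_scene : SceneSpec
        Egg geometry, optics stand-in and noise shared by all eggs.
    out_dir : path, optional
        When given, writes one multi-page TIFF + ground-truth JSON per egg
        and an ``annotations.csv``; when ``rasterize`` is false only the
        analytic ground truths are produced (fast cohort-level simulation).

    Returns ``(annotations DataFrame, list of GroundTruth, list of scenes)``.
    """
    effect_model = effect_model or EffectModel()
    base_scene = base_scene or SceneSpec()
    rng = np.random.default_rng(seed)
    rows, truths, scene_bundles = [], [], []
    egg_no = 0
    for female, male, stage, n_eggs in design:
        if n_eggs < 1:
            raise ValueError(f"design row ({female},{male},{stage}) has n_eggs < 1")
        for _ in range(int(n_eggs)):
            egg_id = f"egg{egg_no:04d}"
            egg_no += 1
            spec = effect_model.curve_for(female, male, stage, rng)
            curve = make_curve(spec, n_samples=n_samples, dense=dense,
                               compute_writhe=compute_writhe)
            blobs = _stage_blobs(stage, curve.points, base_scene, rng)
            scene = replace(base_scene, blobs=blobs,
                            seed=int(rng.integers(0, 2**31 - 1)))
            path = ""
            if rasterize:
                grid, masks, gt = rasterize_scene(scene, curve.points, curve.descriptors)
                gt.curve_spec = spec
                if out_dir is not None:
                    out_dir = Path(out_dir)
                    path = str(out_dir / f"{egg_id}.tif")
                    write_stack(grid, path)
                    gt.to_json(out_dir / f"{egg_id}.truth.json")
                scene_bundles.append((grid, masks))
            else:
                gt = GroundTruth(curve.points, curve.descriptors,
                                 {b.kind: b.center for b in blobs}, scene, spec)
                scene_bundles.append(None)
            truths.append(gt)
            rows.append({"egg_id": egg_id, "female_species": female,
                         "male_species": male, "stage": stage, "path": path})
    annotations = pd.DataFrame(rows, columns=["egg_id", "female_species",
                                              "male_species", "stage", "path"])
    if out_dir is not None:
        annotations.to_csv(Path(out_dir) / "annotations.csv", index=False)
    return annotations, truths, scene_bundles


def _stage_blobs(stage, curve_pts, scene, rng):
    """Stage-appropriate nuclear landmarks near (but off) the flagellum."""
    lo, hi = curve_pts.min(axis=0), curve_pts.max(axis=0)
    span = np.maximum(hi - lo, 0.02)
    offset = 3.0 * scene.tube_radius

    def near(frac):
        base = lo + frac * span
        return tuple(base + rng.uniform(offset, 2 * offset, 3))
    r = 0.004
    if stage == "PN":
        return [Blob("male_pronucleus", near(np.array([0.6, 0.7, 0.6])), r),
                Blob("female_pronucleus", near(np.array([0.4, 0.3, 0.4])), r),
                Blob("polar_bodies", near(np.array([0.2, 0.8, 0.5])), r)]
    return [Blob("nucleus", near(np.array([0.5, 0.5, 0.5])), r)]
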