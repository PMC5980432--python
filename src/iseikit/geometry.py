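"""Shape descriptors of a 3D space curve.

The flagellum centerline arrives as an ordered polyline of 3D points (mm).
Curvature needs a second derivative and torsion/writhe a third, so raw
point-to-point differences amplify digitization jitter badly; all
differential quantities are therefore evaluated on a smoothing-spline
representation of the polyline, with the smoothing level exposed.

Descriptors
-----------
arc length L (mm)
    total length along the curve between its two ends.
net length (mm)
    straight-line 3D distance between the two ends.
aspect ratio (dimensionless)
    L / net length; 1 for a straight curve, larger for wavy or folded ones.
curvature kappa (1/mm)
    reciprocal of the local best-fit circle radius, kappa = |r' x r''|/|r'|^3;
    reported as a profile, as total curvature (integral of kappa ds, radians)
    and as average curvature (total / L).
torsion tau (1/mm)
    rate of rotation of the osculating plane,
    tau = ((r' x r'') . r''') / |r' x r''|^2; signed, positive for a
    right-handed helix.  Undefined where kappa vanishes; such segments are
    masked out of the average.
writhe Wr (dimensionless)
    open-curve Gauss double integral
    Wr = (1/4 pi) iint (t(s) x t(s')) . (r(s) - r(s')) / |r(s)-r(s')|^3 ds ds',
    evaluated by pairwise summation over polyline segments with the singular
    diagonal and adjacent pairs excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import interpolate

__all__ = [
    "SmoothCurve",
    "CurveDescriptors",
    "smooth_curve",
    "arc_length",
    "net_length",
    "aspect_ratio",
    "curvature",
    "torsion",
    "writhe",
    "describe_points",
]

#: curvature (1/mm) below which torsion is treated as undefined
KAPPA_FLOOR = 1e-6


class SmoothCurve:
    """A twice/thrice-differentiable parametric curve r(u), u in [0, 1].

    Thin wrapper over a scipy parametric B-spline; ``__call__`` evaluates
    the position or a derivative with respect to the internal parameter u
    (approximately proportional to arc length for chord-length fitted data).
    """

    def __init__(self, spline: interpolate.BSpline, u: np.ndarray):
        self.spline = spline
        self.u = np.asarray(u, dtype=float)
        self._derivs: dict[int, interpolate.BSpline] = {0: spline}

    def __call__(self, u, der: int = 0) -> np.ndarray:
        if der not in self._derivs:
            self._derivs[der] = self.spline.derivative(der)
        return np.atleast_2d(self._derivs[der](np.atleast_1d(u)))

    @property
    def degree(self) -> int:
        return self.spline.k

    def sample(self, n: int) -> np.ndarray:
        """n points uniform in the spline parameter."""
        return self(np.linspace(0.0, 1.0, n))

    def sample_arclength(self, n: int) -> np.ndarray:
        """n points uniform in arc length (numerical reparameterization)."""
        dense_u = np.linspace(0.0, 1.0, max(8 * n, 2048))
        pts = self(dense_u)
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        targets = np.linspace(0.0, s[-1], n)
        u_of_s = np.interp(targets, s, dense_u)
        return self(u_of_s)


def smooth_curve(points: np.ndarray, smoothing: float | None = None,
                 degree: int = 5) -> SmoothCurve:
    """Fit a smoothing spline through an ordered 3D polyline.

    Parameters
    ----------
    points : (n, 3) array, n >= 4
        Ordered samples along the curve, in mm.
    smoothing : float, optional
        Residual-sum-of-squares bound for the spline fit (mm^2 units,
        summed over points and coordinates).  0 interpolates the points
        exactly.  ``None`` (default) estimates the jitter level from
        second differences of the input and sets the bound to
        ``n * sigma_hat^2`` — the standard expected-residual scaling for
        a smoothing spline under i.i.d. noise of that size.
    degree : int
        Spline degree; quintic by default so the third derivative needed
        by torsion is itself continuous.  Reduced automatically when the
        polyline is too short.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must be an (n, 3) array")
    n = len(pts)
    if n < 4:
        raise ValueError(f"need at least 4 points to fit a curve, got {n}")

    k = min(degree, n - 1)
    if smoothing is None:
        smoothing = n * _jitter_variance(pts)
    # chord-length parameterization, normalized to [0, 1]
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    if np.any(seg == 0):
        keep = np.concatenate([[True], seg > 0])
        pts = pts[keep]
        n = len(pts)
        if n < 4:
            raise ValueError("fewer than 4 distinct points")
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        k = min(k, n - 1)
    u = np.concatenate([[0.0], np.cumsum(seg)])
    u /= u[-1]
    # treat a numerically-zero residual budget as exact interpolation
    floor = 1e-20 * n * float(np.sum(np.var(pts, axis=0)))
    if smoothing <= floor:
        # exact interpolation: the banded collocation solve reproduces
        # degenerate inputs (e.g. collinear points) to machine precision,
        # where the FITPACK smoothing path leaves ~1e-8 wiggle
        spline = interpolate.make_interp_spline(u, pts, k=k)
    else:
        tck, _ = interpolate.splprep(pts.T, u=u, s=smoothing, k=k)
        spline = interpolate.BSpline(tck[0], np.asarray(tck[1]).T, tck[2])
    return SmoothCurve(spline, u)


def _jitter_variance(pts: np.ndarray) -> float:
    """Estimate per-point noise variance (summed over x,y,z) from second
    differences; Var(d2) = 6 sigma^2 for i.i.d. noise on a smooth trend."""
    if len(pts) < 5:
        return 0.0
    d2 = np.diff(pts, n=2, axis=0)
    return float(np.sum(np.var(d2, axis=0)) / 6.0)


# ---------------------------------------------------------------------------
# scalar descriptors


def _dense_eval(curve: SmoothCurve, n: int):
    u = np.linspace(0.0, 1.0, n)
    r1 = curve(u, der=1)
    speed = np.linalg.norm(r1, axis=1)
    return u, r1, speed


def arc_length(curve: SmoothCurve, n: int = 4096) -> float:
    """Total length (mm) along the curve between its two ends."""
    u, _, speed = _dense_eval(curve, n)
    return float(np.trapezoid(speed, u))


def net_length(curve: SmoothCurve) -> float:
    """Straight-line 3D distance (mm) between the two curve ends."""
    ends = curve(np.array([0.0, 1.0]))
    return float(np.linalg.norm(ends[1] - ends[0]))


def aspect_ratio(curve: SmoothCurve) -> float:
    """Arc length divided by net length; 1 for a straight curve."""
    nl = net_length(curve)
    L = arc_length(curve)
    if nl <= 1e-9 * L:
        raise ValueError("net length is zero (closed curve): aspect ratio undefined")
    return L / nl


def curvature(curve: SmoothCurve, n: int = 4096):
    """Curvature profile kappa(u) (1/mm) with total (radians) and average (1/mm).

    Returns ``(u, kappa, total, average)``.
    """
    u = np.linspace(0.0, 1.0, n)
    r1 = curve(u, der=1)
    r2 = curve(u, der=2)
    speed = np.linalg.norm(r1, axis=1)
    cross = np.cross(r1, r2)
    kappa = np.linalg.norm(cross, axis=1) / np.maximum(speed, 1e-300) ** 3
    total = float(np.trapezoid(kappa * speed, u))
    L = float(np.trapezoid(speed, u))
    return u, kappa, total, total / L


def torsion(curve: SmoothCurve, n: int = 4096, kappa_floor: float = KAPPA_FLOOR):
    """Torsion profile tau(u) (1/mm) and its arc-length-weighted average.

    tau is undefined where curvature falls below ``kappa_floor``; those
    samples are masked and excluded from the average rather than letting a
    0/0 evaluation poison it.  Returns ``(u, tau, defined_mask, average)``.
    """
    u = np.linspace(0.0, 1.0, n)
    r1 = curve(u, der=1)
    r2 = curve(u, der=2)
    r3 = curve(u, der=3)
    speed = np.linalg.norm(r1, axis=1)
    cross = np.cross(r1, r2)
    cross_sq = np.einsum("ij,ij->i", cross, cross)
    kappa = np.sqrt(cross_sq) / np.maximum(speed, 1e-300) ** 3
    defined = kappa >= kappa_floor
    tau = np.zeros(n)
    np.divide(np.einsum("ij,ij->i", cross, r3), cross_sq, out=tau, where=defined)
    tau[~defined] = np.nan
    w = speed.copy()
    w[~defined] = 0.0
    denom = np.trapezoid(w, u)
    if denom <= 0:
        avg = float("nan")
    else:
        tw = np.where(defined, tau, 0.0) * w
        avg = float(np.trapezoid(tw, u) / denom)
    return u, tau, defined, avg


def writhe(points: np.ndarray) -> float:
    """Open-curve writhe by the pairwise Gauss sum over polyline segments.

    Each segment contributes its midpoint position, unit tangent and length;
    the diagonal and adjacent (singular) segment pairs are skipped.  The sum
    is exactly antisymmetric under mirror reflection and vanishes for planar
    curves.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must be an (n, 3) array")
    if len(pts) < 10:
        raise ValueError("need at least 10 samples for a writhe estimate")
    d = np.diff(pts, axis=0)
    ds = np.linalg.norm(d, axis=1)
    if np.any(ds == 0):
        raise ValueError("coincident consecutive sample points")
    t = d / ds[:, None]
    mid = 0.5 * (pts[:-1] + pts[1:])
    m = len(mid)

    # pairwise terms; keep strictly non-adjacent pairs |i-j| > 1
    rij = mid[:, None, :] - mid[None, :, :]
    dist = np.linalg.norm(rij, axis=2)
    cross = np.cross(t[:, None, :], t[None, :, :])
    num = np.einsum("ijk,ijk->ij", cross, rij)
    idx = np.arange(m)
    ok = np.abs(idx[:, None] - idx[None, :]) > 1
    integrand = np.zeros((m, m))
    np.divide(num, dist**3, out=integrand, where=ok & (dist > 0))
    integrand *= ds[:, None] * ds[None, :]
    return float(integrand[ok].sum() / (4.0 * np.pi))


# ---------------------------------------------------------------------------
# bundled report


@dataclass
class CurveDescriptors:
    """The scalar shape descriptors of one flagellum centerline."""

    arc_length: float           # mm
    net_length: float           # mm
    aspect_ratio: float         # dimensionless, >= 1
    average_curvature: float    # 1/mm
    total_curvature: float      # radians (integral of kappa ds)
    average_torsion: float      # 1/mm, signed; NaN if undefined everywhere
    writhe: float               # dimensionless
    smoothing: float = 0.0      # spline residual bound actually used
    numerical: bool = True      # True when obtained by quadrature, not closed form
    extras: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "arc_length": self.arc_length,
            "net_length": self.net_length,
            "aspect_ratio": self.aspect_ratio,
            "average_curvature": self.average_curvature,
            "total_curvature": self.total_curvature,
            "average_torsion": self.average_torsion,
            "writhe": self.writhe,
        }


def describe_points(points: np.ndarray, smoothing: float | None = None,
                    n_eval: int = 2048, writhe_segments: int = 256) -> CurveDescriptors:
    """Fit a smoothing spline to an ordered polyline and report all descriptors.

    ``writhe_segments`` controls the arc-length-uniform resampling used for
    the pairwise Gauss sum (cost is quadratic in it).
    """
    curve = smooth_curve(points, smoothing=smoothing)
    L = arc_length(curve, n=n_eval)
    nl = net_length(curve)
    _, _, total, avg_k = curvature(curve, n=n_eval)
    _, _, _, avg_t = torsion(curve, n=n_eval)
    wr = writhe(curve.sample_arclength(writhe_segments + 1))
    if nl <= 1e-9 * L:
        raise ValueError("net length is zero (closed curve): aspect ratio undefined")
    used = smoothing if smoothing is not None else len(points) * _jitter_variance(np.asarray(points, float))
    return CurveDescriptors(
        arc_length=L,
        net_length=nl,
        aspect_ratio=L / nl,
        average_curvature=avg_k,
        total_curvature=total,
        average_torsion=avg_t,
        writhe=wr,
        smoothing=float(used),
        numerical=True,
    )
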