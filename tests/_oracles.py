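"""Independent oracles used by the test suite.

Deliberately naive implementations (double loops, finite differences,
direct numerical integration) that share no code with the package paths
they check.
"""

from __future__ import annotations

import numpy as np
from scipy import integrate, special, stats


def frenet_finite_difference(points: np.ndarray, ds: float):
    """Mean curvature and torsion of a densely, uniformly sampled curve by
    central finite differences of the raw points."""
    r1 = np.gradient(points, ds, axis=0)
    r2 = np.gradient(r1, ds, axis=0)
    r3 = np.gradient(r2, ds, axis=0)
    sl = slice(3, -3)   # drop boundary-contaminated samples
    r1, r2, r3 = r1[sl], r2[sl], r3[sl]
    cross = np.cross(r1, r2)
    speed = np.linalg.norm(r1, axis=1)
    kappa = np.linalg.norm(cross, axis=1) / speed**3
    tau = np.einsum("ij,ij->i", cross, r3) / np.einsum("ij,ij->i", cross, cross)
    return kappa.mean(), tau.mean()


def writhe_double_loop(points: np.ndarray) -> float:
    """Gauss-sum writhe by an explicit O(n^2) python loop over segments."""
    pts = np.asarray(points, float)
    d = np.diff(pts, axis=0)
    ds = np.linalg.norm(d, axis=1)
    t = d / ds[:, None]
    mid = 0.5 * (pts[:-1] + pts[1:])
    total = 0.0
    m = len(mid)
    for i in range(m):
        for j in range(m):
            if abs(i - j) <= 1:
                continue
            rij = mid[i] - mid[j]
            dist = np.sqrt(rij @ rij)
            total += np.cross(t[i], t[j]) @ rij / dist**3 * ds[i] * ds[j]
    return total / (4.0 * np.pi)


def density_double_loop(coords: np.ndarray, radius: float) -> np.ndarray:
    """All-pairs density score: sum of 1/(1+d) over neighbors within radius."""
    n = len(coords)
    out = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = np.linalg.norm(coords[i] - coords[j])
            if d <= radius:
                out[i] += 1.0 / (1.0 + d)
    return out


def flood_fill_26(in_range: np.ndarray, seed) -> np.ndarray:
    """Brute-force 26-connected component of `seed` by BFS."""
    from collections import deque
    shape = in_range.shape
    seen = np.zeros(shape, bool)
    if not in_range[seed]:
        return seen
    q = deque([tuple(seed)])
    seen[tuple(seed)] = True
    while q:
        z, y, x = q.popleft()
        for dz in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    if dz == dy == dx == 0:
                        continue
                    p = (z + dz, y + dy, x + dx)
                    if all(0 <= p[i] < shape[i] for i in range(3)) \
                            and in_range[p] and not seen[p]:
                        seen[p] = True
                        q.append(p)
    return seen


def sequential_anova_projection(y: np.ndarray, design_blocks):
    """Sequential (Type I) ANOVA by orthogonal projections.

    ``design_blocks`` is an ordered list of design matrices, each extending
    the previous model (the first is the intercept).  Returns a list of
    (SS, df) per added block plus the residual (SS, df).
    """
    y = np.asarray(y, float)
    n = len(y)

    def proj_ss(X):
        U, s, _ = np.linalg.svd(X, full_matrices=False)
        rank = int(np.sum(s > 1e-10 * s.max()))
        U = U[:, :rank]
        fitted = U @ (U.T @ y)
        return float(fitted @ fitted), rank

    out = []
    prev_ss, prev_rank = proj_ss(design_blocks[0])
    for X in design_blocks[1:]:
        ss, rank = proj_ss(X)
        out.append((ss - prev_ss, rank - prev_rank))
        prev_ss, prev_rank = ss, rank
    resid_ss = float(y @ y) - prev_ss
    out.append((resid_ss, n - prev_rank))
    return out


def oneway_blocks(labels):
    """Design blocks (intercept; intercept+group dummies) for one-way ANOVA."""
    labels = np.asarray(labels)
    n = len(labels)
    levels = list(dict.fromkeys(labels))
    X0 = np.ones((n, 1))
    dummies = np.column_stack([(labels == l).astype(float) for l in levels[1:]])
    return [X0, np.column_stack([X0, dummies])]


def twoway_blocks(female, male):
    """Design blocks for sequential female -> male -> interaction."""
    female, male = np.asarray(female), np.asarray(male)
    n = len(female)
    X0 = np.ones((n, 1))

    def dummies(lab):
        levels = list(dict.fromkeys(lab))
        return np.column_stack([(lab == l).astype(float) for l in levels[1:]])
    F = dummies(female)
    M = dummies(male)
    FM = np.column_stack([F[:, i] * M[:, j]
                          for i in range(F.shape[1]) for j in range(M.shape[1])])
    X1 = np.column_stack([X0, F])
    X2 = np.column_stack([X1, M])
    X3 = np.column_stack([X2, FM])
    return [X0, X1, X2, X3]


def anova_f_p(blocks_out):
    """Turn (SS, df) sequence into per-effect (F, p) against the residual."""
    *effects, (ss_res, df_res) = blocks_out
    ms_res = ss_res / df_res
    out = []
    for ss, df in effects:
        F = (ss / df) / ms_res
        p = stats.f.sf(F, df, df_res)
        out.append((F, p))
    return out


def studentized_range_sf(q: float, k: int, df: int) -> float:
    """P(Q > q) for the studentized range by direct numerical integration.

    Integrates the classical double integral: the range of k standard
    normals scaled by an independent chi-based standard deviation with
    ``df`` degrees of freedom.
    """
    def inner(s):
        # P(range of k std normals <= q*s)
        def f(z):
            return stats.norm.pdf(z) * (stats.norm.cdf(z) - stats.norm.cdf(z - q * s)) ** (k - 1)
        val, _ = integrate.quad(f, -np.inf, np.inf, epsabs=1e-12, epsrel=1e-10)
        return k * val

    ln_c = (df / 2.0) * np.log(df) - special.gammaln(df / 2.0) - (df / 2.0 - 1.0) * np.log(2.0)

    def outer(s):
        return np.exp(ln_c + (df - 1) * np.log(s) - df * s * s / 2.0) * inner(s)

    cdf, _ = integrate.quad(outer, 0, np.inf, epsabs=1e-12, epsrel=1e-10, limit=200)
    return 1.0 - cdf
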