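"""Geometric niche overlap in a three-component climate space.

Each range's occurrence cloud in the first three principal components is
summarized by two solids: the minimum-volume enclosing ellipsoid (MVE,
via Khachiyan's iterative algorithm) and the convex polyhedron (CP, the
exact convex hull).  Pairwise overlap volumes are estimated by Monte
Carlo hit counting and converted to Jaccard similarity coefficients
``J = V_inter / (V_a + V_b - V_inter)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull


@dataclass
class Ellipsoid3:
    """Solid ellipsoid {x : (x - c)^T S (x - c) <= 1} with S symmetric
    positive definite."""

    center: np.ndarray
    shape: np.ndarray  # 3x3 SPD

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.shape = np.asarray(self.shape, dtype=float)
        if self.center.shape != (3,) or self.shape.shape != (3, 3):
            raise ValueError("Ellipsoid3 is three-dimensional")
        if not np.allclose(self.shape, self.shape.T):
            raise ValueError("shape matrix must be symmetric")
        if np.linalg.eigvalsh(self.shape).min() <= 0:
            raise ValueError("shape matrix must be positive definite")

    @property
    def volume(self) -> float:
        return float(4.0 / 3.0 * np.pi / np.sqrt(np.linalg.det(self.shape)))

    def contains(self, pts: np.ndarray, tol: float = 0.0) -> np.ndarray:
        d = np.atleast_2d(pts) - self.center
        return np.einsum("ij,jk,ik->i", d, self.shape, d) <= 1.0 + tol

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        # half-extent along axis i is sqrt((S^-1)_ii)
        half = np.sqrt(np.diag(np.linalg.inv(self.shape)))
        return self.center - half, self.center + half

    def to_text(self) -> str:
        rows = "\n".join(" ".join(f"{v!r}" for v in row) for row in self.shape)
        return f"center {' '.join(f'{v!r}' for v in self.center)}\nshape\n{rows}\n"


@dataclass
class Polyhedron3:
    """Convex hull of a 3-D point set."""

    vertices: np.ndarray
    hull: ConvexHull

    @property
    def volume(self) -> float:
        return float(self.hull.volume)

    def contains(self, pts: np.ndarray, tol: float = 1e-10) -> np.ndarray:
        pts = np.atleast_2d(pts)
        # hull facet equations: A x + b <= 0 inside
        A = self.hull.equations[:, :3]
        b = self.hull.equations[:, 3]
        return (pts @ A.T + b <= tol).all(axis=1)

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        return self.vertices.min(axis=0), self.vertices.max(axis=0)

    def to_text(self) -> str:
        return "\n".join(" ".join(f"{v!r}" for v in row) for row in self.vertices)


def _affinely_independent(points: np.ndarray) -> bool:
    d = points - points[0]
    return np.linalg.matrix_rank(d) >= points.shape[1]


def min_volume_ellipsoid(points: np.ndarray, tol: float = 1e-6,
                         max_iter: int = 10000,
                         regularize: bool = True) -> Ellipsoid3:
    """Minimum-volume enclosing ellipsoid by Khachiyan's algorithm.

    Iterates barycentric weights until the relative optimality gap drops
    below ``tol``; the returned ellipsoid encloses every input point and
    its volume is within (1 + tol) of the optimum.  Degenerate (coplanar)
    inputs are regularized by a tiny isotropic jitter when ``regularize``
    is on, otherwise raise.
    """
    P = np.asarray(points, dtype=float)
    if P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("points must be (n, 3)")
    if P.shape[0] < 4 or not _affinely_independent(P):
        if not regularize:
            raise ValueError("need >= 4 affinely independent points")
        warnings.warn("degenerate point set; applying isotropic jitter")
        rng = np.random.default_rng(0)
        scale = max(np.ptp(P, axis=0).max(), 1.0)
        P = np.vstack([P + 1e-6 * scale * rng.standard_normal(P.shape)
                       for _ in range(2)])
    n, d = P.shape
    Q = np.column_stack([P, np.ones(n)]).T  # (d+1, n)
    u = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        X = Q @ np.diag(u) @ Q.T
        M = np.einsum("ij,jk,ki->i", Q.T, np.linalg.inv(X), Q)
        j = np.argmax(M)
        maximum = M[j]
        step = (maximum - d - 1.0) / ((d + 1.0) * (maximum - 1.0))
        if maximum <= (1 + tol) * (d + 1):
            break
        u = (1 - step) * u
        u[j] += step
    center = P.T @ u
    cov = P.T @ np.diag(u) @ P - np.outer(center, center)
    S = np.linalg.inv(cov) / d
    # guarantee enclosure despite finite iteration: inflate to the
    # farthest point
    diff = P - center
    r2 = np.einsum("ij,jk,ik->i", diff, S, diff).max()
    if r2 > 1:
        S = S / r2
    return Ellipsoid3(center=center, shape=S)


def convex_hull(points: np.ndarray) -> Polyhedron3:
    """Exact 3-D convex hull (volume by the underlying triangulation)."""
    P = np.asarray(points, dtype=float)
    if P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("points must be (n, 3)")
    if P.shape[0] < 4 or not _affinely_independent(P):
        raise ValueError("need >= 4 affinely independent points")
    hull = ConvexHull(P)
    return Polyhedron3(vertices=P[hull.vertices], hull=hull)


def intersection_volume(a, b, n_mc: int = 100_000, seed: int = 0
                        ) -> tuple[float, float]:
    """Monte-Carlo intersection volume of two solids.

    Uniform proposals are drawn in the axis-aligned bounding box of the
    smaller solid; the estimate is ``box_volume * hit_rate`` with a
    binomial standard error.  Returns (volume, standard_error).
    """
    if n_mc < 1000:
        raise ValueError("n_mc must be >= 1000")
    if a.volume <= 0 or b.volume <= 0:
        raise ValueError("zero-volume shape")
    small = a if a.volume <= b.volume else b
    lo, hi = small.bounding_box()
    box_vol = float(np.prod(hi - lo))
    rng = np.random.default_rng(seed)
    pts = lo + rng.random((n_mc, 3)) * (hi - lo)
    hits = a.contains(pts) & b.contains(pts)
    p = hits.mean()
    se = box_vol * np.sqrt(max(p * (1 - p), 1e-300) / n_mc)
    return box_vol * p, float(se)


def jaccard(vol_a: float, vol_b: float, vol_inter: float,
            rel_tol: float = 0.01) -> float:
    """Jaccard similarity J = V_inter / (V_a + V_b - V_inter).

    ``vol_inter`` may exceed the smaller part volume by up to ``rel_tol``
    (relative) to absorb Monte-Carlo estimation noise, in which case it
    is clamped; a larger excess is treated as inconsistent input.
    """
    if vol_a <= 0 or vol_b <= 0:
        raise ValueError("part volumes must be positive")
    vmin = min(vol_a, vol_b)
    if vol_inter < -rel_tol * vmin or vol_inter > vmin * (1 + rel_tol):
        raise ValueError("intersection volume inconsistent with part volumes")
    vol_inter = min(max(vol_inter, 0.0), min(vol_a, vol_b))
    return float(vol_inter / (vol_a + vol_b - vol_inter))


def pairwise_jaccard(scores3: dict[str, np.ndarray], n_mc: int = 100_000,
                     seed: int = 0, mve_tol: float = 1e-6):
    """MVE and CP Jaccard matrices over all range pairs.

    ``scores3`` maps range label to (n, 3) coordinates in the first three
    principal components.  Returns two pandas DataFrames (MVE, CP) with
    NaN on the diagonal's lower triangle mirrored.
    """
    import pandas as pd

    labels = list(scores3)
    mves = {k: min_volume_ellipsoid(v, tol=mve_tol) for k, v in scores3.items()}
    cps = {k: convex_hull(v) for k, v in scores3.items()}
    out = {}
    for name, shapes in (("mve", mves), ("cp", cps)):
        M = np.full((len(labels), len(labels)), np.nan)
        for i, ki in enumerate(labels):
            M[i, i] = 1.0
            for j in range(i + 1, len(labels)):
                kj = labels[j]
                vol, _se = intersection_volume(
                    shapes[ki], shapes[kj], n_mc=n_mc,
                    seed=seed + 7919 * i + j)
                # Monte-Carlo noise can push the estimate past the
                # smaller part volume; clamp before forming J
                vol = min(vol, shapes[ki].volume, shapes[kj].volume)
                M[i, j] = M[j, i] = jaccard(shapes[ki].volume,
                                            shapes[kj].volume, vol)
        out[name] = pd.DataFrame(M, index=labels, columns=labels)
    return out["mve"], out["cp"]


__all__ = [
    "Ellipsoid3", "Polyhedron3", "min_volume_ellipsoid", "convex_hull",
    "intersection_volume", "jaccard", "pairwise_jaccard",
]
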