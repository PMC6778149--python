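"""Environmental-space (E-space) construction.

Builds the background-calibrated climate space in which niches are
compared: per-range backgrounds from buffered minimum convex polygons, a
PCA calibrated on the pooled background climates, a regular R x R grid
over the first two components, and kernel-smoothed occurrence and
availability densities per range.  Also provides the occurrence-only
"standard" PCA and UPGMA clustering of range mean positions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from shapely import contains_xy
from shapely.geometry import MultiPoint, box

from .grids import ClimateStack
from .prep import EnvTable, OccurrenceSet

#: Gaussian-kernel truncation radius in bandwidths.  Must exceed the
#: ~6 sigma radius at which the kernel falls to the 1e-8 occupancy
#: floor, so the 100% occurrence outline is defined by the floor and
#: not by an arbitrary hard cutoff.
KDE_TRUNCATE = 8.0


@dataclass
class BackgroundRegion:
    """Climatic background available to one range: the raster cells whose
    centres fall inside the buffered minimum convex polygon of the
    range's occurrences."""

    range_label: str
    polygon: object  # shapely geometry
    cells: np.ndarray        # (n_cells, n_variables) climate vectors
    variables: list[str]
    cell_rc: np.ndarray      # (n_cells, 2) row/col indices into the stack
    buffer_deg: float = 0.3


def build_background(occ: OccurrenceSet, stack: ClimateStack,
                     buffer_deg: float = 0.3) -> BackgroundRegion:
    """Minimum convex polygon of a range's occurrences, dilated by
    ``buffer_deg`` degrees; membership by cell centre.

    Fewer than three non-collinear points cannot define a polygon; the
    buffered bounding box is used instead (with a warning).
    """
    pts = MultiPoint(list(zip(occ.lon, occ.lat)))
    hull = pts.convex_hull
    if hull.geom_type != "Polygon":
        warnings.warn(
            f"range {occ.range_label!r} has <3 non-collinear points; "
            "falling back to a buffered bounding box"
        )
        x0, y0, x1, y1 = pts.bounds
        hull = box(x0, y0, x1, y1)
    poly = hull.buffer(buffer_deg) if buffer_deg > 0 else hull
    lon, lat = stack.cell_centers()
    inside = contains_xy(poly, lon.ravel(), lat.ravel()).reshape(stack.shape)
    inside &= stack.land_mask()
    if not inside.any():
        raise ValueError(f"background of range {occ.range_label!r} contains no cells")
    rows, cols = np.nonzero(inside)
    return BackgroundRegion(
        range_label=occ.range_label,
        polygon=poly,
        cells=stack.data[:, rows, cols].T,
        variables=list(stack.variables),
        cell_rc=np.stack([rows, cols], axis=1),
        buffer_deg=buffer_deg,
    )


@dataclass
class EnvSpace:
    """Background-calibrated PCA plus the gridded two-component climate
    space shared by all ranges."""

    variables: list[str]
    center: np.ndarray
    scale: np.ndarray
    loadings: np.ndarray            # (n_variables, n_components), orthonormal
    explained_variance: np.ndarray  # fraction per component
    background_scores: dict = field(default_factory=dict)  # label -> (n, 2)
    grid_resolution: int = 500
    pad_fraction: float = 0.05
    bounds: tuple = ()              # (xmin, xmax, ymin, ymax) after padding

    def transform(self, values: np.ndarray, n_components: int = 2) -> np.ndarray:
        """Project climate vectors with the background centring/scaling."""
        Z = (np.asarray(values, float) - self.center) / self.scale
        return Z @ self.loadings[:, :n_components]


def _signed(loadings: np.ndarray) -> np.ndarray:
    """Fix component signs so the largest-magnitude loading is positive."""
    out = loadings.copy()
    for k in range(out.shape[1]):
        j = np.argmax(np.abs(out[:, k]))
        if out[j, k] < 0:
            out[:, k] = -out[:, k]
    return out


def pca_env(backgrounds: list[BackgroundRegion], grid_resolution: int = 500,
            pad_fraction: float = 0.05) -> EnvSpace:
    """PCA calibrated on the pooled background climates of all ranges.

    Climate vectors are standardized (correlation-matrix PCA: predictors
    have heterogeneous units), each region weighted by its cell count.
    The grid over the first two components spans the pooled background
    scores padded by ``pad_fraction`` per side.
    """
    if not backgrounds:
        raise ValueError("at least one background region required")
    variables = backgrounds[0].variables
    pooled = np.vstack([b.cells for b in backgrounds])
    if pooled.shape[0] < pooled.shape[1]:
        raise ValueError("pooled background smaller than predictor count")
    center = pooled.mean(axis=0)
    scale = pooled.std(axis=0, ddof=1)
    if (scale == 0).any():
        bad = [v for v, s in zip(variables, scale) if s == 0]
        raise ValueError(f"zero-variance predictor(s) across background: {bad}")
    Z = (pooled - center) / scale
    cov = np.cov(Z, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], _signed(evecs[:, order])
    space = EnvSpace(
        variables=list(variables),
        center=center,
        scale=scale,
        loadings=evecs,
        explained_variance=evals / evals.sum(),
        grid_resolution=grid_resolution,
        pad_fraction=pad_fraction,
    )
    scores = {b.range_label: space.transform(b.cells) for b in backgrounds}
    allsc = np.vstack(list(scores.values()))
    mins, maxs = allsc.min(axis=0), allsc.max(axis=0)
    pad = pad_fraction * (maxs - mins)
    space.bounds = (mins[0] - pad[0], maxs[0] + pad[0],
                    mins[1] - pad[1], maxs[1] + pad[1])
    space.background_scores = scores
    return space


@dataclass
class NicheDensity:
    """Kernel-smoothed occurrence and availability densities of one range
    on the shared E-space grid.

    ``z_occ_raw`` is the smoothed occurrence density, ``z_avail`` the
    smoothed background (availability) density, and ``z_cor`` the
    occupancy corrected by availability (occurrence density divided by
    availability where available, renormalized).  All grids sum to 1.
    """

    range_label: str
    z_avail: np.ndarray
    z_occ_raw: np.ndarray
    z_cor: np.ndarray
    bandwidth: tuple
    occupancy_floor: float = 1e-8

    @property
    def occupied_mask_100(self) -> np.ndarray:
        """Cells counted as occupied at the 100% outline: positive
        smoothed occurrence density above a small floor that trims
        kernel-tail leakage."""
        return self.z_occ_raw > self.occupancy_floor * self.z_occ_raw.max()

    def occupancy(self, policy: str = "corrected") -> np.ndarray:
        """Normalized occupancy grid used for overlap and dynamics."""
        if policy == "corrected":
            return self.z_cor
        if policy == "raw":
            return self.z_occ_raw
        raise ValueError("policy must be 'corrected' or 'raw'")

    def quantile_outline(self, q: float) -> np.ndarray:
        """Mask of the cells holding the top ``q`` fraction of occurrence
        density (q = 0.2 gives the core outline, q = 1.0 everything with
        positive density)."""
        if not 0 < q <= 1:
            raise ValueError("q must lie in (0, 1]")
        z = self.z_occ_raw
        flat = np.sort(z[z > 0])[::-1]
        csum = np.cumsum(flat)
        k = np.searchsorted(csum, q * csum[-1])
        thresh = flat[min(k, len(flat) - 1)]
        return z >= thresh


def _grid_density(scores: np.ndarray, space: EnvSpace,
                  bandwidth: tuple | None) -> tuple[np.ndarray, tuple]:
    """Histogram the 2-D scores on the grid and convolve with a Gaussian
    kernel (a grid-evaluated Gaussian KDE)."""
    xmin, xmax, ymin, ymax = space.bounds
    R = space.grid_resolution
    H, _, _ = np.histogram2d(scores[:, 0], scores[:, 1], bins=R,
                             range=[[xmin, xmax], [ymin, ymax]])
    cw = ((xmax - xmin) / R, (ymax - ymin) / R)
    if bandwidth is None:
        # Silverman's rule per axis for a 2-D Gaussian kernel
        n = max(len(scores), 2)
        sd = scores.std(axis=0, ddof=1)
        sd[sd == 0] = 1e-6
        bandwidth = tuple(sd * n ** (-1.0 / 6.0))
    if min(bandwidth) <= 0:
        raise ValueError("bandwidth must be positive")
    sigma = (bandwidth[0] / cw[0], bandwidth[1] / cw[1])
    z = ndimage.gaussian_filter(H, sigma=sigma, mode="constant",
                                truncate=KDE_TRUNCATE)
    z[z < 0] = 0.0
    total = z.sum()
    if total == 0:
        raise ValueError("density collapsed to zero on the grid")
    return z / total, bandwidth


def occurrence_density(occ_scores: np.ndarray, bkg_scores: np.ndarray,
                       space: EnvSpace, bandwidth: tuple | None = None,
                       range_label: str = "", avail_floor: float = 1e-6,
                       occupancy_floor: float = 1e-8) -> NicheDensity:
    """Kernel-smoothed occurrence and availability densities of a range.

    Both densities use a Gaussian kernel on the shared R x R grid
    (Silverman bandwidth per axis unless given).  The corrected occupancy
    divides occurrence density by availability wherever availability
    exceeds ``avail_floor`` times its maximum, then renormalizes; it is
    zero wherever availability is zero.
    """
    if space.grid_resolution < 10:
        raise ValueError("grid resolution must be >= 10")
    occ_scores = np.atleast_2d(np.asarray(occ_scores, float))
    bkg_scores = np.atleast_2d(np.asarray(bkg_scores, float))
    z_occ, bw = _grid_density(occ_scores, space, bandwidth)
    z_avail, _ = _grid_density(bkg_scores, space, bandwidth=None)
    with np.errstate(divide="ignore", invalid="ignore"):
        z_cor = np.where(z_avail > avail_floor * z_avail.max(),
                         z_occ / z_avail, 0.0)
    z_cor[z_avail == 0] = 0.0
    total = z_cor.sum()
    if total > 0:
        z_cor /= total
    return NicheDensity(
        range_label=range_label,
        z_avail=z_avail,
        z_occ_raw=z_occ,
        z_cor=z_cor,
        bandwidth=bw,
        occupancy_floor=occupancy_floor,
    )


@dataclass
class StandardPCA:
    """Occurrence-only PCA summary: eigenvalues, retained components
    (eigenvalue >= 1 under the correlation-matrix convention), and per
    range scores and mean scores."""

    variables: list[str]
    eigenvalues: np.ndarray
    loadings: np.ndarray
    explained_variance: np.ndarray
    retained: np.ndarray          # indices of retained components
    scores: dict                  # label -> (n, n_retained)
    mean_scores: dict             # label -> (n_retained,)
    center: np.ndarray = None
    scale: np.ndarray = None

    def transform(self, values: np.ndarray, n_components: int = 3) -> np.ndarray:
        """Scores on the first ``n_components`` axes (used e.g. for the
        three-component geometric overlap)."""
        Z = (np.asarray(values, float) - self.center) / self.scale
        return Z @ self.loadings[:, :n_components]


def standard_pca(envtables: dict[str, EnvTable], eigenvalue_min: float = 1.0
                 ) -> StandardPCA:
    """PCA on the standardized occurrence climate values only.

    Follows the Kaiser convention: with standardized predictors the
    eigenvalues of the correlation matrix sum to the predictor count, and
    components with eigenvalue >= 1 carry more variance than any single
    input variable; only those enter the range mean positions.
    """
    labels = list(envtables)
    variables = envtables[labels[0]].variables
    pooled = np.vstack([envtables[k].values for k in labels])
    if pooled.shape[0] < len(variables):
        raise ValueError("fewer pooled occurrences than predictors")
    center = pooled.mean(axis=0)
    scale = pooled.std(axis=0, ddof=1)
    if (scale == 0).any():
        raise ValueError("zero-variance predictor among occurrences")
    Z = (pooled - center) / scale
    corr = np.cov(Z, rowvar=False)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], _signed(evecs[:, order])
    retained = np.flatnonzero(evals >= eigenvalue_min)
    if retained.size == 0:
        warnings.warn("no component reaches the eigenvalue threshold; keeping the first")
        retained = np.array([0])
    scores, means = {}, {}
    for k in labels:
        s = ((envtables[k].values - center) / scale) @ evecs[:, retained]
        scores[k] = s
        means[k] = s.mean(axis=0)
    return StandardPCA(
        variables=list(variables),
        eigenvalues=evals,
        loadings=evecs,
        explained_variance=evals / evals.sum(),
        retained=retained,
        scores=scores,
        mean_scores=means,
        center=center,
        scale=scale,
    )


def upgma_cluster(mean_scores: dict[str, np.ndarray]) -> tuple[np.ndarray, str]:
    """UPGMA (average-linkage) clustering of range mean niche positions
    on squared Euclidean distances; returns the linkage matrix and a
    Newick string (ultrametric: leaf depth = merge height / 2)."""
    labels = list(mean_scores)
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate range labels")
    if len(labels) < 2:
        raise ValueError("need at least two ranges to cluster")
    X = np.vstack([mean_scores[k] for k in labels])
    Z = hierarchy.linkage(pdist(X, metric="sqeuclidean"), method="average")
    tree = hierarchy.to_tree(Z)

    def rec(n, parent_h: float) -> str:
        if n.is_leaf():
            return f"{labels[n.id]}:{parent_h / 2:.6g}"
        inner = ",".join(rec(c, n.dist) for c in (n.left, n.right))
        return f"({inner}):{(parent_h - n.dist) / 2:.6g}"

    newick = "(" + ",".join(rec(c, tree.dist) for c in (tree.left, tree.right)) + ");"
    return Z, newick


__all__ = [
    "BackgroundRegion", "EnvSpace", "NicheDensity", "StandardPCA",
    "build_background", "pca_env", "occurrence_density", "standard_pca",
    "upgma_cluster",
]
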