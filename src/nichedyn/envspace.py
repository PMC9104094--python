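"""Shared environmental ordination space and occupancy surfaces.

The comparison space is the plane of the first two principal components of
the standardized, pooled background environments of both ranges (PCA-env).
Each entity (native population, invasive population, or a yearly cumulative
subset) is summarised on a common R x R grid over that plane by three
surfaces:

``o``  Gaussian product-kernel density of the entity's occurrence scores;
``e``  the same KDE of the entity's available (background) scores;
``z``  corrected occupancy ``o / e`` (zero where ``e`` is below the
       availability floor), rescaled to a maximum of 1.

Occupancy corrected by availability is the quantity the expansion /
stability / unfilling decomposition and Schoener's D operate on; analogue
masks and MESS screens guard both against non-analogue conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PcaModel",
    "EntityDensityGrid",
    "AnalogueMask",
    "fit_pca_env",
    "project",
    "shared_bounds",
    "kde_grid",
    "build_density_grid",
    "analogue_mask",
    "mess",
]

#: availability below this fraction of max(e) is treated as absent
AVAILABILITY_FLOOR = 1e-12


@dataclass
class PcaModel:
    """First two axes of a PCA on standardized pooled backgrounds."""

    means: np.ndarray
    scales: np.ndarray
    loadings: np.ndarray           # k x 2, columns orthonormal
    variance_explained: np.ndarray  # fractions, non-increasing
    columns: list[str]

    def project(self, table) -> np.ndarray:
        return project(self, table)


@dataclass
class EntityDensityGrid:
    """Occurrence (o), availability (e) and corrected occupancy (z) surfaces."""

    bounds: tuple[tuple[float, float], tuple[float, float]]
    R: int
    o: np.ndarray
    e: np.ndarray
    z: np.ndarray
    entity: str = ""
    occ_bandwidth: tuple[float, float] | None = None
    bg_bandwidth: tuple[float, float] | None = None

    def axis_centers(self, axis: int) -> np.ndarray:
        lo, hi = self.bounds[axis]
        edges = np.linspace(lo, hi, self.R + 1)
        return 0.5 * (edges[:-1] + edges[1:])

    def same_grid(self, other: "EntityDensityGrid") -> bool:
        return self.R == other.R and np.allclose(self.bounds, other.bounds)


@dataclass
class AnalogueMask:
    """Cells available (above the marginality quantile) in both ranges."""

    mask: np.ndarray
    intersect_quantile: float


def fit_pca_env(background_tables: list[pd.DataFrame]) -> PcaModel:
    """PCA of the standardized union of all background tables.

    Uses every cell of every range so the ordination spans the full
    ecological variance of both study areas. Sign convention: the
    largest-magnitude entry of each loading column is positive, making
    axes reproducible across runs.
    """
    pooled = pd.concat(background_tables, axis=0, ignore_index=True)
    k = pooled.shape[1]
    if len(pooled) < k + 2:
        raise ValueError("need at least k + 2 pooled background rows")
    vals = pooled.to_numpy(dtype=float)
    means = vals.mean(axis=0)
    scales = vals.std(axis=0, ddof=0)
    if (scales == 0).any():
        bad = [c for c, s in zip(pooled.columns, scales) if s == 0]
        raise ValueError(f"constant background column(s): {bad}")
    zed = (vals - means) / scales
    # economy SVD: right singular vectors are the component loadings
    _, svals, vt = np.linalg.svd(zed, full_matrices=False)
    var = svals ** 2 / (len(zed) * k)   # total variance of standardized data = k
    loadings = vt[:2].T.copy()
    for j in range(2):
        if loadings[np.argmax(np.abs(loadings[:, j])), j] < 0:
            loadings[:, j] *= -1
    return PcaModel(means, scales, loadings, var[:2], list(pooled.columns))


def project(pca: PcaModel, table) -> np.ndarray:
    """Score records on the two PCA axes: ((v - mean) / scale) @ loadings."""
    if isinstance(table, pd.DataFrame):
        if list(table.columns) != pca.columns:
            if set(table.columns) != set(pca.columns):
                raise ValueError("table columns do not match the fitted variables")
            table = table[pca.columns]
        vals = table.to_numpy(dtype=float)
    else:
        vals = np.atleast_2d(np.asarray(table, dtype=float))
    if vals.shape[1] != len(pca.columns):
        raise ValueError("column count mismatch with fitted model")
    return ((vals - pca.means) / pca.scales) @ pca.loadings


def shared_bounds(*score_sets: np.ndarray, padding: float = 0.05):
    """Common axis bounds over all score sets, padded by 5% of each range.

    The padding keeps kernels from being truncated at the data extremes.
    All entities compared in one analysis must be gridded on these bounds.
    """
    pooled = np.vstack([np.atleast_2d(s) for s in score_sets])
    out = []
    for axis in range(2):
        lo, hi = pooled[:, axis].min(), pooled[:, axis].max()
        if hi <= lo:
            raise ValueError("degenerate bounds: all scores identical on an axis")
        pad = padding * (hi - lo)
        out.append((float(lo - pad), float(hi + pad)))
    return tuple(out)


def _silverman(scores: np.ndarray, bounds, R: int) -> tuple[float, float]:
    """Per-axis Silverman bandwidth h = sd * n^(-1/6), floored at one cell.

    The floor keeps kernels resolvable on the evaluation grid when the
    sample is tiny or nearly collinear (a sub-cell kernel can underflow at
    every cell centre).
    """
    n = len(scores)
    out = []
    for axis in range(2):
        h = float(np.std(scores[:, axis], ddof=0)) * n ** (-1 / 6)
        cell = (bounds[axis][1] - bounds[axis][0]) / R
        out.append(max(h, cell))
    return tuple(out)


def kde_grid(scores: np.ndarray, bounds, R: int, bw) -> np.ndarray:
    """Separable Gaussian KDE evaluated at cell centres (R x R).

    ``grid[i, j]`` is the product-kernel density at (axis-1 centre i,
    axis-2 centre j): mean over points of the two 1-d Gaussian kernels
    with per-axis bandwidths ``bw = (h1, h2)``. This raw surface is the
    unit the density pipeline is built from; occupancy construction
    additionally floors its far tail (see :func:`build_density_grid`).
    """
    centers = []
    for axis in range(2):
        edges = np.linspace(*bounds[axis], R + 1)
        centers.append(0.5 * (edges[:-1] + edges[1:]))
    hx, hy = bw
    kx = np.exp(-0.5 * ((centers[0][:, None] - scores[None, :, 0]) / hx) ** 2)
    ky = np.exp(-0.5 * ((centers[1][:, None] - scores[None, :, 1]) / hy) ** 2)
    return (kx @ ky.T) / (len(scores) * 2 * np.pi * hx * hy)


def build_density_grid(occ_scores: np.ndarray, bg_scores: np.ndarray,
                       R: int = 100, bandwidth=None, bounds=None,
                       entity: str = "") -> EntityDensityGrid:
    """Build the o/e/z surfaces for one entity on the shared grid.

    ``bounds`` should come from :func:`shared_bounds` over the pooled
    backgrounds of *both* ranges so every entity shares one grid; when
    omitted they are derived from ``bg_scores`` alone. ``bandwidth`` may
    be a fixed (h1, h2) pair applied to both surfaces; by default
    Silverman's rule is applied per axis, independently on the occurrence
    scores (for ``o``) and the background scores (for ``e``).
    """
    occ = np.atleast_2d(np.asarray(occ_scores, float))
    bg = np.atleast_2d(np.asarray(bg_scores, float))
    if len(occ) < 1 or len(bg) < 2:
        raise ValueError("need >= 1 occurrence and >= 2 background scores")
    if bounds is None:
        bounds = shared_bounds(bg)
    if bandwidth is not None:
        occ_bw = bg_bw = (float(bandwidth[0]), float(bandwidth[1])) \
            if np.iterable(bandwidth) else (float(bandwidth),) * 2
    else:
        occ_bw = _silverman(occ, bounds, R)
        bg_bw = _silverman(bg, bounds, R)
    o = kde_grid(occ, bounds, R, occ_bw)
    e = kde_grid(bg, bounds, R, bg_bw)
    # relative floor: density in the far Gaussian tail is treated as absent,
    # so occupancy and availability have finite support and the binarized
    # niches (and z ratios at the envelope fringe) stay meaningful
    o = np.where(o >= AVAILABILITY_FLOOR * o.max(), o, 0.0)
    e = np.where(e >= AVAILABILITY_FLOOR * e.max(), e, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(e > 0, o / np.where(e > 0, e, 1.0), 0.0)
    if z.max() > 0:
        z = z / z.max()
    return EntityDensityGrid(tuple(map(tuple, bounds)), R, o, e, z, entity,
                             occ_bw, bg_bw)


def analogue_mask(grid_native: EntityDensityGrid, grid_invaded: EntityDensityGrid,
                  intersect_quantile: float = 0.0) -> AnalogueMask:
    """Environmental-space cells analogue to both ranges.

    At quantile 0 the mask is simply the joint availability support. A
    quantile q > 0 additionally removes, range by range, the cells whose
    availability falls below that range's q-th quantile computed over its
    own positive cells — discarding the most marginal climates.
    """
    if not grid_native.same_grid(grid_invaded):
        raise ValueError("density grids must share bounds and resolution")
    if not 0 <= intersect_quantile < 1:
        raise ValueError("intersect quantile must be in [0, 1)")
    e1, e2 = grid_native.e, grid_invaded.e
    mask = (e1 > 0) & (e2 > 0)
    if intersect_quantile > 0:
        for e in (e1, e2):
            pos = e[e > 0]
            if pos.size:
                mask &= e > np.quantile(pos, intersect_quantile)
    return AnalogueMask(mask, float(intersect_quantile))


def mess(reference_table: pd.DataFrame, projection_table: pd.DataFrame):
    """Multivariate environmental similarity of projection points to a reference.

    For each variable, with f the percentage of reference values strictly
    below the projection value, min/max the reference extremes and p the
    projected value:

    * f = 0:        s = 100 (p - min) / (max - min)
    * 0 < f <= 50:  s = 2 f
    * 50 < f < 100: s = 2 (100 - f)
    * f = 100:      s = 100 (max - p) / (max - min)

    The MESS value of a point is the minimum of s over variables; negative
    values flag novel conditions outside the reference range. Returns
    ``(per-record MESS vector, fraction of records with MESS >= 0)``.
    """
    if list(reference_table.columns) != list(projection_table.columns):
        if set(reference_table.columns) != set(projection_table.columns):
            raise ValueError("reference and projection variables differ")
        projection_table = projection_table[reference_table.columns]
    ref = reference_table.to_numpy(dtype=float)
    proj = projection_table.to_numpy(dtype=float)
    n_ref = len(ref)
    sims = np.empty_like(proj)
    for j in range(proj.shape[1]):
        col = np.sort(ref[:, j])
        mn, mx = col[0], col[-1]
        if mx <= mn:
            raise ValueError(
                f"constant reference variable {reference_table.columns[j]!r}")
        p = proj[:, j]
        f = 100.0 * np.searchsorted(col, p, side="left") / n_ref
        s = np.where(f <= 50, 2 * f, 2 * (100 - f))
        s = np.where(f == 0, 100 * (p - mn) / (mx - mn), s)
        s = np.where(f == 100, 100 * (mx - p) / (mx - mn), s)
        sims[:, j] = s
    values = sims.min(axis=1)
    return values, float((values >= 0).mean())
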