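"""Niche overlap, permutation tests, and the expansion / stability / unfilling
decomposition.

All metrics operate on corrected-occupancy surfaces (``z`` of an
:class:`~nichedyn.envspace.EntityDensityGrid`) gridded on one shared
environmental space, restricted to analogue conditions:

* Schoener's D = 1 - 0.5 * sum |p1 - p2| over surfaces normalized to unit
  mass: 0 means no overlap, 1 identical niches.
* Expansion: share of the invasive occupancy, within analogue space, that
  falls outside the native niche. Its complement is the maximum niche
  stability the invader could reach without occupying novel conditions,
  hence expansion + max_niche_stability = 1.
* Unfilling: share of the native occupancy, within analogue space, not yet
  matched by the invasive niche; it shrinks as a young invasion fills the
  niche.
* Equivalency test: permutation null built by reallocating the pooled
  occurrences between the two entities (availability surfaces fixed).
* Similarity test: null built by translating one entity's occupancy to a
  random centre within its own available environmental space.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .envspace import AnalogueMask, EntityDensityGrid, analogue_mask, \
    build_density_grid, shared_bounds

__all__ = [
    "NicheDynamicsResult",
    "PermutationTestResult",
    "schoener_d",
    "esu_indices",
    "compare_niches",
    "equivalency_test",
    "similarity_test",
    "temporal_dynamics",
    "marginality_sweep",
]

log = logging.getLogger("nichedyn")


@dataclass
class NicheDynamicsResult:
    """One row of niche metrics at one marginality quantile."""

    D: float
    expansion: float
    max_niche_stability: float
    unfilling: float
    intersect_quantile: float
    n_analogue_cells: int
    flagged: bool = False


@dataclass
class PermutationTestResult:
    observed_D: float
    null_Ds: np.ndarray
    p_value: float
    n_perm: int
    kind: str
    direction: str
    seed: int | None = None

    def __repr__(self) -> str:  # keep the null vector out of reprs
        return (f"PermutationTestResult(kind={self.kind!r}, observed_D="
                f"{self.observed_D:.4f}, p_value={self.p_value:.4f}, "
                f"n_perm={self.n_perm}, direction={self.direction!r})")


def _as_mask(mask, shape) -> np.ndarray:
    if mask is None:
        return np.ones(shape, dtype=bool)
    if isinstance(mask, AnalogueMask):
        return mask.mask
    return np.asarray(mask, dtype=bool)


def _as_z(surface) -> np.ndarray:
    if isinstance(surface, EntityDensityGrid):
        return surface.z
    return np.asarray(surface, dtype=float)


def schoener_d(z1, z2, mask=None) -> float:
    """Niche overlap between two occupancy surfaces on a shared grid.

    Each surface is normalized to sum 1 within the mask (the whole grid if
    no mask), then D = 1 - 0.5 * sum |p1 - p2|. Symmetric, in [0, 1], and
    invariant to rescaling either surface by a positive constant.
    """
    z1, z2 = _as_z(z1), _as_z(z2)
    if z1.shape != z2.shape:
        raise ValueError("surfaces must share a grid")
    m = _as_mask(mask, z1.shape)
    s1, s2 = z1[m].sum(), z2[m].sum()
    if s1 <= 0 or s2 <= 0:
        raise ValueError("a surface has no positive mass within the mask")
    p1, p2 = z1[m] / s1, z2[m] / s2
    return float(1.0 - 0.5 * np.abs(p1 - p2).sum())


def _support(z: np.ndarray, mass_threshold: float) -> np.ndarray:
    """Occupied cells: z > 0, optionally trimming the lowest-z mass fraction.

    KDE tails inflate niche extent; a mass threshold of, say, 0.05 drops
    the set of weakest cells jointly holding 5% of total occupancy.
    """
    if mass_threshold <= 0:
        return z > 0
    flat = np.sort(z[z > 0])
    cum = np.cumsum(flat)
    cut_idx = np.searchsorted(cum, mass_threshold * flat.sum(), side="right")
    level = flat[min(cut_idx, len(flat) - 1)]
    return z > level


def esu_indices(z_native, z_invasive, mask=None,
                occupancy_threshold: float = 0.0):
    """Expansion, maximum niche stability and unfilling within analogue space.

    Within the mask, the native and invasive niches are binarized at
    ``z > 0`` (or at the occupancy-mass threshold). Expansion is the
    invasive occupancy in cells outside the native niche over all invasive
    occupancy in the mask; max niche stability is its complement;
    unfilling is the native occupancy not covered by the invasive niche
    over all native occupancy in the mask. An invasive niche wholly
    outside analogue space yields (1, 0, 1) by convention, with a warning.
    """
    zn, zi = _as_z(z_native), _as_z(z_invasive)
    if zn.shape != zi.shape:
        raise ValueError("surfaces must share a grid")
    m = _as_mask(mask, zn.shape)
    if not m.any():
        raise ValueError("analogue mask is empty")
    N = _support(zn, occupancy_threshold) & m
    I = _support(zi, occupancy_threshold) & m
    if not N.any():
        raise ValueError("native niche lies entirely outside analogue space")
    if not I.any():
        warnings.warn("invasive occupancy entirely outside analogue space; "
                      "expansion = 1 by convention", stacklevel=2)
        return 1.0, 0.0, 1.0
    inv_total = zi[I].sum()
    expansion = float(zi[I & ~N].sum() / inv_total)
    nat_total = zn[N].sum()
    unfilling = float(zn[N & ~I].sum() / nat_total)
    return expansion, 1.0 - expansion, unfilling


def compare_niches(native_grid: EntityDensityGrid, invasive_grid: EntityDensityGrid,
                   intersect_quantile: float = 0.0,
                   occupancy_threshold: float = 0.0) -> NicheDynamicsResult:
    """D and the E/S/U decomposition at one marginality quantile."""
    am = analogue_mask(native_grid, invasive_grid, intersect_quantile)
    n_cells = int(am.mask.sum())
    if n_cells == 0 or not ((native_grid.z > 0) & am.mask).any() \
            or not (invasive_grid.z[am.mask].sum() > 0):
        return NicheDynamicsResult(np.nan, np.nan, np.nan, np.nan,
                                   intersect_quantile, n_cells, flagged=True)
    try:
        d = schoener_d(native_grid.z, invasive_grid.z, am)
    except ValueError:
        d = 0.0
    e, s, u = esu_indices(native_grid.z, invasive_grid.z, am, occupancy_threshold)
    return NicheDynamicsResult(d, e, s, u, intersect_quantile, n_cells)


def _p_value(null: np.ndarray, observed: float, direction: str) -> float:
    n = len(null)
    lo = (1 + int((null <= observed).sum())) / (n + 1)
    hi = (1 + int((null >= observed).sum())) / (n + 1)
    if direction == "lower":
        return lo
    if direction == "higher":
        return hi
    if direction == "two-sided":
        return min(1.0, 2 * min(lo, hi))
    raise ValueError(f"unknown direction {direction!r}")


def equivalency_test(occ_scores_1, occ_scores_2, bg_scores_1, bg_scores_2=None,
                     R: int = 100, n_perm: int = 99, seed: int = 0,
                     direction: str = "lower", bandwidth=None,
                     method: str = "random") -> PermutationTestResult:
    """Niche equivalency: is the observed overlap what random reallocation gives?

    The pooled occurrence scores are repeatedly reassigned to the two
    entities (group sizes preserved); both occupancy surfaces are rebuilt
    on the shared grid with each entity's availability surface held fixed,
    and D recomputed. With ``method='exhaustive'`` every distinct split is
    enumerated instead (only feasible for tiny samples). The default
    one-tailed direction ``'lower'`` rejects equivalency when the observed
    overlap is smaller than the null overlaps.
    """
    o1 = np.atleast_2d(np.asarray(occ_scores_1, float))
    o2 = np.atleast_2d(np.asarray(occ_scores_2, float))
    b1 = np.atleast_2d(np.asarray(bg_scores_1, float))
    b2 = b1 if bg_scores_2 is None else np.atleast_2d(np.asarray(bg_scores_2, float))
    if len(o1) == 0 or len(o2) == 0:
        raise ValueError("both occurrence sets must be non-empty")
    pooled = np.vstack([o1, o2])
    if len(pooled) < 2:
        raise ValueError("pooled occurrence set too small")
    if n_perm < 19:
        raise ValueError("n_perm must be at least 19")
    bounds = shared_bounds(b1, b2, pooled)
    n1 = len(o1)

    def d_of(split1: np.ndarray, split2: np.ndarray) -> float:
        g1 = build_density_grid(split1, b1, R, bandwidth, bounds)
        g2 = build_density_grid(split2, b2, R, bandwidth, bounds)
        return schoener_d(g1.z, g2.z)

    observed = d_of(o1, o2)
    if method == "exhaustive":
        idx = range(len(pooled))
        null = np.array([
            d_of(pooled[list(c)], pooled[[i for i in idx if i not in set(c)]])
            for c in combinations(idx, n1)
        ])
    elif method == "random":
        rng = np.random.default_rng(seed)
        null = np.empty(n_perm)
        for i in range(n_perm):
            perm = rng.permutation(len(pooled))
            null[i] = d_of(pooled[perm[:n1]], pooled[perm[n1:]])
    else:
        raise ValueError(f"unknown method {method!r}")
    p = _p_value(null, observed, direction)
    return PermutationTestResult(observed, null, p, len(null), "equivalency",
                                 direction, seed)


def _shift_surface(z: np.ndarray, shift: tuple[int, int]) -> np.ndarray:
    """Translate a grid by integer offsets, zero-filling; no wrap-around."""
    out = np.zeros_like(z)
    dr, dc = shift
    nr, nc = z.shape
    r_src = slice(max(0, -dr), max(0, min(nr, nr - dr)))
    c_src = slice(max(0, -dc), max(0, min(nc, nc - dc)))
    r_dst = slice(max(0, min(nr, dr)), min(nr, nr + dr))
    c_dst = slice(max(0, min(nc, dc)), min(nc, nc + dc))
    out[r_dst, c_dst] = z[r_src, c_src]
    return out


def similarity_test(grid_1: EntityDensityGrid, grid_2: EntityDensityGrid,
                    n_perm: int = 99, seed: int = 0,
                    direction: str = "higher") -> PermutationTestResult:
    """Niche similarity: is the overlap higher than with a randomly placed niche?

    Each permutation translates entity 2's occupancy surface so that its
    mass centroid lands on a uniformly random cell of entity 2's own
    available space (e > 0); mass shifted outside the support is zeroed.
    The one-tailed p (direction 'higher') is small when the two niches are
    more similar than chance placement would produce.
    """
    if not grid_1.same_grid(grid_2):
        raise ValueError("grids must share bounds and resolution")
    if n_perm < 19:
        raise ValueError("n_perm must be at least 19")
    avail = np.argwhere(grid_2.e > 0)
    if len(avail) < 2:
        raise ValueError("entity 2 available space smaller than 2 cells")
    z2 = grid_2.z
    total = z2.sum()
    if total <= 0:
        raise ValueError("entity 2 has no occupancy mass")
    rows, cols = np.nonzero(z2)
    centroid = (int(round((rows * z2[rows, cols]).sum() / total)),
                int(round((cols * z2[rows, cols]).sum() / total)))
    observed = schoener_d(grid_1.z, z2)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    support = grid_2.e > 0
    for i in range(n_perm):
        target = avail[rng.integers(len(avail))]
        shifted = _shift_surface(z2, (target[0] - centroid[0],
                                      target[1] - centroid[1]))
        shifted = np.where(support, shifted, 0.0)
        null[i] = schoener_d(grid_1.z, shifted) if shifted.sum() > 0 else 0.0
    p = _p_value(null, observed, direction)
    return PermutationTestResult(observed, null, p, n_perm, "similarity",
                                 direction, seed)


def temporal_dynamics(native_grid: EntityDensityGrid, occ_scores, years,
                      bg_scores_invaded, intersect_quantile: float = 0.0,
                      occupancy_threshold: float = 0.0, bandwidth=None,
                      years_grid=None) -> pd.DataFrame:
    """Yearly niche dynamics: each year's cumulative invasive records vs native.

    For each year y, the records dated up to and including y form the
    invasive entity; its occupancy surface is rebuilt on the native grid's
    bounds (availability fixed at the invaded range's full background) and
    compared with the fixed native surface. Returns a tidy frame with one
    row per year: expansion, max_niche_stability, unfilling, D and the
    cumulative record count.
    """
    scores = np.atleast_2d(np.asarray(occ_scores, float))
    yr = np.asarray(years)
    if len(yr) != len(scores):
        raise ValueError("years must align with occurrence scores")
    if len(scores) == 0:
        raise ValueError("no dated records")
    bg = np.atleast_2d(np.asarray(bg_scores_invaded, float))
    bounds = native_grid.bounds
    R = native_grid.R
    inv_full = build_density_grid(scores, bg, R, bandwidth, bounds)
    am = analogue_mask(native_grid, inv_full, intersect_quantile)
    if bandwidth is None:
        # one bandwidth for every cumulative year (taken from the full dated
        # set), so the series reflects accumulating occurrences only
        bandwidth = inv_full.occ_bandwidth
    year_list = sorted(set(yr.tolist())) if years_grid is None else list(years_grid)
    if not np.isin(yr, year_list).any() or (yr <= year_list[0]).sum() == 0:
        raise ValueError("no records at or before the first year")
    rows = []
    for y in year_list:
        sel = yr <= y
        sub = scores[sel]
        g = build_density_grid(sub, bg, R, bandwidth, bounds)
        d = schoener_d(native_grid.z, g.z, am)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            e, s, u = esu_indices(native_grid.z, g.z, am, occupancy_threshold)
        rows.append({"year": y, "expansion": e, "max_niche_stability": s,
                     "unfilling": u, "D": d, "n_records_cumulative": int(sel.sum())})
    return pd.DataFrame(rows)


def marginality_sweep(native_grid: EntityDensityGrid,
                      invasive_grid: EntityDensityGrid,
                      quantiles=(0.0, 0.1, 0.2),
                      occupancy_threshold: float = 0.0) -> pd.DataFrame:
    """Niche metrics while successively discarding marginal climates.

    One row per intersect quantile. Small changes in expansion across
    quantiles indicate the species occupies the commonest available
    conditions rather than marginal ones. A quantile whose analogue mask
    is empty yields a flagged all-NaN row rather than fabricated metrics.
    """
    qs = list(quantiles)
    if qs != sorted(qs) or any(not 0 <= q < 1 for q in qs):
        raise ValueError("quantiles must be ascending within [0, 1)")
    rows = []
    for q in qs:
        res = compare_niches(native_grid, invasive_grid, q, occupancy_threshold)
        rows.append({"intersect_quantile": q, "expansion": res.expansion,
                     "max_niche_stability": res.max_niche_stability,
                     "unfilling": res.unfilling, "D": res.D,
                     "n_analogue_cells": res.n_analogue_cells,
                     "flagged": res.flagged})
    return pd.DataFrame(rows)
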