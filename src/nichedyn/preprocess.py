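"""Occurrence rarefaction and collinearity filtering.

Spatial rarefaction keeps at most one record per grid cell, favouring the
record whose (standardized) environmental vector is most distinct from the
points already retained — the environmentally-weighted analogue of spatial
thinning at the raster resolution. The collinearity filter removes, for
every pair of variables with |Pearson r| at or above a threshold, the
lower-priority member, so the surviving set has no pair above the
threshold.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import EnvLayerStack, OccurrenceSet
from .io import extract_env_at_points

__all__ = ["rarefy_occurrences", "filter_correlated"]

log = logging.getLogger("nichedyn")


def rarefy_occurrences(occ: OccurrenceSet, stack: EnvLayerStack,
                       cell_size: float | None = None) -> OccurrenceSet:
    """Reduce ``occ`` to one record per rarefaction cell.

    Cells are defined on the stack's grid origin with ``cell_size``
    (default: the stack's own resolution). Within a cell the record whose
    per-layer-standardized environmental vector lies farthest (Euclidean)
    from the centroid of the already-kept records is retained; the first
    kept cell and all ties fall back to input order. Idempotent.
    """
    if len(occ) == 0:
        raise ValueError("cannot rarefy an empty occurrence set")
    s = stack.cell_size if cell_size is None else float(cell_size)
    if s <= 0:
        raise ValueError("cell_size must be positive")
    x0, y0 = stack.origin
    col = np.floor((occ.data["x"].to_numpy() - x0) / s).astype(int)
    row = np.floor((y0 - occ.data["y"].to_numpy()) / s).astype(int)

    env = extract_env_at_points(stack, occ)
    # standardize per layer over the records that have environment
    ev = env.to_numpy()
    sd = ev.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    ez = (ev - ev.mean(axis=0)) / sd
    zmap = dict(zip(env.index.to_numpy(), ez))

    cells: dict[tuple[int, int], list[int]] = {}
    for i, key in enumerate(zip(row, col)):
        cells.setdefault(key, []).append(i)

    kept: list[int] = []
    kept_z: list[np.ndarray] = []
    for key, members in cells.items():  # dict preserves first-appearance order
        candidates = [i for i in members if i in zmap]
        if not candidates:
            candidates = members  # no environment: fall back to input order
            choice = candidates[0]
        elif not kept_z:
            choice = candidates[0]
        else:
            centroid = np.mean(kept_z, axis=0)
            dists = np.array([np.linalg.norm(zmap[i] - centroid) for i in candidates])
            # ties broken by input order: argmax returns the first maximum
            choice = candidates[int(np.argmax(dists))]
        kept.append(choice)
        if choice in zmap:
            kept_z.append(zmap[choice])
    kept.sort()
    log.info("rarefaction: %d -> %d records", len(occ), len(kept))
    return occ.subset(kept)


def filter_correlated(env_table: pd.DataFrame, threshold: float = 0.70,
                      priority: list[str] | None = None) -> list[str]:
    """Greedy collinearity filter on a pooled records x variables table.

    For every pair with |Pearson r| >= ``threshold`` the lower-priority
    variable is removed (priority order: the given list, defaulting to
    table column order — earlier means more biologically important, hence
    kept). A constant variable has undefined r; it is treated as
    uncorrelated and kept, with a warning.

    Returns the kept variable names in priority order.
    """
    if env_table.shape[1] < 2:
        raise ValueError("need at least two variables")
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    names = list(env_table.columns)
    if priority is None:
        priority = names
    else:
        unknown = set(priority) - set(names)
        if unknown:
            raise ValueError(f"priority names not in table: {sorted(unknown)}")
        priority = list(priority) + [n for n in names if n not in priority]

    constant = [n for n in names if env_table[n].nunique() <= 1]
    if constant:
        log.warning("constant variable(s) %s: correlation undefined, treated as 0",
                    constant)
    corr = env_table.corr().abs().fillna(0.0)

    kept: list[str] = []
    for name in priority:
        if all(corr.loc[name, k] < threshold for k in kept):
            kept.append(name)
    # postcondition: no surviving pair at/above threshold
    for i, a in enumerate(kept):
        for b in kept[i + 1:]:
            assert corr.loc[a, b] < threshold
    return kept
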