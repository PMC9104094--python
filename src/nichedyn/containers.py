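"""Core data containers: occurrence sets and environmental raster stacks.

Grids are abstract planar rasters: 0-based row/col indexing, x increasing
with column, y decreasing with row (raster convention). ``origin`` is the
(x, y) of the *outer top-left corner* of cell (0, 0) and ``cell_size`` is
the side length of a square cell in km. Cell membership is half-open:
a point with ``x0 + j*s <= x < x0 + (j+1)*s`` belongs to column ``j``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["OccurrenceSet", "EnvLayerStack"]


@dataclass
class OccurrenceSet:
    """Labelled, optionally dated presence records.

    Parameters
    ----------
    data : pandas.DataFrame
        Columns ``x``, ``y`` (finite floats), optional ``year`` (nullable
        integer) and ``population`` (non-empty label, e.g. ``native``,
        ``P1``, ``P2``).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.copy()
        for col in ("x", "y"):
            if col not in df.columns:
                raise ValueError(f"occurrence table lacks mandatory column {col!r}")
            df[col] = df[col].astype(float)
        if not np.isfinite(df[["x", "y"]].to_numpy()).all():
            raise ValueError("occurrence coordinates must be finite")
        if "population" not in df.columns:
            df["population"] = "unlabelled"
        df["population"] = df["population"].astype(str)
        if (df["population"].str.len() == 0).any():
            raise ValueError("population labels must be non-empty")
        if "year" in df.columns:
            df["year"] = df["year"].astype("Int64")
        else:
            df["year"] = pd.Series([pd.NA] * len(df), dtype="Int64")
        self.data = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) array of coordinates."""
        return self.data[["x", "y"]].to_numpy()

    @property
    def years(self) -> pd.Series:
        return self.data["year"]

    def dated(self) -> "OccurrenceSet":
        """Records carrying a year (undated records are dropped)."""
        return OccurrenceSet(self.data[self.data["year"].notna()].reset_index(drop=True))

    def for_population(self, label: str) -> "OccurrenceSet":
        return OccurrenceSet(
            self.data[self.data["population"] == label].reset_index(drop=True)
        )

    def subset(self, index) -> "OccurrenceSet":
        return OccurrenceSet(self.data.iloc[np.asarray(index)].reset_index(drop=True))


@dataclass
class EnvLayerStack:
    """Gridded multi-layer environmental raster sharing one validity mask.

    Attributes
    ----------
    values : ndarray, shape (k, n_rows, n_cols)
    layer_names : list of str, unique
    cell_size : float, km per cell side
    origin : (x0, y0) of the top-left corner
    valid_mask : bool ndarray, shape (n_rows, n_cols)
    """

    values: np.ndarray
    layer_names: list[str]
    cell_size: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)
    valid_mask: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must have shape (k, n_rows, n_cols)")
        k = self.values.shape[0]
        if len(self.layer_names) != k:
            raise ValueError("layer_names length must equal number of layers")
        if len(set(self.layer_names)) != k:
            raise ValueError("layer_names must be unique")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.values.shape[1:], dtype=bool)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.valid_mask.shape != self.values.shape[1:]:
            raise ValueError("valid_mask shape must match grid shape")

    @property
    def k(self) -> int:
        return self.values.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape[1:]

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())

    def cell_of(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Row/col of the cells containing points (half-open membership)."""
        x0, y0 = self.origin
        col = np.floor((np.asarray(x, float) - x0) / self.cell_size).astype(int)
        row = np.floor((y0 - np.asarray(y, float)) / self.cell_size).astype(int)
        return row, col

    def cell_center(self, row, col) -> tuple[np.ndarray, np.ndarray]:
        x0, y0 = self.origin
        x = x0 + (np.asarray(col) + 0.5) * self.cell_size
        y = y0 - (np.asarray(row) + 0.5) * self.cell_size
        return x, y

    def contains(self, x, y) -> np.ndarray:
        row, col = self.cell_of(x, y)
        nr, nc = self.shape
        return (row >= 0) & (row < nr) & (col >= 0) & (col < nc)

    def table(self, mask: np.ndarray | None = None) -> pd.DataFrame:
        """Environmental values of valid cells as a records x k table."""
        m = self.valid_mask if mask is None else (self.valid_mask & mask)
        return pd.DataFrame(
            {name: self.values[i][m] for i, name in enumerate(self.layer_names)}
        )

    def subset_layers(self, names: list[str]) -> "EnvLayerStack":
        idx = [self.layer_names.index(n) for n in names]
        return EnvLayerStack(
            self.values[idx].copy(),
            list(names),
            self.cell_size,
            self.origin,
            self.valid_mask.copy(),
        )
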