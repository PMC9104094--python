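"""Reading and writing occurrence tables and raster stacks.

Occurrences travel as UTF-8 CSV with header ``x,y,year,population`` and a
``.`` decimal separator. Rasters are single-band ESRI ASCII grids
(``.asc``), one file per layer, with NODATA honoured; the stack's validity
mask is the conjunction of the per-layer no-data masks.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import EnvLayerStack, OccurrenceSet

__all__ = [
    "read_occurrences",
    "write_occurrences",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_env_stack",
    "write_env_stack",
    "extract_env_at_points",
]

log = logging.getLogger("nichedyn")

_NODATA = -9999.0


def read_occurrences(path) -> OccurrenceSet:
    """Read an occurrence CSV; rows with unparseable coordinates are rejected.

    Raises on a missing file, an empty file, or missing x/y columns.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: no occurrence rows")
    missing = {"x", "y"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s) {sorted(missing)}")
    xy = df[["x", "y"]].apply(pd.to_numeric, errors="coerce")
    bad = ~np.isfinite(xy.to_numpy()).all(axis=1)
    if bad.any():
        log.warning("%s: rejected %d row(s) with unparseable coordinates", path, bad.sum())
    df = df.loc[~bad].copy()
    if df.empty:
        raise ValueError(f"{path}: no rows with valid coordinates")
    df[["x", "y"]] = xy.loc[~bad]
    if "year" in df.columns:
        df["year"] = pd.to_numeric(df["year"], errors="coerce").round().astype("Int64")
    return OccurrenceSet(df.reset_index(drop=True))


def write_occurrences(occ: OccurrenceSet, path) -> None:
    df = occ.data[["x", "y", "year", "population"]]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_ascii_grid(path) -> tuple[np.ndarray, float, tuple[float, float], float]:
    """Parse one ESRI ASCII grid.

    Returns (values with NODATA as NaN, cell_size, top-left origin, nodata).
    """
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner",
                "xllcenter", "yllcenter", "cellsize", "nodata_value",
            }:
                header[parts[0].lower()] = float(parts[1])
                pos = fh.tell()
            else:
                break
        fh.seek(pos)
        body = np.loadtxt(fh, dtype=float, ndmin=2)
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise ValueError(f"{path}: ASCII grid header lacks {key}")
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if body.shape != (nrows, ncols):
        raise ValueError(
            f"{path}: grid body {body.shape} does not match header ({nrows}, {ncols})"
        )
    s = header["cellsize"]
    if "xllcorner" in header:
        xll, yll = header["xllcorner"], header["yllcorner"]
    else:  # cell-centre registration
        xll, yll = header["xllcenter"] - s / 2, header["yllcenter"] - s / 2
    nodata = header.get("nodata_value", _NODATA)
    values = body.copy()
    values[body == nodata] = np.nan
    origin = (xll, yll + nrows * s)  # top-left corner
    return values, s, origin, nodata


def write_ascii_grid(values: np.ndarray, path, cell_size: float = 1.0,
                     origin: tuple[float, float] = (0.0, 0.0),
                     nodata: float = _NODATA) -> None:
    values = np.asarray(values, dtype=float)
    nrows, ncols = values.shape
    x0, y0 = origin
    out = np.where(np.isnan(values), nodata, values)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {x0!r}\n")
        fh.write(f"yllcorner {y0 - nrows * cell_size!r}\n")
        fh.write(f"cellsize {cell_size!r}\n")
        fh.write(f"NODATA_value {nodata!r}\n")
        for row in out:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_env_stack(source) -> EnvLayerStack:
    """Assemble a stack from ``.asc`` files (a directory or an ordered list).

    Layer names are the file stems. All layers must share shape, cell size
    and extent; a NODATA cell in any layer is invalid in the whole stack.
    """
    if isinstance(source, (str, Path)) and Path(source).is_dir():
        paths = sorted(Path(source).glob("*.asc"))
    else:
        paths = [Path(p) for p in source]
    if not paths:
        raise ValueError("no raster layers found")
    layers, names = [], []
    cell_size = origin = None
    for p in paths:
        vals, s, org, _ = read_ascii_grid(p)
        if cell_size is None:
            cell_size, origin = s, org
        elif vals.shape != layers[0].shape or s != cell_size or org != origin:
            raise ValueError(f"{p}: layer shape/extent mismatch with {paths[0]}")
        layers.append(vals)
        names.append(p.stem)
    values = np.stack(layers)
    valid = np.isfinite(values).all(axis=0)
    values = np.where(np.isfinite(values), values, 0.0)
    return EnvLayerStack(values, names, cell_size, origin, valid)


def write_env_stack(stack: EnvLayerStack, directory) -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = []
    for i, name in enumerate(stack.layer_names):
        vals = stack.values[i].copy()
        vals[~stack.valid_mask] = np.nan
        p = directory / f"{name}.asc"
        write_ascii_grid(vals, p, stack.cell_size, stack.origin)
        out.append(p)
    return out


def extract_env_at_points(stack: EnvLayerStack, occ: OccurrenceSet) -> pd.DataFrame:
    """Nearest-cell environmental values for each record.

    Records falling outside the raster extent or on invalid cells are
    dropped (counts logged); raises if no record remains.
    """
    row, col = stack.cell_of(occ.data["x"], occ.data["y"])
    nr, nc = stack.shape
    inside = (row >= 0) & (row < nr) & (col >= 0) & (col < nc)
    if not inside.any():
        raise ValueError("all points outside raster extent")
    n_outside = int((~inside).sum())
    valid = inside.copy()
    valid[inside] &= stack.valid_mask[row[inside], col[inside]]
    n_invalid = int(inside.sum() - valid.sum())
    if n_outside or n_invalid:
        log.warning("extract_env_at_points: dropped %d outside-extent and %d "
                    "invalid-cell record(s)", n_outside, n_invalid)
    if not valid.any():
        raise ValueError("no record falls on a valid cell")
    r, c = row[valid], col[valid]
    tbl = pd.DataFrame(
        {name: stack.values[i, r, c] for i, name in enumerate(stack.layer_names)},
        index=occ.data.index[valid],
    )
    tbl.attrs["n_dropped"] = n_outside + n_invalid
    return tbl
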