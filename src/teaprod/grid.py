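"""Aligned multi-layer environmental raster stacks.

A stack holds one 2-D array per named environmental variable on a shared
grid (same shape, extent, cell size, nodata sentinel), mirroring how
bioclimatic and terrain layers are co-registered before niche modelling.
Rasters are persisted as single-band ESRI ASCII grids, one file per
variable, file name = variable name.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_NODATA = -9999.0


@dataclass
class EnvironmentalGrid:
    """A stack of co-registered single-band rasters.

    Row 0 is the northernmost row (ESRI ASCII convention); ``xll``/``yll``
    are the coordinates of the lower-left corner of the lower-left cell.
    Coordinates are WGS84 decimal degrees by convention, but any planar
    system works as long as points and grid agree.
    """

    layers: dict[str, np.ndarray]
    xll: float = 0.0
    yll: float = 0.0
    cellsize: float = 1.0
    nodata: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("grid must contain at least one layer")
        shapes = {a.shape for a in self.layers.values()}
        if len(shapes) > 1:
            raise ValueError(f"layers differ in shape: {sorted(shapes)}")
        (self._shape,) = shapes
        if len(self._shape) != 2:
            raise ValueError("layers must be 2-D arrays")
        if self.cellsize <= 0:
            raise ValueError("cellsize must be positive")

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    @property
    def shape(self) -> tuple[int, int]:
        return self._shape

    @property
    def nrows(self) -> int:
        return self._shape[0]

    @property
    def ncols(self) -> int:
        return self._shape[1]

    def cell_center(self, row: np.ndarray, col: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(lon, lat) of cell centers for 0-based row/col (row 0 = north)."""
        lon = self.xll + (np.asarray(col) + 0.5) * self.cellsize
        lat = self.yll + (self.nrows - np.asarray(row) - 0.5) * self.cellsize
        return lon, lat

    def locate(self, lon: np.ndarray, lat: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Nearest-cell (row, col) for coordinates plus an in-extent mask."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.xll) / self.cellsize).astype(int)
        row = self.nrows - 1 - np.floor((lat - self.yll) / self.cellsize).astype(int)
        inside = (col >= 0) & (col < self.ncols) & (row >= 0) & (row < self.nrows)
        return row, col, inside

    def table(self) -> pd.DataFrame:
        """All cells as a flat table (one column per layer), nodata as NaN."""
        out = {}
        for name, arr in self.layers.items():
            v = arr.astype(float).ravel()
            v = np.where(v == self.nodata, np.nan, v)
            out[name] = v
        return pd.DataFrame(out)

    def cell_table(self) -> pd.DataFrame:
        """Flat table with lon/lat of every cell center plus layer values."""
        rows, cols = np.indices(self._shape)
        lon, lat = self.cell_center(rows.ravel(), cols.ravel())
        df = pd.DataFrame({"lon": lon, "lat": lat})
        return pd.concat([df, self.table()], axis=1)


def extract_at_points(grid: EnvironmentalGrid, points: pd.DataFrame) -> pd.DataFrame:
    """Nearest-cell lookup of every layer at each point.

    ``points`` must have ``lon`` and ``lat`` columns.  Points outside the
    grid extent get the nodata sentinel in every variable column and are
    flagged ``outside_extent=True``; the caller can count them from the flag.
    Nodata cells propagate the sentinel unchanged.
    """
    if not {"lon", "lat"}.issubset(points.columns):
        raise ValueError("points table must have 'lon' and 'lat' columns")
    row, col, inside = grid.locate(points["lon"].to_numpy(), points["lat"].to_numpy())
    out = points[["lon", "lat"]].reset_index(drop=True).copy()
    r = np.where(inside, row, 0)
    c = np.where(inside, col, 0)
    for name, arr in grid.layers.items():
        vals = arr[r, c].astype(float)
        vals[~inside] = grid.nodata
        out[name] = vals
    out["outside_extent"] = ~inside
    return out


def write_ascii_grid(path: str, array: np.ndarray, xll: float, yll: float,
                     cellsize: float, nodata: float = DEFAULT_NODATA) -> None:
    arr = np.asarray(array, dtype=float)
    nrows, ncols = arr.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {xll!r}\n")
        fh.write(f"yllcorner {yll!r}\n")
        fh.write(f"cellsize {cellsize!r}\n")
        fh.write(f"NODATA_value {nodata!r}\n")
        for i in range(nrows):
            fh.write(" ".join(repr(float(v)) for v in arr[i]) + "\n")


def read_ascii_grid(path: str) -> tuple[np.ndarray, dict]:
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"
        }:
            header[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:
            break
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ValueError(f"{path}: missing ESRI ASCII header field {key}")
    data = np.loadtxt(lines[n_header:], dtype=float)
    data = np.atleast_2d(data)
    if data.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(f"{path}: data shape {data.shape} disagrees with header")
    return data, header


def write_grid(grid: EnvironmentalGrid, directory: str) -> list[str]:
    """One ``<name>.asc`` per layer; returns the written paths."""
    os.makedirs(directory, exist_ok=True)
    paths = []
    for name, arr in grid.layers.items():
        p = os.path.join(directory, f"{name}.asc")
        write_ascii_grid(p, arr, grid.xll, grid.yll, grid.cellsize, grid.nodata)
        paths.append(p)
    return paths


def read_grid(directory: str, names: list[str] | None = None) -> EnvironmentalGrid:
    """Read a stack written by :func:`write_grid` (all ``*.asc`` by default)."""
    if names is None:
        names = sorted(os.path.splitext(f)[0] for f in os.listdir(directory)
                       if f.endswith(".asc"))
    if not names:
        raise ValueError(f"no .asc rasters found in {directory}")
    layers = {}
    meta = None
    for name in names:
        arr, header = read_ascii_grid(os.path.join(directory, f"{name}.asc"))
        key = (header["xllcorner"], header["yllcorner"], header["cellsize"])
        if meta is None:
            meta = key
            nodata = header.get("nodata_value", DEFAULT_NODATA)
        elif key != meta:
            raise ValueError(f"layer {name} is not co-registered with the stack")
        layers[name] = arr
    return EnvironmentalGrid(layers, xll=meta[0], yll=meta[1], cellsize=meta[2],
                             nodata=nodata)
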