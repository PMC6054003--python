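"""Georeferenced raster data model and spatial primitives.

Grids are plain 2-D numpy arrays in geographic (WGS84) lon/lat with square
cells, rows ordered north to south and columns west to east.  The origin is
the north-west *corner* of the grid; cell centres sit half a cell in from it.
A single nodata sentinel per raster (default -9999) marks missing cells.

Supported on-disk formats: ESRI ASCII grid for single layers and NetCDF
(classic, via xarray's scipy engine) for multi-layer stacks.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import xarray as xr

DEFAULT_NODATA = -9999.0
EARTH_RADIUS_KM = 6371.0


@dataclass
class GridRaster:
    """A single-band georeferenced grid.

    Parameters
    ----------
    values : ndarray of shape (rows, cols)
        Cell values; cells equal to ``nodata`` are missing.
    origin : (lon, lat)
        North-west corner of the grid, decimal degrees.
    cell_size : float
        Cell edge length in decimal degrees (square cells).
    nodata : float
        Missing-value sentinel.
    """

    values: np.ndarray
    origin: tuple[float, float]
    cell_size: float
    nodata: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("GridRaster values must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    # -- geometry -----------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def same_geometry(self, other: "GridRaster", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and abs(self.cell_size - other.cell_size) <= tol
            and abs(self.origin[0] - other.origin[0]) <= tol
            and abs(self.origin[1] - other.origin[1]) <= tol
        )

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """(lon, lat) of the centre of cell (row, col)."""
        lon = self.origin[0] + (col + 0.5) * self.cell_size
        lat = self.origin[1] - (row + 0.5) * self.cell_size
        return lon, lat

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays (lon, lat), each of grid shape, of all cell centres."""
        rows, cols = self.shape
        lon = self.origin[0] + (np.arange(cols) + 0.5) * self.cell_size
        lat = self.origin[1] - (np.arange(rows) + 0.5) * self.cell_size
        return np.meshgrid(lon, lat)

    def index_of(self, lon: float, lat: float) -> tuple[int, int]:
        """Row/col of the cell containing a point (cell-centre registration)."""
        col = int(np.floor((lon - self.origin[0]) / self.cell_size))
        row = int(np.floor((self.origin[1] - lat) / self.cell_size))
        if not (0 <= row < self.shape[0] and 0 <= col < self.shape[1]):
            raise IndexError(f"point ({lon}, {lat}) outside raster extent")
        return row, col

    # -- values -------------------------------------------------------------

    @property
    def valid(self) -> np.ndarray:
        """Boolean array, True where the cell carries data."""
        return (self.values != self.nodata) & np.isfinite(self.values)

    def masked(self) -> np.ndarray:
        """Values with nodata cells replaced by NaN."""
        out = self.values.copy()
        out[~self.valid] = np.nan
        return out

    def with_values(self, values: np.ndarray) -> "GridRaster":
        return replace(self, values=np.asarray(values, dtype=float))

    def copy(self) -> "GridRaster":
        return replace(self, values=self.values.copy())


@dataclass
class MonthlyClimate:
    """Monthly climatology: 12 x precipitation (mm), tmin and tmax (degC).

    All 36 layers share one geometry; stored as (12, rows, cols) stacks.
    """

    prec: np.ndarray
    tmin: np.ndarray
    tmax: np.ndarray
    origin: tuple[float, float]
    cell_size: float
    nodata: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        for name in ("prec", "tmin", "tmax"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.ndim != 3 or arr.shape[0] != 12:
                raise ValueError(f"{name} must have shape (12, rows, cols)")
            setattr(self, name, arr)
        if not (self.prec.shape == self.tmin.shape == self.tmax.shape):
            raise ValueError("prec/tmin/tmax shapes differ")

    @property
    def shape(self) -> tuple[int, int]:
        return self.prec.shape[1:]

    @property
    def valid(self) -> np.ndarray:
        ok = np.ones(self.shape, dtype=bool)
        for stack in (self.prec, self.tmin, self.tmax):
            ok &= np.all((stack != self.nodata) & np.isfinite(stack), axis=0)
        return ok

    def layer(self, var: str, month: int) -> GridRaster:
        """One month (0-based) of one variable as a GridRaster."""
        return GridRaster(getattr(self, var)[month], self.origin,
                          self.cell_size, self.nodata)

    def geometry_raster(self) -> GridRaster:
        return GridRaster(np.zeros(self.shape), self.origin,
                          self.cell_size, self.nodata)

    def check_invariants(self) -> None:
        ok = self.valid
        if np.any(self.prec[:, ok] < 0):
            raise ValueError("negative precipitation")
        if np.any(self.tmax[:, ok] < self.tmin[:, ok]):
            raise ValueError("tmax < tmin")

    def pixel(self, row: int, col: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(prec[12], tmin[12], tmax[12]) at one cell."""
        return (self.prec[:, row, col].copy(),
                self.tmin[:, row, col].copy(),
                self.tmax[:, row, col].copy())

    def copy(self) -> "MonthlyClimate":
        return MonthlyClimate(self.prec.copy(), self.tmin.copy(),
                              self.tmax.copy(), self.origin,
                              self.cell_size, self.nodata)


@dataclass
class AreaMask:
    """Binary (0/1) raster marking an analysis region, e.g. growing areas."""

    mask: GridRaster

    def __post_init__(self) -> None:
        vals = self.mask.values
        ok = self.mask.valid
        if not np.all(np.isin(vals[ok], (0.0, 1.0))):
            raise ValueError("AreaMask must be binary")

    @property
    def boolean(self) -> np.ndarray:
        return self.mask.valid & (self.mask.values == 1.0)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def write_raster(r: GridRaster, path: str) -> None:
    """Write a raster; format chosen by extension (.asc ASCII, .nc NetCDF)."""
    ext = os.path.splitext(path)[1].lower()
    if ext == ".asc":
        _write_ascii(r, path)
    elif ext == ".nc":
        write_stack({"band1": r.values[None]}, r, path)
    else:
        raise ValueError(f"unsupported raster format: {ext}")


def read_raster(path: str) -> GridRaster:
    """Read a single-band raster from ESRI ASCII or NetCDF."""
    if not os.path.exists(path):
        raise IOError(f"no such file: {path}")
    ext = os.path.splitext(path)[1].lower()
    if ext == ".asc":
        return _read_ascii(path)
    if ext == ".nc":
        stacks, geom = read_stack(path)
        name = next(iter(stacks))
        return geom.with_values(stacks[name][0])
    raise ValueError(f"unsupported raster format: {ext}")


def _write_ascii(r: GridRaster, path: str) -> None:
    rows, cols = r.shape
    xll = r.origin[0]
    yll = r.origin[1] - rows * r.cell_size
    with open(path, "w") as fh:
        fh.write(f"ncols {cols}\n")
        fh.write(f"nrows {rows}\n")
        fh.write(f"xllcorner {xll:.10f}\n")
        fh.write(f"yllcorner {yll:.10f}\n")
        fh.write(f"cellsize {r.cell_size:.10f}\n")
        fh.write(f"NODATA_value {r.nodata:g}\n")
        for row in r.values:
            fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")


def _read_ascii(path: str) -> GridRaster:
    header: dict[str, float] = {}
    data_lines: list[str] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in ("ncols", "nrows", "xllcorner", "yllcorner",
                       "cellsize", "nodata_value") and len(parts) == 2:
                header[key] = float(parts[1])
            else:
                data_lines.append(line)
    for req in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if req not in header:
            raise ValueError(f"ASCII grid missing header field {req}")
    rows, cols = int(header["nrows"]), int(header["ncols"])
    values = np.array(" ".join(data_lines).split(), dtype=float)
    if values.size != rows * cols:
        raise ValueError("ASCII grid data size does not match header")
    cell = header["cellsize"]
    origin = (header["xllcorner"], header["yllcorner"] + rows * cell)
    return GridRaster(values.reshape(rows, cols), origin, cell,
                      header.get("nodata_value", DEFAULT_NODATA))


def write_stack(layers: dict[str, np.ndarray], geom: GridRaster,
                path: str) -> None:
    """Write named (layer, row, col) stacks sharing one geometry to NetCDF."""
    rows, cols = geom.shape
    lon = geom.origin[0] + (np.arange(cols) + 0.5) * geom.cell_size
    lat = geom.origin[1] - (np.arange(rows) + 0.5) * geom.cell_size
    data = {}
    for name, stack in layers.items():
        stack = np.asarray(stack, dtype=float)
        data[name] = (("layer", "lat", "lon"), stack)
    ds = xr.Dataset(data, coords={"lat": lat, "lon": lon})
    ds.attrs["cell_size"] = geom.cell_size
    ds.attrs["nodata"] = geom.nodata
    ds.to_netcdf(path, engine="scipy")


def read_stack(path: str) -> tuple[dict[str, np.ndarray], GridRaster]:
    """Inverse of :func:`write_stack`: named stacks plus a geometry raster."""
    with xr.open_dataset(path, engine="scipy") as ds:
        ds = ds.load()
    cell = float(ds.attrs["cell_size"])
    nodata = float(ds.attrs.get("nodata", DEFAULT_NODATA))
    lon = ds["lon"].values
    lat = ds["lat"].values
    origin = (float(lon[0] - cell / 2), float(lat[0] + cell / 2))
    stacks = {str(k): np.asarray(v.values, dtype=float)
              for k, v in ds.data_vars.items()}
    rows, cols = lat.size, lon.size
    geom = GridRaster(np.zeros((rows, cols)), origin, cell, nodata)
    return stacks, geom


def write_monthly_climate(mc: MonthlyClimate, path: str) -> None:
    geom = mc.geometry_raster()
    write_stack({"prec": mc.prec, "tmin": mc.tmin, "tmax": mc.tmax},
                geom, path)


def read_monthly_climate(path: str) -> MonthlyClimate:
    stacks, geom = read_stack(path)
    return MonthlyClimate(stacks["prec"], stacks["tmin"], stacks["tmax"],
                          geom.origin, geom.cell_size, geom.nodata)


# ---------------------------------------------------------------------------
# resampling and distance
# ---------------------------------------------------------------------------

def aggregate_mean(r: GridRaster, factor: int) -> GridRaster:
    """Block-mean aggregation to a coarser grid.

    Each output cell is the mean of the valid cells of a factor x factor
    input block; trailing partial blocks are averaged over the cells that
    exist.  All-nodata blocks become nodata.  Output cell size is
    ``factor * cell_size``.
    """
    if not isinstance(factor, (int, np.integer)) or factor <= 0:
        raise ValueError("factor must be a positive integer")
    if factor == 1:
        return r.copy()
    rows, cols = r.shape
    out_rows = int(np.ceil(rows / factor))
    out_cols = int(np.ceil(cols / factor))
    vals = r.masked()
    out = np.full((out_rows, out_cols), r.nodata)
    for i in range(out_rows):
        for j in range(out_cols):
            block = vals[i * factor:(i + 1) * factor,
                         j * factor:(j + 1) * factor]
            if np.any(np.isfinite(block)):
                out[i, j] = np.nanmean(block)
    return GridRaster(out, r.origin, r.cell_size * factor, r.nodata)


def haversine_km(p1, p2) -> float:
    """Great-circle distance in km between (lon, lat) points, R = 6371 km.

    Accepts scalars or broadcastable arrays of coordinates.
    """
    lon1, lat1 = np.radians(np.asarray(p1[0], dtype=float)), np.radians(
        np.asarray(p1[1], dtype=float))
    lon2, lat2 = np.radians(np.asarray(p2[0], dtype=float)), np.radians(
        np.asarray(p2[1], dtype=float))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(
        dlon / 2) ** 2
    a = np.clip(a, 0.0, 1.0)
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))
    return float(d) if np.ndim(d) == 0 else d
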