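"""Raster readers and writers.

Two formats are supported, chosen by file extension:

``.asc``
    ESRI ASCII grid — plain-text, single band, square cells.  The CRS is
    carried in a ``.prj`` sidecar next to the raster (the format itself has
    no CRS field); a raster without one is rejected, since an ungeoreferenced
    layer cannot be harmonized.
``.nc``
    NetCDF (classic format, written through xarray's scipy engine) — single
    or multi-band grids and annual stacks, with the geotransform, CRS and
    nodata stored as global attributes.

Float layers round-trip losslessly at float32/float64 precision; nodata
cells are written as the sentinel and come back as NaN internally.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import xarray as xr

from .grids import DEFAULT_NODATA, AnnualStack, Grid

_TRANSFORM_ATTR = "geotransform"
_CRS_ATTR = "crs"
_NODATA_ATTR = "nodata"


# ---------------------------------------------------------------------------
# ESRI ASCII grid
# ---------------------------------------------------------------------------

def _read_asc(path: Path) -> Grid:
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.read().split("\n")
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:
            break
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ValueError(f"{path}: malformed ASCII grid header (missing {key})")
    nodata = header.get("nodata_value", DEFAULT_NODATA)
    body = "\n".join(lines[n_header:])
    values = np.loadtxt(body.splitlines(), ndmin=2)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if values.shape != (nrows, ncols):
        raise ValueError(
            f"{path}: data shape {values.shape} does not match header ({nrows}, {ncols})"
        )
    prj = path.with_suffix(".prj")
    if not prj.exists():
        raise ValueError(f"{path}: no CRS — expected sidecar {prj.name}")
    crs = prj.read_text().strip()
    cell = header["cellsize"]
    # header gives the lower-left corner; transform origin is the upper-left
    transform = (
        header["xllcorner"], cell, 0.0,
        header["yllcorner"] + cell * nrows, 0.0, -cell,
    )
    if np.allclose(values, np.round(values)) and np.allclose(nodata, round(nodata)):
        ivals = values.astype(np.int64)
        return Grid(ivals, transform, crs, nodata=int(round(nodata)))
    values[values == nodata] = np.nan
    return Grid(values, transform, crs, nodata=nodata)


def _write_asc(grid: Grid, path: Path) -> None:
    x0, dx, xs, y0, ys, dy = grid.transform
    if xs or ys:
        raise ValueError("ASCII grid cannot represent skewed geotransforms")
    if not np.isclose(dx, -dy):
        raise ValueError("ASCII grid requires square cells; write NetCDF instead")
    nrows, ncols = grid.shape
    if grid.is_float:
        vals = grid.values.copy()
        vals[~np.isfinite(vals)] = grid.nodata
        fmt = "%.9g"
    else:
        vals = grid.values
        fmt = "%d"
    header = (
        f"ncols {ncols}\n"
        f"nrows {nrows}\n"
        f"xllcorner {x0:.9g}\n"
        f"yllcorner {y0 + dy * nrows:.9g}\n"
        f"cellsize {dx:.9g}\n"
        f"NODATA_value {grid.nodata:.9g}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt=fmt)
    path.with_suffix(".prj").write_text(grid.crs + "\n")


# ---------------------------------------------------------------------------
# NetCDF grids and stacks
# ---------------------------------------------------------------------------

def _grid_attrs(grid: Grid) -> dict:
    return {
        _TRANSFORM_ATTR: list(grid.transform),
        _CRS_ATTR: grid.crs,
        _NODATA_ATTR: float(grid.nodata),
    }


def _attrs_to_geometry(attrs) -> tuple[tuple, str, float]:
    if _TRANSFORM_ATTR not in attrs:
        raise ValueError("NetCDF raster is missing its geotransform attribute")
    if _CRS_ATTR not in attrs or not str(attrs[_CRS_ATTR]):
        raise ValueError("NetCDF raster has no CRS")
    transform = tuple(float(t) for t in np.asarray(attrs[_TRANSFORM_ATTR]).ravel())
    return transform, str(attrs[_CRS_ATTR]), float(attrs[_NODATA_ATTR])


def _write_nc(grid: Grid, path: Path) -> None:
    if grid.is_float:
        vals = grid.values.copy()
        vals[~np.isfinite(vals)] = grid.nodata
    else:
        vals = grid.values.astype(np.int32)
    ds = xr.Dataset({"band_1": (("y", "x"), vals)}, attrs=_grid_attrs(grid))
    ds.to_netcdf(path, engine="scipy")


def _read_nc(path: Path, band: int) -> Grid:
    with xr.open_dataset(path, engine="scipy") as ds:
        ds.load()
    transform, crs, nodata = _attrs_to_geometry(ds.attrs)
    band_vars = sorted(v for v in ds.data_vars if str(v).startswith("band_"))
    if band_vars:
        if not 1 <= band <= len(band_vars):
            raise ValueError(f"{path}: band {band} out of range 1..{len(band_vars)}")
        arr = ds[f"band_{band}"].values
    elif "year" in ds.dims:
        raise ValueError(f"{path} is an annual stack; use read_stack()")
    else:
        name = list(ds.data_vars)[0]
        arr = ds[name].values
    if np.issubdtype(arr.dtype, np.integer):
        return Grid(arr.astype(np.int64), transform, crs, nodata=int(round(nodata)))
    arr = arr.astype(float)
    arr[arr == nodata] = np.nan
    return Grid(arr, transform, crs, nodata=nodata)


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

def read_raster(path: str | os.PathLike, band: int = 1) -> Grid:
    """Read one band of a georeferenced raster into a :class:`Grid`.

    Nodata cells are mapped to the internal sentinel (NaN for float layers);
    the geometry (geotransform + CRS) is preserved exactly.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in {".asc", ".txt"}:
        if band != 1:
            raise ValueError("ASCII grids are single-band")
        return _read_asc(path)
    if suffix == ".nc":
        return _read_nc(path, band)
    raise ValueError(f"unsupported raster format: {path.suffix!r}")


def write_raster(grid: Grid, path: str | os.PathLike, *, extra_bands=None) -> None:
    """Write a :class:`Grid` to ``.asc`` or ``.nc`` (by extension).

    ``extra_bands`` (NetCDF only) appends further grids on the same geometry
    as bands 2, 3, ...
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    suffix = path.suffix.lower()
    if suffix in {".asc", ".txt"}:
        if extra_bands:
            raise ValueError("ASCII grids are single-band")
        _write_asc(grid, path)
    elif suffix == ".nc":
        if not extra_bands:
            _write_nc(grid, path)
        else:
            bands = [grid, *extra_bands]
            for b in bands[1:]:
                if not b.same_geometry(grid):
                    raise ValueError("extra bands must share geometry")
            data = {}
            for i, b in enumerate(bands, start=1):
                if b.is_float:
                    vals = b.values.copy()
                    vals[~np.isfinite(vals)] = grid.nodata
                else:
                    vals = b.values.astype(np.int32)
                data[f"band_{i}"] = (("y", "x"), vals)
            xr.Dataset(data, attrs=_grid_attrs(grid)).to_netcdf(path, engine="scipy")
    else:
        raise ValueError(f"unsupported raster format: {path.suffix!r}")


def write_stack(stack: AnnualStack, path: str | os.PathLike) -> None:
    """Write an :class:`AnnualStack` as a NetCDF cube with a year dimension.

    Integer (categorical) stacks keep their dtype and nodata sentinel."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    ref = stack.geometry
    is_int = not ref.is_float
    attrs = _grid_attrs(ref)
    if is_int:
        arr = np.stack([g.values for g in stack.layers]).astype(np.int32)
        attrs["integer_coded"] = 1
    else:
        arr = stack.to_array()
        arr = np.where(np.isfinite(arr), arr, ref.nodata)
    ds = xr.Dataset(
        {"value": (("year", "y", "x"), arr)},
        coords={"year": np.asarray(stack.years, dtype=np.int32)},
        attrs=attrs,
    )
    ds.to_netcdf(path, engine="scipy")


def read_stack(path: str | os.PathLike) -> AnnualStack:
    """Read an annual stack written by :func:`write_stack`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with xr.open_dataset(path, engine="scipy") as ds:
        ds.load()
    transform, crs, nodata = _attrs_to_geometry(ds.attrs)
    years = [int(y) for y in ds["year"].values]
    if int(ds.attrs.get("integer_coded", 0)):
        arr = ds["value"].values.astype(np.int64)
        layers = [
            Grid(arr[i], transform, crs, nodata=int(round(nodata)))
            for i in range(arr.shape[0])
        ]
        return AnnualStack(years=years, layers=layers)
    arr = ds["value"].values.astype(float)
    arr[arr == nodata] = np.nan
    template = Grid(arr[0], transform, crs, nodata=nodata)
    return AnnualStack.from_array(years, arr, template)
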