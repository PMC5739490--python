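"""NetCDF readers/writers for raster cubes and land-cover maps.

Files are CF-style NetCDF (classic format, via xarray's scipy engine) with
``time``/``lat``/``lon`` coordinates, a ``units`` attribute on the data
variable and NaN (float) or a ``_FillValue`` (integer) for missing cells.
Writes add no creation timestamp, so two writes of the same cube are
byte-identical.
"""
from __future__ import annotations

import os

import numpy as np
import xarray as xr

from .grids import GridSpec, LandCoverMap, RasterCube

_TIME_ENC = {"units": "days since 1900-01-01", "calendar": "standard", "dtype": "int32"}


def _grid_from_coords(lat: np.ndarray, lon: np.ndarray, label: str = "") -> GridSpec:
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if lat.size > 1:
        steps = np.diff(lat)
        if np.ptp(np.abs(steps)) > 1e-6:
            raise ValueError("latitude spacing is not uniform")
        cell = abs(float(steps[0]))
    elif lon.size > 1:
        cell = abs(float(np.diff(lon)[0]))
    else:
        raise ValueError("cannot infer cell size from a 1x1 grid")
    lat0 = lat.max() + cell / 2  # row 0 northernmost
    lon0 = lon.min() - cell / 2
    return GridSpec(lat.size, lon.size, cell, (lon0, lat0), label)


def _cube_to_dataset(cube: RasterCube) -> xr.Dataset:
    grid = cube.grid
    da = xr.DataArray(
        cube.values,
        dims=("time", "lat", "lon"),
        coords={
            "time": cube.times.astype("datetime64[ns]"),
            "lat": grid.lats,
            "lon": grid.lons,
        },
        name=cube.variable,
        attrs={"units": cube.units or "1", "cadence": cube.cadence},
    )
    ds = da.to_dataset()
    ds["lat"].attrs.update(units="degrees_north", standard_name="latitude")
    ds["lon"].attrs.update(units="degrees_east", standard_name="longitude")
    ds.attrs["Conventions"] = "CF-1.8"
    if grid.id:
        ds.attrs["grid_id"] = grid.id
    return ds


def write_cube(cube: RasterCube, path: str | os.PathLike) -> str:
    """Write ``cube`` as CF-style NetCDF; returns the path written."""
    ds = _cube_to_dataset(cube)
    ds.to_netcdf(path, engine="scipy", encoding={"time": _TIME_ENC})
    return str(path)


def read_cube(path: str | os.PathLike, variable: str | None = None) -> RasterCube:
    """Read a (time, lat, lon) NetCDF variable into a :class:`RasterCube`.

    The time axis is sorted ascending on read (values reordered to match);
    missing data come back as NaN.
    """
    with xr.open_dataset(path, engine="scipy", decode_timedelta=False) as ds:
        ds.load()
    if "time" not in ds.coords and "time" not in ds.dims:
        raise ValueError(f"{path}: no time coordinate")
    if variable is None:
        candidates = [v for v in ds.data_vars if "time" in ds[v].dims]
        if len(candidates) != 1:
            raise ValueError(
                f"{path}: specify a variable, found {sorted(ds.data_vars)}"
            )
        variable = candidates[0]
    elif variable not in ds.data_vars:
        raise ValueError(f"{path}: variable {variable!r} not found")
    da = ds[variable].transpose("time", "lat", "lon")
    da = da.sortby("time")
    times = da["time"].values.astype("datetime64[D]")
    cadence = da.attrs.get("cadence") or _infer_cadence(times)
    grid = _grid_from_coords(da["lat"].values, da["lon"].values,
                             ds.attrs.get("grid_id", ""))
    values = da.values.astype(float)
    if grid.lats[0] < grid.lats[-1]:  # stored south-up: flip to row 0 = north
        values = values[:, ::-1, :]
    return RasterCube(values, times, cadence, grid, variable,
                      da.attrs.get("units", ""))


def _infer_cadence(times: np.ndarray) -> str:
    if len(times) < 2:
        return "annual"
    step = int(np.median(np.diff(times).astype(int)))
    if step <= 1:
        return "daily"
    if step <= 16:
        return "composite-15d"
    if step <= 31:
        return "monthly"
    return "annual"


def write_landcover(lc: LandCoverMap, path: str | os.PathLike) -> str:
    grid = lc.grid
    da = xr.DataArray(
        lc.codes.astype(np.int32),
        dims=("lat", "lon"),
        coords={"lat": grid.lats, "lon": grid.lons},
        name="landcover",
        attrs={"scheme": lc.scheme},
    )
    ds = da.to_dataset()
    ds.attrs["Conventions"] = "CF-1.8"
    ds.to_netcdf(path, engine="scipy")
    return str(path)


def read_landcover(path: str | os.PathLike) -> LandCoverMap:
    with xr.open_dataset(path, engine="scipy", decode_timedelta=False) as ds:
        ds.load()
    da = ds["landcover"].transpose("lat", "lon")
    grid = _grid_from_coords(da["lat"].values, da["lon"].values)
    codes = da.values
    if grid.lats[0] < grid.lats[-1]:
        codes = codes[::-1, :]
    return LandCoverMap(codes.astype(np.int64), grid, da.attrs.get("scheme", "IGBP-17"))
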