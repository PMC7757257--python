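"""NetCDF reading/writing for :class:`~gppclim.grids.GriddedSeries`.

Files are classic NetCDF with CF-style ``months since`` time units, written
and read through xarray.  Ingest normalises grids to the internal convention
(south-to-north latitudes, -180..180 longitudes) and maps missing values into
the boolean mask.
"""

from __future__ import annotations

import numpy as np
import xarray as xr

from .grids import Grid, GriddedSeries

_FILL = 9.969209968386869e36  # default NetCDF fill


def _time_to_year_month(da: xr.DataArray) -> tuple[np.ndarray, np.ndarray]:
    units = da.attrs.get("units", "")
    if not units.startswith("months since "):
        raise ValueError(f"time units must be 'months since YYYY-MM', got {units!r}")
    origin = units.removeprefix("months since ").strip()
    y0, m0 = (int(p) for p in origin.split("-")[:2])
    offsets = np.asarray(da.values, dtype=int)
    code = (y0 * 12 + (m0 - 1)) + offsets
    return code // 12, code % 12 + 1


def write_gridded(path, field: GriddedSeries, variable: str | None = None) -> None:
    """Write a GriddedSeries as a classic NetCDF file."""
    variable = variable or field.name
    y0, m0 = int(field.years[0]), int(field.months[0])
    offsets = (field.years * 12 + field.months - 1) - (y0 * 12 + m0 - 1)
    vals = np.where(field.missing_mask, np.nan, field.values)
    ds = xr.Dataset(
        {variable: (("time", "lat", "lon"), vals, {"units": field.units, "_FillValue": _FILL})},
        coords={
            "time": ("time", offsets.astype(np.int32), {"units": f"months since {y0:04d}-{m0:02d}"}),
            "lat": ("lat", field.grid.lat_centers, {"units": "degrees_north"}),
            "lon": ("lon", field.grid.lon_centers, {"units": "degrees_east"}),
        },
    )
    ds.to_netcdf(path, engine="scipy")


def read_gridded(path, variable: str) -> GriddedSeries:
    """Read one variable from a NetCDF file into a GriddedSeries.

    Raises a descriptive error if the variable, a time/lat/lon dimension, or
    the units attribute is absent.  Non-internal grid orientations are
    normalised (latitude flipped to ascending; longitudes wrapped to
    -180..180 and rolled to ascending order).
    """
    with xr.open_dataset(path, engine="scipy", decode_times=False, mask_and_scale=True) as ds:
        if variable not in ds:
            raise KeyError(f"variable {variable!r} not in file (has: {sorted(ds.data_vars)})")
        da = ds[variable]
        for dim in ("time", "lat", "lon"):
            if dim not in da.dims:
                raise ValueError(f"variable {variable!r} lacks required dimension {dim!r}")
        units = da.attrs.get("units")
        if units is None:
            raise ValueError(f"variable {variable!r} has no units attribute")
        years, months = _time_to_year_month(ds["time"])
        da = da.transpose("time", "lat", "lon")

        lat = np.asarray(da["lat"].values, float)
        lon = np.asarray(da["lon"].values, float)
        vals = np.asarray(da.values, float)
        if lat.size > 1 and lat[0] > lat[-1]:  # north-to-south -> flip
            lat = lat[::-1]
            vals = vals[:, ::-1, :]
        lon_wrapped = np.where(lon >= 180.0, lon - 360.0, lon)
        order = np.argsort(lon_wrapped)
        if not np.array_equal(order, np.arange(lon.size)):
            lon_wrapped = lon_wrapped[order]
            vals = vals[:, :, order]
        vals = np.where(np.abs(vals) >= _FILL / 2, np.nan, vals)
        grid = Grid(lat, lon_wrapped)
        return GriddedSeries(vals, years, months, grid, units=str(units),
                             missing_mask=~np.isfinite(vals), name=variable)
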