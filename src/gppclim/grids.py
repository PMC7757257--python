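"""Gridded data model and spherical-grid geometry.

The whole pipeline moves monthly ``time x lat x lon`` fields around; this
module defines the containers (:class:`Grid`, :class:`GriddedSeries`,
:class:`RegionDefinition`, :class:`EnsembleSet`), cell-area geometry, and the
area-weighted reductions used for regional integration.

Internal coordinate convention: latitudes are cell centers stored
south-to-north, longitudes are cell centers stored -180 -> 180.  Readers
normalise other conventions on ingest so that downstream code can rely on a
single orientation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

EARTH_RADIUS_KM = 6371.0

#: Unit-conversion table between the flux/state units the pipeline mixes.
#: Conversion factors are multiplicative; month-dependent conversions
#: (gC/m2/month <-> gC/m2/yr) use a nominal 1/12 year month.
UNIT_FACTORS = {
    ("gC/m2/month", "gC/m2/yr"): 12.0,
    ("gC/m2/yr", "gC/m2/month"): 1.0 / 12.0,
}

#: gC -> PgC
GRAMS_TO_PG = 1e-15


def convert_units(values: np.ndarray, from_unit: str, to_unit: str) -> np.ndarray:
    """Convert an array between registered units (no-op if identical)."""
    if from_unit == to_unit:
        return values
    try:
        return values * UNIT_FACTORS[(from_unit, to_unit)]
    except KeyError:
        raise ValueError(f"no registered conversion {from_unit!r} -> {to_unit!r}") from None


@dataclass(frozen=True)
class Grid:
    """A regular lat/lon grid of cell centers on a sphere.

    Parameters
    ----------
    lat_centers, lon_centers
        Cell-center coordinates in degrees; latitudes must be strictly inside
        (-90, 90) and uniformly spaced.
    earth_radius_km
        Sphere radius; the default is the mean Earth radius.
    """

    lat_centers: np.ndarray
    lon_centers: np.ndarray
    earth_radius_km: float = EARTH_RADIUS_KM

    def __post_init__(self):
        lat = np.asarray(self.lat_centers, dtype=float)
        lon = np.asarray(self.lon_centers, dtype=float)
        object.__setattr__(self, "lat_centers", lat)
        object.__setattr__(self, "lon_centers", lon)
        if lat.ndim != 1 or lon.ndim != 1 or lat.size == 0 or lon.size == 0:
            raise ValueError("lat_centers and lon_centers must be non-empty 1-D arrays")
        if np.any(np.abs(lat) >= 90.0):
            raise ValueError("latitude centers must satisfy |lat| < 90")
        dlat = np.diff(lat)
        if lat.size > 1 and not np.allclose(dlat, dlat[0]):
            raise ValueError("latitude centers must be uniformly spaced")
        if np.any(np.abs(lat) + self.cell_width / 2 > 90.0 + 1e-9):
            raise ValueError("grid cells may not cross a pole")

    @property
    def cell_width(self) -> float:
        """Angular cell width in degrees (uniform)."""
        if self.lat_centers.size > 1:
            return float(abs(self.lat_centers[1] - self.lat_centers[0]))
        return float(abs(self.lon_centers[1] - self.lon_centers[0]))

    @property
    def shape(self) -> tuple[int, int]:
        return (self.lat_centers.size, self.lon_centers.size)

    @classmethod
    def global_grid(cls, cell_width: float) -> "Grid":
        """A global grid of the given angular resolution, e.g. 0.5 or 10."""
        half = cell_width / 2.0
        lat = np.arange(-90.0 + half, 90.0, cell_width)
        lon = np.arange(-180.0 + half, 180.0, cell_width)
        return cls(lat, lon)

    def cell_areas(self) -> np.ndarray:
        """Per-cell areas in m2, shape (nlat, nlon).

        area = R^2 * dlon * (sin(lat_top) - sin(lat_bottom)); exact on the
        sphere for rectangular lat/lon cells, so the global sum equals
        4*pi*R^2 up to float rounding.
        """
        r_m = self.earth_radius_km * 1e3
        half = np.deg2rad(self.cell_width) / 2.0
        lat = np.deg2rad(self.lat_centers)
        band = r_m**2 * np.deg2rad(self.cell_width) * (np.sin(lat + half) - np.sin(lat - half))
        areas = np.repeat(band[:, None], self.lon_centers.size, axis=1)
        if np.any(areas <= 0):
            raise ValueError("non-positive cell area; check grid definition")
        return areas


@dataclass
class RegionDefinition:
    """A named boolean cell mask (latitude band, biome class, or custom)."""

    name: str
    mask: np.ndarray
    kind: Literal["latitude-band", "biome", "custom"] = "custom"

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError(f"region {self.name!r} selects no cells")

    @classmethod
    def latitude_band(cls, grid: Grid, name: str, lat_min: float, lat_max: float) -> "RegionDefinition":
        band = (grid.lat_centers >= lat_min) & (grid.lat_centers < lat_max)
        mask = np.repeat(band[:, None], grid.lon_centers.size, axis=1)
        return cls(name=name, mask=mask, kind="latitude-band")


def standard_regions(grid: Grid, northern_edge: float = 30.0, southern_edge: float = -30.0) -> dict[str, RegionDefinition]:
    """Global / Northern / Tropical / Southern latitude-band regions.

    Band edges default to +-30 degrees; they are configurable because the
    source bounds for these bands are not universal.
    """
    full = RegionDefinition("Global", np.ones(grid.shape, bool), kind="latitude-band")
    return {
        "Global": full,
        "Northern": RegionDefinition.latitude_band(grid, "Northern", northern_edge, 90.0),
        "Tropical": RegionDefinition.latitude_band(grid, "Tropical", southern_edge, northern_edge),
        "Southern": RegionDefinition.latitude_band(grid, "Southern", -90.0, southern_edge),
    }


@dataclass
class GriddedSeries:
    """A monthly gridded field: values (T, nlat, nlon) + mask + time axis.

    ``missing_mask`` is True where a value is missing; reductions are
    mask-aware so NaNs never propagate silently.  The time axis is stored as
    parallel integer arrays ``years`` / ``months`` and must be contiguous
    whole months.
    """

    values: np.ndarray
    years: np.ndarray
    months: np.ndarray
    grid: Grid
    units: str
    missing_mask: np.ndarray | None = None
    name: str = "field"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.years = np.asarray(self.years, dtype=int)
        self.months = np.asarray(self.months, dtype=int)
        if self.values.ndim != 3:
            raise ValueError("values must be (time, lat, lon)")
        if self.values.shape[1:] != self.grid.shape:
            raise ValueError(f"values shape {self.values.shape[1:]} does not match grid {self.grid.shape}")
        if self.years.size != self.values.shape[0] or self.months.size != self.values.shape[0]:
            raise ValueError("time axis length does not match values")
        code = self.years * 12 + (self.months - 1)
        if self.years.size > 1 and not np.all(np.diff(code) == 1):
            raise ValueError("time axis must be contiguous whole months")
        if self.missing_mask is None:
            self.missing_mask = ~np.isfinite(self.values)
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
            if self.missing_mask.shape != self.values.shape:
                raise ValueError("missing_mask shape mismatch")
            self.missing_mask = self.missing_mask | ~np.isfinite(self.values)

    # -- time helpers ---------------------------------------------------
    @property
    def n_times(self) -> int:
        return self.values.shape[0]

    @property
    def n_years(self) -> int:
        return int(np.unique(self.years).size)

    def masked(self) -> np.ma.MaskedArray:
        return np.ma.MaskedArray(self.values, mask=self.missing_mask)

    def copy_with(self, **changes) -> "GriddedSeries":
        return dataclasses.replace(self, **changes)

    def complete_years(self) -> np.ndarray:
        """Years for which all 12 calendar months are present on the axis."""
        years, counts = np.unique(self.years, return_counts=True)
        return years[counts == 12]

    def annual_means(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(years, annual values (Y, nlat, nlon), annual missing mask).

        Only complete calendar years enter; a year's cell is missing if any
        of its 12 months is missing there.
        """
        years = self.complete_years()
        if years.size == 0:
            raise ValueError("no complete calendar year on the time axis")
        out = np.empty((years.size,) + self.grid.shape)
        miss = np.zeros((years.size,) + self.grid.shape, bool)
        for k, y in enumerate(years):
            sel = self.years == y
            block = self.values[sel]
            mblock = self.missing_mask[sel]
            miss[k] = mblock.any(axis=0)
            out[k] = np.where(miss[k], np.nan, block.mean(axis=0))
        return years, out, miss


@dataclass
class EnsembleSet:
    """An ordered collection of same-grid, same-axis members of one product."""

    members: list[GriddedSeries]
    product_name: str = "product"

    def __post_init__(self):
        if not self.members:
            raise ValueError("an ensemble needs at least one member")
        ref = self.members[0]
        for m in self.members[1:]:
            if m.values.shape != ref.values.shape:
                raise ValueError("ensemble members must share shape")
            if not (np.array_equal(m.years, ref.years) and np.array_equal(m.months, ref.months)):
                raise ValueError("ensemble members must share the time axis")
            if m.units != ref.units:
                raise ValueError("ensemble members must share units")

    @property
    def n_members(self) -> int:
        return len(self.members)

    @property
    def grid(self) -> Grid:
        return self.members[0].grid

    @property
    def units(self) -> str:
        return self.members[0].units

    def mean(self) -> GriddedSeries:
        stack = np.ma.stack([m.masked() for m in self.members])
        mu = stack.mean(axis=0)
        return self.members[0].copy_with(
            values=mu.filled(np.nan), missing_mask=np.ma.getmaskarray(mu),
            name=f"{self.product_name}_mean",
        )

    def spread(self) -> GriddedSeries:
        """Per-element sample standard deviation (ddof=1); 0 for one member."""
        if self.n_members == 1:
            ref = self.members[0]
            return ref.copy_with(values=np.zeros_like(ref.values), name=f"{self.product_name}_spread")
        stack = np.ma.stack([m.masked() for m in self.members])
        sd = stack.std(axis=0, ddof=1)
        return self.members[0].copy_with(
            values=sd.filled(np.nan), missing_mask=np.ma.getmaskarray(sd),
            name=f"{self.product_name}_spread",
        )


# ---------------------------------------------------------------------------
# area-weighted reductions
# ---------------------------------------------------------------------------

def area_weighted_integral(
    field: GriddedSeries,
    region: RegionDefinition,
    mode: Literal["flux", "state"],
) -> np.ndarray:
    """Reduce a field over a region, masked cells excluded.

    ``flux`` mode integrates a gC/m2/yr (or gC/m2/month, converted) field to
    PgC/yr per time step; ``state`` mode returns the area-weighted mean in the
    field's own units.  An effectively empty region (all cells masked at some
    time step) raises rather than returning zero.
    """
    if region.mask.shape != field.grid.shape:
        raise ValueError("region mask does not match the field's grid")
    areas = field.grid.cell_areas()
    vals = field.values
    if mode == "flux":
        if field.units == "gC/m2/month":
            vals = convert_units(vals, "gC/m2/month", "gC/m2/yr")
        elif field.units != "gC/m2/yr":
            raise ValueError(f"flux integration expects carbon-flux units, got {field.units!r}")
    elif mode != "state":
        raise ValueError("mode must be 'flux' or 'state'")

    region3 = region.mask[None, :, :] & ~field.missing_mask
    if not region3.reshape(field.n_times, -1).any(axis=1).all():
        raise ValueError(f"region {region.name!r} has no unmasked cells at some time step")
    w = areas[None, :, :] * region3
    if mode == "flux":
        return (vals * w).sum(axis=(1, 2)) * GRAMS_TO_PG
    return (np.where(region3, vals, 0.0) * w).sum(axis=(1, 2)) / w.sum(axis=(1, 2))


def area_weighted_mean_map(map2d: np.ndarray, grid: Grid, mask: np.ndarray | None = None) -> float:
    """Area-weighted mean of a 2-D map over unmasked, finite cells."""
    areas = grid.cell_areas()
    ok = np.isfinite(map2d)
    if mask is not None:
        ok &= mask
    if not ok.any():
        raise ValueError("no cells to average")
    return float((map2d[ok] * areas[ok]).sum() / areas[ok].sum())


def regrid_coarsen(field: GriddedSeries, factor: int) -> GriddedSeries:
    """Area-weighted block-average onto a factor-coarser grid.

    Missing fine cells are excluded from each block mean; a coarse cell whose
    children are all missing is itself missing.  Factor 1 is the identity.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError("factor must be a positive integer")
    if factor == 1:
        return field.copy_with()
    ny, nx = field.grid.shape
    if ny % factor or nx % factor:
        raise ValueError(f"factor {factor} does not divide grid shape {(ny, nx)}")
    areas = field.grid.cell_areas()
    w = np.where(field.missing_mask, 0.0, areas[None, :, :])
    v = np.where(field.missing_mask, 0.0, field.values)
    T = field.n_times

    def block(a):  # (T, ny, nx) -> (T, ny/f, nx/f) block sums
        return a.reshape(T, ny // factor, factor, nx // factor, factor).sum(axis=(2, 4))

    wsum = block(w)
    with np.errstate(invalid="ignore", divide="ignore"):
        coarse = block(v * w) / wsum
    miss = wsum == 0.0
    coarse = np.where(miss, np.nan, coarse)
    lat = field.grid.lat_centers.reshape(ny // factor, factor).mean(axis=1)
    lon = field.grid.lon_centers.reshape(nx // factor, factor).mean(axis=1)
    grid = Grid(lat, lon, earth_radius_km=field.grid.earth_radius_km)
    return GriddedSeries(coarse, field.years, field.months, grid, field.units,
                         missing_mask=miss, name=field.name)


def vegetated_mask(products: Sequence[GriddedSeries], floor_gc_m2_yr: float = 10.0,
                   land_mask: np.ndarray | None = None) -> np.ndarray:
    """Cells whose multi-product mean annual GPP exceeds a floor.

    A pragmatic stand-in for a "vegetated land" mask: average the products'
    time-mean GPP (converted to gC/m2/yr) and keep cells above the floor,
    optionally intersected with a land mask.
    """
    means = []
    for p in products:
        m = p.masked().mean(axis=0)
        means.append(convert_units(m.filled(np.nan), p.units, "gC/m2/yr"))
    mean_gpp = np.nanmean(np.stack(means), axis=0)
    mask = np.isfinite(mean_gpp) & (mean_gpp > floor_gc_m2_yr)
    if land_mask is not None:
        mask &= np.asarray(land_mask, bool)
    return mask
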