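"""Satellite-driven light-use-efficiency (LUE) GPP model.

GPP = FPAR x PAR x LUE_max x f(Tmin) x f(VPD), per cell and month, with
biome-dependent parameters.  The temperature and vapour-pressure-deficit
scalars are piecewise-linear clamped ramps in the MOD17 convention: f(Tmin)
rises from 0 at ``tmin_min`` to 1 at ``tmin_max``; f(VPD) falls from 1 at
``vpd_min`` (moist air, no stress) to 0 at ``vpd_max``.

Parameter values are user data, not constants: two illustrative biome tables
ship as package defaults to form the two-member structural ensemble, and any
table can be loaded from the YAML config.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import EnsembleSet, Grid, GriddedSeries

PAR_FRACTION = 0.45  # fraction of downward shortwave that is PAR


@dataclass(frozen=True)
class BiomeParameters:
    """LUE parameters of one biome class."""

    lue_max: float    # gC per MJ absorbed PAR
    tmin_min: float   # degC; f(Tmin) = 0 at or below
    tmin_max: float   # degC; f(Tmin) = 1 at or above
    vpd_min: float    # Pa; f(VPD) = 1 at or below
    vpd_max: float    # Pa; f(VPD) = 0 at or above

    def __post_init__(self):
        if self.lue_max <= 0:
            raise ValueError("LUE_max must be positive")
        if self.tmin_min >= self.tmin_max:
            raise ValueError("require tmin_min < tmin_max")
        if self.vpd_min >= self.vpd_max:
            raise ValueError("require vpd_min < vpd_max")


@dataclass
class BiomeParameterTable:
    """Mapping biome class id -> :class:`BiomeParameters`."""

    params: dict[int, BiomeParameters]
    name: str = "table"

    def covers(self, biome_map: np.ndarray) -> bool:
        return set(np.unique(biome_map)).issubset(self.params)

    def arrays_for(self, biome_map: np.ndarray) -> dict[str, np.ndarray]:
        """Expand the per-biome scalars to per-cell maps."""
        missing = set(np.unique(biome_map)) - set(self.params)
        if missing:
            raise KeyError(f"biome classes {sorted(missing)} absent from table {self.name!r}")
        out = {}
        for attr in ("lue_max", "tmin_min", "tmin_max", "vpd_min", "vpd_max"):
            lut = {b: getattr(p, attr) for b, p in self.params.items()}
            out[attr] = np.vectorize(lut.get, otypes=[float])(biome_map)
        return out

    @classmethod
    def from_dict(cls, d: dict, name: str = "table") -> "BiomeParameterTable":
        return cls({int(k): BiomeParameters(**v) for k, v in d.items()}, name=name)


def default_parameter_tables() -> tuple[BiomeParameterTable, BiomeParameterTable]:
    """Two illustrative biome tables forming the structural ensemble.

    Biome ids: 0 = evergreen forest, 1 = deciduous forest, 2 = grassland /
    savanna, 3 = shrubland.  Values are representative of published MOD17-
    style parameterisations; they are defaults, not calibrated constants.
    """
    a = BiomeParameterTable({
        0: BiomeParameters(1.00, -8.0, 8.5, 800.0, 3000.0),
        1: BiomeParameters(1.20, -6.0, 9.9, 650.0, 1650.0),
        2: BiomeParameters(0.85, -8.0, 12.0, 650.0, 4600.0),
        3: BiomeParameters(0.77, -8.0, 8.8, 650.0, 4100.0),
    }, name="set_a")
    b = BiomeParameterTable({
        0: BiomeParameters(1.17, -8.0, 9.1, 800.0, 3100.0),
        1: BiomeParameters(1.04, -6.0, 9.5, 650.0, 2400.0),
        2: BiomeParameters(0.68, -8.0, 11.4, 650.0, 4900.0),
        3: BiomeParameters(0.84, -8.0, 8.6, 650.0, 4400.0),
    }, name="set_b")
    return a, b


def _ramp_up(x: np.ndarray, lo, hi) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        return np.clip((x - lo) / (hi - lo), 0.0, 1.0)


def f_tmin(tmin, tmin_min, tmin_max):
    """Minimum-temperature scalar: 0 below the ramp, 1 above, linear between."""
    if np.any(np.asarray(tmin_min) >= np.asarray(tmin_max)):
        raise ValueError("require tmin_min < tmin_max")
    return _ramp_up(np.asarray(tmin, float), tmin_min, tmin_max)


def f_vpd(vpd, vpd_min, vpd_max):
    """VPD stress scalar: 1 below vpd_min, 0 above vpd_max, falling linearly."""
    if np.any(np.asarray(vpd_min) >= np.asarray(vpd_max)):
        raise ValueError("require vpd_min < vpd_max")
    return 1.0 - _ramp_up(np.asarray(vpd, float), vpd_min, vpd_max)


def par_from_shortwave(shortwave, days_in_month):
    """Monthly PAR (MJ/m2/month) from mean downward shortwave (W/m2)."""
    sw = np.asarray(shortwave, float)
    if np.any(sw < 0):
        raise ValueError("shortwave must be non-negative")
    return PAR_FRACTION * sw * 86400.0 * np.asarray(days_in_month) * 1e-6


def saturation_vapour_pressure(temp_c) -> np.ndarray:
    """Magnus-formula saturation vapour pressure in Pa at temperature degC."""
    t = np.asarray(temp_c, float)
    return 610.94 * np.exp(17.625 * t / (t + 243.04))


def vpd_from_temperature(temp_c, relative_humidity) -> np.ndarray:
    """VPD (Pa) = (1 - RH) x saturation vapour pressure; a documented helper."""
    rh = np.asarray(relative_humidity, float)
    if np.any((rh < 0) | (rh > 1)):
        raise ValueError("relative humidity must be within [0, 1]")
    return (1.0 - rh) * saturation_vapour_pressure(temp_c)


_DAYS_IN_MONTH = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])


@dataclass
class LUEInputs:
    """Gridded monthly inputs of the LUE model."""

    fpar: GriddedSeries          # [0, 1]
    shortwave: GriddedSeries     # W/m2 (converted to PAR internally)
    tmin: GriddedSeries          # degC
    vpd: GriddedSeries           # Pa
    biome_map: np.ndarray        # integer class per cell

    def __post_init__(self):
        ref = self.fpar
        for s in (self.shortwave, self.tmin, self.vpd):
            if s.values.shape != ref.values.shape:
                raise ValueError("LUE input fields must share shape")
        if self.biome_map.shape != ref.grid.shape:
            raise ValueError("biome map must match the grid")
        if np.nanmin(self.fpar.values) < -1e-9 or np.nanmax(self.fpar.values) > 1 + 1e-9:
            raise ValueError("FPAR must lie within [0, 1]")


def compute_gpp_lue(inputs: LUEInputs, table: BiomeParameterTable) -> GriddedSeries:
    """Elementwise LUE GPP in gC/m2/month; masked where any input is missing."""
    p = table.arrays_for(inputs.biome_map)
    days = _DAYS_IN_MONTH[inputs.fpar.months - 1][:, None, None]
    par = par_from_shortwave(np.maximum(inputs.shortwave.values, 0.0), days)
    gpp = (inputs.fpar.values * par * p["lue_max"][None]
           * f_tmin(inputs.tmin.values, p["tmin_min"][None], p["tmin_max"][None])
           * f_vpd(inputs.vpd.values, p["vpd_min"][None], p["vpd_max"][None]))
    miss = (inputs.fpar.missing_mask | inputs.shortwave.missing_mask
            | inputs.tmin.missing_mask | inputs.vpd.missing_mask)
    return GriddedSeries(np.where(miss, np.nan, gpp), inputs.fpar.years, inputs.fpar.months,
                         inputs.fpar.grid, "gC/m2/month", missing_mask=miss,
                         name=f"gpp_lue_{table.name}")


def lue_ensemble(inputs: LUEInputs, tables: tuple[BiomeParameterTable, BiomeParameterTable] | None = None) -> EnsembleSet:
    """Two-member GPP ensemble from two parameter tables."""
    if tables is None:
        tables = default_parameter_tables()
    if len(tables) != 2:
        raise ValueError("the structural ensemble uses exactly two parameter tables")
    return EnsembleSet([compute_gpp_lue(inputs, t) for t in tables], product_name="rs_lue")
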