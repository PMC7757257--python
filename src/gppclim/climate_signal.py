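"""Anomalies, detrending, trend estimation, and climate-only extraction.

The analysis chain here: anomalies are deviations from the multi-year mean at
monthly, seasonal, or annual scale; trends are ordinary least-squares lines
against calendar year; interannual variability (IAV) is the 1-sigma spread of
the detrended annual series; and the climate-only signal of a paired
CO2-only / CO2-plus-climate simulation is obtained by removing the CO2-only
run's per-calendar-month trend from the full run.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import stats

from .grids import EnsembleSet, GriddedSeries

SEASON_MONTHS = {"DJF": (12, 1, 2), "MAM": (3, 4, 5), "JJA": (6, 7, 8), "SON": (9, 10, 11)}


@dataclass(frozen=True)
class TrendEstimate:
    """OLS linear-trend fit of a yearly series."""

    slope: float        # units per year
    intercept: float
    slope_se: float
    p_value: float      # two-tailed, t distribution with n-2 df
    n: int


def ols_trend(values: np.ndarray, years: np.ndarray | None = None) -> TrendEstimate:
    """Least-squares trend of a yearly series; NaNs are dropped.

    Requires at least three non-missing points and non-zero time variance.
    """
    y = np.asarray(values, float)
    t = np.arange(y.size, dtype=float) if years is None else np.asarray(years, float)
    ok = np.isfinite(y)
    y, t = y[ok], t[ok]
    if y.size < 3:
        raise ValueError(f"need >= 3 non-missing points for a trend, got {y.size}")
    if np.ptp(t) == 0:
        raise ValueError("time axis has zero variance")
    # a perfectly constant series has slope 0 and no sampling error
    if np.allclose(y, y[0]):
        return TrendEstimate(0.0, float(y[0]), 0.0, 1.0, y.size)
    res = stats.linregress(t, y)
    return TrendEstimate(float(res.slope), float(res.intercept), float(res.stderr),
                         float(res.pvalue), y.size)


def detrend(values: np.ndarray, years: np.ndarray | None = None) -> np.ndarray:
    """Remove the fitted OLS line but keep the series mean.

    Output has zero slope and exactly the input's mean; missing values stay
    missing.
    """
    y = np.asarray(values, float)
    t = np.arange(y.size, dtype=float) if years is None else np.asarray(years, float)
    ok = np.isfinite(y)
    fit = ols_trend(y, t)
    out = y.copy()
    out[ok] = y[ok] - (fit.slope * t[ok] + fit.intercept) + np.mean(y[ok])
    return out


def iav(annual_values: np.ndarray, years: np.ndarray | None = None) -> float:
    """Interannual variability: sample sd (ddof=1) of the detrended series."""
    y = np.asarray(annual_values, float)
    d = detrend(y, years)
    return float(np.std(d[np.isfinite(d)], ddof=1))


# -- vectorised per-cell versions -------------------------------------------

def trend_maps(annual: np.ndarray, years: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-cell OLS (slope, slope se, two-tailed p) of (Y, nlat, nlon) data.

    Cells with any missing year are returned as NaN (complete-case).
    """
    Y = annual.shape[0]
    if Y < 3:
        raise ValueError("need >= 3 years")
    t = np.asarray(years, float)
    tc = t - t.mean()
    sxx = (tc**2).sum()
    ok = np.isfinite(annual).all(axis=0)
    a = np.where(ok[None], annual, 0.0)
    slope = (tc[:, None, None] * (a - a.mean(axis=0))).sum(axis=0) / sxx
    resid = a - a.mean(axis=0) - slope[None] * tc[:, None, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        s2 = (resid**2).sum(axis=0) / (Y - 2)
        se = np.sqrt(s2 / sxx)
        tstat = np.where(se > 0, slope / se, np.inf * np.sign(slope + (slope == 0)))
    p = 2.0 * stats.t.sf(np.abs(tstat), df=Y - 2)
    p = np.where(se == 0, np.where(slope == 0, 1.0, 0.0), p)
    nanify = lambda x: np.where(ok, x, np.nan)
    return nanify(slope), nanify(se), nanify(p)


def detrend_cube(annual: np.ndarray, years: np.ndarray) -> np.ndarray:
    """Detrend (Y, nlat, nlon) per cell, preserving each cell's mean."""
    slope, _, _ = trend_maps(annual, years)
    t = np.asarray(years, float)
    tc = t - t.mean()
    out = annual - slope[None] * tc[:, None, None]
    return out


def iav_map(annual: np.ndarray, years: np.ndarray) -> np.ndarray:
    """Per-cell 1-sigma of the detrended annual series."""
    d = detrend_cube(annual, years)
    return np.std(d, axis=0, ddof=1)


# ---------------------------------------------------------------------------
# anomalies
# ---------------------------------------------------------------------------

@dataclass
class AnomalySeries:
    """Deviations from the multi-year climatology at some time scale.

    For ``scale='monthly'`` the values keep monthly resolution and the
    climatology is per calendar month (12, nlat, nlon); for ``'annual'`` the
    values are per complete year; for ``'seasonal'`` per season per year with
    axis order (year, season) and the standard DJF/MAM/JJA/SON seasons.
    """

    values: np.ndarray
    climatology: np.ndarray
    scale: str
    years: np.ndarray
    base_period: tuple[int, int]
    units: str
    seasons: tuple[str, ...] | None = None


def anomalies(field: GriddedSeries, scale: Literal["monthly", "seasonal", "annual"] = "monthly") -> AnomalySeries:
    """Subtract the full-period mean at the requested time scale.

    By construction the anomaly mean over the base period is zero for each
    calendar unit (month, season, or the year), up to float rounding.
    """
    base = (int(field.years.min()), int(field.years.max()))
    if scale == "monthly":
        clim = np.stack([np.nanmean(np.where(field.missing_mask, np.nan, field.values)[field.months == m], axis=0)
                         for m in range(1, 13)])
        vals = field.values - clim[(field.months - 1)]
        vals = np.where(field.missing_mask, np.nan, vals)
        return AnomalySeries(vals, clim, "monthly", field.years.copy(), base, field.units)
    if scale == "annual":
        years, annual, miss = field.annual_means()
        annual = np.where(miss, np.nan, annual)
        clim = np.nanmean(annual, axis=0)
        return AnomalySeries(annual - clim[None], clim, "annual", years, base, field.units)
    if scale == "seasonal":
        names = tuple(SEASON_MONTHS)
        per = [seasonal_means(field, s) for s in names]
        years = per[0][0]
        cube = np.stack([v for _, v in per], axis=1)  # (year, season, ny, nx)
        clim = np.nanmean(cube, axis=0)
        return AnomalySeries(cube - clim[None], clim, "seasonal", years, base, field.units, seasons=names)
    raise ValueError(f"unknown scale {scale!r}")


def seasonal_means(field: GriddedSeries, season: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-year mean over one meteorological season.

    DJF for year Y uses December of Y-1 with January/February of Y, so the
    first year's DJF is missing (NaN).  Returns (years, (Y, nlat, nlon)).
    """
    if season not in SEASON_MONTHS:
        raise ValueError(f"unknown season {season!r}; expected one of {sorted(SEASON_MONTHS)}")
    months = SEASON_MONTHS[season]
    years = field.complete_years()
    vals = np.where(field.missing_mask, np.nan, field.values)
    out = np.full((years.size,) + field.grid.shape, np.nan)
    code = field.years * 12 + field.months - 1
    for k, y in enumerate(years):
        want = [((y - 1 if (season == "DJF" and m == 12) else y) * 12 + m - 1) for m in months]
        idx = np.searchsorted(code, want)
        if np.any(idx >= code.size) or np.any(code[np.minimum(idx, code.size - 1)] != want):
            continue  # season incomplete (e.g. first DJF) -> stays missing
        out[k] = vals[idx].mean(axis=0)
    return years, out


# ---------------------------------------------------------------------------
# climate-only extraction and ensemble statistics
# ---------------------------------------------------------------------------

def remove_s1_trend(s2: GriddedSeries, s1: GriddedSeries, degree: int = 1) -> GriddedSeries:
    """Subtract the CO2-only run's per-calendar-month trend from the full run.

    For each grid cell and calendar month, a degree-``degree`` polynomial in
    year is least-squares fitted to S1's series; its variation about its own
    mean (the fit minus the fitted mean, i.e. centered) is subtracted from
    S2, preserving S2's long-term mean.  With ``degree=1`` the result's
    per-month trend equals trend(S2) - trend(S1).
    """
    if s1.values.shape != s2.values.shape or not np.array_equal(s1.years, s2.years) \
            or not np.array_equal(s1.months, s2.months):
        raise ValueError("S1 and S2 must share grid and time axis")
    out = s2.values.copy()
    for m in range(1, 13):
        sel = s2.months == m
        if not sel.any():
            continue
        yrs = s2.years[sel].astype(float)
        tc = yrs - yrs.mean()
        block = s1.values[sel]            # (Y, ny, nx)
        Y = block.shape[0]
        # Vandermonde fit per cell, centered in time for conditioning
        V = np.vander(tc, degree + 1)     # columns tc^degree .. 1
        coef, *_ = np.linalg.lstsq(V, block.reshape(Y, -1), rcond=None)
        fitted = (V @ coef).reshape(block.shape)
        out[sel] -= fitted - fitted.mean(axis=0)[None]
    miss = s1.missing_mask | s2.missing_mask
    return s2.copy_with(values=np.where(miss, np.nan, out), missing_mask=miss,
                        name=f"{s2.name}_climate_only")


def ensemble_stats(ensemble: EnsembleSet) -> tuple[GriddedSeries, GriddedSeries]:
    """(element-wise mean, 1-sigma sample spread) of an ensemble."""
    return ensemble.mean(), ensemble.spread()
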