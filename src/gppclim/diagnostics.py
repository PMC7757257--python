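"""Cross-product comparison statistics.

Covers the map-level agreement diagnostics between GPP products: per-cell
Pearson correlations of detrended annual anomalies with analytic significance
thresholds, interannual-variability (IAV) hotspot maps normalised by the
domain mean, trend-direction agreement fractions, biome-grouped IAV
distributions, and the areal fraction of significant sensitivities.

All fractions are area-weighted by default (cells shrink toward the poles);
a cell-count convention is available where a caller prefers it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .climate_signal import detrend_cube, iav_map, trend_maps
from .grids import EnsembleSet, Grid, RegionDefinition, area_weighted_mean_map


def critical_r(n: int, alpha: float) -> float:
    """Smallest |r| significant at two-tailed level ``alpha`` for n pairs.

    From the t transform of the correlation coefficient:
    r* = t* / sqrt(n - 2 + t*^2) with t* the two-tailed t critical value on
    n - 2 degrees of freedom.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    tstar = stats.t.ppf(1 - alpha / 2, df=n - 2)
    return float(tstar / np.sqrt(n - 2 + tstar**2))


def _detrended_annual(ens: EnsembleSet) -> tuple[np.ndarray, np.ndarray]:
    """(years, detrended annual anomalies of the ensemble-mean series)."""
    mean = ens.mean()
    years, annual, miss = mean.annual_means()
    annual = np.where(miss, np.nan, annual)
    ok = np.isfinite(annual).all(axis=0)
    d = np.where(ok[None], detrend_cube(np.where(ok[None], annual, 0.0), years), np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return years, d - np.nanmean(d, axis=0)[None]


@dataclass
class CorrelationMap:
    """Per-cell cross-product correlation with its significance threshold."""

    r: np.ndarray
    n_years: int
    alpha: float
    r_critical: float

    @property
    def significant(self) -> np.ndarray:
        return np.where(np.isfinite(self.r), np.abs(self.r) >= self.r_critical, False)


def crossproduct_correlation(a: EnsembleSet, b: EnsembleSet, alpha: float = 0.05) -> CorrelationMap:
    """Pearson r of detrended annual ensemble-mean anomalies, per cell.

    Complete-case: a cell missing in either product is NaN.  Cells with
    degenerate (zero-variance) series are NaN as well.
    """
    ya, da = _detrended_annual(a)
    yb, db = _detrended_annual(b)
    if da.shape != db.shape or not np.array_equal(ya, yb):
        raise ValueError("products must share grid and years")
    n = ya.size
    if n < 3:
        raise ValueError("need at least 3 overlapping years")
    ok = np.isfinite(da).all(axis=0) & np.isfinite(db).all(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        da_c = da - np.nanmean(da, axis=0)[None]
        db_c = db - np.nanmean(db, axis=0)[None]
    with np.errstate(invalid="ignore", divide="ignore"):
        num = np.nansum(da_c * db_c, axis=0)
        den = np.sqrt(np.nansum(da_c**2, axis=0) * np.nansum(db_c**2, axis=0))
        r = np.where(ok & (den > 0), num / den, np.nan)
    return CorrelationMap(r=r, n_years=n, alpha=alpha, r_critical=critical_r(n, alpha))


def member_correlation_spread(a: EnsembleSet, b: EnsembleSet) -> np.ndarray:
    """Per-cell sd of correlations over all member-pair combinations."""
    rs = []
    for ma in a.members:
        for mb in b.members:
            one = EnsembleSet([ma], product_name="_")
            two = EnsembleSet([mb], product_name="_")
            rs.append(crossproduct_correlation(one, two).r)
    return np.std(np.stack(rs), axis=0, ddof=1) if len(rs) > 1 else np.zeros_like(rs[0])


def relative_iav_map(product: EnsembleSet, vegetated: np.ndarray) -> np.ndarray:
    """Per-cell IAV divided by the area-weighted mean IAV of vegetated cells.

    The resulting dimensionless hotspot map has area-weighted mean 1 over
    the vegetated cells entering the normalizer.
    """
    mean = product.mean()
    years, annual, miss = mean.annual_means()
    annual = np.where(miss, np.nan, annual)
    ok = np.isfinite(annual).all(axis=0)
    sig = np.where(ok, iav_map(np.where(ok[None], annual, 0.0), years), np.nan)
    veg = np.asarray(vegetated, bool) & ok
    if not veg.any():
        raise ValueError("no vegetated cells")
    norm = area_weighted_mean_map(sig, mean.grid, veg)
    if norm == 0:
        raise ValueError("mean IAV is zero; relative map undefined")
    return np.where(veg, sig / norm, np.nan)


def trend_agreement(trend_list: list[np.ndarray], grid: Grid, vegetated: np.ndarray,
                    zero_tol: float = 1e-12, area_weighted: bool = True) -> dict[str, float]:
    """Fractions of vegetated area where all products agree on trend sign.

    Returns ``agree_positive``, ``agree_negative``, ``disagree`` summing to
    one.  Cells where any product's |trend| is below ``zero_tol`` count as
    disagreement (a sign cannot be asserted there).
    """
    maps = [np.asarray(t, float) for t in trend_list]
    veg = np.asarray(vegetated, bool)
    for t in maps:
        veg = veg & np.isfinite(t)
    if not veg.any():
        raise ValueError("no vegetated cells with finite trends")
    pos = np.ones_like(veg)
    neg = np.ones_like(veg)
    nonzero = np.ones_like(veg)
    for t in maps:
        pos &= t > zero_tol
        neg &= t < -zero_tol
        nonzero &= np.abs(t) >= zero_tol
    w = grid.cell_areas() if area_weighted else np.ones(grid.shape)
    total = w[veg].sum()
    f_pos = w[veg & pos & nonzero].sum() / total
    f_neg = w[veg & neg & nonzero].sum() / total
    return {"agree_positive": float(f_pos), "agree_negative": float(f_neg),
            "disagree": float(1.0 - f_pos - f_neg)}


def biome_grouped_iav(sigma_map: np.ndarray, biome_map: np.ndarray, grid: Grid,
                      vegetated: np.ndarray | None = None,
                      normalizer: float | None = None) -> pd.DataFrame:
    """Quartile summary of globally-normalised per-cell IAV by biome class.

    Each cell's sigma is divided by the area-weighted global mean cell sigma
    (or a supplied normalizer), cells are grouped by biome, and the median
    and quartiles summarise each group.  Applies to GPP or any proxy field's
    detrended annual sigma.  Biomes with zero usable cells are omitted.
    """
    sig = np.asarray(sigma_map, float)
    ok = np.isfinite(sig)
    if vegetated is not None:
        ok &= np.asarray(vegetated, bool)
    if not ok.any():
        raise ValueError("no usable cells")
    if normalizer is None:
        normalizer = area_weighted_mean_map(sig, grid, ok)
    if normalizer == 0:
        raise ValueError("zero global mean sigma")
    rel = sig / normalizer
    rows = []
    for b in np.unique(np.asarray(biome_map)[ok]):
        vals = rel[ok & (biome_map == b)]
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        rows.append({"biome": b, "n_cells": vals.size, "q1": q1, "median": med, "q3": q3})
    return pd.DataFrame(rows).set_index("biome")


def significant_fraction(p_map: np.ndarray, vegetated: np.ndarray, grid: Grid,
                         region: RegionDefinition | None = None, alpha: float = 0.05,
                         area_weighted: bool = True) -> float:
    """Percent of a region's vegetated area with p below alpha."""
    p = np.asarray(p_map, float)
    sel = np.asarray(vegetated, bool) & np.isfinite(p)
    if region is not None:
        sel &= region.mask
    if not sel.any():
        raise ValueError("region contains no usable vegetated cells")
    w = grid.cell_areas() if area_weighted else np.ones(grid.shape)
    return float(100.0 * w[sel & (p < alpha)].sum() / w[sel].sum())


def product_trend_maps(product: EnsembleSet) -> tuple[np.ndarray, np.ndarray]:
    """(ensemble-mean trend slope map, p-value map) of annual means."""
    mean = product.mean()
    years, annual, miss = mean.annual_means()
    annual = np.where(miss, np.nan, annual)
    slope, _, p = trend_maps(annual, years)
    return slope, p
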