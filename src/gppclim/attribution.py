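"""Climate-sensitivity regression and relative-importance decomposition.

The central statistical model: annual GPP anomalies of a region or grid cell
are decomposed into temperature-, precipitation-, and radiation-forced
components,

    GPP_y = gamma * TEMP_y + lambda * PREC_y + delta * RAD_y + eps_y,

fitted by ordinary least squares (an intercept is included by default; on
anomalies it is ~0 but omitting it would bias coefficients whenever
detrending conventions shift the mean).  For interannual-variability work the
regression runs on detrended series; for trend attribution it runs on the
raw series and each driver's contribution is the OLS trend of its
reconstructed component ``coef_d * x_d``.

Relative importance uses the Lindeman-Merenda-Gold (LMG) decomposition: each
regressor's share of the full-model R^2 is its R^2 increment averaged over
all 3! orders of entry, enumerated exactly.

The module is organised statsmodels-style: build a
:class:`ClimateSensitivityModel` from the four series (or a DataFrame), call
``fit()``, and read estimates, uncertainties, and diagnostics off the
returned :class:`ClimateSensitivityResults`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .climate_signal import detrend, ols_trend
from .grids import Grid, area_weighted_mean_map

DRIVERS = ("temperature", "precipitation", "radiation")
_COEF_NAMES = ("gamma", "lambda", "delta")


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class ClimateSensitivityModel:
    """OLS decomposition of an annual GPP series onto three climate drivers.

    Parameters
    ----------
    gpp, temp, prec, rad
        Annual series of equal length (n >= 8).  Typically anomalies; the
        intercept absorbs any common offset.
    detrend_first
        Remove each series' linear trend before fitting (the IAV convention).
        Leave False when the fit feeds trend attribution.
    include_intercept
        Fit an intercept column (default True).
    years
        Optional calendar years (defaults to 0..n-1); only their spacing
        matters.
    """

    def __init__(self, gpp, temp, prec, rad, detrend_first: bool = True,
                 include_intercept: bool = True, years=None):
        arrs = [np.asarray(a, float) for a in (gpp, temp, prec, rad)]
        n = arrs[0].size
        if any(a.ndim != 1 or a.size != n for a in arrs):
            raise ValueError("all four series must be 1-D and of equal length")
        if n < 8:
            raise ValueError(f"need at least 8 years, got {n}")
        if not all(np.isfinite(a).all() for a in arrs):
            raise ValueError("series must be complete (no NaN); drop missing years first")
        self.years = np.arange(n, dtype=float) if years is None else np.asarray(years, float)
        if detrend_first:
            arrs = [detrend(a, self.years) for a in arrs]
        self.endog = arrs[0]
        self.exog = np.column_stack(arrs[1:])
        self.detrend_first = bool(detrend_first)
        self.include_intercept = bool(include_intercept)
        self._validate_rank()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, gpp: str = "gpp", temp: str = "temperature",
                       prec: str = "precipitation", rad: str = "radiation", **kwargs):
        return cls(df[gpp].values, df[temp].values, df[prec].values, df[rad].values, **kwargs)

    def _validate_rank(self):
        sds = self.exog.std(axis=0)
        for j, sd in enumerate(sds):
            if sd == 0:
                raise ValueError(f"regressor {DRIVERS[j]!r} has zero variance")
        corr = np.corrcoef(self.exog, rowvar=False)
        for i, j in itertools.combinations(range(3), 2):
            if abs(corr[i, j]) > 1 - 1e-12:
                raise ValueError(
                    f"rank-deficient design: {DRIVERS[i]!r} and {DRIVERS[j]!r} are collinear")

    def fit(self) -> "ClimateSensitivityResults":
        """Closed-form OLS fit with t-based inference (df = n - 4)."""
        n = self.endog.size
        X = self.exog
        if self.include_intercept:
            X = np.column_stack([X, np.ones(n)])
        XtX = X.T @ X
        beta = np.linalg.solve(XtX, X.T @ self.endog)
        fitted = X @ beta
        resid = self.endog - fitted
        k = X.shape[1]
        df_resid = n - k
        rss = float(resid @ resid)
        tss = float(((self.endog - self.endog.mean()) ** 2).sum())
        r2 = 1.0 - rss / tss if tss > 0 else 0.0
        sigma2 = rss / df_resid
        cov = sigma2 * np.linalg.inv(XtX)
        se = np.sqrt(np.diag(cov))
        with np.errstate(divide="ignore", invalid="ignore"):
            tvals = np.where(se > 0, beta / se, np.inf * np.sign(beta))
        pvals = 2.0 * stats.t.sf(np.abs(tvals), df=df_resid)
        names = list(_COEF_NAMES) + (["intercept"] if self.include_intercept else [])
        idx = pd.Index(names)
        return ClimateSensitivityResults(
            model=self,
            params=pd.Series(beta, index=idx),
            bse=pd.Series(se, index=idx),
            tvalues=pd.Series(tvals, index=idx),
            pvalues=pd.Series(pvals, index=idx),
            rsquared=r2, resid=resid, fittedvalues=fitted,
            nobs=n, df_resid=df_resid, cov_params=cov,
        )


@dataclass
class ClimateSensitivityResults:
    """Fit results: coefficients, uncertainty, diagnostics, decompositions."""

    model: ClimateSensitivityModel
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    rsquared: float
    resid: np.ndarray
    fittedvalues: np.ndarray
    nobs: int
    df_resid: int
    cov_params: np.ndarray

    @property
    def gamma(self) -> float:
        return float(self.params["gamma"])

    @property
    def lambda_(self) -> float:
        return float(self.params["lambda"])

    @property
    def delta(self) -> float:
        return float(self.params["delta"])

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        """Two-sided (1 - alpha) confidence intervals, t with n-k df."""
        tcrit = stats.t.ppf(1 - alpha / 2, df=self.df_resid)
        lo = self.params - tcrit * self.bse
        hi = self.params + tcrit * self.bse
        return pd.DataFrame({"lower": lo, "upper": hi})

    def lmg_shares(self) -> "ImportanceShares":
        """LMG decomposition of this fit's R^2 (see :func:`lmg_importance`)."""
        return lmg_importance(self.model.endog, self.model.exog[:, 0],
                              self.model.exog[:, 1], self.model.exog[:, 2])

    def driver_trend_contributions(self) -> "DriverTrendContribution":
        """OLS trend of each reconstructed component coef_d * x_d.

        Only meaningful on a fit of NON-detrended series; the residual trend
        closes the budget against the total GPP trend exactly (OLS is linear
        in the decomposed pieces).
        """
        if self.model.detrend_first:
            raise ValueError("trend attribution requires a fit on non-detrended series "
                             "(detrend_first=False)")
        years = self.model.years
        contribs = {}
        for j, drv in enumerate(DRIVERS):
            series = self.params.iloc[j] * self.model.exog[:, j]
            contribs[drv] = ols_trend(series, years).slope
        total = ols_trend(self.model.endog, years).slope
        residual = ols_trend(self.resid, years).slope
        return DriverTrendContribution(contributions=contribs, total_trend=total,
                                       residual_trend=residual)

    def summary(self) -> str:
        """Plain-text summary table in the statsmodels idiom."""
        lines = [
            "Climate sensitivity regression (OLS)",
            "=" * 58,
            f"n = {self.nobs}    df_resid = {self.df_resid}    "
            f"R^2 = {self.rsquared:.4f}    detrended = {self.model.detrend_first}",
            "-" * 58,
            f"{'':>12} {'coef':>10} {'se':>10} {'t':>8} {'P>|t|':>8}",
        ]
        for name in self.params.index:
            lines.append(f"{name:>12} {self.params[name]:>10.4g} {self.bse[name]:>10.4g} "
                         f"{self.tvalues[name]:>8.3g} {self.pvalues[name]:>8.3g}")
        shares = self.lmg_shares()
        lines.append("-" * 58)
        lines.append("LMG shares of R^2: "
                     + "  ".join(f"{d[:4]}={s:.4f}" for d, s in shares.as_dict().items()))
        return "\n".join(lines)


def fit_climate_regression(gpp, temp, prec, rad, detrend_first: bool = True,
                           **kwargs) -> ClimateSensitivityResults:
    """Functional entry point: build the model and fit in one call."""
    return ClimateSensitivityModel(gpp, temp, prec, rad, detrend_first=detrend_first,
                                   **kwargs).fit()


# ---------------------------------------------------------------------------
# LMG relative importance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImportanceShares:
    """Per-driver shares of the full-model R^2 (LMG decomposition)."""

    share_temperature: float
    share_precipitation: float
    share_radiation: float
    r_squared: float
    method: str = "LMG"

    def as_dict(self) -> dict[str, float]:
        return {"temperature": self.share_temperature,
                "precipitation": self.share_precipitation,
                "radiation": self.share_radiation}

    def as_array(self) -> np.ndarray:
        return np.array([self.share_temperature, self.share_precipitation,
                         self.share_radiation])


def _subset_r2(y: np.ndarray, X: np.ndarray) -> dict[frozenset, float]:
    """R^2 of every non-empty regressor subset, from moment matrices.

    Centered cross-moments give R^2(S) = s_yS' S_SS^{-1} s_yS / s_yy without
    refitting each submodel, which keeps the 7 subset evaluations cheap and
    numerically tied to one covariance computation.
    """
    yc = y - y.mean()
    Xc = X - X.mean(axis=0)
    syy = float(yc @ yc)
    if syy == 0:
        raise ValueError("response has zero variance")
    Sxx = Xc.T @ Xc
    sxy = Xc.T @ yc
    out: dict[frozenset, float] = {frozenset(): 0.0}
    p = X.shape[1]
    for r in range(1, p + 1):
        for S in itertools.combinations(range(p), r):
            idx = list(S)
            sol = np.linalg.solve(Sxx[np.ix_(idx, idx)], sxy[idx])
            out[frozenset(S)] = float(sxy[idx] @ sol) / syy
    return out


def lmg_importance(gpp, temp, prec, rad) -> ImportanceShares:
    """LMG relative importance of the three climate drivers.

    Each driver's share is the mean, over the 3! = 6 orders in which the
    regressors can enter the model, of the R^2 increase when that driver
    enters.  The orderings are enumerated explicitly; shares are non-negative
    and sum to the full-model R^2.
    """
    y = np.asarray(gpp, float)
    X = np.column_stack([np.asarray(a, float) for a in (temp, prec, rad)])
    if y.size != X.shape[0]:
        raise ValueError("series lengths differ")
    sds = X.std(axis=0)
    for j, sd in enumerate(sds):
        if sd == 0:
            raise ValueError(f"regressor {DRIVERS[j]!r} has zero variance")
    r2 = _subset_r2(y, X)
    shares = np.zeros(3)
    orders = list(itertools.permutations(range(3)))
    for order in orders:
        seen: set[int] = set()
        for j in order:
            shares[j] += r2[frozenset(seen | {j})] - r2[frozenset(seen)]
            seen.add(j)
    shares /= len(orders)
    return ImportanceShares(float(shares[0]), float(shares[1]), float(shares[2]),
                            r_squared=r2[frozenset({0, 1, 2})])


# ---------------------------------------------------------------------------
# trend attribution and aggregation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DriverTrendContribution:
    """Trend budget: per-driver reconstructed trends + residual = total."""

    contributions: dict[str, float]
    total_trend: float
    residual_trend: float

    @property
    def reconstructed_trend(self) -> float:
        return sum(self.contributions.values())


def normalize_trends(trend_map: np.ndarray, grid: Grid, vegetated: np.ndarray,
                     mode: str = "mean-abs", integral_series_trend: float | None = None) -> np.ndarray:
    """Dimensionless relative trend map.

    ``mode='mean-abs'`` divides by the area-weighted mean of |trend| over
    vegetated cells; ``mode='global-integral'`` divides by a supplied
    globally integrated trend (sign-preserving).  Both conventions appear in
    practice; they differ in sign behaviour and magnitude.
    """
    veg = np.asarray(vegetated, bool) & np.isfinite(trend_map)
    if not veg.any():
        raise ValueError("no vegetated cells with finite trends")
    if mode == "mean-abs":
        norm = area_weighted_mean_map(np.abs(trend_map), grid, veg)
        if norm == 0:
            raise ValueError("all trends are zero; normalizer undefined")
    elif mode == "global-integral":
        if integral_series_trend in (None, 0):
            raise ValueError("global-integral mode needs a non-zero integrated trend")
        norm = integral_series_trend
    else:
        raise ValueError(f"unknown mode {mode!r}")
    out = np.where(veg, trend_map / norm, np.nan)
    return out


def global_driver_contribution(share_maps: np.ndarray, iav_map: np.ndarray,
                               grid: Grid, vegetated: np.ndarray) -> dict[str, float]:
    """Percent contribution of each driver to region-wide GPP variability.

    Per-cell LMG shares are first renormalized to sum to one (attributing all
    explained variability), then weighted by the cell's IAV magnitude and
    area, and aggregated; the three percentages sum to 100.
    """
    shares = np.asarray(share_maps, float)  # (3, ny, nx)
    sigma = np.asarray(iav_map, float)
    tot = shares.sum(axis=0)
    ok = (np.asarray(vegetated, bool) & np.isfinite(sigma) & np.isfinite(tot) & (tot > 0))
    if not ok.any():
        raise ValueError("no usable vegetated cells")
    areas = grid.cell_areas()
    w = sigma * areas
    num = np.array([((shares[d] / tot) * w)[ok].sum() for d in range(3)])
    pct = 100.0 * num / w[ok].sum()
    return dict(zip(DRIVERS, pct))


# ---------------------------------------------------------------------------
# per-cell gridded fits
# ---------------------------------------------------------------------------

@dataclass
class SensitivityMaps:
    """Per-cell regression results on a grid (NaN where not fitted)."""

    gamma: np.ndarray
    lambda_: np.ndarray
    delta: np.ndarray
    se: dict[str, np.ndarray]
    pvalues: dict[str, np.ndarray]
    rsquared: np.ndarray
    shares: np.ndarray            # (3, ny, nx) LMG shares
    conf_low: dict[str, np.ndarray] = field(default_factory=dict)
    conf_high: dict[str, np.ndarray] = field(default_factory=dict)

    def dominant_driver(self) -> np.ndarray:
        """Per-cell argmax of the LMG shares (NaN cells -> -1)."""
        ok = np.isfinite(self.shares).all(axis=0)
        dom = np.argmax(np.where(np.isfinite(self.shares), self.shares, -np.inf), axis=0)
        return np.where(ok, dom, -1)


def fit_sensitivity_maps(gpp_annual: np.ndarray, temp_annual: np.ndarray,
                         prec_annual: np.ndarray, rad_annual: np.ndarray,
                         years: np.ndarray, detrend_first: bool = True,
                         mask: np.ndarray | None = None,
                         ci_alpha: float = 0.05,
                         compute_shares: bool = True) -> SensitivityMaps:
    """Fit the sensitivity regression independently at every grid cell.

    Inputs are (Y, nlat, nlon) annual cubes; cells with missing years or
    outside ``mask`` are skipped (complete-case).  ``compute_shares=False``
    skips the LMG decomposition when only coefficients/p-values are needed.
    """
    Y, ny, nx = gpp_annual.shape
    nanmap = lambda: np.full((ny, nx), np.nan)
    maps = SensitivityMaps(
        gamma=nanmap(), lambda_=nanmap(), delta=nanmap(),
        se={c: nanmap() for c in _COEF_NAMES},
        pvalues={c: nanmap() for c in _COEF_NAMES},
        rsquared=nanmap(), shares=np.full((3, ny, nx), np.nan),
        conf_low={c: nanmap() for c in _COEF_NAMES},
        conf_high={c: nanmap() for c in _COEF_NAMES},
    )
    cubes = (gpp_annual, temp_annual, prec_annual, rad_annual)
    for i in range(ny):
        for j in range(nx):
            if mask is not None and not mask[i, j]:
                continue
            series = [c[:, i, j] for c in cubes]
            if not all(np.isfinite(s).all() for s in series):
                continue
            try:
                res = fit_climate_regression(*series, detrend_first=detrend_first, years=years)
                shares = res.lmg_shares() if compute_shares else None
            except (ValueError, np.linalg.LinAlgError):
                continue
            maps.gamma[i, j] = res.gamma
            maps.lambda_[i, j] = res.lambda_
            maps.delta[i, j] = res.delta
            ci = res.conf_int(ci_alpha)
            for c in _COEF_NAMES:
                maps.se[c][i, j] = res.bse[c]
                maps.pvalues[c][i, j] = res.pvalues[c]
                maps.conf_low[c][i, j] = ci.loc[c, "lower"]
                maps.conf_high[c][i, j] = ci.loc[c, "upper"]
            maps.rsquared[i, j] = res.rsquared
            if shares is not None:
                maps.shares[:, i, j] = shares.as_array()
    return maps
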