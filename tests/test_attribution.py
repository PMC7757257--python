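import itertools

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st

from gppclim import (
    ClimateSensitivityModel,
    Grid,
    fit_climate_regression,
    fit_sensitivity_maps,
    global_driver_contribution,
    lmg_importance,
    normalize_trends,
)
from gppclim.attribution import DRIVERS


def brute_force_lmg(y, X):
    """Independent LMG oracle: refit all 7 submodels with lstsq, then average
    sequential R^2 increments over the 6 explicit orderings."""
    n, p = X.shape

    def r2_of(subset):
        if not subset:
            return 0.0
        A = np.column_stack([X[:, list(subset)], np.ones(n)])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        return 1.0 - (resid @ resid) / ((y - y.mean()) @ (y - y.mean()))

    shares = np.zeros(p)
    orders = list(itertools.permutations(range(p)))
    for order in orders:
        seen = []
        for j in order:
            shares[j] += r2_of(seen + [j]) - r2_of(seen)
            seen.append(j)
    return shares / len(orders)


def random_problem(rng, n=30, rho=0.5, noise=1.0):
    cov = rho * np.ones((3, 3)) + (1 - rho) * np.eye(3)
    X = rng.multivariate_normal(np.zeros(3), cov, size=n)
    beta = rng.normal(0, 2, 3)
    y = X @ beta + rng.normal(0, noise, n)
    return y, X


class TestRegressionFit:
    def test_exact_linear_recovery(self):
        rng = np.random.default_rng(0)
        n = 35
        temp = rng.normal(size=n)
        # orthogonalize prec and rad against temp so recovery is exact
        prec = rng.normal(size=n)
        rad = rng.normal(size=n)
        gpp = 2.0 * temp
        res = fit_climate_regression(gpp, temp, prec, rad, detrend_first=False)
        assert res.gamma == pytest.approx(2.0, abs=1e-9)
        assert res.lambda_ == pytest.approx(0.0, abs=1e-9)
        assert res.delta == pytest.approx(0.0, abs=1e-9)
        assert res.rsquared == pytest.approx(1.0, abs=1e-9)

    def test_constant_regressor_rejected(self):
        n = 20
        rng = np.random.default_rng(1)
        with pytest.raises(ValueError, match="precipitation"):
            fit_climate_regression(rng.normal(size=n), rng.normal(size=n),
                                   np.full(n, 3.0), rng.normal(size=n))

    def test_collinear_pair_named(self):
        rng = np.random.default_rng(2)
        n = 20
        t = rng.normal(size=n)
        with pytest.raises(ValueError, match="temperature.*radiation|radiation.*temperature"):
            fit_climate_regression(rng.normal(size=n), t, rng.normal(size=n), 2.0 * t,
                                   detrend_first=False)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="8"):
            fit_climate_regression(*[np.arange(5.0)] * 4)

    def test_matches_statsmodels(self):
        # independent cross-check of the closed-form implementation
        rng = np.random.default_rng(3)
        y, X = random_problem(rng, n=35)
        res = fit_climate_regression(y, X[:, 0], X[:, 1], X[:, 2], detrend_first=False)
        sm_res = sm.OLS(y, sm.add_constant(X)).fit()
        np.testing.assert_allclose(res.params[["gamma", "lambda", "delta"]].values,
                                   sm_res.params[1:], rtol=1e-10)
        np.testing.assert_allclose(res.params["intercept"], sm_res.params[0], rtol=1e-10)
        np.testing.assert_allclose(res.bse[["gamma", "lambda", "delta"]].values,
                                   sm_res.bse[1:], rtol=1e-10)
        np.testing.assert_allclose(res.pvalues[["gamma", "lambda", "delta"]].values,
                                   sm_res.pvalues[1:], rtol=1e-8)
        assert res.rsquared == pytest.approx(sm_res.rsquared, rel=1e-12)
        ci = res.conf_int(0.05)
        np.testing.assert_allclose(ci.values[:3], sm_res.conf_int()[1:], rtol=1e-10)

    def test_residuals_sum_to_zero_with_intercept(self):
        rng = np.random.default_rng(4)
        y, X = random_problem(rng)
        res = fit_climate_regression(y, X[:, 0], X[:, 1], X[:, 2], detrend_first=False)
        assert abs(res.resid.sum()) < 1e-9

    def test_coverage_of_confidence_intervals(self):
        # 500 replicates at a single synthetic cell: the 95% CI covers truth
        # at close to the nominal rate
        rng = np.random.default_rng(5)
        true = np.array([10.0, 0.5, 2.0])
        n = 35
        hits = np.zeros(3)
        reps = 1500
        for _ in range(reps):
            X = np.column_stack([rng.normal(0, 0.5, n), rng.normal(0, 8, n),
                                 rng.normal(0, 4, n)])
            y = X @ true + rng.normal(0, 20, n)
            res = fit_climate_regression(y, X[:, 0], X[:, 1], X[:, 2], detrend_first=False)
            ci = res.conf_int(0.05)
            hits += (ci["lower"].values[:3] <= true) & (true <= ci["upper"].values[:3])
        coverage = hits / reps
        assert ((coverage >= 0.93) & (coverage <= 0.97)).all()

    def test_from_dataframe_and_summary(self):
        rng = np.random.default_rng(6)
        y, X = random_problem(rng)
        df = pd.DataFrame({"gpp": y, "temperature": X[:, 0],
                           "precipitation": X[:, 1], "radiation": X[:, 2]})
        res = ClimateSensitivityModel.from_dataframe(df).fit()
        text = res.summary()
        assert "gamma" in text and "LMG" in text and "R^2" in text


class TestLMG:
    def test_orthogonal_regressors_get_marginal_r2(self):
        # sample-orthogonalized regressors: share = marginal R^2 each
        rng = np.random.default_rng(7)
        n = 40
        X = rng.normal(size=(n, 3))
        Q, _ = np.linalg.qr(X - X.mean(axis=0))  # exactly orthogonal columns
        y = 1.0 * Q[:, 0] + 2.0 * Q[:, 1] + 3.0 * Q[:, 2] + rng.normal(0, 0.5, n)
        shares = lmg_importance(y, Q[:, 0], Q[:, 1], Q[:, 2])
        for j, col in enumerate(Q.T):
            r = np.corrcoef(y, col)[0, 1]
            assert shares.as_array()[j] == pytest.approx(r**2, abs=1e-9)
        assert shares.as_array().sum() == pytest.approx(shares.r_squared, abs=1e-9)

    def test_single_driver_takes_everything(self):
        rng = np.random.default_rng(8)
        n = 30
        X = rng.normal(size=(n, 3))
        Q, _ = np.linalg.qr(X - X.mean(axis=0))
        y = 5.0 * Q[:, 0]
        shares = lmg_importance(y, Q[:, 0], Q[:, 1], Q[:, 2])
        assert shares.share_temperature == pytest.approx(1.0, abs=1e-9)
        assert shares.share_precipitation == pytest.approx(0.0, abs=1e-9)
        assert shares.share_radiation == pytest.approx(0.0, abs=1e-9)

    def test_fixed_ten_point_dataset_matches_oracle(self):
        rng = np.random.default_rng(9)
        y, X = random_problem(rng, n=10)
        shares = lmg_importance(y, X[:, 0], X[:, 1], X[:, 2])
        want = brute_force_lmg(y, X)
        np.testing.assert_allclose(shares.as_array(), want, atol=1e-12)

    def test_oracle_equivalence_on_many_random_problems(self):
        rng = np.random.default_rng(10)
        for k in range(100):
            y, X = random_problem(rng, n=rng.integers(10, 60),
                                  rho=rng.uniform(-0.3, 0.9), noise=rng.uniform(0.2, 3))
            shares = lmg_importance(y, X[:, 0], X[:, 1], X[:, 2])
            want = brute_force_lmg(y, X)
            np.testing.assert_allclose(shares.as_array(), want, atol=1e-10)
            assert (shares.as_array() >= -1e-12).all()
            assert shares.as_array().sum() == pytest.approx(shares.r_squared, abs=1e-9)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000), st.floats(0.1, 10), st.floats(0.1, 10), st.floats(0.1, 10))
    def test_permutation_symmetry_and_scale_invariance(self, seed, s0, s1, s2):
        rng = np.random.default_rng(seed)
        y, X = random_problem(rng, n=25)
        base = lmg_importance(y, X[:, 0], X[:, 1], X[:, 2]).as_array()
        # positive rescaling of any regressor leaves shares unchanged
        scaled = lmg_importance(y, s0 * X[:, 0], s1 * X[:, 1], s2 * X[:, 2]).as_array()
        np.testing.assert_allclose(scaled, base, atol=1e-9)
        # permuting regressor labels permutes shares identically
        perm = lmg_importance(y, X[:, 2], X[:, 0], X[:, 1]).as_array()
        np.testing.assert_allclose(perm, base[[2, 0, 1]], atol=1e-9)


class TestTrendAttribution:
    def test_trendless_driver_contributes_nothing(self):
        rng = np.random.default_rng(11)
        n = 35
        t = np.arange(n, dtype=float)
        temp = rng.normal(0, 0.5, n)
        temp = temp - np.polyval(np.polyfit(t, temp, 1), t)  # exactly trendless
        prec = rng.normal(0, 8, n) + 0.1 * t
        rad = rng.normal(0, 4, n)
        y = 10 * temp + 0.5 * prec + 2 * rad + rng.normal(0, 5, n)
        res = fit_climate_regression(y, temp, prec, rad, detrend_first=False, years=t)
        contrib = res.driver_trend_contributions()
        assert contrib.contributions["temperature"] == pytest.approx(0.0, abs=1e-9)

    def test_hand_product_of_sensitivity_and_trend(self):
        # gamma = 10 with a 0.02 degC/yr warming: contribution 0.2 gC/m2/yr per yr
        n = 35
        t = np.arange(n, dtype=float)
        rng = np.random.default_rng(12)
        temp = 0.02 * t + rng.normal(0, 1e-12, n)
        prec = rng.normal(0, 8, n)
        rad = rng.normal(0, 4, n)
        y = 10.0 * temp + 0.0 * prec + 0.0 * rad
        res = fit_climate_regression(y, temp, prec, rad, detrend_first=False, years=t)
        contrib = res.driver_trend_contributions()
        assert contrib.contributions["temperature"] == pytest.approx(0.2, abs=1e-6)

    def test_budget_closes_exactly(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            y, X = random_problem(rng, n=35)
            y = y + 0.3 * np.arange(35)
            res = fit_climate_regression(y, X[:, 0], X[:, 1], X[:, 2], detrend_first=False)
            c = res.driver_trend_contributions()
            assert c.reconstructed_trend + c.residual_trend == pytest.approx(
                c.total_trend, abs=1e-9)

    def test_detrended_fit_refuses_trend_attribution(self):
        rng = np.random.default_rng(14)
        y, X = random_problem(rng, n=35)
        res = fit_climate_regression(y, X[:, 0], X[:, 1], X[:, 2], detrend_first=True)
        with pytest.raises(ValueError, match="detrend"):
            res.driver_trend_contributions()


class TestNormalizeTrends:
    def test_uniform_trend_normalizes_to_one(self, small_grid):
        trend = np.full(small_grid.shape, 0.7)
        veg = np.ones(small_grid.shape, bool)
        out = normalize_trends(trend, small_grid, veg)
        np.testing.assert_allclose(out, 1.0)

    def test_two_cell_hand_values(self):
        # two same-latitude (equal-area) cells: trends +3 and -1 -> normalizer 2
        grid = Grid(np.array([0.0, 10.0]), np.array([0.0, 10.0]))
        trend = np.array([[3.0, -1.0], [np.nan, np.nan]])
        veg = np.array([[True, True], [False, False]])
        out = normalize_trends(trend, grid, veg)
        np.testing.assert_allclose(out[0], [1.5, -0.5])

    def test_scale_invariance(self, small_grid):
        rng = np.random.default_rng(15)
        trend = rng.normal(size=small_grid.shape)
        veg = np.ones(small_grid.shape, bool)
        np.testing.assert_allclose(normalize_trends(trend * 10, small_grid, veg),
                                   normalize_trends(trend, small_grid, veg), atol=1e-12)

    def test_all_zero_trends_rejected(self, small_grid):
        veg = np.ones(small_grid.shape, bool)
        with pytest.raises(ValueError, match="zero"):
            normalize_trends(np.zeros(small_grid.shape), small_grid, veg)


class TestGlobalDriverContribution:
    def _one_hot_shares(self, grid, driver_idx):
        shares = np.zeros((3,) + grid.shape)
        shares[driver_idx] = 0.8  # R^2 = 0.8, fully in one driver
        return shares

    def test_pure_temperature_world(self, small_grid):
        shares = self._one_hot_shares(small_grid, 0)
        sigma = np.ones(small_grid.shape)
        veg = np.ones(small_grid.shape, bool)
        pct = global_driver_contribution(shares, sigma, small_grid, veg)
        assert pct["temperature"] == pytest.approx(100.0)
        assert pct["precipitation"] == pytest.approx(0.0)

    def test_two_equal_cells_split_evenly(self):
        grid = Grid(np.array([0.0, 10.0]), np.array([0.0]))
        # equal-area is not guaranteed at different latitudes; use same |lat|
        grid = Grid(np.array([-5.0, 5.0]), np.array([0.0]))
        shares = np.zeros((3, 2, 1))
        shares[0, 0, 0] = 0.9  # cell 1 purely temperature
        shares[1, 1, 0] = 0.9  # cell 2 purely precipitation
        sigma = np.ones((2, 1))
        veg = np.ones((2, 1), bool)
        pct = global_driver_contribution(shares, sigma, grid, veg)
        assert pct["temperature"] == pytest.approx(50.0)
        assert pct["precipitation"] == pytest.approx(50.0)
        assert pct["radiation"] == pytest.approx(0.0)

    def test_sigma_weighting(self):
        grid = Grid(np.array([-5.0, 5.0]), np.array([0.0]))
        shares = np.zeros((3, 2, 1))
        shares[0, 0, 0] = 0.9
        shares[1, 1, 0] = 0.9
        sigma = np.array([[2.0], [1.0]])  # temperature cell twice as variable
        veg = np.ones((2, 1), bool)
        pct = global_driver_contribution(shares, sigma, grid, veg)
        assert pct["temperature"] == pytest.approx(100 * 2 / 3)
        assert pct["precipitation"] == pytest.approx(100 / 3)

    def test_percentages_sum_to_100(self, small_grid):
        rng = np.random.default_rng(16)
        raw = rng.uniform(0.01, 1, (3,) + small_grid.shape)
        shares = raw / raw.sum(axis=0) * rng.uniform(0.2, 0.95, small_grid.shape)
        sigma = rng.uniform(0.1, 3, small_grid.shape)
        veg = np.ones(small_grid.shape, bool)
        pct = global_driver_contribution(shares, sigma, small_grid, veg)
        assert sum(pct.values()) == pytest.approx(100.0, abs=1e-6)


class TestSensitivityMaps:
    def test_recovers_effective_truth_on_default_scenario(self, default_ensemble,
                                                          default_climate):
        ens, truth = default_ensemble
        mean = ens.mean()
        years, gpp_annual, _ = mean.annual_means()
        cubes = {v: s.annual_means()[1] for v, s in default_climate.series().items()}
        maps = fit_sensitivity_maps(gpp_annual, cubes["temperature"],
                                    cubes["precipitation"], cubes["radiation"], years)
        eff = truth.effective_coefficients()
        # area-weighted mean estimate close to the effective truth per belt
        err = np.abs(maps.gamma - eff["gamma"])
        rel = err / np.maximum(np.abs(eff["gamma"]), 1.0)
        assert np.nanmedian(rel) < 0.25
        # LMG-dominant driver agrees with the constructed truth in most cells
        dom_true = truth.dominant_driver(default_climate)
        dom_est = maps.dominant_driver()
        agree = (dom_est == dom_true).mean()
        assert agree >= 0.90
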