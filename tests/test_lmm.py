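"""Random-intercept mixed model: estimates, calibration, derived statistics."""

import numpy as np
import pandas as pd
import pytest

from restfc.lmm import RandomInterceptModel, fit_lmm, nakagawa_r2, standardize_beta


def _simulate(rng, n_groups=80, per_group=6, beta=0.25, sd_u=0.6, sd_e=1.0):
    groups = np.repeat(np.arange(n_groups), per_group)
    x = rng.standard_normal(n_groups * per_group)
    u = sd_u * rng.standard_normal(n_groups)
    y = 0.5 + beta * x + u[groups] + sd_e * rng.standard_normal(len(x))
    return y, x, groups


class TestEstimation:
    def test_matches_statsmodels_mixedlm(self, rng):
        import statsmodels.formula.api as smf

        y, x, groups = _simulate(rng)
        ours = RandomInterceptModel(y, x, groups).fit()
        df = pd.DataFrame({"y": y, "x": x, "g": groups})
        ref = smf.mixedlm("y ~ x", df, groups=df["g"]).fit(reml=True)
        assert ours.fixed_slope == pytest.approx(ref.params["x"], abs=1e-6)
        assert ours.fixed_intercept == pytest.approx(ref.params["Intercept"], abs=1e-6)
        assert ours.residual_variance == pytest.approx(ref.scale, rel=1e-4)
        assert ours.random_intercept_variance == pytest.approx(float(ref.cov_re.iloc[0, 0]), rel=1e-3)
        assert ours.slope_se == pytest.approx(ref.bse["x"], rel=1e-2)

    def test_zero_group_variance_degrades_to_ols(self, rng):
        groups = np.repeat(np.arange(60), 5)
        x = rng.standard_normal(300)
        y = 0.3 * x + rng.standard_normal(300)
        # remove all between-group outcome variance so the REML variance
        # estimate lands on the zero boundary and the fit is exactly GLS=OLS
        for g in range(60):
            y[groups == g] -= (y[groups == g] - 0.3 * x[groups == g]).mean()
        res = RandomInterceptModel(y, x, groups).fit()
        ols_slope = np.polyfit(x, y, 1)[0]
        assert abs(res.fixed_slope - ols_slope) < 1e-4
        assert res.random_intercept_variance < 1e-6

    def test_planted_slope_recovered_within_3_se(self, rng):
        y, x, groups = _simulate(rng, n_groups=164, per_group=6, beta=0.25)
        res = RandomInterceptModel(y, x, groups).fit()
        assert abs(res.fixed_slope - 0.25) < 3 * res.slope_se
        assert res.converged

    def test_type_one_error_calibrated(self):
        from scipy.stats import binom

        rng = np.random.default_rng(77)
        hits = 0
        n_sims = 200
        for _ in range(n_sims):
            groups = np.repeat(np.arange(164), 6)
            x = rng.standard_normal(984)
            y = 0.6 * rng.standard_normal(164)[groups] + rng.standard_normal(984)
            hits += RandomInterceptModel(y, x, groups).fit().slope_p < 0.05
        lo, hi = binom.interval(0.95, n_sims, 0.05)
        assert lo <= hits <= hi

    def test_dataframe_constructor_drops_missing(self, rng):
        y, x, groups = _simulate(rng, n_groups=10, per_group=4)
        df = pd.DataFrame({"y": y, "x": x, "g": groups})
        df.loc[0, "y"] = np.nan
        res = fit_lmm(df, "y", "x", "g")
        assert res.n_observations == len(df) - 1

    def test_single_group_rejected(self, rng):
        with pytest.raises(ValueError):
            RandomInterceptModel(rng.standard_normal(10), rng.standard_normal(10), np.zeros(10))


class TestDerivedStatistics:
    def test_standardize_beta_arithmetic(self):
        assert standardize_beta(0.5, sd_predictor=2.0, sd_outcome=4.0) == 0.25

    def test_standardized_beta_scale_invariant(self, rng):
        y, x, groups = _simulate(rng)
        a = RandomInterceptModel(y, x, groups).fit()
        b = RandomInterceptModel(y, 2.0 * x, groups).fit()
        assert b.fixed_slope == pytest.approx(a.fixed_slope / 2.0, rel=1e-8)
        assert b.standardized_beta == pytest.approx(a.standardized_beta, rel=1e-8)

    def test_standardized_on_standardized_data_is_identity(self, rng):
        y, x, groups = _simulate(rng)
        y = (y - y.mean()) / y.std()
        x = (x - x.mean()) / x.std()
        res = RandomInterceptModel(y, x, groups).fit()
        assert res.standardized_beta == pytest.approx(res.fixed_slope)

    def test_zero_sd_rejected(self):
        with pytest.raises(ValueError):
            standardize_beta(0.5, 0.0, 1.0)

    def test_nakagawa_formula_arithmetic(self):
        marg, cond = nakagawa_r2(1.0, 1.0, 2.0)
        assert (marg, cond) == (0.25, 0.5)

    def test_r2_ordering_and_bounds(self, rng):
        y, x, groups = _simulate(rng)
        res = RandomInterceptModel(y, x, groups).fit()
        assert 0 <= res.marginal_r2 <= res.conditional_r2 <= 1

    def test_null_slope_marginal_r2_near_zero(self, rng):
        y, x, groups = _simulate(rng, beta=0.0)
        res = RandomInterceptModel(y, x, groups).fit()
        assert res.marginal_r2 < 0.02

    def test_zero_group_variance_equates_r2(self, rng):
        groups = np.repeat(np.arange(50), 5)
        x = rng.standard_normal(250)
        y = 0.4 * x + rng.standard_normal(250)
        for g in range(50):  # force the zero-variance boundary
            y[groups == g] -= (y[groups == g] - 0.4 * x[groups == g]).mean()
        res = RandomInterceptModel(y, x, groups).fit()
        assert res.marginal_r2 == pytest.approx(res.conditional_r2, abs=1e-6)

    def test_ci_brackets_estimate_and_summary_renders(self, rng):
        y, x, groups = _simulate(rng)
        res = RandomInterceptModel(y, x, groups).fit()
        lo, hi = res.conf_int()[1]
        assert lo <= res.fixed_slope <= hi
        assert "standardized slope" in res.summary()
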