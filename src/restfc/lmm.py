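"""Random-intercept linear mixed models.

The model is

    y_ij = beta0 + beta1 * x_ij + u_i + e_ij,
    u_i ~ N(0, sigma2_u),  e_ij ~ N(0, sigma2_e),

fitted by REML with the variance ratio lambda = sigma2_u / sigma2_e
profiled out: for fixed lambda the GLS estimates and the residual variance
have closed forms from per-group sufficient statistics, so the REML
criterion reduces to a one-dimensional optimization over log(lambda).

Inference on the slope uses the Wald statistic with a normal reference by
default; a residual-degrees-of-freedom t reference is available via
``use_t``. Standardized coefficients are post-hoc rescalings
(beta * sd_x / sd_y) with CI endpoints transformed identically, and
marginal/conditional R^2 follow the Nakagawa–Schielzeth variance
decomposition.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = ["RandomInterceptModel", "RandomInterceptResults", "fit_lmm", "standardize_beta", "nakagawa_r2"]


class ConvergenceWarning(UserWarning):
    pass


def _group_stats(X: np.ndarray, y: np.ndarray, groups: np.ndarray):
    """Per-group sufficient statistics for the profiled REML criterion."""
    uniq, idx = np.unique(groups, return_inverse=True)
    g = len(uniq)
    p = X.shape[1]
    n_i = np.bincount(idx, minlength=g).astype(float)
    # s_i = X_i' 1, t_i = y_i' 1
    s = np.zeros((g, p))
    for j in range(p):
        s[:, j] = np.bincount(idx, weights=X[:, j], minlength=g)
    t = np.bincount(idx, weights=y, minlength=g)
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)
    return uniq, n_i, s, t, XtX, Xty, yty


class RandomInterceptModel:
    """Random-intercept mixed model for a single predictor.

    Parameters
    ----------
    endog : array-like
        Outcome vector.
    exog : array-like
        Predictor vector (1-D). An intercept is always included.
    groups : array-like
        Group (subject) label per observation.
    """

    def __init__(self, endog, exog, groups):
        y = np.asarray(endog, dtype=float)
        x = np.asarray(exog, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        groups = np.asarray(groups)
        if not (len(y) == len(x) == len(groups)):
            raise ValueError("endog, exog and groups must have equal length")
        if not (np.all(np.isfinite(y)) and np.all(np.isfinite(x))):
            raise ValueError("non-finite values in model data")
        self.endog = y
        self.exog_raw = x
        self.exog = np.column_stack([np.ones(len(y)), x])
        self.groups = groups
        self._stats = _group_stats(self.exog, y, groups)
        if len(self._stats[0]) < 2:
            raise ValueError("need at least 2 groups")

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, outcome: str, predictor: str, group: str) -> "RandomInterceptModel":
        sub = data[[outcome, predictor, group]].dropna()
        return cls(sub[outcome].to_numpy(), sub[predictor].to_numpy(), sub[group].to_numpy())

    # -- profiled criterion ------------------------------------------------

    def _gls(self, lam: float):
        """GLS beta, X'V^-1 X, and GLS residual sum of squares for fixed lambda."""
        uniq, n_i, s, t, XtX, Xty, yty = self._stats
        c = lam / (1.0 + lam * n_i)  # per-group shrinkage weight
        XtVX = XtX - (s * c[:, None]).T @ s
        XtVy = Xty - s.T @ (c * t)
        ytVy = yty - float(c @ t**2)
        beta = np.linalg.solve(XtVX, XtVy)
        rss = ytVy - beta @ XtVy
        return beta, XtVX, max(rss, 1e-300)

    def _neg2_reml(self, log_lam: float, reml: bool = True) -> float:
        lam = np.exp(log_lam)
        uniq, n_i, *_ = self._stats
        n = len(self.endog)
        p = self.exog.shape[1]
        beta, XtVX, rss = self._gls(lam)
        logdet_v = float(np.sum(np.log1p(lam * n_i)))
        if reml:
            df = n - p
            sign, logdet_x = np.linalg.slogdet(XtVX)
            return logdet_v + df * np.log(rss / df) + logdet_x
        return logdet_v + n * np.log(rss / n)

    def fit(self, reml: bool = True, use_t: bool = False, alpha: float = 0.05) -> "RandomInterceptResults":
        """Estimate variance components and fixed effects.

        The variance ratio is profiled on log(lambda) over a wide bracket
        (lambda in [1e-8, 1e6]); the zero-variance boundary is checked
        explicitly so the fit degrades gracefully to OLS.
        """
        n = len(self.endog)
        p = self.exog.shape[1]
        obj = lambda ll: self._neg2_reml(ll, reml=reml)
        res = optimize.minimize_scalar(obj, bounds=(np.log(1e-8), np.log(1e6)), method="bounded")
        converged = bool(res.success)
        lam = float(np.exp(res.x))
        # boundary check: sigma2_u = 0
        if obj(np.log(1e-8)) <= res.fun + 1e-10 or lam < 2e-8:
            lam = 0.0
        beta, XtVX, rss = self._gls(lam)
        df = n - p if reml else n
        sigma2_e = rss / df
        sigma2_u = lam * sigma2_e
        cov_beta = sigma2_e * np.linalg.inv(XtVX)
        se = np.sqrt(np.diag(cov_beta))
        g = len(self._stats[0])
        resid_df = max(n - g - (p - 1), 1)
        if use_t:
            crit = stats.t.ppf(1 - alpha / 2, resid_df)
            pvals = 2 * stats.t.sf(np.abs(beta / se), resid_df)
        else:
            crit = stats.norm.ppf(1 - alpha / 2)
            pvals = 2 * stats.norm.sf(np.abs(beta / se))
        fitted_fixed = self.exog @ beta
        return RandomInterceptResults(
            model=self,
            params=beta,
            bse=se,
            pvalues=pvals,
            conf_int_values=np.column_stack([beta - crit * se, beta + crit * se]),
            random_intercept_variance=float(sigma2_u),
            residual_variance=float(sigma2_e),
            lambda_=lam,
            n_observations=n,
            n_groups=g,
            resid_df=resid_df,
            converged=converged,
            reml=reml,
            use_t=use_t,
            fixed_effects_variance=float(np.var(fitted_fixed)),
        )


@dataclasses.dataclass
class RandomInterceptResults:
    """Fit results: fixed effects, variance components, derived statistics."""

    model: RandomInterceptModel
    params: np.ndarray  # (intercept, slope)
    bse: np.ndarray
    pvalues: np.ndarray
    conf_int_values: np.ndarray  # rows (lower, upper)
    random_intercept_variance: float
    residual_variance: float
    lambda_: float
    n_observations: int
    n_groups: int
    resid_df: int
    converged: bool
    reml: bool
    use_t: bool
    fixed_effects_variance: float

    # -- convenience accessors --------------------------------------------

    @property
    def fixed_intercept(self) -> float:
        return float(self.params[0])

    @property
    def fixed_slope(self) -> float:
        return float(self.params[1])

    @property
    def slope_se(self) -> float:
        return float(self.bse[1])

    @property
    def slope_p(self) -> float:
        return float(self.pvalues[1])

    def conf_int(self) -> np.ndarray:
        return self.conf_int_values

    @property
    def standardized_beta(self) -> float:
        sd_x = float(np.std(self.model.exog_raw[:, 0]))
        sd_y = float(np.std(self.model.endog))
        return standardize_beta(self.fixed_slope, sd_x, sd_y)

    @property
    def standardized_ci(self) -> tuple[float, float]:
        sd_x = float(np.std(self.model.exog_raw[:, 0]))
        sd_y = float(np.std(self.model.endog))
        lo, hi = self.conf_int_values[1]
        return (standardize_beta(lo, sd_x, sd_y), standardize_beta(hi, sd_x, sd_y))

    @property
    def marginal_r2(self) -> float:
        return nakagawa_r2(self.fixed_effects_variance, self.random_intercept_variance, self.residual_variance)[0]

    @property
    def conditional_r2(self) -> float:
        return nakagawa_r2(self.fixed_effects_variance, self.random_intercept_variance, self.residual_variance)[1]

    def summary(self) -> str:
        lines = [
            "Random-intercept mixed model (REML)" if self.reml else "Random-intercept mixed model (ML)",
            f"  observations: {self.n_observations}   groups: {self.n_groups}   converged: {self.converged}",
            f"  sigma2_u (random intercept): {self.random_intercept_variance:.6g}",
            f"  sigma2_e (residual):        {self.residual_variance:.6g}",
            f"  {'term':<12}{'coef':>12}{'se':>12}{'p':>12}{'[0.025':>12}{'0.975]':>12}",
        ]
        for name, b, s, p, (lo, hi) in zip(
            ("intercept", "slope"), self.params, self.bse, self.pvalues, self.conf_int_values
        ):
            lines.append(f"  {name:<12}{b:>12.4f}{s:>12.4f}{p:>12.4g}{lo:>12.4f}{hi:>12.4f}")
        lo, hi = self.standardized_ci
        lines.append(f"  standardized slope: {self.standardized_beta:.4f}  95% CI [{lo:.4f}, {hi:.4f}]")
        lines.append(f"  marginal R2: {self.marginal_r2:.4f}   conditional R2: {self.conditional_r2:.4f}")
        return "\n".join(lines)


def fit_lmm(table: pd.DataFrame, outcome: str, predictor: str, group: str, **fit_kws) -> RandomInterceptResults:
    """Fit ``outcome ~ predictor + (1 | group)`` on a long-format table."""
    return RandomInterceptModel.from_dataframe(table, outcome, predictor, group).fit(**fit_kws)


def standardize_beta(beta: float, sd_predictor: float, sd_outcome: float) -> float:
    """Post-hoc standardized coefficient: beta * sd_x / sd_y."""
    if sd_predictor <= 0 or sd_outcome <= 0:
        raise ValueError("standard deviations must be positive")
    return float(beta * sd_predictor / sd_outcome)


def nakagawa_r2(fixed_effects_variance: float, random_variance: float, residual_variance: float) -> tuple[float, float]:
    """Marginal and conditional R^2 for a random-intercept model.

    marginal = var_fixed / total; conditional = (var_fixed + var_random) /
    total, with total = var_fixed + var_random + var_residual.
    """
    total = fixed_effects_variance + random_variance + residual_variance
    if total <= 0:
        raise ValueError("total variance is zero; R2 undefined")
    return (fixed_effects_variance / total, (fixed_effects_variance + random_variance) / total)
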