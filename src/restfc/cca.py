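"""Canonical correlation analysis against a univariate outcome.

Used here purely as a dimension-reduction device: for each behavioral
phenotype, the first (and only) canonical variate of a multivariate
predictor set (questionnaire items, or network-connectivity edges) is the
linear combination maximally correlated with that phenotype. With a
univariate second set the canonical correlation equals the multiple
correlation R of the outcome on the predictor set.

Canonical-variate scores are computed, by default, as the matrix product
of the column-standardized predictors with the structure loadings (the
correlations between each predictor and the variate); the conventional
canonical-coefficient scoring is available via ``mode="coefficients"``.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = ["CCAUnivariate", "CCAResult", "cv_scores"]


class RankDeficiencyWarning(UserWarning):
    pass


@dataclasses.dataclass
class CCAResult:
    """First canonical pair of a predictor set against a single outcome."""

    canonical_correlation: float
    loadings: np.ndarray          # structure correlations, one per predictor
    coefficients: np.ndarray      # canonical weights on centered predictors
    scores: np.ndarray            # per-subject canonical-variate scores
    p_value: float                # F test of R^2 (equivalent to Wilks here)
    n: int
    variable_names: Sequence[str] | None = None

    def summary(self) -> str:
        lines = [
            "CCA (univariate outcome)",
            f"  n = {self.n}   canonical correlation = {self.canonical_correlation:.4f}   p = {self.p_value:.4g}",
            f"  {'variable':<24}{'loading':>10}{'coef':>10}",
        ]
        names = self.variable_names or [f"x{i + 1}" for i in range(len(self.loadings))]
        for name, ld, cf in zip(names, self.loadings, self.coefficients):
            lines.append(f"  {name:<24}{ld:>10.4f}{cf:>10.4f}")
        return "\n".join(lines)


class CCAUnivariate:
    """Canonical correlation of an n x p predictor set with an n-vector outcome.

    The first canonical direction is obtained from the SVD of the whitened
    cross-covariance ``Sxx^{-1/2} Sxy / sqrt(Syy)``; with a univariate
    outcome this is a single vector whose norm is the canonical
    correlation. Rank-deficient predictor sets are whitened with a
    pseudo-inverse square root (with a warning).
    """

    def __init__(self, X, y, variable_names: Sequence[str] | None = None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n x p)")
        n, p = X.shape
        if len(y) != n:
            raise ValueError("X and y lengths differ")
        if n <= p + 1:
            raise ValueError(f"need n > p + 1 (n={n}, p={p})")
        if np.any(X.std(axis=0) == 0):
            raise ValueError("constant predictor column")
        if y.std() == 0:
            raise ValueError("constant outcome")
        self.X = X
        self.y = y
        self.variable_names = list(variable_names) if variable_names is not None else None

    def fit(self) -> CCAResult:
        n, p = self.X.shape
        Xc = self.X - self.X.mean(axis=0)
        yc = self.y - self.y.mean()
        sxx = Xc.T @ Xc / (n - 1)
        sxy = Xc.T @ yc / (n - 1)
        syy = float(yc @ yc) / (n - 1)
        evals, evecs = np.linalg.eigh(sxx)
        tol = evals.max() * 1e-10
        keep = evals > tol
        if not np.all(keep):
            warnings.warn(
                f"predictor set is rank deficient (rank {keep.sum()} < {p}); using pseudo-inverse whitening",
                RankDeficiencyWarning,
            )
        inv_sqrt = (evecs[:, keep] / np.sqrt(evals[keep])) @ evecs[:, keep].T
        k = inv_sqrt @ sxy / np.sqrt(syy)
        cc = float(np.linalg.norm(k))
        if cc == 0:
            coef = np.zeros(p)
            scores = np.zeros(n)
        else:
            coef = inv_sqrt @ k / cc
            scores = Xc @ coef
            # orient the variate so it correlates positively with the outcome
            if scores @ yc < 0:  # pragma: no cover - norm construction keeps it >= 0
                coef, scores = -coef, -scores
        cc = min(cc, 1.0)
        sd = scores.std()
        if sd > 0:
            loadings = (Xc / Xc.std(axis=0)).T @ ((scores - scores.mean()) / sd) / n
        else:
            loadings = np.zeros(p)
        rank = int(keep.sum())
        df2 = n - rank - 1
        r2 = cc**2
        if r2 >= 1.0:
            p_value = 0.0
        else:
            f_stat = (r2 / rank) / ((1 - r2) / df2)
            p_value = float(stats.f.sf(f_stat, rank, df2))
        return CCAResult(
            canonical_correlation=cc,
            loadings=np.clip(loadings, -1.0, 1.0),
            coefficients=coef,
            scores=scores,
            p_value=p_value,
            n=n,
            variable_names=self.variable_names,
        )


def cv_scores(X, weights, mode: str = "loadings") -> np.ndarray:
    """Canonical-variate scores from a weight vector.

    The predictor matrix is column-standardized (z-scored) and multiplied
    by ``weights``: the structure loadings in the default ``"loadings"``
    mode, or the canonical coefficients in ``"coefficients"`` mode.
    """
    if mode not in ("loadings", "coefficients"):
        raise ValueError(f"unknown scoring mode {mode!r}")
    X = np.asarray(X, dtype=float)
    w = np.asarray(weights, dtype=float).ravel()
    if X.shape[1] != len(w):
        raise ValueError("weight length does not match predictor count")
    sd = X.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("constant predictor column")
    Z = (X - X.mean(axis=0)) / sd
    return Z @ w
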