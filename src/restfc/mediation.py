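"""Simple (single-mediator) mediation with a percentile bootstrap.

Paths are standardized least-squares coefficients:

    A  : mediator ~ predictor
    B  : mediator coefficient in  outcome ~ predictor + mediator
    C' : predictor coefficient in outcome ~ predictor + mediator
    C  : outcome ~ predictor

The indirect effect is A*B, and for least-squares fits on one sample the
decomposition C = C' + A*B holds as an algebraic identity. Its 95%
confidence interval comes from case-resampled bootstrap replicates
(percentile method, default 5000 replicates, seeded); the interval
excluding zero flags a significant indirect effect.
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = ["MediationModel", "MediationResult", "mediate"]

DEFAULT_N_BOOT = 5000


def _standardized_paths(r_xm: np.ndarray, r_xy: np.ndarray, r_my: np.ndarray):
    """Closed-form standardized paths from the three pairwise correlations."""
    denom = 1.0 - r_xm**2
    denom = np.where(np.abs(denom) < 1e-12, np.nan, denom)
    a = r_xm
    b = (r_my - r_xm * r_xy) / denom
    c_prime = (r_xy - r_xm * r_my) / denom
    c = r_xy
    return a, b, c, c_prime


def _corr_rows(x: np.ndarray, m: np.ndarray, y: np.ndarray):
    """Row-wise pairwise correlations for (n_boot, n) resample matrices."""

    def z(v):
        mu = v.mean(axis=-1, keepdims=True)
        sd = v.std(axis=-1, keepdims=True)
        sd = np.where(sd == 0, np.nan, sd)
        return (v - mu) / sd

    zx, zm, zy = z(x), z(m), z(y)
    n = x.shape[-1]
    return (zx * zm).sum(-1) / n, (zx * zy).sum(-1) / n, (zm * zy).sum(-1) / n


@dataclasses.dataclass
class MediationResult:
    """Standardized mediation paths with bootstrap CI for the indirect effect."""

    path_a: float
    path_b: float
    path_c: float
    path_c_prime: float
    se_a: float
    se_b: float
    se_c: float
    se_c_prime: float
    indirect: float
    bootstrap_ci_95: tuple[float, float]
    indirect_p: float
    n: int
    n_boot: int
    seed: int | None
    ci_type: str = "percentile"

    @property
    def significant(self) -> bool:
        """True when the bootstrap CI for the indirect effect excludes 0."""
        lo, hi = self.bootstrap_ci_95
        return bool(lo > 0 or hi < 0)

    def summary(self) -> str:
        lo, hi = self.bootstrap_ci_95
        return "\n".join(
            [
                f"Mediation (n = {self.n}, {self.n_boot} bootstrap replicates, seed = {self.seed})",
                f"  A  (predictor -> mediator):          {self.path_a:+.4f} (SE {self.se_a:.4f})",
                f"  B  (mediator -> outcome | predictor):{self.path_b:+.4f} (SE {self.se_b:.4f})",
                f"  C  (total effect):                   {self.path_c:+.4f} (SE {self.se_c:.4f})",
                f"  C' (direct effect):                  {self.path_c_prime:+.4f} (SE {self.se_c_prime:.4f})",
                f"  indirect A*B: {self.indirect:+.4f}   95% {self.ci_type} CI [{lo:+.4f}, {hi:+.4f}]"
                f"   {'significant' if self.significant else 'not significant'}",
            ]
        )


class MediationModel:
    """Single-mediator model over three aligned observation vectors."""

    def __init__(self, predictor, mediator, outcome):
        x = np.asarray(predictor, dtype=float).ravel()
        m = np.asarray(mediator, dtype=float).ravel()
        y = np.asarray(outcome, dtype=float).ravel()
        if not (len(x) == len(m) == len(y)):
            raise ValueError("predictor, mediator and outcome lengths differ")
        if len(x) < 10:
            raise ValueError("need at least 10 observations")
        if not all(np.all(np.isfinite(v)) for v in (x, m, y)):
            raise ValueError("non-finite values")
        if m.std() == 0 or y.std() == 0 or x.std() == 0:
            raise ValueError("constant predictor, mediator or outcome")
        self.x, self.m, self.y = x, m, y

    def fit(self, n_boot: int = DEFAULT_N_BOOT, seed: int | None = None) -> MediationResult:
        x, m, y = self.x, self.m, self.y
        n = len(x)
        r_xm, r_xy, r_my = _corr_rows(x[None, :], m[None, :], y[None, :])
        a, b, c, c_prime = (float(v[0]) for v in _standardized_paths(r_xm, r_xy, r_my))
        # OLS standard errors on standardized variables
        se_a = np.sqrt((1 - a**2) / (n - 2))
        resid_var = (1 - r_xy[0] ** 2 - b * (r_my[0] - r_xm[0] * r_xy[0])) / (n - 3)
        inv_diag = 1.0 / (1 - r_xm[0] ** 2)
        se_b = se_c_prime = float(np.sqrt(max(resid_var, 0.0) * inv_diag))
        se_c = float(np.sqrt((1 - c**2) / (n - 2)))

        rng = np.random.default_rng(seed)
        idx = rng.integers(0, n, size=(n_boot, n))
        rb_xm, rb_xy, rb_my = _corr_rows(x[idx], m[idx], y[idx])
        ab, bb, *_ = _standardized_paths(rb_xm, rb_xy, rb_my)
        boot_indirect = ab * bb
        boot_indirect = boot_indirect[np.isfinite(boot_indirect)]
        lo, hi = np.percentile(boot_indirect, [2.5, 97.5])
        n_eff = len(boot_indirect)
        p_lo = np.mean(boot_indirect <= 0)
        p_hi = np.mean(boot_indirect >= 0)
        p = float(np.clip(2 * min(p_lo, p_hi), 1.0 / n_eff, 1.0))
        return MediationResult(
            path_a=a,
            path_b=b,
            path_c=c,
            path_c_prime=c_prime,
            se_a=float(se_a),
            se_b=se_b,
            se_c=se_c,
            se_c_prime=se_c_prime,
            indirect=a * b,
            bootstrap_ci_95=(float(lo), float(hi)),
            indirect_p=p,
            n=n,
            n_boot=n_boot,
            seed=seed,
        )


def mediate(predictor, mediator, outcome, n_boot: int = DEFAULT_N_BOOT, seed: int | None = None) -> MediationResult:
    """Convenience wrapper: fit a single-mediator model in one call."""
    return MediationModel(predictor, mediator, outcome).fit(n_boot=n_boot, seed=seed)
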