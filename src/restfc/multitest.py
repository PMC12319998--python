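"""Benjamini–Hochberg FDR correction over caller-declared test families.

Families are declared by the analysis that owns them (e.g., the 36
network-edge tests of one questionnaire item form one family; the 12
item-level fingerprint tests another; the per-phenotype canonical-variate
correlations and indirect effects form families of their own). Adjusted
p-values of exactly 0 or 1 pass through unmodified.
"""

from __future__ import annotations

import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = ["fdr_bh"]


def fdr_bh(p_values, family_label: str = "") -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values for one family.

    Returns adjusted values that are monotone in the input order statistics
    and capped at 1. ``family_label`` is carried for error messages only;
    the caller decides family membership.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p-values must be a 1-D sequence")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError(f"p-values outside [0, 1] in family {family_label!r}")
    return multipletests(p, method="fdr_bh")[1]
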