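"""Behavioral phenotype screening.

Subject-level phenotype tables carry missing entries as NaN. A phenotype
enters the cross-sectional analyses only when at least 90% of the analyzed
subjects have valid data for it (inclusive boundary); analyses of an
included phenotype then use listwise-complete subjects.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["phenotype_inclusion", "INCLUSION_THRESHOLD"]

INCLUSION_THRESHOLD = 0.90


def phenotype_inclusion(behavior: pd.DataFrame, threshold: float = INCLUSION_THRESHOLD) -> list[str]:
    """Phenotype columns with a valid-data fraction >= ``threshold``.

    ``behavior`` has one row per analyzed subject; every column other than
    ``subject_id`` is treated as a phenotype. Missingness must be encoded
    as NaN.
    """
    pheno_cols = [c for c in behavior.columns if c != "subject_id"]
    if behavior.empty or not pheno_cols:
        raise ValueError("empty behavior table")
    valid_fraction = behavior[pheno_cols].notna().mean(axis=0)
    return [c for c in pheno_cols if valid_fraction[c] >= threshold]
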