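"""Within-subject run-pair contrast tables.

Each subject with r valid runs contributes C(r, 2) records; each record
carries the mean absolute difference (MAD) of the two runs' FC fingerprint
vectors, the MAD of their 12 questionnaire item scores, and the per-item
absolute differences. The long-format table feeds the random-intercept
mixed models directly.
"""

from __future__ import annotations

import itertools
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .connectivity import FCVector

__all__ = [
    "mad",
    "build_contrast_table",
    "nonoverlapping_subset",
    "average_snycq",
    "item_columns",
]

logger = logging.getLogger(__name__)

#: Default minimum number of valid runs for a subject to enter the analysis.
MIN_VALID_RUNS = 3


def mad(vec_a: np.ndarray, vec_b: np.ndarray) -> float:
    """Mean absolute difference between two equal-length vectors."""
    a = np.asarray(vec_a, dtype=float)
    b = np.asarray(vec_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite values")
    return float(np.mean(np.abs(a - b)))


def item_columns(n_items: int) -> list[str]:
    """Column names for per-item absolute differences."""
    return [f"item_{i + 1:02d}_absdiff" for i in range(n_items)]


def build_contrast_table(
    fc_vectors: Mapping[str, Mapping[str, FCVector]],
    snycq: pd.DataFrame,
    min_valid_runs: int = MIN_VALID_RUNS,
) -> pd.DataFrame:
    """Long-format run-pair contrast table.

    Parameters
    ----------
    fc_vectors
        subject_id -> {run_id -> FCVector} for valid (non-excluded) runs.
    snycq
        Questionnaire table with columns ``subject_id``, ``run_id`` and one
        column per item (every column that is neither id column is treated
        as an item score).
    min_valid_runs
        Subjects with fewer valid runs (after FC/questionnaire matching)
        are dropped.

    Returns
    -------
    DataFrame with columns ``subject_id, run_a, run_b, mad_fc,
    mad_snycq_full, item_XX_absdiff ...``; one row per unique unordered
    run pair per retained subject, run_a < run_b.
    """
    items = [c for c in snycq.columns if c not in ("subject_id", "run_id")]
    q = snycq.set_index(["subject_id", "run_id"])
    rows = []
    for subject in sorted(fc_vectors):
        runs = {}
        for run_id, vec in fc_vectors[subject].items():
            if (subject, run_id) not in q.index:
                logger.warning("run %s/%s has no questionnaire row; dropped", subject, run_id)
                continue
            runs[run_id] = (vec, q.loc[(subject, run_id), items].to_numpy(dtype=float))
        if len(runs) < min_valid_runs:
            logger.info("subject %s has %d valid runs (< %d); excluded", subject, len(runs), min_valid_runs)
            continue
        for run_a, run_b in itertools.combinations(sorted(runs), 2):
            vec_a, q_a = runs[run_a]
            vec_b, q_b = runs[run_b]
            row = {
                "subject_id": subject,
                "run_a": run_a,
                "run_b": run_b,
                "mad_fc": mad(vec_a.values, vec_b.values),
                "mad_snycq_full": mad(q_a, q_b),
            }
            absdiff = np.abs(q_a - q_b)
            for name, val in zip(item_columns(len(items)), absdiff):
                row[name] = val
            rows.append(row)
    return pd.DataFrame(rows)


def _default_pairs(runs: Sequence[str]) -> list[tuple[str, str]]:
    """Disjoint pairing in acquisition order: (1st,2nd), (3rd,4th), ...

    A subject with an odd run count contributes the pairs of adjacent runs
    closest in acquisition order; the leftover run is unused.
    """
    runs = sorted(runs)
    return [(runs[i], runs[i + 1]) for i in range(0, len(runs) - 1, 2)]


def nonoverlapping_subset(
    table: pd.DataFrame,
    scheme: Mapping[str, Sequence[tuple[str, str]]] | None = None,
) -> pd.DataFrame:
    """Restrict a contrast table to non-overlapping run pairs.

    In the full table every run takes part in several contrasts, making
    the MADs mutually dependent; this sensitivity variant retains, per
    subject, a set of disjoint pairs so each run appears at most once.

    ``scheme`` maps subject_id to an explicit list of (run_a, run_b) pairs;
    the default pairs runs in acquisition order ((run1, run2), (run3, run4);
    3-run subjects contribute the first two runs only). Overlapping schemes
    raise.
    """
    keep = []
    for subject, grp in table.groupby("subject_id", sort=True):
        runs = sorted(set(grp["run_a"]).union(grp["run_b"]))
        pairs = list(scheme[subject]) if scheme is not None and subject in scheme else _default_pairs(runs)
        flat = [r for p in pairs for r in p]
        if len(flat) != len(set(flat)):
            raise ValueError(f"overlapping pairing scheme for subject {subject}: {pairs}")
        wanted = {tuple(sorted(p)) for p in pairs}
        mask = [tuple(sorted((a, b))) in wanted for a, b in zip(grp["run_a"], grp["run_b"])]
        keep.append(grp[mask])
    return pd.concat(keep, ignore_index=True) if keep else table.iloc[:0].copy()


def average_snycq(snycq: pd.DataFrame) -> pd.DataFrame:
    """Across-run mean of each questionnaire item, per subject.

    Input and output share the item columns; the output has one row per
    subject. Subjects with zero valid runs are absent by construction.
    """
    items = [c for c in snycq.columns if c not in ("subject_id", "run_id")]
    if snycq.empty:
        raise ValueError("empty questionnaire table")
    return snycq.groupby("subject_id", sort=True)[items].mean().reset_index()
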