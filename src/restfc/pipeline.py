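"""End-to-end analyses.

Three analyses chain the lower-level modules:

1. *Fingerprint similarity* — within-subject run-pair MAD of the FC
   fingerprint regressed on run-pair questionnaire dissimilarity (the
   full-scale MAD and each item's absolute difference) in random-intercept
   mixed models, with an FDR family over the item-level tests and a
   non-overlapping-contrast sensitivity rerun.
2. *Network correlates* — every unique network-pair connectivity value
   regressed on every questionnaire item (run level, random intercept per
   subject); one FDR family of edge tests per item.
3. *CCA + mediation* — per behavioral phenotype, canonical variates of the
   across-run questionnaire means and of the concatenated-run network
   edges against that phenotype; the two variate-behavior correlations
   (FDR over phenotypes for each variate) and a bootstrap mediation of
   variate_FNC -> variate_questionnaire -> behavior, with FDR over the
   indirect effects.

A power-simulation harness estimates, from explicit generative
parameters, the detection probability of either the similarity-slope test
or the mediation indirect-effect test.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cca import CCAUnivariate, cv_scores
from .connectivity import aggregate_fnc, compute_fc, concatenate_runs, vectorize_fc
from .data import ParcellatedTimeseries
from .lmm import RandomInterceptModel, fit_lmm
from .mediation import MediationModel
from .multitest import fdr_bh
from .phenotypes import INCLUSION_THRESHOLD, phenotype_inclusion
from .similarity import MIN_VALID_RUNS, build_contrast_table, item_columns, nonoverlapping_subset
from .synthetic import SyntheticConfig

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "prepare_run_level",
    "prepare_subject_level",
    "run_hypothesis1",
    "run_hypothesis2",
    "run_hypothesis3",
    "run_power_simulation",
    "PowerParameters",
    "PowerReport",
]


@dataclasses.dataclass
class PipelineConfig:
    """Analysis configuration; hashed into every output manifest."""

    synthetic: SyntheticConfig | None = None
    motion_threshold: float = 0.25
    min_valid_runs: int = MIN_VALID_RUNS
    phenotype_threshold: float = INCLUSION_THRESHOLD
    n_boot: int = 5000
    seed: int = 0
    use_t: bool = False

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        if self.synthetic is not None:
            payload["synthetic"] = {
                k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in dataclasses.asdict(self.synthetic).items()
            }
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def manifest(self) -> dict:
        return {"config_hash": self.config_hash(), "seed": self.seed, "n_boot": self.n_boot}


# ---------------------------------------------------------------------------
# data preparation


def prepare_run_level(timeseries: Sequence[ParcellatedTimeseries]):
    """Per-run FC fingerprints and network-edge tables.

    Returns ``(fc_vectors, fnc_table)``: a subject -> {run -> FCVector}
    map, and a long DataFrame with one row per run carrying every unique
    network-pair edge as a column.
    """
    fc_vectors: dict[str, dict] = {}
    rows = []
    for ts in timeseries:
        fc = compute_fc(ts)
        fc_vectors.setdefault(ts.subject_id, {})[ts.run_id] = vectorize_fc(fc)
        edges = aggregate_fnc(fc).unique_edges()
        row = {"subject_id": ts.subject_id, "run_id": ts.run_id}
        row.update(edges.to_dict())
        rows.append(row)
    return fc_vectors, pd.DataFrame(rows)


def prepare_subject_level(timeseries: Sequence[ParcellatedTimeseries]) -> pd.DataFrame:
    """Concatenate each subject's runs (per-run z-scoring), recompute FC, and
    aggregate to one row of unique network edges per subject."""
    by_subject: dict[str, list] = {}
    for ts in timeseries:
        by_subject.setdefault(ts.subject_id, []).append(ts)
    rows = []
    for subject in sorted(by_subject):
        runs = sorted(by_subject[subject], key=lambda t: t.run_id)
        fc = compute_fc(concatenate_runs(runs))
        row = {"subject_id": subject}
        row.update(aggregate_fnc(fc).unique_edges().to_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def filter_subjects(table: pd.DataFrame, subjects: Sequence[str] | None) -> pd.DataFrame:
    """Generic subject-filtering hook (e.g., age-bin reanalyses)."""
    if subjects is None:
        return table
    return table[table["subject_id"].isin(set(subjects))].reset_index(drop=True)


# ---------------------------------------------------------------------------
# hypothesis 1: fingerprint similarity


def _similarity_models(contrast: pd.DataFrame, use_t: bool) -> pd.DataFrame:
    if contrast["subject_id"].nunique() < 2:
        raise ValueError("fewer than 2 subjects survive filtering")
    items = [c for c in contrast.columns if c.endswith("_absdiff")]
    rows = []
    for name, predictor in [("full_scale", "mad_snycq_full")] + [
        (c.removesuffix("_absdiff"), c) for c in items
    ]:
        res = fit_lmm(contrast, "mad_fc", predictor, "subject_id", use_t=use_t)
        lo, hi = res.standardized_ci
        rows.append(
            {
                "model": name,
                "predictor": predictor,
                "beta_std": res.standardized_beta,
                "ci_low": lo,
                "ci_high": hi,
                "p": res.slope_p,
                "marginal_r2": res.marginal_r2,
                "conditional_r2": res.conditional_r2,
                "n_records": res.n_observations,
                "n_subjects": res.n_groups,
                "converged": res.converged,
            }
        )
    out = pd.DataFrame(rows)
    item_mask = out["model"] != "full_scale"
    out.loc[item_mask, "p_fdr"] = fdr_bh(out.loc[item_mask, "p"].to_numpy(), "item-level fingerprint tests")
    return out


def run_hypothesis1(
    fc_vectors: Mapping[str, Mapping],
    snycq: pd.DataFrame,
    min_valid_runs: int = MIN_VALID_RUNS,
    use_t: bool = False,
    subjects: Sequence[str] | None = None,
):
    """Fingerprint-similarity analysis.

    Returns ``(results, nonoverlapping_results, contrast_table)``: the
    full-scale model plus one model per item (standardized slope, CI, p,
    item-family FDR), the same models refitted on the non-overlapping
    contrast subset, and the underlying long-format contrast table.
    """
    if subjects is not None:
        fc_vectors = {s: r for s, r in fc_vectors.items() if s in set(subjects)}
    contrast = build_contrast_table(fc_vectors, snycq, min_valid_runs=min_valid_runs)
    results = _similarity_models(contrast, use_t)
    nonoverlap = _similarity_models(nonoverlapping_subset(contrast), use_t)
    logger.info("hypothesis 1: %d contrast records from %d subjects", len(contrast), contrast["subject_id"].nunique())
    return results, nonoverlap, contrast


# ---------------------------------------------------------------------------
# hypothesis 2: network correlates of each item


def run_hypothesis2(
    fnc_table: pd.DataFrame,
    snycq: pd.DataFrame,
    use_t: bool = False,
    subjects: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Univariate network-edge correlates of every questionnaire item.

    One random-intercept model per (edge, item) pair on the run-level
    data; with 8 networks and 12 items this is 36 x 12 = 432 fits. FDR is
    applied within each item's family of edge tests. Edges undefined for
    every run (single-node networks) are skipped with a warning.
    """
    fnc_table = filter_subjects(fnc_table, subjects)
    merged = fnc_table.merge(snycq, on=["subject_id", "run_id"], how="inner", validate="one_to_one")
    edge_cols = [c for c in fnc_table.columns if c not in ("subject_id", "run_id")]
    item_cols = [c for c in snycq.columns if c not in ("subject_id", "run_id")]
    dropped = [c for c in edge_cols if merged[c].isna().all()]
    if dropped:
        logger.warning("skipping undefined network edges: %s", dropped)
        edge_cols = [c for c in edge_cols if c not in dropped]
    rows = []
    groups = merged["subject_id"].to_numpy()
    for item in item_cols:
        x = merged[item].to_numpy(dtype=float)
        for edge in edge_cols:
            res = RandomInterceptModel(merged[edge].to_numpy(dtype=float), x, groups).fit(use_t=use_t)
            lo, hi = res.standardized_ci
            rows.append(
                {
                    "item": item,
                    "edge": edge,
                    "beta_std": res.standardized_beta,
                    "ci_low": lo,
                    "ci_high": hi,
                    "p": res.slope_p,
                    "marginal_r2": res.marginal_r2,
                    "conditional_r2": res.conditional_r2,
                    "converged": res.converged,
                }
            )
    out = pd.DataFrame(rows)
    out["p_fdr"] = np.nan
    for item in item_cols:
        mask = out["item"] == item
        out.loc[mask, "p_fdr"] = fdr_bh(out.loc[mask, "p"].to_numpy(), f"edge tests for {item}")
    return out


# ---------------------------------------------------------------------------
# hypothesis 3: CCA-derived variates chained into mediation


def run_hypothesis3(
    fnc_subject: pd.DataFrame,
    snycq_means: pd.DataFrame,
    behavior: pd.DataFrame,
    phenotype_threshold: float = INCLUSION_THRESHOLD,
    n_boot: int = 5000,
    seed: int | None = 0,
    subjects: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-phenotype canonical variates and bootstrap mediation.

    For each phenotype passing the valid-data gate: a canonical variate of
    the questionnaire means and one of the subject-level network edges are
    derived against the phenotype (listwise-complete subjects), scored by
    structure loadings, correlated with the phenotype (FDR over phenotypes
    per variate), and chained into a variate_FNC -> variate_SNYCQ ->
    behavior mediation whose indirect effect gets a seeded percentile
    bootstrap CI; FDR is applied over the indirect-effect p-values.
    """
    fnc_subject = filter_subjects(fnc_subject, subjects)
    snycq_means = filter_subjects(snycq_means, subjects)
    behavior = filter_subjects(behavior, subjects)
    included = phenotype_inclusion(behavior, threshold=phenotype_threshold)
    if not included:
        raise ValueError("no phenotype passes the inclusion gate")
    base = fnc_subject.merge(snycq_means, on="subject_id", validate="one_to_one").merge(
        behavior, on="subject_id", validate="one_to_one"
    )
    edge_cols = [c for c in fnc_subject.columns if c != "subject_id"]
    edge_cols = [c for c in edge_cols if not base[c].isna().any()]
    item_cols = [c for c in snycq_means.columns if c != "subject_id"]
    rng = np.random.default_rng(seed)
    rows = []
    for pheno in included:
        sub = base.dropna(subset=[pheno])
        y = sub[pheno].to_numpy(dtype=float)
        res_q = CCAUnivariate(sub[item_cols].to_numpy(dtype=float), y, item_cols).fit()
        res_f = CCAUnivariate(sub[edge_cols].to_numpy(dtype=float), y, edge_cols).fit()
        cv_q = cv_scores(sub[item_cols].to_numpy(dtype=float), res_q.loadings, mode="loadings")
        cv_f = cv_scores(sub[edge_cols].to_numpy(dtype=float), res_f.loadings, mode="loadings")
        from scipy import stats as _st

        r_q, p_q = _st.pearsonr(cv_q, y)
        r_f, p_f = _st.pearsonr(cv_f, y)
        boot_seed = int(rng.integers(0, 2**31 - 1))
        med = MediationModel(cv_f, cv_q, y).fit(n_boot=n_boot, seed=boot_seed)
        rows.append(
            {
                "phenotype": pheno,
                "n": len(sub),
                "cca_r_snycq": res_q.canonical_correlation,
                "r_cv_snycq": r_q,
                "p_cv_snycq": p_q,
                "cca_r_fnc": res_f.canonical_correlation,
                "r_cv_fnc": r_f,
                "p_cv_fnc": p_f,
                "path_a": med.path_a,
                "path_b": med.path_b,
                "path_c": med.path_c,
                "path_c_prime": med.path_c_prime,
                "indirect": med.indirect,
                "indirect_ci_low": med.bootstrap_ci_95[0],
                "indirect_ci_high": med.bootstrap_ci_95[1],
                "indirect_p": med.indirect_p,
                "indirect_significant": med.significant,
                "n_boot": n_boot,
                "seed": boot_seed,
            }
        )
    out = pd.DataFrame(rows)
    out["p_cv_snycq_fdr"] = fdr_bh(out["p_cv_snycq"].to_numpy(), "CV_SNYCQ-behavior correlations")
    out["p_cv_fnc_fdr"] = fdr_bh(out["p_cv_fnc"].to_numpy(), "CV_FNC-behavior correlations")
    out["indirect_p_fdr"] = fdr_bh(out["indirect_p"].to_numpy(), "indirect effects")
    return out


# ---------------------------------------------------------------------------
# power simulation


@dataclasses.dataclass
class PowerParameters:
    """Explicit generative parameters for the power harness.

    ``analysis`` selects the target test: ``"similarity_lmm"`` simulates
    long-format contrast data with a planted standardized slope
    (``beta_std``), ``n_subjects`` groups of ``rows_per_subject`` records
    and a random-intercept share ``icc`` of the residual variance;
    ``"mediation"`` simulates subject-level (predictor, mediator, outcome)
    triples with standardized paths a/b/c' and tests the bootstrap CI of
    the indirect effect (``n_boot`` replicates).
    """

    analysis: str = "similarity_lmm"
    n_subjects: int = 164
    rows_per_subject: int = 6
    beta_std: float = 0.25
    icc: float = 0.4
    path_a: float = 0.4
    path_b: float = 0.4
    path_cprime: float = 0.3
    n_boot: int = 1000
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.analysis not in ("similarity_lmm", "mediation"):
            raise ValueError(f"unknown analysis {self.analysis!r}")
        if not 0 <= self.icc < 1:
            raise ValueError("icc must lie in [0, 1)")


@dataclasses.dataclass
class PowerReport:
    power: float
    se: float
    n_sims: int
    parameters: PowerParameters
    seed: int | None


def _simulate_similarity_once(p: PowerParameters, rng: np.random.Generator) -> bool:
    n = p.n_subjects * p.rows_per_subject
    x = rng.standard_normal(n)
    groups = np.repeat(np.arange(p.n_subjects), p.rows_per_subject)
    resid_var = max(1.0 - p.beta_std**2, 1e-12)
    u = np.sqrt(p.icc * resid_var) * rng.standard_normal(p.n_subjects)
    e = np.sqrt((1 - p.icc) * resid_var) * rng.standard_normal(n)
    y = p.beta_std * x + u[groups] + e
    res = RandomInterceptModel(y, x, groups).fit()
    return res.slope_p < p.alpha


def _simulate_mediation_once(p: PowerParameters, rng: np.random.Generator) -> bool:
    n = p.n_subjects
    a, b, cp = p.path_a, p.path_b, p.path_cprime
    x = rng.standard_normal(n)
    m = a * x + np.sqrt(max(1 - a**2, 1e-12)) * rng.standard_normal(n)
    noise = max(1 - b**2 - cp**2 - 2 * a * b * cp, 1e-12)
    y = cp * x + b * m + np.sqrt(noise) * rng.standard_normal(n)
    med = MediationModel(x, m, y).fit(n_boot=p.n_boot, seed=int(rng.integers(0, 2**31 - 1)))
    return med.significant


def run_power_simulation(
    parameters: PowerParameters, n_sims: int = 1000, seed: int | None = 0
) -> PowerReport:
    """Monte-Carlo power of the target test under explicit parameters.

    Returns the fraction of simulations with a significant target effect
    and its binomial standard error. Fewer than 50 simulations triggers a
    Monte-Carlo-error warning.
    """
    if n_sims < 50:
        import warnings

        warnings.warn("n_sims < 50: Monte-Carlo error will dominate the power estimate")
    rng = np.random.default_rng(seed)
    simulate = _simulate_similarity_once if parameters.analysis == "similarity_lmm" else _simulate_mediation_once
    hits = sum(simulate(parameters, rng) for _ in range(n_sims))
    power = hits / n_sims
    se = float(np.sqrt(power * (1 - power) / n_sims))
    return PowerReport(power=power, se=se, n_sims=n_sims, parameters=parameters, seed=seed)
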