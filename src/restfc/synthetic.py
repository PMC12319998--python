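"""Synthetic multi-run datasets with a planted mediation structure.

The generator emulates the statistical skeleton the analyses assume:

* every subject carries a stable FC fingerprint (a subject-specific
  perturbation of a common network-structured connectivity matrix, plus a
  latent *trait* loaded onto one nominated network-pair block of edges);
* every run carries a latent *thought state* whose within-subject
  (run-to-run) fluctuation perturbs a second, disjoint block of edges;
* the questionnaire items are noisy monotone readouts of the run states,
  mapped to the instrument's 0-100 grid in steps of 5;
* subject-level behavior is generated jointly from the FC trait and the
  subject's mean thought state, with standardized path coefficients
  a (trait -> state), b (state -> behavior) and c' (direct
  trait -> behavior), so the planted indirect effect is a*b.

Run-level state deviations are mean-centered within subject, so the
across-run questionnaire average identifies the subject mean state and the
planted paths stay interpretable on the standardized scale. Only these
centered deviations drive the state -> FC edge perturbation: the subject
mean state therefore reaches behavior exclusively through the
questionnaire (mediator) route while the FC route carries only the trait,
keeping the two planted paths identifiable downstream. Trait and state
load *disjoint* edge blocks for the same reason. All ground-truth latent
draws and the planted coefficients are recorded.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as _signal
from scipy import stats as _stats

from .data import ParcellatedTimeseries

__all__ = ["SyntheticConfig", "GroundTruth", "generate_dataset", "simulate_timeseries", "ConfigurationError"]


class ConfigurationError(ValueError):
    """A SyntheticConfig field violates its contract."""


class MatrixError(ValueError):
    """Target correlation matrix is unusable (not positive definite)."""


#: Default questionnaire loadings on the single latent state: the first
#: item is the clearly dominant readout (a vigilance-like dimension), the
#: rest are weaker with mixed signs. Item noise (``item_noise_sd``) is of
#: the same order as the state signal, so the loading differences are
#: expressed in how well each item tracks the state.
DEFAULT_ITEM_LOADINGS = np.array(
    [0.90, 0.45, 0.40, 0.45, 0.35, 0.45, -0.40, 0.45, -0.35, 0.30, 0.40, 0.45]
)


@dataclasses.dataclass
class SyntheticConfig:
    """Generative parameters; defaults are the package's study conditions.

    ``state_loading_matrix`` is items x states; ``state_to_edge_weights``
    is (states, nodes, nodes) or a scalar (a scalar builds the default
    disjoint-block weight pattern scaled by it; 0 plants no state -> FC
    coupling at all).
    """

    n_subjects: int = 164
    n_runs: int = 4
    n_nodes: int = 50
    n_networks: int = 8
    n_items: int = 12
    n_timepoints: int = 657
    sampling_interval: float = 1.4
    fingerprint_sd: float = 0.10
    state_loading_matrix: np.ndarray | None = None
    state_to_edge_weights: np.ndarray | float = 0.25
    trait_edge_weight: float = 0.25
    behavior_path_a: float = 0.4
    behavior_path_b: float = 0.4
    behavior_path_cprime: float = 0.3
    item_noise_sd: float = 1.0
    state_run_sd: float = 1.0
    within_network_r: float = 0.35
    between_network_r: float = 0.08
    ar_coefficient: float = 0.4
    missing_fraction: float = 0.05
    seed: int = 0

    # nominated network-pair blocks (0-based network indices)
    trait_block: tuple[int, int] = (0, 1)
    state_block: tuple[int, int] = (2, 3)

    def __post_init__(self) -> None:
        for field in ("n_subjects", "n_runs", "n_nodes", "n_networks", "n_items", "n_timepoints"):
            if int(getattr(self, field)) < 1:
                raise ConfigurationError(f"{field} must be >= 1")
        if self.n_runs < 3:
            raise ConfigurationError("n_runs must be >= 3 (subjects need at least 3 valid runs)")
        if self.n_nodes < 2 * self.n_networks:
            raise ConfigurationError("n_nodes must allow >= 2 nodes per network (n_nodes >= 2*n_networks)")
        if not 0 <= self.missing_fraction < 1:
            raise ConfigurationError("missing_fraction must lie in [0, 1)")
        for field in ("item_noise_sd", "state_run_sd", "fingerprint_sd"):
            if getattr(self, field) <= 0:
                raise ConfigurationError(f"{field} must be > 0")
        for field in ("behavior_path_a", "behavior_path_b", "behavior_path_cprime", "trait_edge_weight"):
            if not np.isfinite(getattr(self, field)):
                raise ConfigurationError(f"{field} must be finite")
        if not -1 < self.ar_coefficient < 1:
            raise ConfigurationError("ar_coefficient must lie in (-1, 1)")
        a = self.behavior_path_a
        if not -1 <= a <= 1:
            raise ConfigurationError("behavior_path_a must lie in [-1, 1]")
        if self._behavior_noise_var() <= 0:
            raise ConfigurationError(
                "behavior_path_a/b/cprime imply a behavior variance > 1; shrink the paths"
            )
        if max(self.trait_block) >= self.n_networks or max(self.state_block) >= self.n_networks:
            raise ConfigurationError("trait_block/state_block index a network beyond n_networks")

    def _behavior_noise_var(self) -> float:
        a, b, c = self.behavior_path_a, self.behavior_path_b, self.behavior_path_cprime
        return 1.0 - b**2 - c**2 - 2 * a * b * c

    # -- derived structure -------------------------------------------------

    @property
    def n_states(self) -> int:
        return self.loadings.shape[1]

    @property
    def loadings(self) -> np.ndarray:
        if self.state_loading_matrix is not None:
            lam = np.atleast_2d(np.asarray(self.state_loading_matrix, dtype=float))
            if lam.shape[0] != self.n_items:
                lam = lam.T
            if lam.shape[0] != self.n_items:
                raise ConfigurationError("state_loading_matrix must be n_items x n_states")
            return lam
        base = DEFAULT_ITEM_LOADINGS
        reps = int(np.ceil(self.n_items / len(base)))
        return np.tile(base, reps)[: self.n_items, None]

    def network_labels(self) -> list[str]:
        return [f"net{i + 1}" for i in range(self.n_networks)]

    def node_networks(self) -> np.ndarray:
        """Nearly balanced node -> network assignment, in node order."""
        return np.array([f"net{(i % self.n_networks) + 1}" for i in range(self.n_nodes)])

    def _block_mask(self, block: tuple[int, int]) -> np.ndarray:
        nets = self.node_networks()
        la, lb = (f"net{block[0] + 1}", f"net{block[1] + 1}")
        in_a = nets == la
        in_b = nets == lb
        mask = np.outer(in_a, in_b) | np.outer(in_b, in_a)
        np.fill_diagonal(mask, False)
        return mask

    def edge_weights(self) -> np.ndarray:
        """(states, nodes, nodes) per-edge effect of each state on Fisher-z FC."""
        w = self.state_to_edge_weights
        if np.isscalar(w):
            mask = self._block_mask(self.state_block).astype(float)
            return np.repeat((float(w) * mask)[None, :, :], self.n_states, axis=0)
        w = np.asarray(w, dtype=float)
        if w.ndim == 2:
            w = w[None, :, :]
        if w.shape != (self.n_states, self.n_nodes, self.n_nodes):
            raise ConfigurationError("state_to_edge_weights must be (n_states, n_nodes, n_nodes)")
        return w

    def trait_weights(self) -> np.ndarray:
        return self.trait_edge_weight * self._block_mask(self.trait_block).astype(float)

    def fc_summary_block(self) -> tuple[str, str]:
        """The declared FNC contrast carrying the trait: a network-pair block
        whose mean edge is the behavioral 'FC summary'."""
        return (f"net{self.trait_block[0] + 1}", f"net{self.trait_block[1] + 1}")


@dataclasses.dataclass
class GroundTruth:
    """Everything the generator actually used, for recovery checks."""

    traits: np.ndarray                 # (n_subjects,)
    mean_states: np.ndarray            # (n_subjects, n_states)
    run_states: np.ndarray             # (n_subjects, n_runs, n_states)
    loadings: np.ndarray               # (n_items, n_states)
    edge_weights: np.ndarray           # (n_states, n_nodes, n_nodes)
    trait_weights: np.ndarray          # (n_nodes, n_nodes)
    path_a: float
    path_b: float
    path_cprime: float
    seed: int

    @property
    def expected_indirect(self) -> float:
        return self.path_a * self.path_b


def simulate_timeseries(
    target_fc: np.ndarray,
    n_timepoints: int,
    ar_coefficient: float = 0.0,
    seed: int | np.random.Generator | None = None,
    subject_id: str = "sub",
    run_id: str = "run",
    sampling_interval: float = 1.4,
    network_assignment: dict | None = None,
    burn_in: int = 50,
) -> ParcellatedTimeseries:
    """Stationary Gaussian series with a given population cross-correlation.

    Independent unit-variance AR(1) channels (identical autocorrelation,
    so the instantaneous cross-correlation is untouched) are colored by the
    Cholesky factor of ``target_fc``. The empirical correlation converges
    to the target as ``n_timepoints`` grows.
    """
    c = np.asarray(target_fc, dtype=float)
    n = c.shape[0]
    c = (c + c.T) / 2.0
    np.fill_diagonal(c, 1.0)
    try:
        chol = np.linalg.cholesky(c)
    except np.linalg.LinAlgError:
        raise MatrixError(
            "target FC matrix is not positive definite; repair it with a ridge, "
            "e.g. (C + eps*I) / (1 + eps)"
        ) from None
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    phi = float(ar_coefficient)
    innov = rng.standard_normal((n, n_timepoints + burn_in))
    if phi != 0.0:
        x = _signal.lfilter([np.sqrt(1 - phi**2)], [1.0, -phi], innov, axis=1)
    else:
        x = innov
    data = chol @ x[:, burn_in:]
    labels = [f"n{i + 1:04d}" for i in range(n)]
    if network_assignment is None:
        network_assignment = {lab: "net1" for lab in labels}
    return ParcellatedTimeseries(
        subject_id=subject_id,
        run_id=run_id,
        data=data,
        sampling_interval=sampling_interval,
        node_labels=labels,
        network_assignment=network_assignment,
    )


def _ridge_repair(c: np.ndarray, eps: float = 1e-6, max_tries: int = 40) -> np.ndarray:
    """Smallest diagonal ridge making a correlation matrix Cholesky-able."""
    for _ in range(max_tries):
        try:
            np.linalg.cholesky(c)
            return c
        except np.linalg.LinAlgError:
            c = (c + eps * np.eye(len(c))) / (1.0 + eps)
            eps *= 4
    raise MatrixError("could not repair target FC matrix to positive definite")


def generate_dataset(config: SyntheticConfig):
    """Generate one full synthetic dataset.

    Returns
    -------
    timeseries : list[ParcellatedTimeseries]
        One entry per subject-run (``n_subjects * n_runs``).
    snycq : DataFrame
        Per-run questionnaire scores on the {0, 5, ..., 100} grid; columns
        ``subject_id, run_id, item_01 ... item_NN``.
    behavior : DataFrame
        One row per subject with phenotypes ``mediated`` (planted paths
        a/b/c'), ``direct_only`` (same total effect, no mediation) and
        ``null_pheno`` (pure noise); ``missing_fraction`` of entries NaN.
    truth : GroundTruth
    """
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    (ss_trait, ss_state, ss_dev, ss_fing, ss_item, ss_behav, ss_mask, ss_ts) = ss.spawn(8)
    rng_trait = np.random.default_rng(ss_trait)
    rng_state = np.random.default_rng(ss_state)
    rng_dev = np.random.default_rng(ss_dev)
    rng_fing = np.random.default_rng(ss_fing)
    rng_item = np.random.default_rng(ss_item)
    rng_behav = np.random.default_rng(ss_behav)
    rng_mask = np.random.default_rng(ss_mask)

    n_s, n_r, n_k = cfg.n_subjects, cfg.n_runs, cfg.n_states
    a, b, cp = cfg.behavior_path_a, cfg.behavior_path_b, cfg.behavior_path_cprime

    traits = rng_trait.standard_normal(n_s)
    mean_states = a * traits[:, None] + np.sqrt(1 - a**2) * rng_state.standard_normal((n_s, n_k))
    deviations = cfg.state_run_sd * rng_dev.standard_normal((n_s, n_r, n_k))
    deviations -= deviations.mean(axis=1, keepdims=True)  # run-average identifies the mean state
    run_states = mean_states[:, None, :] + deviations

    # questionnaire scores: noisy item readouts -> normal-quantile map -> grid of 5
    lam = cfg.loadings
    state_var = 1.0 + cfg.state_run_sd**2 * (n_r - 1) / n_r
    raw_scale = np.sqrt((lam**2).sum(axis=1) * state_var + cfg.item_noise_sd**2)
    raw = run_states @ lam.T + cfg.item_noise_sd * rng_item.standard_normal((n_s, n_r, cfg.n_items))
    scores = 5.0 * np.round(20.0 * _stats.norm.cdf(raw / raw_scale))

    # FC targets in Fisher-z space: base network structure + subject
    # fingerprint + trait block + run-state blocks
    nets = cfg.node_networks()
    same_net = nets[:, None] == nets[None, :]
    base_r = np.where(same_net, cfg.within_network_r, cfg.between_network_r)
    np.fill_diagonal(base_r, 0.0)
    base_z = np.arctanh(base_r)
    w_state = cfg.edge_weights()
    w_trait = cfg.trait_weights()

    iu = np.triu_indices(cfg.n_nodes, k=1)
    assignment = dict(zip([f"n{i + 1:04d}" for i in range(cfg.n_nodes)], nets))
    run_seeds = ss_ts.spawn(n_s * n_r)
    timeseries = []
    snycq_rows = []
    for s in range(n_s):
        fing = np.zeros((cfg.n_nodes, cfg.n_nodes))
        fing[iu] = cfg.fingerprint_sd * rng_fing.standard_normal(len(iu[0]))
        fing = fing + fing.T
        subj_z = base_z + fing + w_trait * traits[s]
        for r in range(n_r):
            z = subj_z + np.tensordot(deviations[s, r], w_state, axes=1)
            target = np.tanh(z)
            np.fill_diagonal(target, 1.0)
            target = _ridge_repair(target)
            ts = simulate_timeseries(
                target,
                cfg.n_timepoints,
                ar_coefficient=cfg.ar_coefficient,
                seed=np.random.default_rng(run_seeds[s * n_r + r]),
                subject_id=f"sub{s + 1:03d}",
                run_id=f"run{r + 1}",
                sampling_interval=cfg.sampling_interval,
                network_assignment=assignment,
            )
            timeseries.append(ts)
            row = {"subject_id": f"sub{s + 1:03d}", "run_id": f"run{r + 1}"}
            for j in range(cfg.n_items):
                row[f"item_{j + 1:02d}"] = scores[s, r, j]
            snycq_rows.append(row)
    snycq = pd.DataFrame(snycq_rows)

    # behavior: planted mediated phenotype, a direct-only control with the
    # same total effect, and a pure-noise control
    m_bar = mean_states.mean(axis=1)
    noise_sd = np.sqrt(cfg._behavior_noise_var())
    mediated = cp * traits + b * m_bar + noise_sd * rng_behav.standard_normal(n_s)
    c_total = cp + a * b
    direct_only = c_total * traits + np.sqrt(max(1 - c_total**2, 1e-12)) * rng_behav.standard_normal(n_s)
    null_pheno = rng_behav.standard_normal(n_s)
    behavior = pd.DataFrame(
        {
            "subject_id": [f"sub{s + 1:03d}" for s in range(n_s)],
            "mediated": mediated,
            "direct_only": direct_only,
            "null_pheno": null_pheno,
        }
    )
    if cfg.missing_fraction > 0:
        for col in ("mediated", "direct_only", "null_pheno"):
            mask = rng_mask.random(n_s) < cfg.missing_fraction
            behavior.loc[mask, col] = np.nan

    truth = GroundTruth(
        traits=traits,
        mean_states=mean_states,
        run_states=run_states,
        loadings=lam,
        edge_weights=w_state,
        trait_weights=w_trait,
        path_a=a,
        path_b=b,
        path_cprime=cp,
        seed=cfg.seed,
    )
    return timeseries, snycq, behavior, truth
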