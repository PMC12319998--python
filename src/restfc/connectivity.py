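"""Functional-connectivity matrices, fingerprint vectors, and network-level
aggregation.

A run's FC matrix holds Fisher-z transformed Pearson correlations between
all node pairs. The FC fingerprint is the half-vectorized lower triangle
(row-major, 0-based, strictly below the diagonal). Network-level FNC
aggregates FC edges into a K x K matrix whose diagonal carries the mean
within-network edge (distinct node pairs only) and whose off-diagonal
carries the mean between-network edge.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .data import DataError, ParcellatedTimeseries, SchemaError

__all__ = [
    "FCMatrix",
    "FCVector",
    "FNCMatrix",
    "compute_fc",
    "vectorize_fc",
    "reassemble_fc",
    "aggregate_fnc",
    "concatenate_runs",
    "fnc_unique_edges",
]

#: Correlations are clamped to this magnitude before the atanh transform so
#: Fisher-z values stay finite for degenerate (duplicated-node) inputs.
R_CLAMP = 0.999999


@dataclasses.dataclass
class FCMatrix:
    """Symmetric node x node matrix of Fisher-z correlations.

    The diagonal is set to 0 and excluded from all downstream statistics.
    """

    values: np.ndarray
    node_labels: Sequence[str]
    networks: np.ndarray
    subject_id: str = ""
    run_id: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise SchemaError("FC matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise DataError("FC matrix is not symmetric")
        if not np.all(np.isfinite(v)):
            raise DataError("non-finite FC values")
        self.values = v
        self.networks = np.asarray(self.networks)

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


@dataclasses.dataclass
class FCVector:
    """Half-vectorized FC fingerprint: the strict lower triangle in
    row-major order. ``index_map[k] = (i, j)`` with ``i > j``."""

    values: np.ndarray
    index_map: np.ndarray  # (n_edges, 2) int array, columns (node_i, node_j)
    subject_id: str = ""
    run_id: str = ""

    def __len__(self) -> int:
        return len(self.values)


@dataclasses.dataclass
class FNCMatrix:
    """K x K network-averaged connectivity; diagonal = within-network mean.

    ``undefined`` flags networks with fewer than 2 nodes, whose diagonal
    entry has no distinct node pair and is NaN.
    """

    values: np.ndarray
    network_labels: Sequence[str]
    undefined: Sequence[str]
    subject_id: str = ""
    run_id: str = ""

    @property
    def n_networks(self) -> int:
        return self.values.shape[0]

    def unique_edges(self) -> pd.Series:
        """The K(K+1)/2 unique entries (lower triangle incl. diagonal),
        indexed by '<net_a>-<net_b>' labels; undefined entries dropped."""
        labels = list(self.network_labels)
        out = {}
        for i in range(len(labels)):
            for j in range(i + 1):
                if i == j and labels[i] in self.undefined:
                    continue
                out[f"{labels[j]}-{labels[i]}"] = self.values[i, j]
        return pd.Series(out)


def compute_fc(ts: ParcellatedTimeseries) -> FCMatrix:
    """Fisher-z FC matrix from one run: pairwise Pearson r, clamped to
    ``|r| <= 0.999999``, then atanh. Diagonal forced to 0."""
    if ts.n_timepoints < 3:
        raise DataError("need at least 3 timepoints to estimate correlations")
    sd = ts.data.std(axis=1)
    dead = np.where(sd == 0)[0]
    if dead.size:
        names = [ts.node_labels[i] for i in dead[:5]]
        raise DataError(f"zero-variance node(s): {names}")
    r = np.corrcoef(ts.data)
    r = np.clip(r, -R_CLAMP, R_CLAMP)
    z = np.arctanh(r)
    np.fill_diagonal(z, 0.0)
    z = (z + z.T) / 2.0  # exact symmetry against float round-off
    return FCMatrix(
        values=z,
        node_labels=list(ts.node_labels),
        networks=ts.networks,
        subject_id=ts.subject_id,
        run_id=ts.run_id,
    )


def _tril_indices(n: int) -> np.ndarray:
    i, j = np.tril_indices(n, k=-1)
    return np.column_stack([i, j])


def vectorize_fc(fc: FCMatrix) -> FCVector:
    """Lower-triangle fingerprint vector of length n(n-1)/2 with its
    position -> (node_i, node_j) index map (row-major, i > j)."""
    idx = _tril_indices(fc.n_nodes)
    return FCVector(
        values=fc.values[idx[:, 0], idx[:, 1]].copy(),
        index_map=idx,
        subject_id=fc.subject_id,
        run_id=fc.run_id,
    )


def reassemble_fc(vec: FCVector, n_nodes: int | None = None) -> np.ndarray:
    """Rebuild the symmetric off-diagonal matrix from a fingerprint vector
    (round-trip inverse of :func:`vectorize_fc`; diagonal zero)."""
    if n_nodes is None:
        n_nodes = int(vec.index_map.max()) + 1
    m = np.zeros((n_nodes, n_nodes))
    m[vec.index_map[:, 0], vec.index_map[:, 1]] = vec.values
    return m + m.T


def aggregate_fnc(fc: FCMatrix) -> FNCMatrix:
    """Average FC edges into a K x K network-level (FNC) matrix.

    Off-diagonal (A, B): mean over all edges with one endpoint in A and
    one in B. Diagonal (A, A): mean over distinct node pairs within A
    (self-pairs excluded). A network with < 2 nodes gets a NaN diagonal
    entry and is listed in ``undefined``.
    """
    networks = np.asarray(fc.networks)
    labels = sorted(pd.unique(networks).tolist())
    if len(labels) < 2:
        raise DataError("need at least 2 networks to aggregate")
    k = len(labels)
    out = np.zeros((k, k))
    undefined = []
    members = {lab: np.where(networks == lab)[0] for lab in labels}
    for a in range(k):
        ia = members[labels[a]]
        for b in range(a + 1):
            ib = members[labels[b]]
            if a == b:
                if len(ia) < 2:
                    out[a, a] = np.nan
                    undefined.append(labels[a])
                    continue
                block = fc.values[np.ix_(ia, ia)]
                iu = np.triu_indices(len(ia), k=1)
                out[a, a] = block[iu].mean()
            else:
                out[a, b] = out[b, a] = fc.values[np.ix_(ia, ib)].mean()
    return FNCMatrix(
        values=out,
        network_labels=labels,
        undefined=undefined,
        subject_id=fc.subject_id,
        run_id=fc.run_id,
    )


def fnc_unique_edges(k: int) -> int:
    """Number of unique FNC entries for K networks (K(K+1)/2; 36 for K=8)."""
    return k * (k + 1) // 2


def concatenate_runs(runs: Sequence[ParcellatedTimeseries]) -> ParcellatedTimeseries:
    """Join runs along time for one subject, z-scoring each run per node
    first so inter-run mean/scale offsets cannot inflate correlations."""
    if not runs:
        raise SchemaError("no runs to concatenate")
    ref = runs[0]
    bad = [r.run_id for r in runs if list(r.node_labels) != list(ref.node_labels)]
    if bad:
        raise SchemaError(f"runs with mismatched node sets: {bad}")
    blocks = []
    for r in runs:
        mu = r.data.mean(axis=1, keepdims=True)
        sd = r.data.std(axis=1, keepdims=True)
        if np.any(sd == 0):
            raise DataError(f"zero-variance node in run {r.run_id}")
        blocks.append((r.data - mu) / sd)
    joined = np.hstack(blocks)
    return ParcellatedTimeseries(
        subject_id=ref.subject_id,
        run_id="+".join(r.run_id for r in runs),
        data=joined,
        sampling_interval=ref.sampling_interval,
        node_labels=list(ref.node_labels),
        network_assignment=dict(ref.network_assignment),
    )
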