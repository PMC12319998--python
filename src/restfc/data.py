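"""Core data containers shared across the pipeline.

The atomic unit of the package is one resting-state run of parcellated
(node-level) BOLD timeseries for one subject, together with the node
network labels needed for network-level aggregation.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["ParcellatedTimeseries", "read_timeseries", "write_timeseries"]


class SchemaError(ValueError):
    """Input table does not have the expected shape or columns."""


class DataError(ValueError):
    """Input values violate a data contract (non-finite, zero variance, ...)."""


@dataclasses.dataclass
class ParcellatedTimeseries:
    """Node-by-time numeric matrix for one subject-run.

    Parameters
    ----------
    subject_id, run_id
        Labels identifying the subject and the run within subject.
    data
        ``(n_nodes, n_timepoints)`` float array.
    sampling_interval
        Repetition time in seconds.
    node_labels
        One label per node (row).
    network_assignment
        Node -> network label map covering every node exactly once.
    """

    subject_id: str
    run_id: str
    data: np.ndarray
    sampling_interval: float
    node_labels: Sequence[str]
    network_assignment: Mapping[str, str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise SchemaError("timeseries data must be a 2-D node x time matrix")
        if len(self.node_labels) != self.data.shape[0]:
            raise SchemaError(
                f"{len(self.node_labels)} node labels for {self.data.shape[0]} rows"
            )
        missing = [n for n in self.node_labels if n not in self.network_assignment]
        if missing:
            raise SchemaError(f"nodes without network assignment: {missing[:5]}")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")

    @property
    def n_nodes(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]

    @property
    def networks(self) -> np.ndarray:
        """Network label per node, in node order."""
        return np.asarray([self.network_assignment[n] for n in self.node_labels])

    def copy_with(self, data: np.ndarray) -> "ParcellatedTimeseries":
        """Same metadata, new data matrix (used by denoising stages)."""
        return ParcellatedTimeseries(
            subject_id=self.subject_id,
            run_id=self.run_id,
            data=np.asarray(data, dtype=float),
            sampling_interval=self.sampling_interval,
            node_labels=list(self.node_labels),
            network_assignment=dict(self.network_assignment),
        )


def write_timeseries(ts: ParcellatedTimeseries, directory: str | Path) -> Path:
    """Write one run as a delimited matrix plus a node-network sidecar table.

    Returns the path of the matrix file
    (``<subject>_<run>_timeseries.tsv``); the sidecar is
    ``<subject>_<run>_nodes.tsv`` with columns ``node`` and ``network``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = f"{ts.subject_id}_{ts.run_id}"
    mat_path = directory / f"{stem}_timeseries.tsv"
    df = pd.DataFrame(ts.data, index=list(ts.node_labels))
    df.to_csv(mat_path, sep="\t", header=False, float_format="%.8g")
    sidecar = pd.DataFrame(
        {"node": list(ts.node_labels), "network": [ts.network_assignment[n] for n in ts.node_labels]}
    )
    sidecar["sampling_interval"] = ts.sampling_interval
    sidecar.to_csv(directory / f"{stem}_nodes.tsv", sep="\t", index=False)
    return mat_path


def read_timeseries(mat_path: str | Path) -> ParcellatedTimeseries:
    """Read a run written by :func:`write_timeseries`."""
    mat_path = Path(mat_path)
    stem = mat_path.name.removesuffix("_timeseries.tsv")
    subject_id, _, run_id = stem.rpartition("_")
    df = pd.read_csv(mat_path, sep="\t", header=None, index_col=0)
    sidecar = pd.read_csv(mat_path.with_name(f"{stem}_nodes.tsv"), sep="\t")
    assignment = dict(zip(sidecar["node"].astype(str), sidecar["network"].astype(str)))
    return ParcellatedTimeseries(
        subject_id=subject_id,
        run_id=run_id,
        data=df.to_numpy(dtype=float),
        sampling_interval=float(sidecar["sampling_interval"].iloc[0]),
        node_labels=[str(n) for n in df.index],
        network_assignment=assignment,
    )
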