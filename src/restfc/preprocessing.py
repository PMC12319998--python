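"""Node-level denoising and run exclusion.

Operates from the parcellated stage onward: nuisance regression against a
confound design (motion, tissue signals, their derivatives, slow-drift
cosines), zero-phase low-pass filtering, and motion-based run exclusion.
Volume-level steps (realignment, registration, distortion correction) are
out of scope; confound regression on node series is used in place of the
voxelwise original, which commutes with linear parcellation averaging up
to the parcel-mean approximation.

The processing order contract is: confound regression first, then the
low-pass filter (see :func:`denoise`).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .data import DataError, ParcellatedTimeseries, SchemaError

__all__ = [
    "ConfoundSet",
    "MotionSummary",
    "mean_rms_displacement",
    "build_cosine_basis",
    "regress_confounds",
    "lowpass_filter",
    "denoise",
    "MOTION_THRESHOLD_MM",
]

#: Default exclusion threshold on mean frame-to-frame RMS displacement (mm).
MOTION_THRESHOLD_MM = 0.25

#: Default rotation-to-displacement conversion radius (mm).
BRAIN_RADIUS_MM = 50.0

#: Default slow-drift cutoff period for the cosine basis (seconds).
DRIFT_CUTOFF_S = 128.0


@dataclasses.dataclass
class MotionSummary:
    """Motion summary for one run: mean relative RMS displacement and the
    exclusion flag (excluded iff strictly greater than the threshold)."""

    run_id: str
    mean_rms_displacement: float
    excluded: bool
    threshold: float = MOTION_THRESHOLD_MM


def mean_rms_displacement(
    motion_parameters: np.ndarray | pd.DataFrame,
    brain_radius: float = BRAIN_RADIUS_MM,
    threshold: float = MOTION_THRESHOLD_MM,
    run_id: str = "",
) -> MotionSummary:
    """Mean frame-to-frame RMS displacement from 6 rigid-body parameters.

    Expects a time x 6 table: three translations in millimetres followed by
    three rotations in radians. Rotations are converted to arc length at
    ``brain_radius``; per-frame displacement is the Euclidean norm of the
    six converted first differences, averaged over frame transitions
    (FSL-style relative displacement).

    A run is flagged ``excluded`` when the mean displacement is strictly
    greater than ``threshold`` (a run exactly at the threshold is kept).
    """
    params = np.asarray(motion_parameters, dtype=float)
    if params.ndim != 2 or params.shape[1] != 6:
        raise SchemaError(
            f"motion parameters must be time x 6 (3 translations mm, 3 rotations rad); got {params.shape}"
        )
    if not np.all(np.isfinite(params)):
        raise DataError("non-finite motion parameters")
    diffs = np.diff(params, axis=0)
    diffs[:, 3:] *= brain_radius
    per_frame = np.sqrt(np.sum(diffs**2, axis=1))
    mean_disp = float(per_frame.mean()) if per_frame.size else 0.0
    return MotionSummary(
        run_id=run_id,
        mean_rms_displacement=mean_disp,
        excluded=bool(mean_disp > threshold),
        threshold=threshold,
    )


def build_cosine_basis(
    n_timepoints: int, sampling_interval: float, cutoff_period: float = DRIFT_CUTOFF_S
) -> np.ndarray:
    """Discrete-cosine drift basis covering periods >= ``cutoff_period``.

    Returns ``n_timepoints x k`` with ``k = floor(2 * N * TR / cutoff_period)``
    unit-normalized, mutually orthogonal DCT-II columns (no constant term;
    the regression design supplies its own intercept). ``k`` may be 0.
    """
    if n_timepoints < 2:
        raise ValueError("need at least 2 timepoints for a drift basis")
    if cutoff_period <= 2 * sampling_interval:
        raise ValueError("cutoff_period must exceed twice the sampling interval")
    n_cols = int(np.floor(2.0 * n_timepoints * sampling_interval / cutoff_period))
    t = np.arange(n_timepoints)
    basis = np.empty((n_timepoints, n_cols))
    for k in range(1, n_cols + 1):
        col = np.cos(np.pi * k * (2 * t + 1) / (2.0 * n_timepoints))
        basis[:, k - 1] = col / np.linalg.norm(col)
    return basis


@dataclasses.dataclass
class ConfoundSet:
    """Nuisance regressors for one run.

    ``motion_parameters`` is time x 6; ``tissue_signals`` holds the
    white-matter, CSF and global-signal columns (time x m). First-order
    temporal derivatives of both blocks are appended automatically
    (backward differences, first row zero), together with the cosine
    drift columns.
    """

    motion_parameters: np.ndarray | None = None
    tissue_signals: np.ndarray | None = None
    cosine_basis: np.ndarray | None = None
    include_derivatives: bool = True

    def design_matrix(self, n_timepoints: int) -> np.ndarray:
        """Full-rank confound design including an intercept column."""
        blocks = [np.ones((n_timepoints, 1))]
        raw = []
        for block in (self.motion_parameters, self.tissue_signals):
            if block is None:
                continue
            block = np.atleast_2d(np.asarray(block, dtype=float))
            if block.shape[0] != n_timepoints:
                block = block.T
            if block.shape[0] != n_timepoints:
                raise SchemaError("confound block length does not match the timeseries")
            raw.append(block)
        for block in raw:
            blocks.append(block)
        if self.include_derivatives:
            for block in raw:
                blocks.append(np.diff(block, axis=0, prepend=block[:1]))
        if self.cosine_basis is not None:
            cb = np.asarray(self.cosine_basis, dtype=float)
            if cb.shape[0] != n_timepoints:
                raise SchemaError("cosine basis length does not match the timeseries")
            blocks.append(cb)
        design = np.hstack(blocks)
        if not np.all(np.isfinite(design)):
            raise DataError("non-finite values in confound regressors")
        return _drop_dependent_columns(design)


def _drop_dependent_columns(design: np.ndarray, rtol: float = 1e-10) -> np.ndarray:
    """Reduce a rank-deficient design by pivoted-QR column selection."""
    from scipy.linalg import qr

    _, r, piv = qr(design, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    keep = diag > rtol * diag.max()
    kept = np.sort(piv[: keep.sum()])
    return design[:, kept]


def regress_confounds(ts: ParcellatedTimeseries, confounds: ConfoundSet) -> ParcellatedTimeseries:
    """Replace each node series by its least-squares residual against the
    confound design (intercept always included).

    Residuals are numerically orthogonal to every confound column; applying
    the same regression twice is a no-op.
    """
    design = confounds.design_matrix(ts.n_timepoints)
    y = ts.data.T  # time x nodes
    if not np.all(np.isfinite(y)):
        raise DataError("non-finite values in timeseries")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    residual = y - design @ beta
    return ts.copy_with(residual.T)


def lowpass_filter(ts: ParcellatedTimeseries, cutoff_hz: float = 0.1, order: int = 4) -> ParcellatedTimeseries:
    """Zero-phase Butterworth low-pass filter applied along time.

    A forward-backward (filtfilt) order-``order`` Butterworth design: zero
    phase distortion, squared magnitude response. ``cutoff_hz`` must be
    below the Nyquist frequency implied by the sampling interval.
    """
    fs = 1.0 / ts.sampling_interval
    if cutoff_hz >= fs / 2.0:
        raise ValueError(f"cutoff {cutoff_hz} Hz is at or above Nyquist ({fs / 2.0:.4g} Hz)")
    if cutoff_hz <= 0:
        raise ValueError("cutoff must be positive")
    sos = signal.butter(order, cutoff_hz, btype="low", fs=fs, output="sos")
    filtered = signal.sosfiltfilt(sos, ts.data, axis=1)
    return ts.copy_with(filtered)


def denoise(
    ts: ParcellatedTimeseries,
    confounds: ConfoundSet | None = None,
    cutoff_hz: float = 0.1,
    drift_cutoff_period: float = DRIFT_CUTOFF_S,
) -> ParcellatedTimeseries:
    """Full node-level denoising for one run: confound regression, then the
    0.1 Hz low-pass filter (in that order).

    When ``confounds`` carries no cosine basis, one is built from the run's
    length and sampling interval with ``drift_cutoff_period``.
    """
    if confounds is None:
        confounds = ConfoundSet()
    if confounds.cosine_basis is None:
        confounds = dataclasses.replace(
            confounds,
            cosine_basis=build_cosine_basis(ts.n_timepoints, ts.sampling_interval, drift_cutoff_period),
        )
    return lowpass_filter(regress_confounds(ts, confounds), cutoff_hz=cutoff_hz)


def motion_table(summaries: Sequence[MotionSummary], subject_ids: Sequence[str] | None = None) -> pd.DataFrame:
    """Run-level motion summary table (subject, run, displacement, excluded)."""
    rows = []
    for i, s in enumerate(summaries):
        rows.append(
            {
                "subject_id": subject_ids[i] if subject_ids is not None else "",
                "run_id": s.run_id,
                "mean_rms_displacement": s.mean_rms_displacement,
                "excluded": s.excluded,
            }
        )
    return pd.DataFrame(rows)
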