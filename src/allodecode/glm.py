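"""Nuisance removal and per-trial beta-series estimation.

The preprocessing contract is: (1) high-pass filter the voxel time series by
projecting out a cosine drift basis with a 128 s cutoff; (2) regress out a
24-column motion confound model (parameters, backward differences, squares
and squared differences), the confounds themselves filtered identically;
(3) estimate one beta per trial with the "Add" scheme — for each trial, an
ordinary least-squares fit with three columns: an unconvolved boxcar covering
the three volumes acquired 6-12 s after that trial's onset, a union boxcar of
all other trials' windows, and an intercept. The 6-12 s window targets the
haemodynamic peak of the stationary (blank-screen) phase of the trial, which
occupies 2-6 s after onset. A volume counts as inside a window when its
acquisition midpoint does, so on-grid onsets at TR = 2 s activate exactly
three volumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .synth import MotionSeries, RoiTimeSeries

__all__ = [
    "ConfoundMatrix",
    "TrialBetas",
    "friston24_expansion",
    "cosine_drift_basis",
    "highpass",
    "highpass_array",
    "residualize",
    "trial_boxcar",
    "estimate_trial_betas",
    "WINDOW_START_S",
    "WINDOW_END_S",
]

logger = logging.getLogger(__name__)

#: beta-estimation window relative to trial onset, half-open [start, end)
WINDOW_START_S = 6.0
WINDOW_END_S = 12.0


@dataclass
class ConfoundMatrix:
    """24 x T motion confound model: parameters, their backward differences,
    their squares, and the squares of the differences (in that row order)."""

    rows: np.ndarray  # (24, T)

    def validate(self) -> None:
        if self.rows.shape[0] != 24:
            raise ValueError("confound matrix must have 24 rows")
        if not np.allclose(self.rows[12:18], self.rows[0:6] ** 2):
            raise ValueError("rows 13-18 must be squares of rows 1-6")
        if not np.allclose(self.rows[18:24], self.rows[6:12] ** 2):
            raise ValueError("rows 19-24 must be squares of rows 7-12")


@dataclass
class TrialBetas:
    """Per-trial response estimates for one run, rows in trial-table order."""

    run: int
    betas: np.ndarray  # (n_trials, n_voxels)

    def validate(self) -> None:
        if not np.all(np.isfinite(self.betas)):
            raise ValueError("betas contain non-finite values")


def friston24_expansion(motion: MotionSeries) -> ConfoundMatrix:
    """Expand six realignment parameters to the 24-regressor motion model.

    The derivative is the backward difference with the first sample set to 0.
    """
    p = np.asarray(motion.params, dtype=float)
    if p.shape[0] != 6 or p.shape[1] < 2:
        raise ValueError("motion must be 6 x T with T >= 2")
    d = np.zeros_like(p)
    d[:, 1:] = np.diff(p, axis=1)
    cm = ConfoundMatrix(rows=np.vstack([p, d, p**2, d**2]))
    cm.validate()
    return cm


def cosine_drift_basis(T: int, tr_s: float, cutoff_s: float = 128.0) -> np.ndarray:
    """DCT-II drift basis whose columns span fluctuations slower than
    ``cutoff_s``: component k has frequency k / (2 T TR), and k runs from 1 to
    floor(2 T TR / cutoff). Columns are unit-normalised; a (T, K) array
    (possibly K = 0)."""
    if cutoff_s <= 2 * tr_s:
        raise ValueError("cutoff must exceed twice the TR")
    K = int(np.floor(2 * T * tr_s / cutoff_s))
    n = np.arange(T)
    basis = np.column_stack(
        [np.cos(np.pi * k * (2 * n + 1) / (2 * T)) for k in range(1, K + 1)]
    ) if K else np.empty((T, 0))
    if K:
        basis /= np.linalg.norm(basis, axis=0, keepdims=True)
    return basis


def highpass_array(data: np.ndarray, tr_s: float, cutoff_s: float = 128.0) -> np.ndarray:
    """High-pass rows of a (channels, T) array by projecting out the cosine
    drift basis; the per-channel mean is preserved."""
    data = np.asarray(data, dtype=float)
    T = data.shape[1]
    basis = cosine_drift_basis(T, tr_s, cutoff_s)
    mean = data.mean(axis=1, keepdims=True)
    centred = data - mean
    if basis.shape[1]:
        centred = centred - (centred @ basis) @ basis.T
    return centred + mean


def highpass(ts: RoiTimeSeries, cutoff_s: float = 128.0) -> RoiTimeSeries:
    """High-pass an ROI time series (see :func:`highpass_array`)."""
    return RoiTimeSeries(
        roi_label=ts.roi_label,
        data=highpass_array(ts.data, ts.tr_s, cutoff_s),
        tr_s=ts.tr_s,
        run=ts.run,
    )


def residualize(ts: RoiTimeSeries, confounds: ConfoundMatrix) -> RoiTimeSeries:
    """Per-voxel OLS residuals of the series against the confound rows plus an
    intercept. The caller is responsible for filtering the confounds with the
    same high-pass as the data. Rank-deficient confound sets are handled by
    the pseudoinverse (equivalent to dropping dependent rows) with a warning.
    """
    X = np.column_stack([confounds.rows.T, np.ones(confounds.rows.shape[1])])
    if X.shape[0] != ts.n_volumes:
        raise ValueError("confound length does not match time series")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        logger.warning(
            "confound matrix rank-deficient (rank %d < %d); dependent rows ignored",
            rank,
            X.shape[1],
        )
    coef, *_ = np.linalg.lstsq(X, ts.data.T, rcond=None)
    resid = ts.data.T - X @ coef
    return RoiTimeSeries(roi_label=ts.roi_label, data=resid.T, tr_s=ts.tr_s, run=ts.run)


def trial_boxcar(onset_s: float, T: int, tr_s: float) -> np.ndarray:
    """Unconvolved 0/1 regressor: volumes whose acquisition midpoint lies in
    [onset + 6 s, onset + 12 s)."""
    mids = (np.arange(T) + 0.5) * tr_s
    return ((mids >= onset_s + WINDOW_START_S) & (mids < onset_s + WINDOW_END_S)).astype(float)


def estimate_trial_betas(ts: RoiTimeSeries, onsets: Sequence[float], run: int | None = None) -> TrialBetas:
    """Estimate each trial's response with its own 3-column "Add" model.

    For trial t the design is [boxcar(t), union of all other trials' boxcars,
    intercept]; the stored estimate is the coefficient of the first column.
    ``ts`` should already be high-passed and residualized.
    """
    onsets = np.asarray(onsets, dtype=float)
    T, tr = ts.n_volumes, ts.tr_s
    boxcars = np.stack([trial_boxcar(o, T, tr) for o in onsets])  # (n_trials, T)
    for i, (o, b) in enumerate(zip(onsets, boxcars)):
        if o + WINDOW_END_S > T * tr:
            raise ValueError(f"trial {i} window extends past run end (onset {o:.1f} s)")
        n_active = int(b.sum())
        if n_active != 3:
            logger.info("trial %d has %d active volumes (off-grid onset)", i, n_active)
    betas = np.empty((len(onsets), ts.n_voxels))
    ones = np.ones(T)
    for t in range(len(onsets)):
        others = (boxcars.sum(axis=0) - boxcars[t] > 0).astype(float)
        X = np.column_stack([boxcars[t], others, ones])
        coef, *_ = np.linalg.lstsq(X, ts.data.T, rcond=None)
        betas[t] = coef[0]
    tb = TrialBetas(run=run if run is not None else ts.run, betas=betas)
    tb.validate()
    return tb


def preprocess_run(
    ts: RoiTimeSeries,
    motion: MotionSeries | None,
    cutoff_s: float = 128.0,
) -> RoiTimeSeries:
    """High-pass, then regress out the 24-regressor motion model (confounds
    filtered with the same high-pass). With ``motion=None`` only the filter is
    applied."""
    filtered = highpass(ts, cutoff_s)
    if motion is None:
        return filtered
    conf = friston24_expansion(motion)
    conf_filtered = ConfoundMatrix(rows=highpass_array(conf.rows, ts.tr_s, cutoff_s))
    return residualize(filtered, conf_filtered)
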