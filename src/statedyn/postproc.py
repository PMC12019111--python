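"""ROI time-series postprocessing: detrend, band-pass, nuisance
regression, motion/intensity scrubbing, demeaning.

The stages mirror a standard resting-state BOLD postprocessing chain:
linear detrending, a 0.01-0.08 Hz zero-phase Butterworth band-pass,
OLS regression of six motion and three tissue (WM/CSF/global signal)
nuisance regressors, censoring of frames with framewise displacement
(FD) > 0.5 mm or DVARS > 150, and demeaning over the kept frames.
Filtering precedes censoring so the filter never sees gapped data;
censoring marks frames in the mask rather than deleting rows, and
downstream stages drop masked frames.
"""
from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .types import RoiTimeSeries, ScrubbingReport

FD_THRESHOLD_MM = 0.5
DVARS_THRESHOLD = 150.0
HEAD_RADIUS_MM = 50.0  # Power-style rotation-to-arc-length conversion


class EmptyScanError(ValueError):
    """Raised when an operation is left with zero kept frames."""


def detrend(ts: RoiTimeSeries) -> RoiTimeSeries:
    """Remove the per-ROI least-squares linear trend (and hence the mean)."""
    if ts.n_frames < 3:
        raise ValueError("detrend requires at least 3 frames")
    out = sps.detrend(ts.data, axis=0, type="linear")
    return ts.copy_with(out)


def _bandpass_array(data: np.ndarray, tr_seconds: float, low_hz: float,
                    high_hz: float, order: int) -> np.ndarray:
    nyquist = 1.0 / (2.0 * tr_seconds)
    if high_hz >= nyquist:
        raise ValueError(f"high_hz={high_hz} must be below Nyquist={nyquist:.4f} Hz")
    if low_hz >= high_hz:
        raise ValueError("low_hz must be below high_hz")
    b, a = sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=1.0 / tr_seconds)
    # remove the column mean first (the filter's DC gain is zero anyway);
    # Gustafsson edge handling keeps start/end transients out of the output
    centered = data - data.mean(axis=0, keepdims=True)
    return sps.filtfilt(b, a, centered, axis=0, method="gust")


def bandpass(ts: RoiTimeSeries, low_hz: float = 0.01, high_hz: float = 0.08,
             order: int = 2) -> RoiTimeSeries:
    """Zero-phase Butterworth band-pass per ROI (forward-backward)."""
    return ts.copy_with(_bandpass_array(ts.data, ts.tr_seconds, low_hz, high_hz, order))


def regress_nuisance(ts: RoiTimeSeries) -> RoiTimeSeries:
    """OLS-residualize every ROI column on [intercept | 9 confounds]."""
    if ts.confounds is None:
        raise ValueError("confounds are required for nuisance regression")
    conf = np.asarray(ts.confounds, dtype=float)
    design = np.column_stack([np.ones(ts.n_frames), conf])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify columns whose removal restores full rank
        bad = []
        for j in range(1, design.shape[1]):
            reduced = np.delete(design, j, axis=1)
            if np.linalg.matrix_rank(reduced) == rank:
                bad.append(ts.confounds.columns[j - 1])
        raise ValueError(f"rank-deficient confound design; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(design, ts.data, rcond=None)
    out = ts.data - design @ beta
    return ts.copy_with(out)


def compute_fd(motion_params: np.ndarray, head_radius_mm: float = HEAD_RADIUS_MM) -> np.ndarray:
    """Framewise displacement: sum of |frame-to-frame| changes of the six
    rigid-body parameters, rotations (rad) converted to arc length on a
    sphere of ``head_radius_mm``. ``fd[0] = 0`` (no predecessor)."""
    motion = np.asarray(motion_params, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6 or motion.shape[0] < 2:
        raise ValueError("motion_params must be a T x 6 matrix with T >= 2")
    diffs = np.abs(np.diff(motion, axis=0))
    diffs[:, 3:] *= head_radius_mm
    fd = np.zeros(motion.shape[0])
    fd[1:] = diffs.sum(axis=1)
    return fd


def compute_dvars(data: np.ndarray) -> np.ndarray:
    """DVARS: RMS across ROIs of the frame-to-frame signal difference;
    ``dvars[0] = 0`` by convention."""
    data = np.asarray(data, dtype=float)
    dvars = np.zeros(data.shape[0])
    dvars[1:] = np.sqrt(np.mean(np.diff(data, axis=0) ** 2, axis=1))
    return dvars


def censor_frames(fd: np.ndarray, dvars: np.ndarray,
                  fd_thresh: float = FD_THRESHOLD_MM,
                  dvars_thresh: float = DVARS_THRESHOLD) -> np.ndarray:
    """Keep-mask: frame t is censored iff fd[t] > fd_thresh OR
    dvars[t] > dvars_thresh (strict inequalities)."""
    fd = np.asarray(fd, dtype=float)
    dvars = np.asarray(dvars, dtype=float)
    if fd.shape != dvars.shape:
        raise ValueError("fd and dvars must have equal length")
    return ~((fd > fd_thresh) | (dvars > dvars_thresh))


def demean(ts: RoiTimeSeries) -> RoiTimeSeries:
    """Subtract each ROI's mean over kept frames (censored frames shift too)."""
    if ts.n_kept == 0:
        raise EmptyScanError("no kept frames to demean over")
    means = ts.data[ts.censor_mask].mean(axis=0)
    return ts.copy_with(ts.data - means)


def postprocess_scan(
    ts: RoiTimeSeries,
    low_hz: float = 0.01,
    high_hz: float = 0.08,
    fd_thresh: float = FD_THRESHOLD_MM,
    dvars_thresh: float = DVARS_THRESHOLD,
) -> tuple[RoiTimeSeries, ScrubbingReport]:
    """Full chain: detrend -> band-pass -> nuisance regression -> censor ->
    demean. FD comes from the raw motion regressors; DVARS from the
    regressed (pre-censoring) series. Confound columns are filtered with
    the data so the regression cannot reintroduce out-of-band energy.
    """
    out = detrend(ts)
    out = bandpass(out, low_hz, high_hz)
    if out.confounds is not None:
        filt_conf = out.confounds.copy()
        filt_conf.iloc[:, :] = _bandpass_array(
            np.asarray(out.confounds, float), ts.tr_seconds, low_hz, high_hz, 2)
        tmp = RoiTimeSeries(out.data, out.tr_seconds, out.subject_id, out.condition,
                            confounds=filt_conf, censor_mask=out.censor_mask)
        out = regress_nuisance(tmp)
        fd = compute_fd(np.asarray(ts.confounds)[:, :6])
    else:
        fd = np.zeros(ts.n_frames)
    dvars = compute_dvars(out.data)
    keep = censor_frames(fd, dvars, fd_thresh, dvars_thresh) & ts.censor_mask
    if not keep.any():
        raise EmptyScanError("all frames censored")
    # the raw confounds travel with the output so the chain can be re-applied
    raw_conf = None if ts.confounds is None else ts.confounds.copy()
    out = RoiTimeSeries(out.data, out.tr_seconds, out.subject_id, out.condition,
                        confounds=raw_conf, censor_mask=keep)
    out = demean(out)
    report = ScrubbingReport(fd=fd, dvars=dvars,
                             n_censored=int((~keep).sum()),
                             fd_thresh=fd_thresh, dvars_thresh=dvars_thresh)
    return out, report
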