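"""Temporal denoising: nuisance regression and band-pass filtering.

Mirrors Conn-style resting-state denoising: mean white-matter / CSF
signals are regressed out of every channel, then a zero-phase
0.008-0.08 Hz band-pass keeps the canonical resting-state band.
Regression runs before filtering so the confound fit cannot reintroduce
out-of-band energy.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal

from .containers import TimeSeries

DEFAULT_BAND = (0.008, 0.08)  # Hz


def bandpass(series: TimeSeries, low_hz: float = DEFAULT_BAND[0],
             high_hz: float = DEFAULT_BAND[1], order: int = 2) -> TimeSeries:
    """Zero-phase Butterworth band-pass (forward-backward) per channel.

    ``low_hz = 0`` degenerates to a low-pass. The effective magnitude
    response is the squared single-pass response (filtfilt).
    """
    fs = 1.0 / series.tr_seconds
    nyq = fs / 2.0
    if not (0 <= low_hz < high_hz):
        raise ValueError("require 0 <= low_hz < high_hz")
    if high_hz >= nyq:
        raise ValueError(
            f"high_hz={high_hz} must be below the Nyquist frequency "
            f"{nyq:.6g} Hz implied by TR={series.tr_seconds} s")
    if low_hz > 0:
        sos = signal.butter(order, [low_hz, high_hz], btype="bandpass",
                            fs=fs, output="sos")
    else:
        sos = signal.butter(order, high_hz, btype="lowpass", fs=fs,
                            output="sos")
    filtered = signal.sosfiltfilt(sos, series.values, axis=0)
    return series.copy_with(filtered)


def regress_nuisance(series: TimeSeries, confounds: np.ndarray) -> TimeSeries:
    """Residualize each channel on [intercept | confounds] (least squares).

    Exactly collinear confound columns (after intercept augmentation)
    are dropped with a warning naming the dropped column indices.
    Residuals are orthogonal to every retained confound.
    """
    confounds = np.atleast_2d(np.asarray(confounds, dtype=float))
    if confounds.shape[0] != series.n_time:
        if confounds.shape[1] == series.n_time:
            confounds = confounds.T
        else:
            raise ValueError("confounds must have the same number of time "
                             "points as the series")
    X = np.column_stack([np.ones(series.n_time), confounds])
    keep = np.ones(X.shape[1], dtype=bool)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # greedy scan: drop any column linearly dependent on earlier ones
        kept_cols: list[int] = []
        for j in range(X.shape[1]):
            trial = X[:, kept_cols + [j]]
            if np.linalg.matrix_rank(trial) == len(kept_cols) + 1:
                kept_cols.append(j)
            else:
                keep[j] = False
        dropped = [j - 1 for j in range(X.shape[1]) if not keep[j]]
        warnings.warn(f"dropping collinear confound column(s) {dropped}",
                      UserWarning, stacklevel=2)
        X = X[:, keep]
    beta, *_ = np.linalg.lstsq(X, series.values, rcond=None)
    resid = series.values - X @ beta
    return series.copy_with(resid)


def denoise(series: TimeSeries, confounds: np.ndarray | None = None,
            low_hz: float = DEFAULT_BAND[0],
            high_hz: float = DEFAULT_BAND[1]) -> TimeSeries:
    """Nuisance regression (if confounds given) followed by band-pass."""
    out = series
    if confounds is not None:
        out = regress_nuisance(out, confounds)
    return bandpass(out, low_hz, high_hz)
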