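"""Filtering, resampling and time alignment.

Keypoint coordinates are low-pass filtered with a zero-phase Butterworth
filter before inverse kinematics (default 5 Hz cutoff at 30 Hz for the
markerless stream, 8 Hz at 120 Hz for the reference stream). Angle and
orientation streams are upsampled to the reference rate, and a single integer
lag per trial, found by normalized cross-correlation of an angle channel,
removes the constant acquisition latency between the two systems.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline

from .errors import (
    InsufficientDataError,
    ParameterError,
    UndefinedCorrelationError,
)
from .rotation_core import slerp

__all__ = [
    "FilterSpec",
    "butterworth_zero_phase",
    "resample_scalar",
    "resample_orientation",
    "cross_correlation_align",
]


@dataclass(frozen=True)
class FilterSpec:
    """Single-pass Butterworth design; forward-backward application squares
    the magnitude response and cancels the phase."""

    order: int = 4
    cutoff_hz: float = 5.0
    rate_hz: float = 30.0
    zero_phase: bool = True

    def __post_init__(self):
        if self.order < 2 or self.order % 2 != 0:
            raise ParameterError("filter order must be an even integer >= 2")
        if not 0.0 < self.cutoff_hz < self.rate_hz / 2.0:
            raise ParameterError(
                f"cutoff {self.cutoff_hz} Hz must lie in (0, Nyquist={self.rate_hz / 2} Hz)"
            )

    def sos(self) -> np.ndarray:
        return sps.butter(self.order, self.cutoff_hz, fs=self.rate_hz, output="sos")


def butterworth_zero_phase(series, spec: FilterSpec, axis: int = 0) -> np.ndarray:
    """Forward-backward Butterworth filtering with odd-reflection padding.

    DC gain is exactly 1 and the effective magnitude response is the square of
    the single-pass response. Pad length is three times the filter order.
    """
    x = np.asarray(series, dtype=float)
    n = x.shape[axis]
    padlen = 3 * spec.order
    if n <= padlen:
        raise InsufficientDataError(
            f"series length {n} must exceed 3 x order = {padlen}"
        )
    if not spec.zero_phase:
        return sps.sosfilt(spec.sos(), x, axis=axis)
    return sps.sosfiltfilt(spec.sos(), x, axis=axis, padtype="odd", padlen=padlen)


def _check_ratio(from_rate: float, to_rate: float) -> tuple[int, bool]:
    if from_rate <= 0 or to_rate <= 0:
        raise ParameterError("rates must be positive")
    if to_rate >= from_rate:
        ratio = to_rate / from_rate
        up = True
    else:
        ratio = from_rate / to_rate
        up = False
    r = int(round(ratio))
    if abs(ratio - r) > 1e-9:
        raise ParameterError(
            f"rate ratio {ratio} must be an integer ({from_rate} -> {to_rate} Hz)"
        )
    return r, up


def resample_scalar(values, from_rate: float, to_rate: float) -> np.ndarray:
    """Resample scalar channel(s) between integer-multiple rates.

    Upsampling uses a cubic spline (exact on polynomials up to degree 3 and at
    coincident input timestamps); downsampling keeps every k-th sample.
    """
    x = np.asarray(values, dtype=float)
    r, up = _check_ratio(from_rate, to_rate)
    if r == 1:
        return x.copy()
    if not up:
        return x[::r].copy()
    n = x.shape[0]
    if n < 2:
        return x.copy()
    t_in = np.arange(n) / from_rate
    t_out = np.arange((n - 1) * r + 1) / to_rate
    out = CubicSpline(t_in, x, axis=0)(t_out)
    out[::r] = x  # preserve coincident samples exactly
    return out


def resample_orientation(quats, from_rate: float, to_rate: float) -> np.ndarray:
    """Resample a quaternion stream; upsampling SLERPs between adjacent frames."""
    q = np.asarray(quats, dtype=float)
    if q.ndim != 2 or q.shape[1] != 4:
        raise ParameterError("quats must have shape (n, 4)")
    r, up = _check_ratio(from_rate, to_rate)
    if r == 1:
        return q.copy()
    if not up:
        return q[::r].copy()
    n = q.shape[0]
    out = np.empty(((n - 1) * r + 1, 4))
    for i in range(n - 1):
        out[i * r] = q[i]
        for k in range(1, r):
            out[i * r + k] = slerp(q[i], q[i + 1], k / r)
    out[-1] = q[-1]
    return out


def cross_correlation_align(
    a: np.ndarray, b: np.ndarray, rate_hz: float, max_lag_s: float = 2.0
) -> tuple[int, np.ndarray, np.ndarray]:
    """Integer-lag alignment of two equally sampled channels.

    The lag maximises the normalized cross-correlation of the mean-removed
    signals over ``[-max_lag, +max_lag]``. A positive lag means ``b`` is
    delayed relative to ``a`` (``b[t] ~ a[t - lag]``); the returned pair is
    truncated to the common support with the delay removed.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    max_lag = int(round(max_lag_s * rate_hz))
    n = min(len(a), len(b))
    if n <= 2 * max_lag:
        raise InsufficientDataError(
            f"overlap {n} samples must exceed 2 x max lag = {2 * max_lag}"
        )
    a0 = a[:n] - a[:n].mean()
    b0 = b[:n] - b[:n].mean()
    if np.allclose(a0, 0.0) or np.allclose(b0, 0.0):
        raise UndefinedCorrelationError("constant input has no defined correlation")
    # lags visited in order of increasing |lag| so exact ties (e.g. periodic
    # inputs shifted by a full period) resolve to the smallest shift
    best_lag, best_corr = 0, -np.inf
    for lag in sorted(range(-max_lag, max_lag + 1), key=lambda k: (abs(k), k)):
        if lag >= 0:
            xa, xb = a0[: n - lag], b0[lag:]
        else:
            xa, xb = a0[-lag:], b0[: n + lag]
        denom = np.linalg.norm(xa) * np.linalg.norm(xb)
        if denom == 0:
            continue
        corr = float(np.dot(xa, xb)) / denom
        if corr > best_corr + 1e-12:
            best_corr, best_lag = corr, lag
    lag = best_lag
    if lag >= 0:
        return lag, a[: n - lag], b[lag:n]
    return lag, a[-lag:n], b[: n + lag]
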