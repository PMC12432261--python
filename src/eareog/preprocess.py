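"""Deterministic signal conditioning for EOG and camera gaze traces.

The canonical chains are:

* EOG trial chain: linear detrend → centered mean filter (length 50) →
  min–max normalization to [−1, 1];
* camera trial chain: interpolate missing samples → resample to 125 Hz →
  0.1–15 Hz 5th-order Butterworth band-pass → mean filter (length 50) →
  min–max normalization.

Filtering is zero-phase (forward–backward) so downstream lag estimates do
not inherit filter group delay.  All stages are length-preserving except
resampling, which preserves duration.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .core import GazeTrace

__all__ = [
    "bandpass",
    "bandpass_recording",
    "detrend_linear",
    "mean_filter",
    "normalize_unit",
    "interpolate_missing",
    "resample_to",
    "preprocess_eog_trial",
    "preprocess_camera_trial",
]

DEFAULT_LOW_HZ = 0.1
DEFAULT_HIGH_HZ = 15.0
DEFAULT_ORDER = 5
DEFAULT_MEAN_FILTER_LEN = 50


def bandpass(
    series: np.ndarray,
    sample_rate_hz: float,
    low_hz: float = DEFAULT_LOW_HZ,
    high_hz: float = DEFAULT_HIGH_HZ,
    order: int = DEFAULT_ORDER,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass.  Output length equals input length."""
    series = np.asarray(series, dtype=float)
    nyq = sample_rate_hz / 2.0
    if not (0.0 < low_hz < high_hz < nyq):
        raise ValueError(f"cutoffs must satisfy 0 < {low_hz} < {high_hz} < Nyquist {nyq}")
    if len(series) <= 3 * order:
        raise ValueError("series too short for the requested filter order")
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=sample_rate_hz, output="sos")
    return signal.sosfiltfilt(sos, series)


def bandpass_recording(recording, **kwargs):
    """Apply :func:`bandpass` to every channel of a recording."""
    return recording.map_channels(lambda x: bandpass(x, recording.sample_rate_hz, **kwargs))


def detrend_linear(series: np.ndarray) -> np.ndarray:
    """Remove the least-squares straight line; result has zero mean and zero
    least-squares slope."""
    series = np.asarray(series, dtype=float)
    if len(series) < 2:
        raise ValueError("need at least 2 samples to detrend")
    return signal.detrend(series, type="linear")


def mean_filter(series: np.ndarray, length: int = DEFAULT_MEAN_FILTER_LEN) -> np.ndarray:
    """Centered moving average with edge windows truncated to the available
    samples.  For even lengths the window extends one sample further to the
    right: sample ``i`` averages indices ``[i-(L-1)//2, i+L//2]``."""
    series = np.asarray(series, dtype=float)
    if length < 1:
        raise ValueError("filter length must be >= 1")
    n = len(series)
    left = (length - 1) // 2
    right = length // 2
    csum = np.concatenate(([0.0], np.cumsum(series)))
    i = np.arange(n)
    lo = np.maximum(i - left, 0)
    hi = np.minimum(i + right, n - 1)
    return (csum[hi + 1] - csum[lo]) / (hi + 1 - lo)


def normalize_unit(series: np.ndarray) -> tuple[np.ndarray, bool]:
    """Min–max map onto [−1, 1]: ``x' = 2(x−min)/(max−min) − 1``.

    Returns ``(scaled, degenerate)``; a constant input maps to all zeros
    with ``degenerate=True`` so callers can exclude the trial instead of
    propagating NaNs.
    """
    series = np.asarray(series, dtype=float)
    if len(series) < 2:
        raise ValueError("need at least 2 samples to normalize")
    lo, hi = float(np.min(series)), float(np.max(series))
    # sub-nanovolt (or float-residue) spans count as constant: amplifying
    # them to [-1, 1] would manufacture signal out of rounding noise
    if hi - lo <= max(1e-9, 1e-12 * float(np.max(np.abs(series)))):
        return np.zeros_like(series), True
    return 2.0 * (series - lo) / (hi - lo) - 1.0, False


def interpolate_missing(trace: GazeTrace) -> GazeTrace:
    """Linearly interpolate across invalid runs; leading/trailing gaps take
    the nearest valid value.  The result is fully valid."""
    valid = trace.valid
    if valid.sum() < 2:
        raise ValueError("need at least 2 valid samples to interpolate")
    idx = np.arange(len(trace))
    good = idx[valid]

    def fill(series: np.ndarray) -> np.ndarray:
        return np.interp(idx, good, series[valid])

    return GazeTrace(
        sample_rate_hz=trace.sample_rate_hz,
        horizontal_deg=fill(trace.horizontal_deg),
        vertical_deg=fill(trace.vertical_deg),
        valid=np.ones(len(trace), dtype=bool),
        start_time_s=trace.start_time_s,
    )


def resample_to(trace: GazeTrace, target_hz: float = 125.0) -> GazeTrace:
    """Linear interpolation onto a uniform grid at ``target_hz`` spanning the
    same time range.  Requires a fully valid trace."""
    if target_hz <= 0:
        raise ValueError("target_hz must be positive")
    if not trace.valid.all():
        raise ValueError("trace has invalid samples; run interpolate_missing first")
    t_old = trace.times()
    span = t_old[-1] - t_old[0]
    n_new = int(np.floor(span * target_hz + 1e-9)) + 1
    t_new = trace.start_time_s + np.arange(n_new) / target_hz
    return GazeTrace(
        sample_rate_hz=target_hz,
        horizontal_deg=np.interp(t_new, t_old, trace.horizontal_deg),
        vertical_deg=np.interp(t_new, t_old, trace.vertical_deg),
        valid=np.ones(n_new, dtype=bool),
        start_time_s=trace.start_time_s,
    )


def preprocess_eog_trial(
    series: np.ndarray, mean_filter_len: int = DEFAULT_MEAN_FILTER_LEN
) -> tuple[np.ndarray, bool]:
    """EOG trial chain: detrend → mean filter → normalize.

    Assumes the recording was already band-pass filtered at ingest.
    Returns ``(series, degenerate)``.
    """
    x = detrend_linear(series)
    x = mean_filter(x, mean_filter_len)
    return normalize_unit(x)


def preprocess_camera_trial(
    trace: GazeTrace,
    axis: str = "horizontal",
    target_hz: float = 125.0,
    mean_filter_len: int = DEFAULT_MEAN_FILTER_LEN,
) -> tuple[np.ndarray, bool]:
    """Camera trial chain: interpolate → resample → band-pass → mean filter →
    normalize.  Returns ``(series, degenerate)`` at ``target_hz``."""
    full = interpolate_missing(trace)
    resampled = resample_to(full, target_hz)
    x = bandpass(resampled.axis(axis), target_hz)
    x = mean_filter(x, mean_filter_len)
    return normalize_unit(x)
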