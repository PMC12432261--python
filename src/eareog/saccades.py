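"""Saccade epoch extraction, labeling, voltage deflections and averaging.

Each outbound fixation event yields one 2 s epoch whose window starts
0.75 s before the stimulus onset, so with a typical reaction latency the
saccade lands near the window center.  Start/end labeling runs on the
gold-standard channel for the saccade's axis with a velocity-threshold
rule; epochs without a clear saccade are marked invalid and excluded.

The voltage deflection of a labelled saccade is the mean of the last ten
samples of the saccade span minus the mean of the first ten (post-minus-pre
convention, so leftward/downward saccades on a right-positive channel give
negative deflections).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import GazeTrace, MultiChannelRecording, StatTestResult
from .montage import MontagePair, differential
from .preprocess import mean_filter
from .stimulus import DIRECTION_AXIS, DIRECTION_SIGN, StimulusEvent, StimulusSchedule
from .synth import GOLD_HORIZONTAL, GOLD_VERTICAL

__all__ = [
    "SaccadeEpoch",
    "extract_epochs",
    "label_saccade",
    "label_epochs",
    "deflection",
    "epoch_deflection",
    "average_waveform",
    "interpolate_to_common_length",
    "deflection_table",
    "per_angle_mean_deflections",
    "deflection_amplitude_correlation",
    "correlation_pvalue",
    "gold_channel_for",
]

DEFAULT_WINDOW_S = 2.0
DEFAULT_PRE_ONSET_S = 0.75


def gold_channel_for(direction: str) -> str:
    """Gold-standard channel matching a saccade direction's axis."""
    return GOLD_HORIZONTAL if DIRECTION_AXIS[direction] == "horizontal" else GOLD_VERTICAL


@dataclass
class SaccadeEpoch:
    """A windowed saccade with per-channel µV series and, once labelled,
    half-open start/end sample indices into the window."""

    participant_id: int
    cycle: int
    direction: str
    amplitude_deg: float
    window: dict[str, np.ndarray]
    sample_rate_hz: float
    kind: str = "saccade_out"
    start_idx: int | None = None
    end_idx: int | None = None
    valid: bool = False

    @property
    def signed_amplitude_deg(self) -> float:
        sign = DIRECTION_SIGN[self.direction]
        return sign * self.amplitude_deg if self.kind == "saccade_out" else -sign * self.amplitude_deg

    @property
    def axis(self) -> str:
        return DIRECTION_AXIS[self.direction]

    def series(self, channel_or_pair) -> np.ndarray:
        """Window series for a raw channel label or a montage differential."""
        if isinstance(channel_or_pair, MontagePair):
            return self.window[channel_or_pair.channel_a] - self.window[channel_or_pair.channel_b]
        return self.window[channel_or_pair]


def extract_epochs(
    recording: MultiChannelRecording,
    schedule: StimulusSchedule,
    window_s: float = DEFAULT_WINDOW_S,
    pre_onset_s: float = DEFAULT_PRE_ONSET_S,
    include_returns: bool = False,
    participant_id: int = 0,
) -> tuple[list[SaccadeEpoch], int]:
    """Cut one fixed-length window per saccade event.

    The window is ``[onset − pre_onset_s, onset − pre_onset_s + window_s)``.
    Events whose window does not fit inside the recording are skipped.
    Returns ``(epochs, n_skipped)``.
    """
    kinds = ("saccade_out", "saccade_return") if include_returns else ("saccade_out",)
    n_expected = int(round(window_s * recording.sample_rate_hz))
    epochs: list[SaccadeEpoch] = []
    skipped = 0
    for event in schedule.events_of_kind(*kinds):
        t0 = event.start_s - pre_onset_s
        t1 = t0 + window_s
        try:
            window = recording.slice_time(t0, t1)
        except ValueError:
            skipped += 1
            continue
        if window.n_samples != n_expected:
            skipped += 1
            continue
        epochs.append(
            SaccadeEpoch(
                participant_id=participant_id,
                cycle=event.cycle,
                direction=event.direction,
                amplitude_deg=event.amplitude_deg,
                window=window.channels,
                sample_rate_hz=recording.sample_rate_hz,
                kind=event.kind,
            )
        )
    return epochs, skipped


def label_saccade(
    gold_window: np.ndarray,
    direction: str,
    sample_rate_hz: float = 125.0,
    rel_threshold: float = 0.15,
    mad_factor: float = 5.0,
    smooth_len: int = 15,
    channel_sign: float = 1.0,
) -> tuple[int, int] | None:
    """Velocity-threshold saccade labeler on a gold-standard window.

    The window is differentiated and smoothed; the labelled span brackets
    the velocity peak whose sign matches the expected deflection direction,
    out to the nearest crossings below ``rel_threshold`` of the peak speed.
    Returns half-open ``(start, end)`` indices, or None when the peak speed
    is below ``mad_factor`` times the MAD of the velocity (no clear
    saccade).  ``channel_sign`` flips the expected polarity for channels
    wired opposite to the right/up-positive convention.
    """
    x = np.asarray(gold_window, dtype=float)
    if len(x) < 3 * smooth_len:
        return None
    vel = np.gradient(mean_filter(x, smooth_len)) * sample_rate_hz
    vel = mean_filter(vel, smooth_len)
    expected_sign = DIRECTION_SIGN[direction] * channel_sign
    signed = vel * expected_sign
    peak_idx = int(np.argmax(signed))
    peak = signed[peak_idx]
    mad = float(np.median(np.abs(vel - np.median(vel))))
    if peak <= 0 or peak < mad_factor * max(mad, 1e-12):
        return None
    thresh = rel_threshold * peak
    below = signed < thresh
    start = peak_idx
    while start > 0 and not below[start - 1]:
        start -= 1
    end = peak_idx
    while end < len(x) - 1 and not below[end + 1]:
        end += 1
    return start, end + 1


def label_epochs(
    epochs: list[SaccadeEpoch],
    channel_sign: dict[str, float] | None = None,
    **labeler_kwargs,
) -> list[SaccadeEpoch]:
    """Label every epoch in place from its gold-standard channel; epochs
    without a clear saccade stay invalid.  Returns the same list."""
    channel_sign = channel_sign or {}
    for ep in epochs:
        channel = gold_channel_for(ep.direction)
        sign = channel_sign.get(channel, 1.0)
        if ep.kind == "saccade_return":
            sign = -sign
        span = label_saccade(
            ep.window[channel], ep.direction, ep.sample_rate_hz, channel_sign=sign, **labeler_kwargs
        )
        if span is None:
            ep.valid = False
            ep.start_idx = ep.end_idx = None
        else:
            ep.start_idx, ep.end_idx = span
            ep.valid = True
    return epochs


def deflection(
    window_series: np.ndarray,
    start_idx: int,
    end_idx: int,
    n_samples: int = 10,
    mode: str = "span",
) -> float:
    """Voltage deflection across a labelled saccade span (µV).

    ``span`` mode (default): mean of the last ``n_samples`` of the span
    minus the mean of the first ``n_samples`` of the span.  ``flank`` mode
    uses the plateaus just outside the span instead.  Returns NaN when the
    required samples are unavailable.
    """
    x = np.asarray(window_series, dtype=float)
    if not (0 <= start_idx < end_idx <= len(x)):
        raise ValueError("invalid saccade span")
    if mode == "span":
        span = x[start_idx:end_idx]
        if len(span) < 2 * n_samples:
            return float("nan")
        return float(span[-n_samples:].mean() - span[:n_samples].mean())
    if mode == "flank":
        if start_idx < n_samples or end_idx + n_samples > len(x):
            return float("nan")
        return float(x[end_idx : end_idx + n_samples].mean() - x[start_idx - n_samples : start_idx].mean())
    raise ValueError("mode must be span|flank")


def epoch_deflection(epoch: SaccadeEpoch, channel_or_pair, **kwargs) -> float:
    if not epoch.valid:
        return float("nan")
    return deflection(epoch.series(channel_or_pair), epoch.start_idx, epoch.end_idx, **kwargs)


def average_waveform(
    epochs: list[SaccadeEpoch], channel_or_pair
) -> tuple[np.ndarray, np.ndarray]:
    """Baseline-shifted average saccade waveform for a channel or montage.

    Each valid epoch is shifted by its pre-start mean (the average level of
    the montage before the saccade), then averaged pointwise.  Returns
    ``(mean, sd)`` with the sample SD (ddof=0 for a single epoch).
    """
    rows = []
    for ep in epochs:
        if not ep.valid or ep.start_idx is None or ep.start_idx == 0:
            continue  # need pre-start samples for the baseline
        x = ep.series(channel_or_pair)
        rows.append(x - x[: ep.start_idx].mean())
    if not rows:
        raise ValueError("no valid labelled epochs in group")
    arr = np.vstack(rows)
    sd = arr.std(axis=0, ddof=1) if len(rows) > 1 else np.zeros(arr.shape[1])
    return arr.mean(axis=0), sd


def interpolate_to_common_length(series: np.ndarray, n_points: int) -> np.ndarray:
    """Linearly resample a window to ``n_points`` samples over the same
    relative time span."""
    if n_points < 20:
        raise ValueError("n_points must be >= 20")
    x = np.asarray(series, dtype=float)
    old = np.linspace(0.0, 1.0, len(x))
    new = np.linspace(0.0, 1.0, n_points)
    return np.interp(new, old, x)


def deflection_table(
    epochs: list[SaccadeEpoch],
    pairs: list[MontagePair],
    gold_channels: tuple[str, str] = (GOLD_HORIZONTAL, GOLD_VERTICAL),
    mode: str = "span",
) -> pd.DataFrame:
    """Per-epoch deflections for every montage and gold channel.

    Columns: participant, cycle, direction, axis, amplitude_deg,
    angle_change_deg (signed ground truth), valid, start_idx, end_idx, one
    column per montage label and per gold channel.  Invalid epochs keep NaN
    deflections.
    """
    rows = []
    for ep in epochs:
        row = {
            "participant": ep.participant_id,
            "cycle": ep.cycle,
            "direction": ep.direction,
            "axis": ep.axis,
            "amplitude_deg": ep.amplitude_deg,
            "angle_change_deg": ep.signed_amplitude_deg,
            "valid": ep.valid,
            "start_idx": ep.start_idx if ep.start_idx is not None else -1,
            "end_idx": ep.end_idx if ep.end_idx is not None else -1,
        }
        for pair in pairs:
            row[pair.label] = epoch_deflection(ep, pair, mode=mode)
        for ch in gold_channels:
            row[ch] = epoch_deflection(ep, ch, mode=mode)
        rows.append(row)
    return pd.DataFrame(rows)


def per_angle_mean_deflections(
    table: pd.DataFrame, column: str, direction: str
) -> pd.Series:
    """Mean deflection per amplitude for one direction, valid epochs only,
    indexed by amplitude (ascending)."""
    sub = table[(table["direction"] == direction) & table["valid"]]
    sub = sub.dropna(subset=[column])
    if sub.empty:
        raise ValueError(f"no valid epochs for direction {direction!r}")
    return sub.groupby("amplitude_deg")[column].mean().sort_index()


def correlation_pvalue(r: float, n: int) -> float:
    """Two-sided p-value for a Pearson correlation via the t transform
    t = r·√(n−2)/√(1−r²) with n−2 degrees of freedom."""
    if n < 3:
        raise ValueError("need n >= 3")
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), n - 2))


def deflection_amplitude_correlation(ear_means, gold_means) -> StatTestResult:
    """Pearson correlation between per-angle mean deflections of an ear
    montage and the gold standard (default 6 angles per direction)."""
    a = np.asarray(ear_means, dtype=float)
    b = np.asarray(gold_means, dtype=float)
    if len(a) != len(b):
        raise ValueError("paired means must have equal length")
    if len(a) < 3:
        raise ValueError("need at least 3 paired means")
    r = float(np.corrcoef(a, b)[0, 1])
    return StatTestResult(r, correlation_pvalue(r, len(a)), "pearson", len(a))
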