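"""Core data model and file I/O for earEOG analyses.

Conventions used throughout the package:

* time is in seconds, samples are 0-indexed, windows are half-open
  ``[start, end)``;
* electric potentials are in microvolts (µV), gaze angles in degrees;
* gaze angles are signed: right/up positive, left/down negative;
* missing camera samples are encoded as ``valid=False`` plus a non-finite
  value — they are never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Electrode",
    "ElectrodeLayout",
    "MultiChannelRecording",
    "GazeTrace",
    "StatTestResult",
    "FormatError",
    "read_recording_csv",
    "write_recording_csv",
    "read_gaze_csv",
    "write_gaze_csv",
    "write_results_table",
    "read_results_table",
]


class FormatError(ValueError):
    """Raised when an on-disk file violates the expected format."""


# --------------------------------------------------------------------------
# electrode layout


@dataclass(frozen=True)
class Electrode:
    """A single electrode: label, head-frame position and role.

    Positions are in meters in a head-centered frame: x to the subject's
    right, y anterior (out of the face), z superior.
    """

    label: str
    position: tuple[float, float, float]
    role: str = "measurement"  # measurement | reference | ground
    side: str = "left"  # left | right | periorbital

    def __post_init__(self) -> None:
        if self.role not in ("measurement", "reference", "ground"):
            raise ValueError(f"unknown electrode role {self.role!r}")
        if self.side not in ("left", "right", "periorbital"):
            raise ValueError(f"unknown electrode side {self.side!r}")
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"electrode {self.label!r}: position must be a finite 3-vector")


@dataclass(frozen=True)
class ElectrodeLayout:
    """A full set of electrodes with exactly one reference and one ground
    among the non-periorbital electrodes."""

    electrodes: tuple[Electrode, ...]

    def __post_init__(self) -> None:
        labels = [e.label for e in self.electrodes]
        if len(set(labels)) != len(labels):
            raise ValueError("electrode labels must be unique")
        aural = [e for e in self.electrodes if e.side != "periorbital"]
        n_ref = sum(e.role == "reference" for e in aural)
        n_gnd = sum(e.role == "ground" for e in aural)
        if n_ref != 1 or n_gnd != 1:
            raise ValueError(
                f"layout needs exactly one reference and one ground among "
                f"non-periorbital electrodes (got {n_ref} / {n_gnd})"
            )

    def __getitem__(self, label: str) -> Electrode:
        for e in self.electrodes:
            if e.label == label:
                return e
        raise KeyError(label)

    def __contains__(self, label: str) -> bool:
        return any(e.label == label for e in self.electrodes)

    @property
    def measurement_labels(self) -> list[str]:
        """Labels of non-periorbital measurement electrodes."""
        return [
            e.label
            for e in self.electrodes
            if e.role == "measurement" and e.side != "periorbital"
        ]

    @property
    def reference(self) -> Electrode:
        return next(e for e in self.electrodes if e.role == "reference")

    def position(self, label: str) -> np.ndarray:
        return np.asarray(self[label].position, dtype=float)


# --------------------------------------------------------------------------
# time series containers


def _check_series(name: str, x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError(f"{name}: series must be 1-D")
    return x


@dataclass
class MultiChannelRecording:
    """Uniformly sampled multichannel potential recording in µV."""

    sample_rate_hz: float
    channels: dict[str, np.ndarray]
    start_time_s: float = 0.0

    def __post_init__(self) -> None:
        if not self.sample_rate_hz > 0:
            raise ValueError("sample_rate_hz must be positive")
        if not self.channels:
            raise ValueError("recording needs at least one channel")
        lengths = set()
        for label, series in self.channels.items():
            series = _check_series(label, series)
            if not np.all(np.isfinite(series)):
                raise ValueError(f"channel {label!r} contains non-finite samples")
            self.channels[label] = series
            lengths.add(len(series))
        if len(lengths) != 1:
            raise ValueError(f"channels have unequal lengths: {sorted(lengths)}")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    def times(self) -> np.ndarray:
        return self.start_time_s + np.arange(self.n_samples) / self.sample_rate_hz

    def slice_time(self, t0: float, t1: float) -> "MultiChannelRecording":
        """Return the sub-recording covering the half-open window [t0, t1)."""
        i0, i1 = _window_indices(self.start_time_s, self.sample_rate_hz, self.n_samples, t0, t1)
        return MultiChannelRecording(
            sample_rate_hz=self.sample_rate_hz,
            channels={k: v[i0:i1].copy() for k, v in self.channels.items()},
            start_time_s=self.start_time_s + i0 / self.sample_rate_hz,
        )

    def map_channels(self, fn) -> "MultiChannelRecording":
        """Apply ``fn(series)`` to every channel, preserving metadata."""
        return MultiChannelRecording(
            sample_rate_hz=self.sample_rate_hz,
            channels={k: np.asarray(fn(v), dtype=float) for k, v in self.channels.items()},
            start_time_s=self.start_time_s,
        )


def _window_indices(start_time_s, rate, n, t0, t1):
    if t1 <= t0:
        raise ValueError("empty window")
    eps = 1e-9
    i0 = int(np.ceil((t0 - start_time_s) * rate - eps))
    i1 = int(np.ceil((t1 - start_time_s) * rate - eps))
    i0 = max(i0, 0)
    i1 = min(i1, n)
    if i1 <= i0:
        raise ValueError(f"window [{t0}, {t1}) lies outside the recording")
    return i0, i1


@dataclass
class GazeTrace:
    """Horizontal/vertical gaze angle series in degrees with a validity mask.

    Invalid samples may hold non-finite values; at least one sample must be
    valid.
    """

    sample_rate_hz: float
    horizontal_deg: np.ndarray
    vertical_deg: np.ndarray
    valid: np.ndarray | None = None
    start_time_s: float = 0.0

    def __post_init__(self) -> None:
        if not self.sample_rate_hz > 0:
            raise ValueError("sample_rate_hz must be positive")
        self.horizontal_deg = _check_series("horizontal_deg", self.horizontal_deg)
        self.vertical_deg = _check_series("vertical_deg", self.vertical_deg)
        if len(self.horizontal_deg) != len(self.vertical_deg):
            raise ValueError("horizontal and vertical series must have equal length")
        if self.valid is None:
            self.valid = np.ones(len(self.horizontal_deg), dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if len(self.valid) != len(self.horizontal_deg):
            raise ValueError("valid mask length mismatch")
        if len(self.valid) and not self.valid.any():
            raise ValueError("gaze trace has no valid samples")
        ok = self.valid
        if not (
            np.all(np.isfinite(self.horizontal_deg[ok]))
            and np.all(np.isfinite(self.vertical_deg[ok]))
        ):
            raise ValueError("valid samples must be finite")

    def __len__(self) -> int:
        return len(self.horizontal_deg)

    @property
    def duration_s(self) -> float:
        return len(self) / self.sample_rate_hz

    def times(self) -> np.ndarray:
        return self.start_time_s + np.arange(len(self)) / self.sample_rate_hz

    def axis(self, name: str) -> np.ndarray:
        if name == "horizontal":
            return self.horizontal_deg
        if name == "vertical":
            return self.vertical_deg
        raise ValueError(f"unknown axis {name!r}")

    def slice_time(self, t0: float, t1: float) -> "GazeTrace":
        i0, i1 = _window_indices(self.start_time_s, self.sample_rate_hz, len(self), t0, t1)
        return GazeTrace(
            sample_rate_hz=self.sample_rate_hz,
            horizontal_deg=self.horizontal_deg[i0:i1].copy(),
            vertical_deg=self.vertical_deg[i0:i1].copy(),
            valid=self.valid[i0:i1].copy(),
            start_time_s=self.start_time_s + i0 / self.sample_rate_hz,
        )


@dataclass(frozen=True)
class StatTestResult:
    """Outcome of a statistical test."""

    statistic: float
    p_value: float
    test_name: str
    n: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")


# --------------------------------------------------------------------------
# CSV I/O


def _infer_rate(time_s: np.ndarray) -> float:
    dt = np.diff(time_s)
    if np.any(dt <= 0):
        raise FormatError("time_s column must be strictly increasing")
    return 1.0 / float(np.median(dt))


def read_recording_csv(path: str | Path) -> MultiChannelRecording:
    """Read a recording CSV with a ``time_s`` column plus one column per
    channel (µV).  The sample rate is inferred from the median time step."""
    with open(path) as fh:
        header = fh.readline().strip().split(",")
    if len(set(header)) != len(header):
        raise FormatError("duplicated channel header")
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(str(exc)) from exc
    if "time_s" not in df.columns:
        raise FormatError("recording CSV must have a 'time_s' column")
    if len(df) < 2:
        raise FormatError("recording CSV needs at least 2 samples")
    labels = [c for c in df.columns if c != "time_s"]
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            raise FormatError(f"non-numeric values in column {col!r}")
    time_s = df["time_s"].to_numpy(dtype=float)
    rate = _infer_rate(time_s)
    return MultiChannelRecording(
        sample_rate_hz=rate,
        channels={l: df[l].to_numpy(dtype=float) for l in labels},
        start_time_s=float(time_s[0]),
    )


def write_recording_csv(recording: MultiChannelRecording, path: str | Path) -> None:
    df = pd.DataFrame({"time_s": recording.times()})
    for label, series in recording.channels.items():
        df[label] = series
    df.to_csv(path, index=False, float_format="%.9g")


def read_gaze_csv(path: str | Path) -> GazeTrace:
    """Read a gaze CSV with columns time_s, h_deg, v_deg, valid."""
    df = pd.read_csv(path)
    required = {"time_s", "h_deg", "v_deg", "valid"}
    if not required.issubset(df.columns):
        raise FormatError(f"gaze CSV must have columns {sorted(required)}")
    if len(df) < 2:
        raise FormatError("gaze CSV needs at least 2 samples")
    time_s = df["time_s"].to_numpy(dtype=float)
    return GazeTrace(
        sample_rate_hz=_infer_rate(time_s),
        horizontal_deg=df["h_deg"].to_numpy(dtype=float),
        vertical_deg=df["v_deg"].to_numpy(dtype=float),
        valid=df["valid"].to_numpy(dtype=bool),
        start_time_s=float(time_s[0]),
    )


def write_gaze_csv(trace: GazeTrace, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "time_s": trace.times(),
            "h_deg": trace.horizontal_deg,
            "v_deg": trace.vertical_deg,
            "valid": trace.valid.astype(int),
        }
    )
    df.to_csv(path, index=False, float_format="%.9g")


def write_results_table(rows: Sequence[Mapping], path: str | Path) -> None:
    """Write homogeneous result records to CSV with a stable column order.

    Byte output is deterministic for fixed input.  Raises on an empty record
    set or on records with mismatched field sets.
    """
    rows = list(rows)
    if not rows:
        raise ValueError("cannot write an empty results table")
    fields = list(rows[0].keys())
    for i, row in enumerate(rows):
        if list(row.keys()) != fields:
            raise ValueError(f"record {i} has field set {list(row.keys())} != {fields}")
    df = pd.DataFrame(rows, columns=fields)
    df.to_csv(path, index=False, float_format="%.9g")


def read_results_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
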