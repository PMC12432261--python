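"""Pursuit and saccade stimulus schedules and their implied gaze trajectories.

The default stimulus grid mirrors a desktop study protocol: one-dimensional
smooth pursuits (simple harmonic motion at 0.33, 0.5 and 1 Hz with opening
angles 2.5–15° in 2.5° steps) and step saccades to fixation points in the
four cardinal directions at the same angular grid, with 2 s fixations and
2 s center returns.

Angles are signed: right/up positive, left/down negative.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .core import GazeTrace

__all__ = [
    "ScreenGeometry",
    "StimulusEvent",
    "StimulusSchedule",
    "DEFAULT_ANGLES_DEG",
    "DEFAULT_PURSUIT_FREQS_HZ",
    "DIRECTION_SIGN",
    "DIRECTION_AXIS",
    "pursuit_trajectory",
    "pursuit_schedule",
    "saccade_schedule",
    "schedule_to_gaze",
    "deg_to_screen_mm",
    "px_to_mm",
]

DEFAULT_ANGLES_DEG = (2.5, 5.0, 7.5, 10.0, 12.5, 15.0)
DEFAULT_PURSUIT_FREQS_HZ = (0.33, 0.5, 1.0)
DIRECTION_SIGN = {"right": 1.0, "left": -1.0, "up": 1.0, "down": -1.0}
DIRECTION_AXIS = {"right": "horizontal", "left": "horizontal", "up": "vertical", "down": "vertical"}


@dataclass(frozen=True)
class ScreenGeometry:
    """Physical display geometry used to convert visual angles to on-screen
    offsets.  Defaults: 23-inch 1920×1080 panel viewed from 0.50 m."""

    diagonal_m: float = 0.5842
    resolution_px: tuple[int, int] = (1920, 1080)
    viewing_distance_m: float = 0.50

    def __post_init__(self) -> None:
        if self.diagonal_m <= 0 or self.viewing_distance_m <= 0:
            raise ValueError("screen dimensions must be positive")
        if min(self.resolution_px) <= 0:
            raise ValueError("resolution must be positive")

    @property
    def width_m(self) -> float:
        rx, ry = self.resolution_px
        return self.diagonal_m * rx / math.hypot(rx, ry)

    @property
    def height_m(self) -> float:
        rx, ry = self.resolution_px
        return self.diagonal_m * ry / math.hypot(rx, ry)

    @property
    def pixel_pitch_mm(self) -> float:
        return 1000.0 * self.width_m / self.resolution_px[0]


def deg_to_screen_mm(angle_deg: float, geometry: ScreenGeometry = ScreenGeometry()) -> float:
    """On-screen offset (mm from center) subtending ``angle_deg`` at the
    configured viewing distance: ``d·tan(θ)``."""
    if abs(angle_deg) >= 90.0:
        raise ValueError("visual angle must be below 90°")
    return 1000.0 * geometry.viewing_distance_m * math.tan(math.radians(angle_deg))


def px_to_mm(px: float, geometry: ScreenGeometry = ScreenGeometry()) -> float:
    """Convert a pixel count to millimeters using the panel's pixel pitch."""
    return px * geometry.pixel_pitch_mm


@dataclass(frozen=True)
class StimulusEvent:
    """One stimulus episode.

    ``kind`` is one of pursuit | saccade_out | saccade_return | rest.
    Pursuit events carry axis/frequency/phase; saccade events carry a
    cardinal direction.  ``amplitude_deg`` is the (positive) opening angle
    for pursuits and the fixation eccentricity for saccades.
    """

    kind: str
    start_s: float
    duration_s: float
    amplitude_deg: float = 0.0
    axis: str | None = None
    direction: str | None = None
    frequency_hz: float | None = None
    phase_rad: float | None = None
    cycle: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("pursuit", "saccade_out", "saccade_return", "rest"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.duration_s <= 0:
            raise ValueError("event duration must be positive")
        if self.kind == "pursuit":
            if self.axis not in ("horizontal", "vertical"):
                raise ValueError("pursuit events need axis horizontal|vertical")
            if not self.frequency_hz or self.frequency_hz <= 0:
                raise ValueError("pursuit events need a positive frequency")
        if self.kind in ("saccade_out", "saccade_return") and self.direction not in DIRECTION_SIGN:
            raise ValueError("saccade events need a cardinal direction")

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s

    @property
    def signed_amplitude_deg(self) -> float:
        if self.direction is None:
            return self.amplitude_deg
        return DIRECTION_SIGN[self.direction] * self.amplitude_deg


@dataclass
class StimulusSchedule:
    """Chronologically ordered, non-overlapping stimulus events."""

    events: list[StimulusEvent]
    geometry: ScreenGeometry = ScreenGeometry()
    cycle_index: int = 0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not self.events:
            raise ValueError("schedule must contain at least one event")
        for prev, nxt in zip(self.events, self.events[1:]):
            if nxt.start_s < prev.end_s - 1e-9:
                raise ValueError(
                    f"overlapping events at t={nxt.start_s:.3f}s (previous ends {prev.end_s:.3f}s)"
                )
        if self.events[-1].kind != "rest":
            raise ValueError("schedule must end with a rest event")

    @property
    def duration_s(self) -> float:
        return self.events[-1].end_s

    def events_of_kind(self, *kinds: str) -> list[StimulusEvent]:
        return [e for e in self.events if e.kind in kinds]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "geometry": asdict(self.geometry),
            "cycle_index": self.cycle_index,
            "rng_seed": self.rng_seed,
            "events": [
                {k: v for k, v in asdict(e).items() if v is not None} for e in self.events
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "StimulusSchedule":
        payload = json.loads(Path(path).read_text())
        geom = payload.get("geometry", {})
        if "resolution_px" in geom:
            geom["resolution_px"] = tuple(geom["resolution_px"])
        return cls(
            events=[StimulusEvent(**e) for e in payload["events"]],
            geometry=ScreenGeometry(**geom),
            cycle_index=payload.get("cycle_index", 0),
            rng_seed=payload.get("rng_seed", 0),
        )


# --------------------------------------------------------------------------
# trajectories


def pursuit_trajectory(
    amplitude_deg: float,
    frequency_hz: float,
    phase_rad: float = 0.0,
    duration_s: float = 6.0,
    axis: str = "horizontal",
    sample_rate_hz: float = 125.0,
) -> GazeTrace:
    """Simple-harmonic 1-D pursuit target: θ(t) = A·sin(2πft + φ) on the
    requested axis, identically zero on the other axis."""
    if amplitude_deg <= 0:
        raise ValueError("amplitude_deg must be positive")
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if sample_rate_hz <= 0:
        raise ValueError("sample_rate_hz must be positive")
    if axis not in ("horizontal", "vertical"):
        raise ValueError("axis must be horizontal|vertical")
    n = int(round(duration_s * sample_rate_hz))
    t = np.arange(n) / sample_rate_hz
    theta = amplitude_deg * np.sin(2.0 * np.pi * frequency_hz * t + phase_rad)
    zero = np.zeros(n)
    if axis == "horizontal":
        return GazeTrace(sample_rate_hz, theta, zero)
    return GazeTrace(sample_rate_hz, zero, theta)


# --------------------------------------------------------------------------
# schedule builders


def pursuit_schedule(
    amplitudes_deg=DEFAULT_ANGLES_DEG,
    frequencies_hz=DEFAULT_PURSUIT_FREQS_HZ,
    axes=("horizontal", "vertical"),
    duration_s: float = 6.0,
    gap_s: float = 1.0,
    cycles: int = 1,
    seed: int = 0,
    geometry: ScreenGeometry = ScreenGeometry(),
) -> StimulusSchedule:
    """Build the pursuit task: every axis × frequency × opening-angle
    combination for ``duration_s`` each, separated by rest gaps.  The phase
    of each trial (the target's starting position on its path) is drawn
    uniformly from a seeded generator and recorded in the event."""
    if not amplitudes_deg:
        raise ValueError("need at least one amplitude")
    rng = np.random.default_rng(seed)
    events: list[StimulusEvent] = []
    t = 0.0
    for cycle in range(cycles):
        for axis in axes:
            for f in frequencies_hz:
                for amp in amplitudes_deg:
                    phase = float(rng.uniform(0.0, 2.0 * np.pi))
                    events.append(
                        StimulusEvent(
                            kind="pursuit",
                            start_s=t,
                            duration_s=duration_s,
                            amplitude_deg=amp,
                            axis=axis,
                            frequency_hz=f,
                            phase_rad=phase,
                            cycle=cycle,
                        )
                    )
                    t += duration_s
                    events.append(StimulusEvent(kind="rest", start_s=t, duration_s=gap_s))
                    t += gap_s
    return StimulusSchedule(events=events, geometry=geometry, rng_seed=seed)


def saccade_schedule(
    angles_deg=DEFAULT_ANGLES_DEG,
    directions=("left", "right", "up", "down"),
    fixation_s: float = 2.0,
    rest_s: float = 2.0,
    cycles: int = 1,
    geometry: ScreenGeometry = ScreenGeometry(),
    lead_in_s: float = 2.0,
) -> StimulusSchedule:
    """Build the saccade task: for each direction and eccentricity the target
    jumps from the center to the fixation point for ``fixation_s`` and then
    returns to the center for ``rest_s``.  Defaults emit 24 outbound events
    per cycle (6 angles × 4 directions)."""
    if not angles_deg:
        raise ValueError("need at least one angle")
    if any(a <= 0 for a in angles_deg):
        raise ValueError("angles must be positive")
    if list(angles_deg) != sorted(angles_deg):
        raise ValueError("angles must be ascending")
    if fixation_s <= 0 or rest_s <= 0:
        raise ValueError("fixation_s and rest_s must be positive")
    events: list[StimulusEvent] = []
    t = 0.0
    if lead_in_s > 0:
        events.append(StimulusEvent(kind="rest", start_s=t, duration_s=lead_in_s))
        t += lead_in_s
    for cycle in range(cycles):
        for direction in directions:
            for amp in angles_deg:
                events.append(
                    StimulusEvent(
                        kind="saccade_out",
                        start_s=t,
                        duration_s=fixation_s,
                        amplitude_deg=amp,
                        direction=direction,
                        cycle=cycle,
                    )
                )
                t += fixation_s
                events.append(
                    StimulusEvent(
                        kind="saccade_return",
                        start_s=t,
                        duration_s=rest_s,
                        amplitude_deg=amp,
                        direction=direction,
                        cycle=cycle,
                    )
                )
                t += rest_s
    events.append(StimulusEvent(kind="rest", start_s=t, duration_s=rest_s))
    return StimulusSchedule(events=events, geometry=geometry)


def schedule_to_gaze(
    schedule: StimulusSchedule,
    sample_rate_hz: float = 125.0,
    saccade_latency_s: float = 0.2,
) -> GazeTrace:
    """Ideal-observer gaze trajectory implied by a schedule: sinusoid during
    pursuit, steps (delayed by a constant reaction latency) at saccade
    events, 0° during rest."""
    if sample_rate_hz <= 0:
        raise ValueError("sample_rate_hz must be positive")
    n = int(round(schedule.duration_s * sample_rate_hz))
    t = np.arange(n) / sample_rate_hz
    h = np.zeros(n)
    v = np.zeros(n)
    for event in schedule.events:
        if event.kind in ("saccade_out", "saccade_return"):
            onset = event.start_s + saccade_latency_s
            i = int(np.ceil(onset * sample_rate_hz - 1e-9))
            if i >= n:
                continue
            target = event.signed_amplitude_deg if event.kind == "saccade_out" else 0.0
            if DIRECTION_AXIS[event.direction] == "horizontal":
                h[i:] = target
            else:
                v[i:] = target
    for event in schedule.events:
        if event.kind == "pursuit":
            i0 = int(np.ceil(event.start_s * sample_rate_hz - 1e-9))
            i1 = min(int(np.ceil(event.end_s * sample_rate_hz - 1e-9)), n)
            tt = t[i0:i1] - event.start_s
            theta = event.amplitude_deg * np.sin(
                2.0 * np.pi * event.frequency_hz * tt + (event.phase_rad or 0.0)
            )
            if event.axis == "horizontal":
                h[i0:i1] = theta
                v[i0:i1] = 0.0
            else:
                v[i0:i1] = theta
                h[i0:i1] = 0.0
    return GazeTrace(sample_rate_hz, h, v)
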