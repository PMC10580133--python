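"""Shared data model for the smartphone pinching test pipeline.

A test run is a 30-second task in which the participant squeezes on-screen
tomato shapes with two fingers of the tested hand while the other hand holds
the device.  The raw record of a run is three event streams (touch, shape
appearances, inertial samples) plus metadata.  Screen coordinates use the
device convention: origin top-left, x rightward, y downward, in
device-independent points.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime
from typing import Optional, Sequence

TOUCH_PHASES = ("down", "move", "up")
HANDS = ("dominant", "nondominant")
GROUPS = ("HC", "MS")

#: Clinical anchor names carried on participant records.  9HPT times are in
#: seconds (dominant/nondominant hand); SDMT is a count of correct responses;
#: the rest are questionnaire/exam scores.
ANCHOR_NAMES = (
    "hpt_dominant",
    "hpt_nondominant",
    "edss",
    "fss_pyramidal",
    "fss_cerebellar",
    "msis29_arm",
    "sdmt",
    "fsmc_total",
    "fsmc_physical",
    "fsmc_cognitive",
)

#: Anchors collected only in the MS group (not administered to controls).
MS_ONLY_ANCHORS = ("edss", "fss_pyramidal", "fss_cerebellar", "msis29_arm")


class ValidationError(ValueError):
    """An object violates a data-model invariant."""


@dataclass(frozen=True)
class TouchEvent:
    """One touchscreen sample: time (s since run start), finger track id,
    phase (down/move/up) and screen position in points."""

    t: float
    finger_id: int
    phase: str
    x: float
    y: float

    def __post_init__(self) -> None:
        if self.phase not in TOUCH_PHASES:
            raise ValidationError(f"touch phase must be one of {TOUCH_PHASES}, got {self.phase!r}")
        if not (self.t >= 0):
            raise ValidationError(f"touch time must be >= 0, got {self.t}")
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValidationError("touch coordinates must be finite")


@dataclass(frozen=True)
class ShapeEvent:
    """Appearance of one target shape: time, center, radius, order index."""

    t_appear: float
    cx: float
    cy: float
    radius: float
    index: int

    def __post_init__(self) -> None:
        if not (self.radius > 0):
            raise ValidationError(f"shape radius must be > 0, got {self.radius}")
        if not (self.t_appear >= 0):
            raise ValidationError(f"shape time must be >= 0, got {self.t_appear}")


@dataclass(frozen=True)
class ImuSample:
    """One inertial sample: time, acceleration in g (gravity included) and
    inclination — the angle (rad) between the screen normal and gravity,
    0 when the device lies flat, screen up."""

    t: float
    ax: float
    ay: float
    az: float
    inclination: float

    @property
    def magnitude(self) -> float:
        return math.sqrt(self.ax**2 + self.ay**2 + self.az**2)


@dataclass
class TestRun:
    """One 30-second pinching test run with all raw event streams."""

    run_id: str
    participant_id: str
    timestamp: datetime
    hand: str
    duration: float
    touch_events: list[TouchEvent] = field(default_factory=list)
    shape_events: list[ShapeEvent] = field(default_factory=list)
    imu: list[ImuSample] = field(default_factory=list)

    def validate(self) -> "TestRun":
        """Check every data-model invariant; raise ValidationError on the
        first violation, return self otherwise."""
        if self.hand not in HANDS:
            raise ValidationError(f"hand must be one of {HANDS}, got {self.hand!r}")
        if not (self.duration > 0):
            raise ValidationError("duration must be positive")
        for ev in self.touch_events:
            if not (0 <= ev.t <= self.duration):
                raise ValidationError(
                    f"touch event at t={ev.t} outside [0, {self.duration}]"
                )
        for sh in self.shape_events:
            if not (0 <= sh.t_appear <= self.duration):
                raise ValidationError(
                    f"shape event at t={sh.t_appear} outside [0, {self.duration}]"
                )
        for s in self.imu:
            if not (0 <= s.t <= self.duration):
                raise ValidationError(f"imu sample at t={s.t} outside [0, {self.duration}]")
        # shape appearance strictly increasing with index
        shapes = sorted(self.shape_events, key=lambda s: s.index)
        for a, b in zip(shapes, shapes[1:]):
            if not (b.t_appear > a.t_appear):
                raise ValidationError(
                    "shape appearance times must be strictly increasing with index"
                )
        # imu times nondecreasing
        for a, b in zip(self.imu, self.imu[1:]):
            if b.t < a.t:
                raise ValidationError("imu sample times must be nondecreasing")
        self._validate_finger_tracks()
        return self

    def _validate_finger_tracks(self) -> None:
        by_finger: dict[int, list[TouchEvent]] = {}
        for ev in self.touch_events:
            by_finger.setdefault(ev.finger_id, []).append(ev)
        for fid, evs in by_finger.items():
            for a, b in zip(evs, evs[1:]):
                if b.t < a.t:
                    raise ValidationError(f"finger {fid} events out of time order")
            # each finger track may consist of several down..up segments
            state = "up"
            for ev in evs:
                if ev.phase == "down":
                    if state == "down":
                        raise ValidationError(f"finger {fid}: 'down' while already down")
                    state = "down"
                elif ev.phase == "up":
                    if state == "up":
                        raise ValidationError(f"finger {fid}: 'up' before 'down'")
                    state = "up"
                else:  # move
                    if state == "up":
                        raise ValidationError(f"finger {fid}: 'move' outside down..up")
            if state != "up":
                raise ValidationError(f"finger {fid}: track does not end with 'up'")


@dataclass
class ParticipantRecord:
    """Demographics, group label and clinical anchors for one participant.

    ``visit_anchors`` maps each anchor name to up to three per-visit values
    (baseline, week 12, week 24); missing visits are simply absent.  EDSS and
    MSIS-29 arm items are collected in the MS group only.
    """

    participant_id: str
    age: float
    sex: str
    group: str
    visit_anchors: dict[str, list[float]] = field(default_factory=dict)

    def validate(self) -> "ParticipantRecord":
        if self.sex not in ("F", "M"):
            raise ValidationError(f"sex must be F or M, got {self.sex!r}")
        if self.group not in GROUPS:
            raise ValidationError(f"group must be one of {GROUPS}, got {self.group!r}")
        for name, values in self.visit_anchors.items():
            if name not in ANCHOR_NAMES:
                raise ValidationError(f"unknown anchor {name!r}")
            if len(values) > 3:
                raise ValidationError(f"anchor {name!r} has more than 3 visit values")
            if self.group == "HC" and name in MS_ONLY_ANCHORS:
                raise ValidationError(f"anchor {name!r} must not be present for HC")
        return self


@dataclass
class FeatureVector:
    """Named feature values for one run, in three families (13 pinching,
    11 inertial, 13 fatigability).  Missing values are ``None``."""

    run_id: str
    participant_id: str
    timestamp: datetime
    hand: str
    values: dict[str, Optional[float]] = field(default_factory=dict)

    def __getitem__(self, name: str) -> Optional[float]:
        return self.values[name]


def finger_segments(
    events: Sequence[TouchEvent],
) -> list[tuple[int, float, float, list[TouchEvent]]]:
    """Split touch events into per-finger down..up segments.

    Returns tuples ``(finger_id, t_down, t_up, events)`` ordered by t_down.
    Events must satisfy the track invariants (checked in TestRun.validate).
    """
    by_finger: dict[int, list[TouchEvent]] = {}
    for ev in events:
        by_finger.setdefault(ev.finger_id, []).append(ev)
    segments = []
    for fid, evs in by_finger.items():
        current: list[TouchEvent] = []
        for ev in evs:
            if ev.phase == "down":
                current = [ev]
            elif ev.phase == "move":
                current.append(ev)
            else:  # up
                current.append(ev)
                segments.append((fid, current[0].t, ev.t, current))
                current = []
    segments.sort(key=lambda s: (s[1], s[0]))
    return segments
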