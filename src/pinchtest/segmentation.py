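"""Segmentation of a run's touch stream into pinch attempts.

An attempt is a maximal interval during which at least one finger is on the
screen, bounded by all-fingers-up gaps.  Each attempt is assigned to the
target shape whose lifetime (appearance until the next appearance) contains
the attempt start, classified as two-finger when exactly two finger tracks
overlap in time, and as successful when both first-contact points fall
within a capture radius of the shape center and the fingers close to at
most a configured fraction of their initial separation.

The success rule mirrors the simulator's so that labels are consistent end
to end; both parameters are configurable.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .model import ShapeEvent, TestRun, TouchEvent, finger_segments


@dataclass
class SuccessRules:
    capture_radius: float = 1.5    # multiple of the shape radius
    squeeze_fraction: float = 0.5  # final/initial inter-finger distance, inclusive


@dataclass
class FingerTrack:
    finger_id: int
    t_down: float
    t_up: float
    events: list[TouchEvent]

    @property
    def first_point(self) -> tuple[float, float]:
        return (self.events[0].x, self.events[0].y)

    @property
    def last_point(self) -> tuple[float, float]:
        return (self.events[-1].x, self.events[-1].y)


@dataclass
class PinchAttempt:
    attempt_index: int
    target_shape_index: Optional[int]
    tracks: list[FingerTrack] = field(default_factory=list)
    is_two_finger: bool = False
    is_successful: bool = False

    @property
    def t_start(self) -> float:
        return min(tr.t_down for tr in self.tracks)

    @property
    def t_end(self) -> float:
        return max(tr.t_up for tr in self.tracks)


def _dist(p: tuple[float, float], q: tuple[float, float]) -> float:
    return math.hypot(p[0] - q[0], p[1] - q[1])


def _concurrent_pair(attempt: PinchAttempt) -> Optional[tuple[FingerTrack, FingerTrack]]:
    """The two tracks if the attempt has exactly two and they overlap in time."""
    if len(attempt.tracks) != 2:
        return None
    a, b = attempt.tracks
    if min(a.t_up, b.t_up) >= max(a.t_down, b.t_down):
        return a, b
    return None


def segment_attempts(run: TestRun, rules: SuccessRules | None = None) -> list[PinchAttempt]:
    """Segment and classify all pinch attempts of a run, ordered by start.

    A run with no touch events yields an empty list.  Attempts with more
    than two concurrent fingers count as performed but not two-finger.
    """
    rules = rules or SuccessRules()
    segments = finger_segments(run.touch_events)
    if not segments:
        return []
    shapes = sorted(run.shape_events, key=lambda s: s.t_appear)

    # group per-finger segments into maximal overlapping clusters:
    # a new attempt starts when a finger goes down after all are up
    attempts: list[PinchAttempt] = []
    current: list[FingerTrack] = []
    current_end = -math.inf
    for fid, t_down, t_up, evs in segments:
        track = FingerTrack(fid, t_down, t_up, evs)
        if current and t_down > current_end:
            attempts.append(PinchAttempt(len(attempts), None, current))
            current = []
            current_end = -math.inf
        current.append(track)
        current_end = max(current_end, t_up)
    if current:
        attempts.append(PinchAttempt(len(attempts), None, current))

    for att in attempts:
        att.target_shape_index = _active_shape(shapes, att.t_start)
        shape = None
        if att.target_shape_index is not None:
            shape = next(s for s in shapes if s.index == att.target_shape_index)
        classify_attempt(att, shape, rules)
    return attempts


def _active_shape(shapes: Sequence[ShapeEvent], t: float) -> Optional[int]:
    """Index of the shape whose lifetime (appearance -> next appearance)
    contains t; None when no shape has appeared yet."""
    active = None
    for s in shapes:
        if s.t_appear <= t:
            active = s.index
        else:
            break
    return active


def classify_attempt(
    attempt: PinchAttempt, shape: Optional[ShapeEvent], rules: SuccessRules
) -> PinchAttempt:
    """Set the two-finger and success flags in place.

    Success requires: exactly two concurrently-down fingers, both first
    contacts within ``capture_radius x shape.radius`` of the shape center,
    and a final inter-finger distance at most ``squeeze_fraction`` times the
    initial one (boundary inclusive).
    """
    pair = _concurrent_pair(attempt)
    attempt.is_two_finger = pair is not None
    attempt.is_successful = False
    if pair is None or shape is None:
        return attempt
    a, b = pair
    center = (shape.cx, shape.cy)
    capture = rules.capture_radius * shape.radius
    on_target = _dist(a.first_point, center) <= capture and _dist(b.first_point, center) <= capture
    d0 = _dist(a.first_point, b.first_point)
    d1 = _dist(a.last_point, b.last_point)
    squeezed = d0 > 0 and d1 <= rules.squeeze_fraction * d0
    attempt.is_successful = on_target and squeezed
    return attempt
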