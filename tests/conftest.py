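"""Shared fixtures: crafted runs and small simulated cohorts."""
from __future__ import annotations

from datetime import datetime

import numpy as np
import pytest

from pinchtest.model import ImuSample, ShapeEvent, TestRun, TouchEvent
from pinchtest.simulate import CohortConfig, simulate_cohort


def make_touch_track(
    finger_id: int,
    t_down: float,
    t_up: float,
    points: list[tuple[float, float]],
) -> list[TouchEvent]:
    """A down..move..up track visiting the given points at uniform times."""
    n = len(points)
    times = np.linspace(t_down, t_up, n)
    events = []
    for k, ((x, y), t) in enumerate(zip(points, times)):
        phase = "down" if k == 0 else ("up" if k == n - 1 else "move")
        events.append(TouchEvent(t=float(t), finger_id=finger_id, phase=phase, x=x, y=y))
    return events


def make_run(
    touch: list[TouchEvent],
    shapes: list[ShapeEvent] | None = None,
    imu: list[ImuSample] | None = None,
    duration: float = 30.0,
    hand: str = "dominant",
    run_id: str = "r1",
    participant_id: str = "p1",
) -> TestRun:
    if shapes is None:
        shapes = [ShapeEvent(0.0, 180.0, 320.0, 55.0, 0)]
    if imu is None:
        t = np.arange(0, duration + 1e-9, 0.04)
        imu = [ImuSample(float(tt), 0.6, 0.0, 0.8, 0.64) for tt in t]
    return TestRun(
        run_id=run_id,
        participant_id=participant_id,
        timestamp=datetime(2026, 1, 5, 18, 0),
        hand=hand,
        duration=duration,
        touch_events=sorted(touch, key=lambda e: (e.t, e.finger_id)),
        shape_events=shapes,
        imu=imu,
    ).validate()


def straight_pinch_run(n_attempts: int = 3, offset: float = 0.0) -> TestRun:
    """Noise-free run: each attempt's two fingers converge in straight lines
    onto the shape center; attempt k starts at 1 + 3k + offset seconds.
    Track times are multiples of 1/16 s (binary-exact), so a time-shifted
    copy has bit-identical relative event times."""
    center = (180.0, 320.0)
    touch: list[TouchEvent] = []
    shapes = [ShapeEvent(0.0, center[0], center[1], 55.0, 0)]
    for k in range(n_attempts):
        t0 = 1.0 + 3.0 * k + offset
        p_a = [(center[0] - 70 + i * 6.2, center[1]) for i in range(11)]
        p_b = [(center[0] + 70 - i * 6.2, center[1]) for i in range(11)]
        touch += make_touch_track(0, t0, t0 + 0.625, p_a)
        touch += make_touch_track(1, t0, t0 + 0.625, p_b)
    return make_run(touch, shapes=shapes)


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny but complete cohort exercising every pipeline stage."""
    cfg = CohortConfig(n_hc=3, n_ms=5, study_days=8, seed=123)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def simulated_runs(small_cohort):
    return small_cohort[0]
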