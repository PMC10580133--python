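"""The 37 pinching-test features.

Three families are computed per run:

* 13 **pinching** features from the touch stream — counts and fractions of
  attempts, finger-coordination asynchronies, responsiveness (gap time),
  movement extent and straightness, and speed;
* 11 **inertial** features from the stabilizing hand — mean/SD/excess
  kurtosis of the acceleration magnitude over three windows (during
  attempts, between attempts, whole test) plus two orientation summaries;
* 13 **fatigability** features — second-half minus first-half value of each
  pinching feature within the run.

Per-attempt quantities are summarized across all two-finger attempts by the
configured within-run aggregate (median by default).  Path and velocity
features are computed on coordinate channels resampled to 60 Hz and
low-pass filtered; timing landmarks (touch-down/lift times) come from the
raw events so filtering cannot shift them.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .model import FeatureVector, TestRun
from .preprocess import (
    PreprocessConfig,
    UniformTrace,
    _butter_design,
    _filtfilt_sos,
    resample_uniform,
)
from .segmentation import FingerTrack, PinchAttempt, _concurrent_pair, _dist

PINCHING_FEATURES = (
    "n_pinches",                    # number of performed pinches (attempts)
    "n_successful_pinches",
    "successful_attempts_fraction",
    "two_finger_attempts_fraction",
    "pinch_time",                   # s, t_end - t_start per attempt
    "gap_time",                     # s, t_start - target shape appearance
    "double_touch_asynchrony",      # s, |t_down difference| of the two fingers
    "double_lift_asynchrony",       # s, |t_up difference|
    "first_points_distance",        # points, inter-finger distance at contact
    "last_points_distance",         # points, inter-finger distance at lift
    "finger_path_length",           # points, both fingers' polylines summed
    "finger_velocity",              # points/s, path length / pinch time
    "finger_path_ratio",            # path length / straight displacement, >= 1
)

IMU_FEATURES = (
    "acc_magnitude_mean_pinch_duration",
    "acc_magnitude_sd_pinch_duration",
    "acc_magnitude_kurt_pinch_duration",
    "acc_magnitude_mean_pinch_gaps",
    "acc_magnitude_sd_pinch_gaps",
    "acc_magnitude_kurt_pinch_gaps",
    "acc_magnitude_mean_whole_test",
    "acc_magnitude_sd_whole_test",
    "acc_magnitude_kurt_whole_test",
    "horizontalness",               # mean |cos(inclination)|, 1 = flat
    "orientation_stability",        # -SD(inclination), higher = steadier
)

FATIGABILITY_FEATURES = tuple(f"fatigability_{name}" for name in PINCHING_FEATURES)

ALL_FEATURES = PINCHING_FEATURES + IMU_FEATURES + FATIGABILITY_FEATURES

#: family, per-attempt vs per-run, units, and direction in which worsening
#: upper-extremity function moves the value (+1 = increases, -1 = decreases,
#: 0 = no monotone prior).
FEATURE_DEFINITIONS: dict[str, dict] = {}
for _name in PINCHING_FEATURES:
    FEATURE_DEFINITIONS[_name] = {
        "family": "pinching",
        "level": "per_run" if _name.startswith(("n_", "successful", "two_")) else "per_attempt",
        "units": {
            "n_pinches": "count", "n_successful_pinches": "count",
            "successful_attempts_fraction": "fraction",
            "two_finger_attempts_fraction": "fraction",
            "pinch_time": "s", "gap_time": "s",
            "double_touch_asynchrony": "s", "double_lift_asynchrony": "s",
            "first_points_distance": "pt", "last_points_distance": "pt",
            "finger_path_length": "pt", "finger_velocity": "pt/s",
            "finger_path_ratio": "ratio",
        }[_name],
        "worsening": {
            "n_pinches": -1, "n_successful_pinches": -1,
            "successful_attempts_fraction": -1, "two_finger_attempts_fraction": -1,
            "pinch_time": +1, "gap_time": +1,
            "double_touch_asynchrony": +1, "double_lift_asynchrony": +1,
            "first_points_distance": 0, "last_points_distance": 0,
            "finger_path_length": 0, "finger_velocity": 0,
            "finger_path_ratio": +1,
        }[_name],
    }
for _name in IMU_FEATURES:
    FEATURE_DEFINITIONS[_name] = {
        "family": "imu",
        "level": "per_run",
        "units": "rad" if "orient" in _name or _name == "horizontalness" else "g",
        "worsening": -1 if _name == "orientation_stability" else 0,
    }
for _name in FATIGABILITY_FEATURES:
    FEATURE_DEFINITIONS[_name] = {
        "family": "fatigability",
        "level": "per_run",
        "units": FEATURE_DEFINITIONS[_name.removeprefix("fatigability_")]["units"],
        "worsening": 0,
    }

assert len(PINCHING_FEATURES) == 13 and len(IMU_FEATURES) == 11 and len(FATIGABILITY_FEATURES) == 13


@dataclass
class FeatureConfig:
    within_run_aggregate: str = "median"   # or "mean", across two-finger attempts
    preprocess: PreprocessConfig = None    # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.preprocess is None:
            self.preprocess = PreprocessConfig()
        if self.within_run_aggregate not in ("median", "mean"):
            raise ValueError("within_run_aggregate must be 'median' or 'mean'")

    def aggregate(self, values: Sequence[float]) -> Optional[float]:
        values = [v for v in values if v is not None and math.isfinite(v)]
        if not values:
            return None
        return float(np.median(values) if self.within_run_aggregate == "median" else np.mean(values))


def _filtered_polyline(track: FingerTrack, cfg: PreprocessConfig) -> np.ndarray:
    """Resample a finger track to the touch grid and low-pass filter it;
    returns an (n, 2) polyline.  Tracks too short to resample are used raw."""
    t = np.array([e.t for e in track.events])
    x = np.array([e.x for e in track.events])
    y = np.array([e.y for e in track.events])
    t, idx = np.unique(t, return_index=True)
    if t.size < 2:
        return np.column_stack([x[:1], y[:1]])
    x, y = x[idx], y[idx]
    trace = resample_uniform(t, {"x": x, "y": y}, cfg.touch_fs)
    arr = np.column_stack([trace.channels["x"], trace.channels["y"]])
    sos, zi = _butter_design(
        cfg.butter_order, float(cfg.effective_cutoff(cfg.touch_fs)), float(cfg.touch_fs)
    )
    if len(arr) > 3 * (2 * len(sos) + 1):
        arr = _filtfilt_sos(sos, zi, arr)
    return arr


def polyline_length(points: np.ndarray) -> float:
    if len(points) < 2:
        return 0.0
    return float(np.sum(np.hypot(*np.diff(points, axis=0).T)))


def _attempt_quantities(
    att: PinchAttempt, shape_appear: Optional[float], cfg: FeatureConfig
) -> Optional[dict[str, float]]:
    """Per-attempt quantities for one two-finger attempt; None otherwise."""
    pair = _concurrent_pair(att)
    if pair is None:
        return None
    a, b = pair
    q: dict[str, float] = {}
    q["pinch_time"] = att.t_end - att.t_start
    if shape_appear is not None:
        q["gap_time"] = att.t_start - shape_appear
    q["double_touch_asynchrony"] = abs(a.t_down - b.t_down)
    q["double_lift_asynchrony"] = abs(a.t_up - b.t_up)
    q["first_points_distance"] = _dist(a.first_point, b.first_point)
    q["last_points_distance"] = _dist(a.last_point, b.last_point)
    pa = _filtered_polyline(a, cfg.preprocess)
    pb = _filtered_polyline(b, cfg.preprocess)
    path = polyline_length(pa) + polyline_length(pb)
    q["finger_path_length"] = path
    if q["pinch_time"] > 0:
        q["finger_velocity"] = path / q["pinch_time"]
    straight = float(np.hypot(*(pa[-1] - pa[0]))) + float(np.hypot(*(pb[-1] - pb[0])))
    if straight > 0:
        q["finger_path_ratio"] = path / straight
    return q


def _quantities_by_attempt(
    attempts: Sequence[PinchAttempt],
    shape_appearances: dict[int, float],
    cfg: FeatureConfig,
) -> dict[int, Optional[dict[str, float]]]:
    return {
        att.attempt_index: _attempt_quantities(
            att, shape_appearances.get(att.target_shape_index), cfg  # type: ignore[arg-type]
        )
        for att in attempts
    }


def _pinching_from_attempts(
    attempts: Sequence[PinchAttempt],
    shape_appearances: dict[int, float],
    cfg: FeatureConfig,
    qcache: Optional[dict[int, Optional[dict[str, float]]]] = None,
) -> dict[str, Optional[float]]:
    out: dict[str, Optional[float]] = {name: None for name in PINCHING_FEATURES}
    n = len(attempts)
    n_two = sum(1 for a in attempts if a.is_two_finger)
    n_succ = sum(1 for a in attempts if a.is_successful)
    out["n_pinches"] = float(n)
    out["n_successful_pinches"] = float(n_succ)
    if n > 0:
        out["successful_attempts_fraction"] = n_succ / n
        out["two_finger_attempts_fraction"] = n_two / n
    if qcache is None:
        qcache = _quantities_by_attempt(attempts, shape_appearances, cfg)
    per_attempt: dict[str, list[float]] = {}
    for att in attempts:
        q = qcache.get(att.attempt_index)
        if q is None:
            continue
        for name, v in q.items():
            per_attempt.setdefault(name, []).append(v)
    for name in PINCHING_FEATURES:
        if FEATURE_DEFINITIONS[name]["level"] == "per_attempt":
            out[name] = cfg.aggregate(per_attempt.get(name, []))
    return out


def pinching_features(
    run: TestRun, attempts: Sequence[PinchAttempt], cfg: FeatureConfig | None = None
) -> dict[str, Optional[float]]:
    """The 13 touch-stream features for one run.

    Counts and fractions cover all attempts; per-attempt quantities are
    aggregated across two-finger attempts.  A run with zero two-finger
    attempts still emits counts and fractions, with per-attempt features
    missing.
    """
    cfg = cfg or FeatureConfig()
    appearances = {s.index: s.t_appear for s in run.shape_events}
    return _pinching_from_attempts(attempts, appearances, cfg)


def _excess_kurtosis(values: np.ndarray) -> Optional[float]:
    """Population (biased) excess kurtosis; None for < 4 samples or zero
    variance."""
    if values.size < 4:
        return None
    m = values.mean()
    m2 = np.mean((values - m) ** 2)
    if m2 == 0:
        return None
    m4 = np.mean((values - m) ** 4)
    return float(m4 / m2**2 - 3.0)


def imu_features(
    run: TestRun,
    attempts: Sequence[PinchAttempt],
    imu_trace: UniformTrace | None,
) -> dict[str, Optional[float]]:
    """The 11 stabilizing-hand features for one run.

    Windows: *pinch duration* = samples inside any attempt interval,
    *pinch gaps* = the complement within the trimmed span, *whole test* =
    all samples.  An absent or unprocessable inertial stream yields all 11
    missing; a window with fewer than 4 samples yields a missing kurtosis.
    """
    out: dict[str, Optional[float]] = {name: None for name in IMU_FEATURES}
    if imu_trace is None or imu_trace.n == 0:
        return out
    mag = imu_trace.channels["magnitude"]
    inc = imu_trace.channels["inclination"]
    times = imu_trace.times
    in_attempt = np.zeros(times.size, dtype=bool)
    for att in attempts:
        in_attempt |= (times >= att.t_start) & (times <= att.t_end)
    windows = {
        "pinch_duration": mag[in_attempt],
        "pinch_gaps": mag[~in_attempt],
        "whole_test": mag,
    }
    for wname, values in windows.items():
        if values.size >= 1:
            out[f"acc_magnitude_mean_{wname}"] = float(values.mean())
        if values.size >= 2:
            out[f"acc_magnitude_sd_{wname}"] = float(values.std(ddof=0))
        out[f"acc_magnitude_kurt_{wname}"] = _excess_kurtosis(values)
    out["horizontalness"] = float(np.mean(np.abs(np.cos(inc))))
    out["orientation_stability"] = float(-np.std(inc, ddof=0))
    return out


def fatigability_features(
    run: TestRun,
    attempts: Sequence[PinchAttempt],
    cfg: FeatureConfig | None = None,
    _qcache: Optional[dict[int, Optional[dict[str, float]]]] = None,
) -> dict[str, Optional[float]]:
    """Second-half minus first-half value of each pinching feature.

    Attempts are assigned to halves by their start time relative to
    duration/2 (boundary in the second half); each half is summarized with
    the same within-run aggregate as the pinching features.  A feature
    undefined in either half is missing.
    """
    cfg = cfg or FeatureConfig()
    mid = run.duration / 2
    appearances = {s.index: s.t_appear for s in run.shape_events}
    first = [a for a in attempts if a.t_start < mid]
    second = [a for a in attempts if a.t_start >= mid]
    f1 = _pinching_from_attempts(first, appearances, cfg, _qcache)
    f2 = _pinching_from_attempts(second, appearances, cfg, _qcache)
    out: dict[str, Optional[float]] = {}
    for name in PINCHING_FEATURES:
        a, b = f1[name], f2[name]
        out[f"fatigability_{name}"] = None if a is None or b is None else b - a
    return out


def extract_features(
    run: TestRun,
    attempts: Sequence[PinchAttempt],
    imu_trace: UniformTrace | None,
    cfg: FeatureConfig | None = None,
) -> FeatureVector:
    """All 37 features for one run, as a FeatureVector in registry order."""
    cfg = cfg or FeatureConfig()
    appearances = {s.index: s.t_appear for s in run.shape_events}
    qcache = _quantities_by_attempt(attempts, appearances, cfg)
    values: dict[str, Optional[float]] = {}
    values.update(_pinching_from_attempts(attempts, appearances, cfg, qcache))
    values.update(imu_features(run, attempts, imu_trace))
    values.update(fatigability_features(run, attempts, cfg, qcache))
    ordered = {name: values[name] for name in ALL_FEATURES}
    return FeatureVector(
        run_id=run.run_id,
        participant_id=run.participant_id,
        timestamp=run.timestamp,
        hand=run.hand,
        values=ordered,
    )
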