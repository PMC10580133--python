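"""The 37-feature extractor: definitions, oracles, invariants."""
from __future__ import annotations

import numpy as np
import pytest

from pinchtest.features import (
    ALL_FEATURES,
    FATIGABILITY_FEATURES,
    FEATURE_DEFINITIONS,
    IMU_FEATURES,
    PINCHING_FEATURES,
    FeatureConfig,
    _filtered_polyline,
    extract_features,
    fatigability_features,
    imu_features,
    pinching_features,
    polyline_length,
)
from pinchtest.model import ImuSample
from pinchtest.preprocess import PreprocessConfig, preprocess_imu
from pinchtest.segmentation import segment_attempts

from conftest import make_run, make_touch_track, straight_pinch_run
from test_segmentation import two_finger_gesture


class TestRegistry:
    def test_family_sizes(self):
        assert len(PINCHING_FEATURES) == 13
        assert len(IMU_FEATURES) == 11
        assert len(FATIGABILITY_FEATURES) == 13
        assert len(ALL_FEATURES) == 37

    def test_fatigability_names_mirror_pinching(self):
        assert FATIGABILITY_FEATURES == tuple(
            f"fatigability_{n}" for n in PINCHING_FEATURES
        )

    def test_definitions_cover_all(self):
        assert set(FEATURE_DEFINITIONS) == set(ALL_FEATURES)


class TestPinching:
    def test_simultaneous_touchdowns_zero_asynchrony(self):
        run = straight_pinch_run(n_attempts=3)
        attempts = segment_attempts(run)
        feats = pinching_features(run, attempts)
        assert feats["double_touch_asynchrony"] == 0.0
        assert feats["double_lift_asynchrony"] == 0.0

    def test_straight_fingers_path_ratio_one(self):
        run = straight_pinch_run(n_attempts=2)
        attempts = segment_attempts(run)
        feats = pinching_features(run, attempts)
        assert feats["finger_path_ratio"] == pytest.approx(1.0, abs=1e-9)

    def test_counts_and_fractions(self):
        touch = two_finger_gesture(1.0) + two_finger_gesture(3.0) + make_touch_track(
            0, 6.0, 6.3, [(10, 10), (11, 11), (12, 12)]
        )
        run = make_run(touch)
        feats = pinching_features(run, segment_attempts(run))
        assert feats["n_pinches"] == 3
        assert feats["n_successful_pinches"] == 2
        assert feats["successful_attempts_fraction"] == pytest.approx(2 / 3)
        assert feats["two_finger_attempts_fraction"] == pytest.approx(2 / 3)

    def test_gap_time_measured_from_shape_appearance(self):
        run = straight_pinch_run(n_attempts=1)  # attempt starts at t = 1.0
        feats = pinching_features(run, segment_attempts(run))
        assert feats["gap_time"] == pytest.approx(1.0, abs=1e-9)

    def test_first_last_point_distances(self):
        touch = two_finger_gesture(1.0, start_off=70.0, end_off=8.0)
        run = make_run(touch)
        feats = pinching_features(run, segment_attempts(run))
        assert feats["first_points_distance"] == pytest.approx(140.0, abs=1e-9)
        assert feats["last_points_distance"] == pytest.approx(16.0, abs=1e-9)

    def test_path_length_matches_polyline_oracle(self, simulated_runs):
        cfg = FeatureConfig()
        run = next(r for r in simulated_runs if r.touch_events)
        attempts = [a for a in segment_attempts(run) if a.is_two_finger]
        att = attempts[0]
        feats = pinching_features(run, [att], cfg)
        total = 0.0
        for tr in att.tracks:
            pts = _filtered_polyline(tr, cfg.preprocess)
            # brute-force polyline sum, sample by sample
            s = 0.0
            for p, q in zip(pts, pts[1:]):
                s += float(np.hypot(q[0] - p[0], q[1] - p[1]))
            total += s
        assert feats["finger_path_length"] == pytest.approx(total, abs=1e-9)

    def test_zero_two_finger_attempts_leaves_per_attempt_missing(self):
        touch = make_touch_track(0, 1.0, 1.4, [(10, 10), (20, 20), (30, 30)])
        run = make_run(touch)
        feats = pinching_features(run, segment_attempts(run))
        assert feats["n_pinches"] == 1
        assert feats["pinch_time"] is None
        assert feats["finger_path_ratio"] is None


class TestImu:
    def _trace(self, samples):
        return preprocess_imu(samples, PreprocessConfig())

    def test_constant_flat_stream(self):
        samples = [ImuSample(t, 0.0, 0.0, 1.0, 0.0) for t in np.arange(0, 30.01, 0.04)]
        run = straight_pinch_run()
        run.imu = samples
        feats = imu_features(run, segment_attempts(run), self._trace(samples))
        assert feats["acc_magnitude_mean_whole_test"] == pytest.approx(1.0, abs=1e-12)
        assert feats["acc_magnitude_sd_whole_test"] == pytest.approx(0.0, abs=1e-12)
        assert feats["horizontalness"] == pytest.approx(1.0, abs=1e-12)

    def test_vertical_steady_device(self):
        samples = [
            ImuSample(t, 1.0, 0.0, 0.0, np.pi / 2) for t in np.arange(0, 30.01, 0.04)
        ]
        run = straight_pinch_run()
        feats = imu_features(run, segment_attempts(run), self._trace(samples))
        assert feats["horizontalness"] == pytest.approx(0.0, abs=1e-12)
        assert feats["orientation_stability"] == pytest.approx(0.0, abs=1e-12)

    def test_absent_stream_gives_all_missing(self):
        run = straight_pinch_run()
        feats = imu_features(run, segment_attempts(run), None)
        assert all(feats[name] is None for name in IMU_FEATURES)

    def test_kurtosis_matches_moment_oracle_and_normal_null(self):
        rng = np.random.default_rng(11)
        x = rng.normal(0, 0.05, 10_000) + 1.0
        t = np.arange(x.size) * 0.003 + 2.0
        from pinchtest.preprocess import UniformTrace

        trace = UniformTrace(2.0, 1 / 0.003, {"magnitude": x, "inclination": np.zeros_like(x)})
        run = straight_pinch_run()
        feats = imu_features(run, [], trace)
        kurt = feats["acc_magnitude_kurt_whole_test"]
        m = x.mean()
        oracle = np.mean((x - m) ** 4) / np.mean((x - m) ** 2) ** 2 - 3
        assert kurt == pytest.approx(oracle, abs=1e-12)
        assert abs(kurt) < 4 * np.sqrt(24 / x.size)  # within CI of 0

    def test_small_window_kurtosis_missing(self):
        from pinchtest.preprocess import UniformTrace

        trace = UniformTrace(2.0, 50.0, {"magnitude": np.array([1.0, 1.1, 0.9]),
                                         "inclination": np.zeros(3)})
        run = straight_pinch_run()
        feats = imu_features(run, [], trace)
        assert feats["acc_magnitude_kurt_whole_test"] is None


class TestFatigability:
    def test_mirrored_halves_give_exact_zero(self):
        # second half replicates the first (touch AND shape streams),
        # shifted by duration/2
        from pinchtest.model import ShapeEvent

        run1 = straight_pinch_run(n_attempts=3)          # attempts at 1, 4, 7 s
        run2 = straight_pinch_run(n_attempts=3, offset=15.0)  # at 16, 19, 22 s
        touch = run1.touch_events + run2.touch_events
        shapes = [ShapeEvent(0.0, 180.0, 320.0, 55.0, 0),
                  ShapeEvent(15.0, 180.0, 320.0, 55.0, 1)]
        run = make_run(touch, shapes=shapes)
        feats = fatigability_features(run, segment_attempts(run))
        for name in FATIGABILITY_FEATURES:
            if feats[name] is not None:
                assert feats[name] == 0.0
        # per-attempt features must actually be present
        assert feats["fatigability_pinch_time"] == 0.0
        assert feats["fatigability_n_pinches"] == 0.0

    def test_constant_offset_in_pinch_time(self):
        run1 = straight_pinch_run(n_attempts=3)
        touch = list(run1.touch_events)
        # second half: same gestures but each 0.2 s longer
        for k in range(3):
            t0 = 16.0 + 3.0 * k
            touch += two_finger_gesture(t0, dur=0.825)
        run = make_run(touch)
        feats = fatigability_features(run, segment_attempts(run))
        assert feats["fatigability_pinch_time"] == pytest.approx(0.2, abs=1e-9)

    def test_matches_recomputation_oracle(self, simulated_runs):
        cfg = FeatureConfig()
        run = simulated_runs[4]
        attempts = segment_attempts(run)
        feats = fatigability_features(run, attempts, cfg)
        mid = run.duration / 2
        first = [a for a in attempts if a.t_start < mid]
        second = [a for a in attempts if a.t_start >= mid]
        f1 = pinching_features(run, first, cfg)
        f2 = pinching_features(run, second, cfg)
        for name in PINCHING_FEATURES:
            expected = (
                None if f1[name] is None or f2[name] is None else f2[name] - f1[name]
            )
            got = feats[f"fatigability_{name}"]
            if expected is None:
                assert got is None
            else:
                assert got == pytest.approx(expected, abs=1e-12)

    def test_empty_half_gives_missing(self):
        run = straight_pinch_run(n_attempts=2)  # all attempts in first half
        feats = fatigability_features(run, segment_attempts(run))
        assert feats["fatigability_pinch_time"] is None


class TestInvariants:
    def test_exact_slot_counts_per_run(self, simulated_runs):
        run = simulated_runs[0]
        attempts = segment_attempts(run)
        trace = preprocess_imu(run.imu, PreprocessConfig())
        fv = extract_features(run, attempts, trace)
        assert list(fv.values.keys()) == list(ALL_FEATURES)

    def test_path_ratio_at_least_one_and_fractions_bounded(self, simulated_runs):
        for run in simulated_runs[:25]:
            attempts = segment_attempts(run)
            feats = pinching_features(run, attempts)
            if feats["finger_path_ratio"] is not None:
                assert feats["finger_path_ratio"] >= 1.0 - 1e-9
            for name in ("successful_attempts_fraction", "two_finger_attempts_fraction"):
                if feats[name] is not None:
                    assert 0.0 <= feats[name] <= 1.0
            assert feats["n_successful_pinches"] <= feats["n_pinches"]

    def test_time_translation_invariance(self):
        from dataclasses import replace

        from pinchtest.model import ShapeEvent, TouchEvent

        run = straight_pinch_run(n_attempts=3)
        attempts = segment_attempts(run)
        base = pinching_features(run, attempts)

        shift = 0.75
        shifted = make_run(
            [replace(e, t=e.t + shift) for e in run.touch_events],
            shapes=[ShapeEvent(s.t_appear + shift, s.cx, s.cy, s.radius, s.index)
                    for s in run.shape_events],
        )
        feats = pinching_features(shifted, segment_attempts(shifted))
        for name in PINCHING_FEATURES:
            if name == "gap_time":
                continue  # measured from shape appearance, which also shifted
            a, b = base[name], feats[name]
            if a is None:
                assert b is None
            else:
                assert b == pytest.approx(a, abs=1e-9)
        assert feats["gap_time"] == pytest.approx(base["gap_time"], abs=1e-9)
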