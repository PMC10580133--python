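"""Event-level synthetic cohort generator.

The generator stands in for the raw data of a 24-week remote-monitoring
study: each participant carries a latent upper-extremity disability score
``d`` (unitless, ~0 for healthy controls, larger = more impaired) and a
latent fatigue trait correlated with it.  Every simulated run is a full
30-second event stream — shapes appearing, two finger tracks approaching
and squeezing each shape along minimum-jerk paths with AR(1) tremor, and an
inertial stream from the stabilizing hand — so the entire downstream
pipeline (segmentation, preprocessing, feature extraction, validity
filtering, psychometrics) can be exercised end to end.

How the latent score shapes a run (all slopes configurable):

* reaction latency (gap time) and attempt duration increase with d;
* touch-down/lift asynchronies and trajectory tremor increase with d;
* the probability that an attempt succeeds decreases with d, so performed
  and successful pinch counts fall;
* hand instability (acceleration noise, inclination wobble) increases with d;
* with probability ``invalid_run_prob`` the device lies flat on a table
  (near-zero acceleration variance, inclination ~ 0), producing a run the
  validity filter must reject.

Within-run fatigue: attempts starting in the second half of the test are
slowed by ``fatigue_slope`` times the participant's (positive part of the)
daily fatigue level; with ``fatigue_slope = 0`` the two halves are
statistically identical and fatigability features are centered on zero.

Clinical anchors are monotone functions of d (or of the fatigue trait for
the fatigue questionnaire) plus visit noise, three visits per participant.
Only signs and orderings are calibrated; no attempt is made to match the
original study's effect sizes.

Consecutive runs of a participant alternate dominant/nondominant hand.
Randomness derives from a single root seed through per-participant,
per-run substreams, so regenerating any subset is stable.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Optional

import numpy as np

from .model import (
    ImuSample,
    ParticipantRecord,
    ShapeEvent,
    TestRun,
    TouchEvent,
)

SCREEN_W, SCREEN_H = 360.0, 640.0
SHAPE_RADIUS = 55.0          # points
START_OFFSET = 70.0          # finger distance from shape center at contact
SUCCESS_END_OFFSET = 8.0     # finger distance from center after a squeeze
FAIL_SQUEEZE_RATIO = 0.75    # final/initial separation of a failed squeeze
MISS_OFFSET = 170.0          # distance of a missed attempt from the shape
TOUCH_RATE = 30.0            # Hz of simulated raw touch events
IMU_RATE = 25.0              # Hz of simulated raw inertial samples
SHAPE_DELAY = 0.05           # s between a success and the next appearance


def _sigmoid(z: float) -> float:
    return 1.0 / (1.0 + math.exp(-z))


@dataclass
class CohortConfig:
    """Study conditions of the synthetic cohort.

    Defaults mirror the source study's design: 18 controls and 67 people
    with MS followed for 24 weeks (168 days), two runs per day (one per
    hand, alternating).
    """

    n_hc: int = 18
    n_ms: int = 67
    study_days: int = 168
    runs_per_day: int = 2
    duration: float = 30.0

    # latent disability d per group (truncated normal, d >= 0)
    d_mean_hc: float = 0.25
    d_sd_hc: float = 0.15
    d_mean_ms: float = 1.0
    d_sd_ms: float = 0.55
    day_noise_sd: float = 0.15       # day-level wobble of d
    hand_penalty: float = 0.15       # added to d for the nondominant hand

    # fatigue
    fatigue_d_correlation: float = 0.6   # corr(fatigue trait, d)
    fatigue_day_sd: float = 0.3          # daily fluctuation of fatigue level
    fatigue_slope: float = 0.25          # s slowdown per unit fatigue, 2nd half

    # run mechanics as functions of the day's effective d
    gap_base: float = 0.50               # s, reaction latency at d = 0
    gap_slope: float = 0.30              # s per unit d
    dur_base: float = 0.45               # s, attempt duration at d = 0
    dur_slope: float = 0.15
    async_base: float = 0.020            # s, touch/lift asynchrony SD at d = 0
    async_slope: float = 0.045
    tremor_base: float = 0.6             # points, AR(1) innovation SD at d = 0
    tremor_slope: float = 2.2
    success_intercept: float = 2.4       # success logit at d = 0
    success_slope: float = -1.0          # per unit d
    one_finger_base: float = 0.04        # P(one-finger attempt) at d = 0
    one_finger_slope: float = 0.05
    acc_noise_base: float = 0.012        # g, hand-instability noise at d = 0
    acc_noise_slope: float = 0.020
    inc_noise_base: float = 0.02         # rad
    inc_noise_slope: float = 0.035

    invalid_run_prob: float = 0.05       # P(device flat on a table)

    # anchor links: anchor = intercept + slope * latent + N(0, noise)
    anchor_links: dict = field(default_factory=lambda: {
        "hpt_dominant":   {"intercept": 17.5, "slope": 4.5, "noise": 1.2},
        "hpt_nondominant": {"intercept": 17.8, "slope": 4.5, "noise": 1.2},
        "edss":           {"intercept": 0.0, "slope": 2.3, "noise": 0.55},
        "fss_pyramidal":  {"intercept": 0.0, "slope": 1.2, "noise": 0.7},
        "fss_cerebellar": {"intercept": 0.0, "slope": 1.0, "noise": 0.7},
        "msis29_arm":     {"intercept": 0.0, "slope": 24.0, "noise": 11.0},
        "sdmt":           {"intercept": 64.0, "slope": -9.0, "noise": 6.5},
        "fsmc_total":     {"intercept": 22.0, "slope": 36.0, "noise": 6.0},
    })

    seed: int = 0

    def validate(self) -> "CohortConfig":
        if min(self.n_hc, self.n_ms, self.study_days, self.runs_per_day) < 0:
            raise ValueError("counts must be >= 0")
        for name in ("d_sd_hc", "d_sd_ms", "day_noise_sd", "fatigue_day_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 <= self.invalid_run_prob <= 1):
            raise ValueError("invalid_run_prob must be in [0, 1]")
        if not (-1 <= self.fatigue_d_correlation <= 1):
            raise ValueError("fatigue_d_correlation must be in [-1, 1]")
        return self


@dataclass
class LatentState:
    """Ground truth for one simulated participant."""

    participant_id: str
    group: str
    d: float                       # latent disability
    fatigue: float                 # latent fatigue trait
    age: float
    sex: str
    dominant_hand: str = "right"


def _draw_latents(cfg: CohortConfig, rng: np.random.Generator) -> list[LatentState]:
    states = []
    for group, n in (("HC", cfg.n_hc), ("MS", cfg.n_ms)):
        mu = cfg.d_mean_hc if group == "HC" else cfg.d_mean_ms
        sd = cfg.d_sd_hc if group == "HC" else cfg.d_sd_ms
        for i in range(n):
            d = max(0.0, rng.normal(mu, sd))
            rho = cfg.fatigue_d_correlation
            fatigue = max(0.0, rho * d + math.sqrt(max(0.0, 1 - rho**2)) * rng.normal(mu, sd))
            pid = f"{group}{i + 1:03d}"
            age = float(np.clip(rng.normal(35.0 if group == "HC" else 39.0, 8.0), 18, 55))
            sex = "F" if rng.random() < (0.33 if group == "HC" else 0.67) else "M"
            states.append(LatentState(pid, group, d, fatigue, age, sex,
                                      "left" if rng.random() < 0.1 else "right"))
    return states


def _min_jerk(n: int) -> np.ndarray:
    tau = np.linspace(0.0, 1.0, n)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def _finger_events(
    fid: int,
    t_down: float,
    t_up: float,
    p0: np.ndarray,
    p1: np.ndarray,
    tremor_sd: float,
    rng: np.random.Generator,
) -> list[TouchEvent]:
    """One down..move..up track along a minimum-jerk straight path with AR(1)
    tremor on interior samples; endpoints are noise-free so that contact and
    lift landmarks are exact."""
    n = max(3, int(round((t_up - t_down) * TOUCH_RATE)) + 1)
    t = np.linspace(t_down, t_up, n)
    s = _min_jerk(n)
    pos = p0[None, :] + s[:, None] * (p1 - p0)[None, :]
    if tremor_sd > 0 and n > 2:
        noise = np.zeros((n, 2))
        phi = 0.8
        innov = rng.normal(0.0, tremor_sd, size=(n, 2))
        for k in range(1, n - 1):
            noise[k] = phi * noise[k - 1] + innov[k]
        noise[0] = noise[-1] = 0.0
        pos = pos + noise
    events = []
    for k in range(n):
        phase = "down" if k == 0 else ("up" if k == n - 1 else "move")
        events.append(TouchEvent(t=float(t[k]), finger_id=fid, phase=phase,
                                 x=float(pos[k, 0]), y=float(pos[k, 1])))
    return events


def _shape_center(rng: np.random.Generator) -> np.ndarray:
    margin = SHAPE_RADIUS + START_OFFSET + 20
    return np.array([
        rng.uniform(margin, SCREEN_W - margin) if SCREEN_W > 2 * margin else SCREEN_W / 2,
        rng.uniform(margin, SCREEN_H - margin),
    ])


def simulate_run(
    state: LatentState,
    day: int,
    hand: str,
    rng: np.random.Generator,
    cfg: CohortConfig | None = None,
    run_index: int = 0,
    fatigue_level: Optional[float] = None,
) -> TestRun:
    """Simulate one 30-second run for a participant on a given day and hand."""
    cfg = (cfg or CohortConfig()).validate()
    d_day = max(0.0, state.d + rng.normal(0.0, cfg.day_noise_sd))
    if hand == "nondominant":
        d_day += cfg.hand_penalty
    if fatigue_level is None:
        fatigue_level = max(0.0, state.fatigue + rng.normal(0.0, cfg.fatigue_day_sd))
    invalid = rng.random() < cfg.invalid_run_prob

    gap_mean = cfg.gap_base + cfg.gap_slope * d_day
    dur_mean = cfg.dur_base + cfg.dur_slope * d_day
    async_sd = cfg.async_base + cfg.async_slope * d_day
    tremor_sd = cfg.tremor_base + cfg.tremor_slope * d_day
    p_success = _sigmoid(cfg.success_intercept + cfg.success_slope * d_day)
    p_one = min(0.5, cfg.one_finger_base + cfg.one_finger_slope * d_day)
    slow2 = cfg.fatigue_slope * fatigue_level  # second-half slowdown, s

    duration = cfg.duration
    touch: list[TouchEvent] = []
    shapes: list[ShapeEvent] = []
    shape_idx = 0
    center = _shape_center(rng)
    shapes.append(ShapeEvent(0.0, float(center[0]), float(center[1]), SHAPE_RADIUS, 0))
    t = 0.0  # time the current shape appeared or the last attempt ended
    while True:
        in_second_half = t >= duration / 2
        extra = slow2 if in_second_half else 0.0
        gap = max(0.12, rng.normal(gap_mean + extra, 0.25 * gap_mean))
        t_start = t + gap
        dur = max(0.2, rng.normal(dur_mean + 0.5 * extra, 0.08))
        if t_start + dur > duration - 0.05:
            break
        one_finger = rng.random() < p_one
        success = (not one_finger) and rng.random() < p_success
        down_async = abs(rng.normal(0.0, async_sd))
        lift_async = abs(rng.normal(0.0, async_sd))

        theta = rng.uniform(0, 2 * math.pi)
        u = np.array([math.cos(theta), math.sin(theta)])
        if one_finger:
            p0 = center + START_OFFSET * u
            p1 = center + SUCCESS_END_OFFSET * u
            touch.extend(_finger_events(0, t_start, t_start + dur, p0, p1, tremor_sd, rng))
        else:
            if success:
                c = center
                end_off = SUCCESS_END_OFFSET
            elif rng.random() < 0.5:  # missed the shape entirely
                phi2 = rng.uniform(0, 2 * math.pi)
                c = center + MISS_OFFSET * np.array([math.cos(phi2), math.sin(phi2)])
                end_off = SUCCESS_END_OFFSET
            else:  # on target but did not squeeze enough
                c = center
                end_off = START_OFFSET * FAIL_SQUEEZE_RATIO
            starts = (c + START_OFFSET * u, c - START_OFFSET * u)
            ends = (c + end_off * u, c - end_off * u)
            t0s = (t_start, t_start + down_async)
            t1s = (t_start + dur, t_start + dur + lift_async)
            if t1s[1] > duration:
                break
            for fid in (0, 1):
                touch.extend(
                    _finger_events(fid, t0s[fid], t1s[fid],
                                   np.asarray(starts[fid]), np.asarray(ends[fid]),
                                   tremor_sd, rng)
                )
        t_end = t_start + dur + (0.0 if one_finger else lift_async)
        if success:
            shape_idx += 1
            t_next_shape = t_end + SHAPE_DELAY
            if t_next_shape >= duration:
                break
            center = _shape_center(rng)
            shapes.append(ShapeEvent(float(t_next_shape), float(center[0]),
                                     float(center[1]), SHAPE_RADIUS, shape_idx))
            t = t_next_shape
        else:
            t = t_end

    imu = _simulate_imu(duration, d_day, invalid, cfg, rng)
    touch.sort(key=lambda e: (e.t, e.finger_id))
    stamp = datetime(2026, 1, 5) + timedelta(days=day, hours=18, minutes=run_index)
    return TestRun(
        run_id=f"{state.participant_id}-d{day:03d}-r{run_index}",
        participant_id=state.participant_id,
        timestamp=stamp,
        hand=hand,
        duration=duration,
        touch_events=touch,
        shape_events=shapes,
        imu=imu,
    )


def _simulate_imu(
    duration: float,
    d_day: float,
    invalid: bool,
    cfg: CohortConfig,
    rng: np.random.Generator,
) -> list[ImuSample]:
    n = int(duration * IMU_RATE) + 1
    t = np.linspace(0.0, duration, n)
    if invalid:
        # device flat on a table: pure gravity plus sensor noise
        acc = np.tile([0.0, 0.0, 1.0], (n, 1)) + rng.normal(0.0, 2e-4, size=(n, 3))
        inc = np.abs(rng.normal(0.0, 0.002, size=n))
    else:
        theta0 = float(np.clip(rng.normal(0.9, 0.15), 0.4, 1.4))
        inc_noise = cfg.inc_noise_base + cfg.inc_noise_slope * d_day
        acc_noise = cfg.acc_noise_base + cfg.acc_noise_slope * d_day
        wobble = np.zeros(n)
        innov = rng.normal(0.0, inc_noise, size=n)
        phi = 0.9
        for k in range(1, n):
            wobble[k] = phi * wobble[k - 1] + innov[k]
        inc = np.clip(theta0 + wobble, 0.05, math.pi - 0.05)
        acc = np.column_stack([
            np.sin(inc) * 0.7, np.sin(inc) * 0.3, np.cos(inc)
        ]) + rng.normal(0.0, acc_noise, size=(n, 3))
    return [
        ImuSample(float(t[k]), float(acc[k, 0]), float(acc[k, 1]), float(acc[k, 2]),
                  float(inc[k]))
        for k in range(n)
    ]


def _anchor_visits(
    state: LatentState, cfg: CohortConfig, rng: np.random.Generator
) -> dict[str, list[float]]:
    """Three clinic visits per anchor, monotone in the latent scores."""
    anchors: dict[str, list[float]] = {}
    for name, link in cfg.anchor_links.items():
        if state.group == "HC" and name in ("edss", "fss_pyramidal", "fss_cerebellar", "msis29_arm"):
            continue
        latent = state.fatigue if name.startswith("fsmc") else state.d
        values = []
        for _ in range(3):
            v = link["intercept"] + link["slope"] * latent + rng.normal(0.0, link["noise"])
            if name.startswith("hpt"):
                v = max(12.0, v)
            elif name == "edss":
                v = float(np.clip(round(v * 2) / 2, 0.0, 5.5))
            elif name.startswith("fss"):
                v = float(np.clip(round(v), 0, 6))
            elif name == "msis29_arm":
                v = float(np.clip(v, 0.0, 100.0))
            elif name == "sdmt":
                v = float(np.clip(round(v), 5, 110))
            elif name == "fsmc_total":
                v = float(np.clip(v, 20.0, 100.0))
            values.append(float(v))
        anchors[name] = values
    if "fsmc_total" in anchors:
        phys = [round(0.52 * v, 1) for v in anchors["fsmc_total"]]
        anchors["fsmc_physical"] = phys
        anchors["fsmc_cognitive"] = [round(t - p, 1) for t, p in zip(anchors["fsmc_total"], phys)]
    return anchors


def simulate_cohort(
    cfg: CohortConfig | None = None,
) -> tuple[list[TestRun], list[ParticipantRecord], list[LatentState]]:
    """Simulate the full cohort: event-level runs, participant records with
    three-visit anchors, and the ground-truth latent table.

    Deterministic for a fixed config (including its seed).  Consecutive
    runs of each participant alternate hands, starting dominant.
    """
    cfg = (cfg or CohortConfig()).validate()
    root = np.random.SeedSequence(cfg.seed)
    latent_ss, *participant_ss = root.spawn(1 + cfg.n_hc + cfg.n_ms)
    states = _draw_latents(cfg, np.random.default_rng(latent_ss))

    runs: list[TestRun] = []
    participants: list[ParticipantRecord] = []
    for state, ss in zip(states, participant_ss):
        anchor_ss, day_root = ss.spawn(2)
        anchors = _anchor_visits(state, cfg, np.random.default_rng(anchor_ss))
        participants.append(
            ParticipantRecord(
                participant_id=state.participant_id,
                age=state.age,
                sex=state.sex,
                group=state.group,
                visit_anchors=anchors,
            ).validate()
        )
        run_counter = 0
        for day, day_ss in enumerate(day_root.spawn(cfg.study_days)):
            day_rng = np.random.default_rng(day_ss)
            fatigue_level = max(0.0, state.fatigue + day_rng.normal(0.0, cfg.fatigue_day_sd))
            for slot in range(cfg.runs_per_day):
                hand = "dominant" if run_counter % 2 == 0 else "nondominant"
                runs.append(
                    simulate_run(state, day, hand, day_rng, cfg,
                                 run_index=slot, fatigue_level=fatigue_level)
                )
                run_counter += 1
    return runs, participants, states
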