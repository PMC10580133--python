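"""Run validity, cohort retention, and windowed aggregation.

Because the test is self-administered, runs performed with the device lying
flat on a hard surface must be rejected; this is detected from the
stabilizing-hand inertial stream (near-zero acceleration-magnitude
variability together with a near-zero inclination).  Participants must
contribute at least 20 valid runs (per analyzed hand) to be retained.
Features are aggregated per participant over consecutive 2-week windows
anchored at the participant's first valid run (median; SD additionally for
fatigability features), each window requiring at least 3 valid runs, and
over the whole study.  Clinical anchors are averaged over the (up to 3)
clinic visits.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import ParticipantRecord, TestRun
from .preprocess import UniformTrace

STUDY_WINDOW = "study"  # sentinel window label for whole-study aggregates


@dataclass
class ValidityRules:
    min_acc_sd: float = 0.005          # g; below this the device is suspiciously still
    max_flat_inclination: float = 0.1  # rad; near 0 = lying flat, screen up
    min_runs_per_participant: int = 20
    min_runs_per_window: int = 3
    window_days: int = 14

    def validate(self) -> "ValidityRules":
        if self.min_acc_sd < 0 or self.max_flat_inclination < 0:
            raise ValueError("validity thresholds must be >= 0")
        if min(self.min_runs_per_participant, self.min_runs_per_window, self.window_days) < 1:
            raise ValueError("count thresholds must be >= 1")
        return self


def is_valid_run(
    run: TestRun,
    imu_trace: Optional[UniformTrace],
    rules: ValidityRules | None = None,
) -> tuple[bool, str]:
    """Flag a run invalid when the device was lying flat.

    Invalid iff acceleration-magnitude SD is strictly below ``min_acc_sd``
    AND mean inclination is below ``max_flat_inclination`` (a still but
    tilted device, e.g. propped against a stand, is not flagged).  A run
    without a processable inertial stream is invalid with reason
    ``no_imu``.
    """
    rules = (rules or ValidityRules()).validate()
    if imu_trace is None or imu_trace.n < 2:
        return False, "no_imu"
    mag_sd = float(np.std(imu_trace.channels["magnitude"], ddof=0))
    mean_inc = float(np.mean(imu_trace.channels["inclination"]))
    if mag_sd < rules.min_acc_sd and mean_inc < rules.max_flat_inclination:
        return False, "flat_device"
    return True, ""


def filter_cohort(
    feature_rows: pd.DataFrame,
    rules: ValidityRules | None = None,
    hand: str | None = "dominant",
) -> tuple[set[str], pd.DataFrame]:
    """Retain participants with >= ``min_runs_per_participant`` valid runs.

    ``feature_rows`` must carry ``participant_id``, ``hand`` and a boolean
    ``valid`` column.  When ``hand`` is given, only that hand's runs are
    counted (hands are analyzed independently).  Returns the retained
    participant ids and an exclusion log with per-participant valid-run
    counts.
    """
    rules = (rules or ValidityRules()).validate()
    rows = feature_rows if hand is None else feature_rows[feature_rows["hand"] == hand]
    counts = rows.groupby("participant_id")["valid"].sum()
    retained = {str(p) for p, c in counts.items() if c >= rules.min_runs_per_participant}
    log = pd.DataFrame({
        "participant_id": counts.index,
        "n_valid_runs": counts.values.astype(int),
        "retained": [str(p) in retained for p in counts.index],
    })
    return retained, log


def _window_aggregate(values: np.ndarray, method: str) -> float:
    if method == "median":
        return float(np.median(values))
    if method == "sd":
        return float(np.std(values, ddof=1)) if values.size > 1 else float("nan")
    raise ValueError(f"unknown aggregation method {method!r}")


def aggregate_windows(
    feature_rows: pd.DataFrame,
    feature_names: Sequence[str],
    rules: ValidityRules | None = None,
    method: str = "median",
    hand: str | None = "dominant",
) -> pd.DataFrame:
    """Aggregate valid runs over consecutive 2-week windows.

    Windows are ``window_days``-day bins counted from each participant's
    first valid run (per hand).  A window needs at least
    ``min_runs_per_window`` valid runs to be emitted, and each feature
    needs that many non-missing values within the window.  Returns tidy
    rows (participant_id, hand, window_index, n_valid_runs, method,
    feature columns).
    """
    rules = (rules or ValidityRules()).validate()
    rows = feature_rows[feature_rows["valid"]].copy()
    if hand is not None:
        rows = rows[rows["hand"] == hand]
    out = []
    for (pid, h), sub in rows.groupby(["participant_id", "hand"], sort=False):
        t0 = sub["timestamp"].min()
        days = (sub["timestamp"] - t0).dt.total_seconds() / 86400.0
        widx = np.floor(days / rules.window_days).astype(int)
        for w, wsub in sub.groupby(widx):
            if len(wsub) < rules.min_runs_per_window:
                continue
            rec: dict[str, object] = {
                "participant_id": pid,
                "hand": h,
                "window_index": int(w),
                "n_valid_runs": len(wsub),
                "method": method,
            }
            for name in feature_names:
                v = wsub[name].dropna().to_numpy(dtype=float)
                rec[name] = (
                    _window_aggregate(v, method)
                    if v.size >= rules.min_runs_per_window
                    else float("nan")
                )
            out.append(rec)
    cols = ["participant_id", "hand", "window_index", "n_valid_runs", "method", *feature_names]
    return pd.DataFrame(out, columns=cols)


def aggregate_study(
    feature_rows: pd.DataFrame,
    feature_names: Sequence[str],
    rules: ValidityRules | None = None,
    method: str = "median",
    hand: str | None = "dominant",
) -> pd.DataFrame:
    """Whole-study aggregate: one bin per participant spanning all valid
    runs (per hand)."""
    rules = (rules or ValidityRules()).validate()
    wide_rules = ValidityRules(
        min_acc_sd=rules.min_acc_sd,
        max_flat_inclination=rules.max_flat_inclination,
        min_runs_per_participant=rules.min_runs_per_participant,
        min_runs_per_window=rules.min_runs_per_window,
        window_days=10**6,  # one bin spans any realistic study
    )
    df = aggregate_windows(feature_rows, feature_names, wide_rules, method, hand)
    df = df.drop(columns=["window_index"])
    df.insert(2, "window", STUDY_WINDOW)
    return df


def aggregate_anchors(participant: ParticipantRecord) -> dict[str, float]:
    """Mean of the available clinic-visit values per anchor; anchors with no
    visit values are absent from the result."""
    out = {}
    for name, values in participant.visit_anchors.items():
        vals = [v for v in values if v is not None and np.isfinite(v)]
        if vals:
            out[name] = float(np.mean(vals))
    return out


def anchor_table(participants: Sequence[ParticipantRecord]) -> pd.DataFrame:
    """Participant-level table of demographics and visit-averaged anchors."""
    rows = []
    for p in participants:
        rec: dict[str, object] = {
            "participant_id": p.participant_id,
            "age": p.age,
            "sex": p.sex,
            "group": p.group,
        }
        rec.update(aggregate_anchors(p))
        rows.append(rec)
    return pd.DataFrame(rows)
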