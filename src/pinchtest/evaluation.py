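"""Standard validation experiments for the pipeline.

Each function builds its own inputs (synthetic cohorts or crafted runs),
runs the relevant pipeline stages, and returns the measured quantities.
They back both the validation test suite and the reproduction script, so
the numbers reported anywhere are always recomputed from scratch.
"""
from __future__ import annotations

from datetime import datetime
from typing import Sequence

import numpy as np
import pandas as pd

from .aggregate import aggregate_windows
from .features import (
    FATIGABILITY_FEATURES,
    FEATURE_DEFINITIONS,
    PINCHING_FEATURES,
    fatigability_features,
)
from .model import ImuSample, ShapeEvent, TestRun, TouchEvent
from .pipeline import AnalysisConfig, analyze_cohort, extract_run_features
from .psychometrics import (
    _anova_icc21,
    adjusted_spearman,
    bh_fdr,
    icc21,
    mann_whitney_auc,
)
from .segmentation import segment_attempts
from .simulate import CohortConfig, simulate_cohort

#: pinching features whose generative link to the latent disability score
#: has a declared direction (the registry's direction-of-worsening)
SIGNED_FEATURES: dict[str, int] = {
    name: FEATURE_DEFINITIONS[name]["worsening"]
    for name in PINCHING_FEATURES
    if FEATURE_DEFINITIONS[name]["worsening"] != 0
}


def feature_count_contract() -> dict[str, int]:
    """Family sizes the extractor emits for any run."""
    from .features import ALL_FEATURES, IMU_FEATURES

    return {
        "n_pinching_features": len(PINCHING_FEATURES),
        "n_imu_features": len(IMU_FEATURES),
        "n_fatigability_features": len(FATIGABILITY_FEATURES),
        "n_total_features": len(ALL_FEATURES),
    }


def icc_recovery(
    seed: int,
    rhos: Sequence[float] = (0.2, 0.5, 0.8),
    n_subjects: int = 100,
    n_windows: int = 6,
    n_replicates: int = 10,
) -> dict[float, float]:
    """Mean ICC(2,1) estimate over replicate cohorts with known variance
    ratio rho (subject variance / total variance)."""
    out = {}
    for j, rho in enumerate(rhos):
        rng = np.random.default_rng(seed + 1000 * j)
        estimates = []
        for _ in range(n_replicates):
            table = (
                rng.normal(0, np.sqrt(rho), (n_subjects, 1))
                + rng.normal(0, np.sqrt(1 - rho), (n_subjects, n_windows))
            )
            long = pd.DataFrame({
                "subject": np.repeat(np.arange(n_subjects), n_windows),
                "window": np.tile(np.arange(n_windows), n_subjects),
                "value": table.ravel(),
            })
            estimates.append(icc21(long, n_boot=0).icc)
        out[rho] = float(np.mean(estimates))
    return out


def icc_balanced_anova_agreement(seed: int, n_tables: int = 20) -> float:
    """Max |ICC - classical ANOVA ICC(2,1)| over random balanced tables."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_tables):
        n = int(rng.integers(4, 15))
        k = int(rng.integers(3, 8))
        table = (
            rng.normal(0, 1, (n, 1))
            + rng.normal(0, 0.5, (1, k))
            + rng.normal(0, 0.8, (n, k))
        )
        long = pd.DataFrame({
            "subject": np.repeat(np.arange(n), k),
            "window": np.tile(np.arange(k), n),
            "value": table.ravel(),
        })
        est = icc21(long, n_boot=0).icc
        worst = max(worst, abs(est - _anova_icc21(table)))
    return worst


def auc_identity_suite(seed: int, n_datasets: int = 100) -> float:
    """Max |AUC - pair-count oracle| over random two-group datasets,
    including heavily tied integer-valued ones."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for j in range(n_datasets):
        n1 = int(rng.integers(5, 40))
        n2 = int(rng.integers(5, 40))
        if j % 2 == 0:  # integer-valued: many ties
            a = rng.integers(0, 6, n1).astype(float)
            b = rng.integers(0, 6, n2).astype(float)
        else:
            a = rng.normal(0, 1, n1)
            b = rng.normal(0.3, 1, n2)
        _, auc = mann_whitney_auc(a, b)
        wins = (b[None, :] > a[:, None]).sum()
        ties = (b[None, :] == a[:, None]).sum()
        oracle = (wins + 0.5 * ties) / (n1 * n2)
        worst = max(worst, abs(auc - oracle))
    return worst


def bh_identity_suite(seed: int, n_vectors: int = 50) -> float:
    """Max |BH adjusted p - step-up oracle| over random p-vectors."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_vectors):
        p = rng.uniform(0, 1, int(rng.integers(3, 30)))
        adj = bh_fdr(p)
        m = len(p)
        order = np.argsort(p)
        oracle = np.empty(m)
        prev = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            prev = min(prev, p[i] * m / rank)
            oracle[i] = prev
        worst = max(worst, float(np.max(np.abs(adj - oracle))))
    return worst


def confound_removal_check(seed: int, n: int = 200) -> dict[str, float]:
    """Adjusted Spearman on two constructed cases: a feature that is a pure
    function of age (must vanish after adjustment) and a feature equal to
    the anchor (must stay near 1)."""
    rng = np.random.default_rng(seed)
    age = rng.uniform(20, 60, n)
    sex = rng.choice(["F", "M"], n)
    anchor = rng.normal(0, 1, n)
    pure_age = 3.0 * age - 10.0
    r_age = adjusted_spearman(pure_age, anchor, age, sex, n_boot=0).r
    r_identity = adjusted_spearman(anchor, anchor.copy(), age, sex, n_boot=0).r
    return {"abs_r_pure_age_feature": abs(r_age), "r_identity_feature": float(r_identity)}


def _mirrored_half_run() -> TestRun:
    """Crafted run whose second half replicates the first, shifted by half
    the test duration; event times are multiples of 1/16 s so the copy is
    binary-exact."""
    center = (180.0, 320.0)
    touch: list[TouchEvent] = []
    shapes = [ShapeEvent(0.0, center[0], center[1], 55.0, 0),
              ShapeEvent(15.0, center[0], center[1], 55.0, 1)]
    for half in (0.0, 15.0):
        for k in range(3):
            t0 = 1.0 + 4.0 * k + half
            for fid, sign in ((0, -1.0), (1, 1.0)):
                xs = [center[0] + sign * (70.0 - 6.2 * i) for i in range(11)]
                for i, x in enumerate(xs):
                    t = t0 + 0.0625 * i
                    phase = "down" if i == 0 else ("up" if i == 10 else "move")
                    touch.append(TouchEvent(t, fid, phase, x, center[1]))
    touch.sort(key=lambda e: (e.t, e.finger_id))
    imu = [ImuSample(0.04 * i, 0.6, 0.0, 0.8, 0.64) for i in range(751)]
    return TestRun("mirror", "p1", datetime(2026, 1, 5), "dominant", 30.0,
                   touch, shapes, imu).validate()


def fatigability_null_check() -> dict[str, float]:
    """All 13 fatigability features on a run with identical halves."""
    run = _mirrored_half_run()
    attempts = segment_attempts(run)
    feats = fatigability_features(run, attempts)
    values = [feats[name] for name in FATIGABILITY_FEATURES]
    assert all(v is not None for v in values), "all 13 values must be defined"
    return {
        "n_defined": float(sum(v is not None for v in values)),
        "max_abs_fatigability": float(max(abs(v) for v in values)),
    }


def window_aggregation_identity(seed: int, n_windows: int = 50) -> float:
    """Max deviation of window aggregates from two-pass statistics."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    t0 = pd.Timestamp("2026-01-05")
    for _ in range(n_windows):
        n = int(rng.integers(3, 12))
        vals = rng.normal(10, 3, n)
        df = pd.DataFrame({
            "participant_id": "p", "hand": "dominant", "valid": True,
            "timestamp": [t0 + pd.Timedelta(days=int(d)) for d in
                          rng.integers(0, 13, n)],
            "f": vals,
        })
        med = aggregate_windows(df, ["f"])["f"].iloc[0]
        sd = aggregate_windows(df, ["f"], method="sd")["f"].iloc[0]
        mean = vals.sum() / n
        var = ((vals - mean) ** 2).sum() / (n - 1)
        worst = max(worst, abs(med - float(np.median(vals))),
                    abs(sd - float(np.sqrt(var))))
    return worst


def end_to_end_sign_recovery(
    seed: int,
    n_ms: int = 100,
    n_hc: int = 12,
    study_days: int = 56,
    n_boot: int = 30,
) -> dict[str, object]:
    """Full-pipeline evaluation on a simulated cohort.

    Simulates the cohort at event level, extracts all 37 features, applies
    validity filtering and aggregation, and checks (a) that the adjusted
    Spearman sign between each direction-linked feature and the 9HPT anchor
    matches the generative direction, and (b) that those features separate
    MS-Normal from MS-Abnormal (oriented AUC > 0.5 in the matching
    direction).
    """
    cfg = CohortConfig(n_hc=n_hc, n_ms=n_ms, study_days=study_days, seed=seed)
    runs, participants, states = simulate_cohort(cfg)
    features = extract_run_features(runs)
    analysis = AnalysisConfig(n_boot=n_boot)
    report = analyze_cohort(
        features,
        participants,
        analysis,
        rng=np.random.default_rng(seed),
        icc_features=["gap_time", "double_touch_asynchrony", "n_pinches"],
        correlation_features=list(SIGNED_FEATURES),
    )
    corr = report.correlation_frame()
    hpt = corr[corr["anchor"] == "hpt_dominant"].set_index("feature")
    sign_matches = {
        name: bool(np.sign(hpt.loc[name, "r"]) == SIGNED_FEATURES[name])
        for name in SIGNED_FEATURES
        if name in hpt.index
    }
    kg = report.known_groups_frame()
    contrast = kg[kg["contrast"] == "pinching: MS-Normal vs MS-Abnormal"]
    contrast = contrast.set_index("feature")
    auc = {
        name: (float(contrast.loc[name, "auc"]), int(contrast.loc[name, "direction"]))
        for name in SIGNED_FEATURES
        if name in contrast.index
    }
    icc = {r.feature: r.icc for r in report.icc}
    return {
        "n_runs": len(runs),
        "n_retained": len(report.retained),
        "sign_matches": sign_matches,
        "correlations_hpt": {n: float(hpt.loc[n, "r"]) for n in hpt.index},
        "kg_auc_normal_vs_abnormal": auc,
        "icc": icc,
        "report": report,
    }
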