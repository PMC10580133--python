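"""End-to-end orchestration: runs -> features -> aggregates -> psychometrics.

This module wires the stages together the way the analyses consume them:
per-run feature extraction with validity flags, cohort retention, 2-week
window and whole-study aggregation, and the four analysis arms.  Each stage
is also usable on its own.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .aggregate import (
    STUDY_WINDOW,
    ValidityRules,
    aggregate_study,
    aggregate_windows,
    anchor_table,
    filter_cohort,
    is_valid_run,
)
from .features import (
    ALL_FEATURES,
    FATIGABILITY_FEATURES,
    IMU_FEATURES,
    PINCHING_FEATURES,
    FeatureConfig,
    extract_features,
)
from .model import ParticipantRecord, TestRun
from .preprocess import PreprocessError, preprocess_imu
from .psychometrics import (
    CorrelationResult,
    ICCResult,
    KnownGroupsResult,
    adjusted_spearman,
    fatigue_subgroups,
    icc21,
    known_groups,
    ms_subgroups,
)
from .segmentation import SuccessRules, segment_attempts


@dataclass
class AnalysisConfig:
    """Tunables of the analysis stages, one attribute per config block."""

    features: FeatureConfig = field(default_factory=FeatureConfig)
    segmentation: SuccessRules = field(default_factory=SuccessRules)
    validity: ValidityRules = field(default_factory=ValidityRules)
    hand: str = "dominant"
    n_boot: int = 200
    anchors: Sequence[str] = (
        "hpt_dominant", "edss", "msis29_arm", "sdmt", "fsmc_total",
    )


def extract_run_features(
    runs: Sequence[TestRun], config: AnalysisConfig | None = None
) -> pd.DataFrame:
    """Per-run feature table with validity flags.

    Returns one row per run: metadata, ``valid``/``invalid_reason`` from the
    inertial-stream check, and the 37 feature columns (NaN = missing).
    """
    config = config or AnalysisConfig()
    rows = []
    for run in runs:
        attempts = segment_attempts(run, config.segmentation)
        try:
            imu_trace = preprocess_imu(run.imu, config.features.preprocess)
        except PreprocessError:
            imu_trace = None
        valid, reason = is_valid_run(run, imu_trace, config.validity)
        fv = extract_features(run, attempts, imu_trace, config.features)
        rec: dict[str, object] = {
            "run_id": run.run_id,
            "participant_id": run.participant_id,
            "timestamp": run.timestamp,
            "hand": run.hand,
            "valid": valid,
            "invalid_reason": reason,
        }
        for name in ALL_FEATURES:
            v = fv.values[name]
            rec[name] = float("nan") if v is None else v
        rows.append(rec)
    df = pd.DataFrame(rows)
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df


@dataclass
class AnalysisReport:
    """Collected outputs of the four analysis arms."""

    retained: set[str]
    exclusion_log: pd.DataFrame
    windows_median: pd.DataFrame
    windows_sd: pd.DataFrame
    study_median: pd.DataFrame
    study_sd: pd.DataFrame
    anchors: pd.DataFrame
    icc: list[ICCResult]
    correlations: list[CorrelationResult]
    known_groups: list[KnownGroupsResult]

    def icc_frame(self) -> pd.DataFrame:
        cols = ["feature", "icc", "ci_low", "ci_high",
                "n_subjects", "n_windows_total", "band"]
        return pd.DataFrame([vars(r) for r in self.icc], columns=cols)

    def correlation_frame(self) -> pd.DataFrame:
        cols = ["feature", "anchor", "r", "ci_low", "ci_high", "n", "band"]
        return pd.DataFrame([vars(r) for r in self.correlations], columns=cols)

    def known_groups_frame(self) -> pd.DataFrame:
        cols = ["feature", "contrast", "p_raw", "p_fdr", "auc",
                "direction", "cohen_d", "n_a", "n_b"]
        return pd.DataFrame([vars(r) for r in self.known_groups], columns=cols)


#: feature categories for FDR grouping, matching the four report tables
FEATURE_CATEGORIES: dict[str, tuple[str, ...]] = {
    "pinching": PINCHING_FEATURES,
    "imu": IMU_FEATURES,
    "fatigability_median": FATIGABILITY_FEATURES,
    "fatigability_sd": FATIGABILITY_FEATURES,
}


def analyze_cohort(
    feature_rows: pd.DataFrame,
    participants: Sequence[ParticipantRecord],
    config: AnalysisConfig | None = None,
    rng: np.random.Generator | None = None,
    icc_features: Sequence[str] | None = None,
    correlation_features: Sequence[str] | None = None,
) -> AnalysisReport:
    """Run retention, aggregation and the psychometric arms on extracted
    features.

    ``icc_features``/``correlation_features`` restrict the (expensive)
    bootstrap analyses to a subset; None means all 37.
    """
    config = config or AnalysisConfig()
    rng = rng or np.random.default_rng(0)
    retained, log = filter_cohort(feature_rows, config.validity, config.hand)
    rows = feature_rows[feature_rows["participant_id"].isin(retained)]

    windows_median = aggregate_windows(rows, ALL_FEATURES, config.validity, "median", config.hand)
    windows_sd = aggregate_windows(rows, FATIGABILITY_FEATURES, config.validity, "sd", config.hand)
    study_median = aggregate_study(rows, ALL_FEATURES, config.validity, "median", config.hand)
    study_sd = aggregate_study(rows, FATIGABILITY_FEATURES, config.validity, "sd", config.hand)
    anchors = anchor_table(participants)
    anchors = anchors[anchors["participant_id"].isin(retained)].reset_index(drop=True)

    icc_results: list[ICCResult] = []
    for feat in icc_features if icc_features is not None else ALL_FEATURES:
        long = windows_median.rename(
            columns={"participant_id": "subject", "window_index": "window", feat: "value"}
        )[["subject", "window", "value"]]
        try:
            icc_results.append(icc21(long, feature=feat, n_boot=config.n_boot, rng=rng))
        except Exception:
            continue

    ms_anchors = anchors[anchors["group"] == "MS"]
    merged = study_median.merge(ms_anchors, on="participant_id", how="inner")
    corr_results: list[CorrelationResult] = []
    for feat in correlation_features if correlation_features is not None else ALL_FEATURES:
        for anchor in config.anchors:
            if anchor not in merged.columns:
                continue
            try:
                corr_results.append(
                    adjusted_spearman(
                        merged[feat].to_numpy(float),
                        merged[anchor].to_numpy(float),
                        merged["age"].to_numpy(float),
                        merged["sex"].tolist(),
                        feature=feat,
                        anchor=anchor,
                        n_boot=config.n_boot,
                        rng=rng,
                    )
                )
            except Exception:
                continue

    kg_results = known_groups_analysis(study_median, study_sd, anchors)
    return AnalysisReport(
        retained=retained,
        exclusion_log=log,
        windows_median=windows_median,
        windows_sd=windows_sd,
        study_median=study_median,
        study_sd=study_sd,
        anchors=anchors,
        icc=icc_results,
        correlations=corr_results,
        known_groups=kg_results,
    )


def known_groups_analysis(
    study_median: pd.DataFrame,
    study_sd: pd.DataFrame,
    anchors: pd.DataFrame,
) -> list[KnownGroupsResult]:
    """All known-groups contrasts with per-category FDR correction.

    Contrasts: HC vs MS-Normal, HC vs MS-Abnormal, MS-Normal vs
    MS-Abnormal for every category; fatigued vs non-fatigued (within MS)
    for the fatigability categories.
    """
    sub = ms_subgroups(anchors)
    fat = fatigue_subgroups(anchors)
    results: list[KnownGroupsResult] = []
    for category, feats in FEATURE_CATEGORIES.items():
        table = study_sd if category == "fatigability_sd" else study_median
        merged = table.merge(anchors, on="participant_id", how="inner")
        labels = ms_subgroups(merged)
        contrasts = [
            ("HC vs MS-Normal", labels == "HC", labels == "MS-Normal"),
            ("HC vs MS-Abnormal", labels == "HC", labels == "MS-Abnormal"),
            ("MS-Normal vs MS-Abnormal", labels == "MS-Normal", labels == "MS-Abnormal"),
        ]
        if category.startswith("fatigability"):
            flabels = fatigue_subgroups(merged)
            contrasts.append(
                ("non-fatigued vs fatigued", flabels == "non-fatigued", flabels == "fatigued")
            )
        for name, a, b in contrasts:
            try:
                res = known_groups(
                    merged,
                    a.to_numpy(),
                    b.to_numpy(),
                    merged["age"].to_numpy(float),
                    merged["sex"].tolist(),
                    contrast=f"{category}: {name}",
                    features=list(feats),
                )
            except Exception:
                continue
            results.extend(res)
    return results
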