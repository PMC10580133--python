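"""Shared vs complementary information across the 13 pinching features.

Within-person associations are estimated with the repeated-measures
correlation (per-subject intercepts, common slope) over 2-week windows;
the cross-sectional feature space is summarized by PCA explained-variance
fractions and a varimax-rotated principal-axis factor analysis.
"""
from pinchtest import (
    ALL_FEATURES,
    CohortConfig,
    PINCHING_FEATURES,
    aggregate_study,
    aggregate_windows,
    extract_run_features,
    factor_summary,
    pca_summary,
    rm_correlation,
    simulate_cohort,
)

cfg = CohortConfig(n_hc=6, n_ms=20, study_days=42, seed=5)
runs, participants, _ = simulate_cohort(cfg)
features = extract_run_features(runs)
windows = aggregate_windows(features, ALL_FEATURES)
study = aggregate_study(features, ALL_FEATURES)

pairs = [("n_pinches", "pinch_time"), ("n_pinches", "gap_time"),
         ("n_pinches", "finger_velocity"), ("gap_time", "finger_path_ratio")]
print("repeated-measures correlations (within-person, across windows):")
for fa, fb in pairs:
    sub = windows.rename(columns={"participant_id": "subject", fa: "x", fb: "y"})
    r, dof = rm_correlation(sub[["subject", "x", "y"]])
    print(f"  {fa:<14s} vs {fb:<18s} r_rm = {r:+.2f}  (df = {dof})")

mat = study[list(PINCHING_FEATURES)]
fractions, counts = pca_summary(mat)
cum = fractions.cumsum()
print(f"\nPCA of the {mat.shape[1]} pinching features "
      f"({mat.dropna().shape[0]} participants):")
print("  cumulative explained variance:",
      " ".join(f"{c:.2f}" for c in cum[:8]))
print(f"  components for 80% of variance: {counts[0.8]}; for 90%: {counts[0.9]}")

loadings, communalities = factor_summary(mat, n_factors=3)
print("\nvarimax-rotated factor loadings (|loading| >= 0.5 marked):")
for name, row in loadings.iterrows():
    marks = " ".join(f"{v:+.2f}{'*' if abs(v) >= 0.5 else ' '}" for v in row)
    print(f"  {name:<30s} {marks}")
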