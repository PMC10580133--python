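"""Simulate a small cohort and extract the 37 per-run features.

Each simulated run is a full 30-second event stream; the extractor
segments pinch attempts, preprocesses the touch and inertial signals, and
emits 13 pinching + 11 inertial + 13 fatigability features per run along
with a validity flag (runs with the device flat on a table are invalid).
"""
import pandas as pd

from pinchtest import CohortConfig, extract_run_features, simulate_cohort

cfg = CohortConfig(n_hc=3, n_ms=6, study_days=10, seed=42)
runs, participants, states = simulate_cohort(cfg)
print(f"simulated {len(runs)} runs for {len(participants)} participants")

features = extract_run_features(runs)
print(f"feature table: {features.shape[0]} rows x {features.shape[1]} columns")
print(f"valid runs: {int(features['valid'].sum())} "
      f"({features['valid'].mean():.0%}); invalid reasons: "
      f"{features.loc[~features['valid'], 'invalid_reason'].unique().tolist()}")

cols = ["participant_id", "hand", "n_pinches", "n_successful_pinches",
        "gap_time", "double_touch_asynchrony", "finger_path_ratio"]
print("\nfirst runs (gap/asynchrony in seconds; path ratio 1 = straight):")
print(features[cols].head(6).round(3).to_string(index=False))

# more impaired participants pinch fewer shapes and move less smoothly
truth = pd.DataFrame([{"participant_id": s.participant_id, "d": s.d} for s in states])
by_person = (
    features[features["valid"]]
    .groupby("participant_id")[["n_pinches", "finger_path_ratio"]]
    .median()
)
by_person["latent_disability"] = truth.set_index("participant_id")["d"]
print("\nper-participant medians vs latent disability:")
print(by_person.round(3).to_string())
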