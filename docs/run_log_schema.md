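# Run-log schema (version 1)

One JSON document per test run, with four top-level sections. All times are
seconds since run start unless `meta.time_unit` is `"ms"`, in which case
every time field (including `meta.duration`) is divided by 1000 on read.

```json
{
  "schema_version": 1,
  "meta": {
    "run_id": "MS001-d003-r0",
    "participant_id": "MS001",
    "timestamp": "2026-01-08T18:00:00",
    "hand": "dominant",
    "duration": 30.0,
    "time_unit": "s"
  },
  "touch":  [{"t": 1.02, "finger_id": 0, "phase": "down", "x": 110.0, "y": 320.0}, ...],
  "shapes": [{"t_appear": 0.0, "cx": 180.0, "cy": 320.0, "radius": 55.0, "index": 0}, ...],
  "imu":    [{"t": 0.0, "ax": 0.61, "ay": 0.02, "az": 0.79, "inclination": 0.66}, ...]
}
```

Field conventions:

* **Coordinates** — origin top-left, x rightward, y downward, units =
  device-independent points.
* **touch.phase** — one of `down`, `move`, `up`; each finger track is a
  time-ordered sequence of `down .. move* .. up` segments. A `finger_id`
  may be reused across non-overlapping segments.
* **shapes** — one entry per target shape appearance; `t_appear` strictly
  increasing with `index`; `radius > 0`.
* **imu.ax/ay/az** — acceleration in g, gravity included;
  **imu.inclination** — angle in radians between the screen normal and
  gravity (0 = device flat, screen up). Sample times nondecreasing.
* All event times must lie in `[0, duration]`.

Violations raise a structured parse error naming the offending field
(schema problems) or a validation error (invariant violations).

# Tabular outputs

All tables are UTF-8 CSV with a header row; missing values are empty cells.

* **Feature table** (`pinch extract`) — one row per run: `run_id`,
  `participant_id`, `timestamp` (ISO-8601), `hand`, `valid`,
  `invalid_reason`, then the 37 feature columns in registry order
  (13 pinching, 11 inertial, 13 fatigability).
* **Window aggregates** (`pinch aggregate`) — `participant_id`, `hand`,
  `window_index` (0-based from each participant's first valid run; the
  whole-study table uses a `window` column holding `study`),
  `n_valid_runs`, `method` (`median` or `sd`), feature columns.
* **Participants** — one row per participant-visit: `participant_id`,
  `age`, `sex` (`F`/`M`), `group` (`HC`/`MS`), `visit` (0-2), then anchor
  columns (`hpt_dominant`, `hpt_nondominant`, `edss`, `fss_pyramidal`,
  `fss_cerebellar`, `msis29_arm`, `sdmt`, `fsmc_total`, `fsmc_physical`,
  `fsmc_cognitive`); anchors not collected for a group/visit are empty.
* **Psychometric results** (`pinch analyze`) — tidy tables `icc.csv`
  (feature, icc, ci_low, ci_high, n_subjects, n_windows_total, band),
  `correlations.csv` (feature, anchor, r, ci_low, ci_high, n, band) and
  `known_groups.csv` (feature, contrast, p_raw, p_fdr, auc, direction,
  cohen_d, n_a, n_b).
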