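"""Reading and writing run logs and tabular outputs.

Run logs are one JSON document per run with top-level keys
``{schema_version, meta, touch, shapes, imu}``.  Times are stored in seconds
since run start; a log may declare ``meta.time_unit: "ms"`` in which case all
times are divided by 1000 on read.  The schema is documented in
``docs/run_log_schema.md``.

Tabular outputs (feature tables, window aggregates, psychometric results)
are UTF-8 CSV with an empty cell as the missing-value token.
"""
from __future__ import annotations

import json
import math
from datetime import datetime
from pathlib import Path
from typing import Iterable, Sequence, Union

import pandas as pd

from .model import (
    FeatureVector,
    ImuSample,
    ParticipantRecord,
    ShapeEvent,
    TestRun,
    TouchEvent,
    ValidationError,
)

SCHEMA_VERSION = 1

PathLike = Union[str, Path]


class ParseError(ValueError):
    """A run log does not conform to the documented schema."""

    def __init__(self, message: str, field: str = ""):
        super().__init__(message)
        self.field = field


def _require(doc: dict, key: str, context: str) -> object:
    if key not in doc:
        raise ParseError(f"missing field {context}{key!r}", field=f"{context}{key}")
    return doc[key]


def write_run(run: TestRun, path: PathLike) -> None:
    """Serialize a TestRun to a run-log JSON document."""
    doc = {
        "schema_version": SCHEMA_VERSION,
        "meta": {
            "run_id": run.run_id,
            "participant_id": run.participant_id,
            "timestamp": run.timestamp.isoformat(),
            "hand": run.hand,
            "duration": run.duration,
            "time_unit": "s",
        },
        "touch": [
            {"t": e.t, "finger_id": e.finger_id, "phase": e.phase, "x": e.x, "y": e.y}
            for e in run.touch_events
        ],
        "shapes": [
            {"t_appear": s.t_appear, "cx": s.cx, "cy": s.cy, "radius": s.radius, "index": s.index}
            for s in run.shape_events
        ],
        "imu": [
            {"t": s.t, "ax": s.ax, "ay": s.ay, "az": s.az, "inclination": s.inclination}
            for s in run.imu
        ],
    }
    Path(path).write_text(json.dumps(doc), encoding="utf-8")


def read_run(path: PathLike) -> TestRun:
    """Read and validate a run-log JSON document.

    Raises ParseError on schema violations (naming the offending field) and
    ValidationError when the parsed run violates a data-model invariant.
    """
    try:
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise ParseError(f"not valid JSON: {exc}") from exc
    if not isinstance(doc, dict):
        raise ParseError("run log must be a JSON object")
    meta = _require(doc, "meta", "")
    if not isinstance(meta, dict):
        raise ParseError("'meta' must be an object", field="meta")
    unit = meta.get("time_unit", "s")
    if unit not in ("s", "ms"):
        raise ParseError(f"unsupported time_unit {unit!r}", field="meta.time_unit")
    scale = 1e-3 if unit == "ms" else 1.0

    def _num(value: object, field: str) -> float:
        if not isinstance(value, (int, float)) or isinstance(value, bool) or not math.isfinite(value):
            raise ParseError(f"field {field!r} must be a finite number, got {value!r}", field=field)
        return float(value)

    touch = []
    for i, e in enumerate(doc.get("touch", [])):
        touch.append(
            TouchEvent(
                t=_num(_require(e, "t", f"touch[{i}]."), f"touch[{i}].t") * scale,
                finger_id=int(_require(e, "finger_id", f"touch[{i}].")),
                phase=str(_require(e, "phase", f"touch[{i}].")),
                x=_num(_require(e, "x", f"touch[{i}]."), f"touch[{i}].x"),
                y=_num(_require(e, "y", f"touch[{i}]."), f"touch[{i}].y"),
            )
        )
    shapes = []
    for i, s in enumerate(doc.get("shapes", [])):
        shapes.append(
            ShapeEvent(
                t_appear=_num(_require(s, "t_appear", f"shapes[{i}]."), f"shapes[{i}].t_appear") * scale,
                cx=_num(_require(s, "cx", f"shapes[{i}]."), f"shapes[{i}].cx"),
                cy=_num(_require(s, "cy", f"shapes[{i}]."), f"shapes[{i}].cy"),
                radius=_num(_require(s, "radius", f"shapes[{i}]."), f"shapes[{i}].radius"),
                index=int(_require(s, "index", f"shapes[{i}].")),
            )
        )
    imu = []
    for i, s in enumerate(doc.get("imu", [])):
        imu.append(
            ImuSample(
                t=_num(_require(s, "t", f"imu[{i}]."), f"imu[{i}].t") * scale,
                ax=_num(_require(s, "ax", f"imu[{i}]."), f"imu[{i}].ax"),
                ay=_num(_require(s, "ay", f"imu[{i}]."), f"imu[{i}].ay"),
                az=_num(_require(s, "az", f"imu[{i}]."), f"imu[{i}].az"),
                inclination=_num(
                    _require(s, "inclination", f"imu[{i}]."), f"imu[{i}].inclination"
                ),
            )
        )
    run = TestRun(
        run_id=str(_require(meta, "run_id", "meta.")),
        participant_id=str(_require(meta, "participant_id", "meta.")),
        timestamp=datetime.fromisoformat(str(_require(meta, "timestamp", "meta."))),
        hand=str(_require(meta, "hand", "meta.")),
        duration=_num(_require(meta, "duration", "meta."), "meta.duration") * scale,
        touch_events=touch,
        shape_events=shapes,
        imu=imu,
    )
    return run.validate()


METADATA_COLUMNS = ["run_id", "participant_id", "timestamp", "hand"]


def feature_table(rows: Sequence[FeatureVector]) -> pd.DataFrame:
    """Assemble feature vectors into a rectangular DataFrame.

    All rows must share one feature-name set; column order is metadata
    columns followed by feature names in the order of the first row.
    """
    if not rows:
        return pd.DataFrame(columns=METADATA_COLUMNS)
    names = list(rows[0].values.keys())
    name_set = set(names)
    records = []
    for fv in rows:
        if set(fv.values.keys()) != name_set:
            raise ValidationError(
                f"run {fv.run_id}: feature names differ from the first row"
            )
        rec = {
            "run_id": fv.run_id,
            "participant_id": fv.participant_id,
            "timestamp": fv.timestamp.isoformat(),
            "hand": fv.hand,
        }
        for n in names:
            v = fv.values[n]
            rec[n] = float("nan") if v is None else v
        records.append(rec)
    return pd.DataFrame.from_records(records, columns=METADATA_COLUMNS + names)


def write_feature_table(rows: Sequence[FeatureVector], path: PathLike) -> None:
    """Write one CSV row per run; missing values are empty cells."""
    feature_table(rows).to_csv(path, index=False)


def read_feature_table(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "timestamp" in df.columns:
        df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df


def write_participants(records: Iterable[ParticipantRecord], path: PathLike) -> None:
    """Write one CSV row per participant-visit; anchors missing a visit are
    empty cells."""
    rows = []
    for rec in records:
        n_visits = max((len(v) for v in rec.visit_anchors.values()), default=0)
        for visit in range(max(n_visits, 1)):
            row: dict[str, object] = {
                "participant_id": rec.participant_id,
                "age": rec.age,
                "sex": rec.sex,
                "group": rec.group,
                "visit": visit,
            }
            for name, values in rec.visit_anchors.items():
                row[name] = values[visit] if visit < len(values) else float("nan")
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_participants(path: PathLike) -> list[ParticipantRecord]:
    df = pd.read_csv(path)
    records = []
    for pid, sub in df.groupby("participant_id", sort=False):
        sub = sub.sort_values("visit")
        anchors: dict[str, list[float]] = {}
        anchor_cols = [c for c in sub.columns if c not in ("participant_id", "age", "sex", "group", "visit")]
        for name in anchor_cols:
            vals = [float(v) for v in sub[name] if pd.notna(v)]
            if vals:
                anchors[name] = vals
        records.append(
            ParticipantRecord(
                participant_id=str(pid),
                age=float(sub["age"].iloc[0]),
                sex=str(sub["sex"].iloc[0]),
                group=str(sub["group"].iloc[0]),
                visit_anchors=anchors,
            ).validate()
        )
    return records
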