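"""Readers for the two raw-data dialects and the cleaned interchange format.

Two source layouts are supported:

* Ohio-style: one XML archive per subject with ``glucose_level``,
  ``exercise`` and ``basis_heart_rate`` event sections plus a body-weight
  attribute. Glucose is in mg/dL at 5-minute sampling, exercise events are
  self-reported with a 1-10 intensity, a duration in minutes and a start
  timestamp.
* D1namo-style: one folder per subject with a glucose registration CSV
  (``date,time,glucose,type``; concentrations in mmol/L; type ``cgm`` or
  ``manual``) and a 1 Hz sensor summary CSV with heart rate and the Zephyr
  activity level.

Both are parsed into :class:`RawSubjectData`; unit conversion (mmol/L to
mg/dL, factor 18.0182) happens downstream so all feature math runs on one
scale. The cleaned interchange format is a headered CSV mirroring the
record structure [date, time, BG, HR, exercise] with weight kept separately
in the header line.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .records import SubjectSeries, make_series_frame

__all__ = [
    "RawSubjectData",
    "ParseError",
    "SchemaError",
    "read_ohio_subject",
    "read_d1namo_subject",
    "write_cleaned",
    "read_cleaned",
]

log = logging.getLogger(__name__)

#: Accepted timestamp dialects, tried in order.
_TS_FORMATS = ("%Y-%m-%d %H:%M:%S", "%d-%m-%Y %H:%M:%S")


class ParseError(ValueError):
    """Malformed input file."""


class SchemaError(ValueError):
    """Input file lacks a required column or section."""


@dataclass
class ExerciseEvent:
    ts: pd.Timestamp
    intensity: Optional[int]
    duration_min: Optional[float]
    kind: str = "exercise"
    competitive: bool = False


@dataclass
class RawSubjectData:
    """Raw per-subject event lists, sorted by timestamp, before cleaning."""

    subject_id: str
    weight: Optional[float]
    glucose_events: pd.DataFrame  # [ts, value, unit, kind]; kind cgm|manual
    exercise_events: list[ExerciseEvent] = field(default_factory=list)
    hr_events: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["ts", "hr_bpm"])
    )
    highrate_stream: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["ts", "hr_bpm", "activity"])
    )


def _parse_ts(text: str, formats=_TS_FORMATS) -> pd.Timestamp:
    for fmt in formats:
        try:
            return pd.Timestamp(pd.to_datetime(text, format=fmt))
        except (ValueError, TypeError):
            continue
    raise ParseError(f"unparseable timestamp {text!r}")


def read_ohio_subject(path, ts_formats=_TS_FORMATS) -> RawSubjectData:
    """Parse an Ohio-style subject XML archive.

    Missing sections yield empty event lists; a missing weight raises,
    because body weight is a required feature of both feature sets.
    """
    from lxml import etree

    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise ParseError(f"{path}: malformed XML: {exc}") from exc
    root = tree.getroot()

    subject_id = root.get("id") or path.stem
    weight_attr = root.get("weight")
    if weight_attr is None:
        raise SchemaError(
            f"{path}: weight unavailable (body weight is a required feature)"
        )
    weight = float(weight_attr)

    def _events(section: str):
        node = root.find(section)
        return [] if node is None else node.findall("event")

    g_ts, g_val = [], []
    for ev in _events("glucose_level"):
        g_ts.append(_parse_ts(ev.get("ts"), ts_formats))
        g_val.append(float(ev.get("value")))
    glucose = pd.DataFrame(
        {"ts": g_ts, "value": g_val, "unit": "mg/dL", "kind": "cgm"}
    ).sort_values("ts", kind="stable", ignore_index=True)

    exercise: list[ExerciseEvent] = []
    for ev in _events("exercise"):
        intensity = ev.get("intensity")
        duration = ev.get("duration")
        exercise.append(
            ExerciseEvent(
                ts=_parse_ts(ev.get("ts"), ts_formats),
                intensity=None if intensity is None else int(intensity),
                duration_min=None if duration is None else float(duration),
                kind=ev.get("type", "exercise"),
                competitive=(ev.get("competitive", "false").lower() == "true"),
            )
        )
    exercise.sort(key=lambda e: e.ts)

    h_ts, h_val = [], []
    for ev in _events("basis_heart_rate"):
        h_ts.append(_parse_ts(ev.get("ts"), ts_formats))
        h_val.append(float(ev.get("value")))
    hr = pd.DataFrame({"ts": h_ts, "hr_bpm": h_val}).sort_values(
        "ts", kind="stable", ignore_index=True
    )

    return RawSubjectData(
        subject_id=subject_id,
        weight=weight,
        glucose_events=glucose,
        exercise_events=exercise,
        hr_events=hr,
    )


def read_d1namo_subject(path) -> RawSubjectData:
    """Parse a D1namo-style subject folder.

    Expects ``glucose.csv`` (date, time, glucose in mmol/L, type) and
    ``sensor.csv`` (datetime, hr, activity at 1 Hz); manual finger-stick rows
    are retained but tagged so cleaning can exclude them from the CGM grid.
    Unparseable rows are skipped with a logged count.
    """
    path = Path(path)
    glucose_path = path / "glucose.csv"
    sensor_path = path / "sensor.csv"
    if not glucose_path.exists():
        raise SchemaError(f"{path}: glucose.csv not found")
    if not sensor_path.exists():
        raise SchemaError(f"{path}: sensor.csv not found")

    glucose_raw = pd.read_csv(glucose_path, dtype=str)
    for col in ("date", "time", "glucose", "type"):
        if col not in glucose_raw.columns:
            raise SchemaError(f"{glucose_path}: missing column {col!r}")

    rows, skipped = [], 0
    for _, row in glucose_raw.iterrows():
        try:
            ts = _parse_ts(f"{row['date']} {row['time']}")
            value = float(row["glucose"])
            kind = str(row["type"]).strip().lower()
        except (ParseError, ValueError):
            skipped += 1
            continue
        rows.append((ts, value, kind))
    if skipped:
        log.warning("%s: skipped %d unparseable glucose rows", glucose_path, skipped)
    glucose = pd.DataFrame(rows, columns=["ts", "value", "kind"])
    glucose["unit"] = "mmol/L"
    glucose = glucose[["ts", "value", "unit", "kind"]].sort_values(
        "ts", kind="stable", ignore_index=True
    )

    sensor_raw = pd.read_csv(sensor_path)
    if len(sensor_raw) == 0:
        highrate = pd.DataFrame(columns=["ts", "hr_bpm", "activity"])
    else:
        for col in ("datetime", "hr", "activity"):
            if col not in sensor_raw.columns:
                raise SchemaError(f"{sensor_path}: missing column {col!r}")
        highrate = pd.DataFrame(
            {
                "ts": pd.to_datetime(sensor_raw["datetime"]),
                "hr_bpm": pd.to_numeric(sensor_raw["hr"], errors="coerce"),
                "activity": pd.to_numeric(sensor_raw["activity"], errors="coerce"),
            }
        ).sort_values("ts", kind="stable", ignore_index=True)

    weight_path = path / "weight.txt"
    weight = float(weight_path.read_text().strip()) if weight_path.exists() else None

    return RawSubjectData(
        subject_id=path.name,
        weight=weight,
        glucose_events=glucose,
        highrate_stream=highrate,
    )


# ---------------------------------------------------------------------------
# Cleaned interchange format: headered CSV, lossless round-trip.
# ---------------------------------------------------------------------------


def write_cleaned(series: SubjectSeries, path) -> None:
    """Write a cleaned series as CSV: a metadata comment line, then one row
    per registration with columns [date, time, bg_mgdl, hr_bpm, exercise]."""
    path = Path(path)
    frame = pd.DataFrame(
        {
            "date": series.data["ts"].dt.strftime("%Y-%m-%d"),
            "time": series.data["ts"].dt.strftime("%H:%M:%S"),
            "bg_mgdl": series.data["bg_mgdl"].map(lambda v: format(v, ".17g")),
            "hr_bpm": series.data["hr_bpm"].map(
                lambda v: "" if np.isnan(v) else format(v, ".17g")
            ),
            "exercise": series.data["exercise"].astype(int),
        }
    )
    header = (
        f"# subject_id={series.subject_id} weight={series.weight!r} "
        f"interval={series.nominal_interval} units={series.unit_system}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        frame.to_csv(fh, index=False)


def read_cleaned(path) -> SubjectSeries:
    """Inverse of :func:`write_cleaned` (lossless round-trip)."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# "):
            raise ParseError(f"{path}: missing metadata header line")
        meta = dict(
            item.split("=", 1) for item in header[2:].strip().split(" ") if "=" in item
        )
        body = pd.read_csv(fh, dtype={"date": str, "time": str})
    ts = pd.to_datetime(body["date"] + " " + body["time"], format="%Y-%m-%d %H:%M:%S")
    frame = make_series_frame(
        ts,
        body["bg_mgdl"].astype(float),
        pd.to_numeric(body["hr_bpm"], errors="coerce")
        if "hr_bpm" in body
        else None,
        body["exercise"].astype(np.int8),
    )
    return SubjectSeries(
        subject_id=meta["subject_id"],
        weight=float(meta["weight"]),
        data=frame,
        nominal_interval=int(meta.get("interval", 5)),
        unit_system=meta.get("units", "mg/dL"),
    )
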