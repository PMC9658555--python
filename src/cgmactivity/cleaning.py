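"""Cleaning rules: exercise labeling, 24 h block extraction, 1 Hz aggregation.

The detection task is framed on cleaned 5-minute series. For Ohio-style
data the binary exercise label is set to 1 on every registration during an
ongoing self-reported episode, except that episodes with reported intensity
below 2 are ignored. Analysis is restricted to midnight-to-midnight day
blocks in which the CGM signal is (nearly) complete and at least one
exercise registration exists; days without any reported activity are
discarded because unreported exercise would poison the negative class.

For D1namo-style data the 1 Hz heart-rate/activity stream is averaged
between consecutive glucose registrations, and a registration is labeled
as exercise when its mean Zephyr activity level exceeds 0.2 (the mild-
activity threshold), strictly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ingest import RawSubjectData
from .records import MMOL_TO_MGDL, SubjectSeries, make_series_frame

__all__ = [
    "CleaningConfig",
    "DayBlock",
    "label_exercise",
    "aggregate_highrate",
    "extract_day_blocks",
    "series_from_ohio",
    "series_from_d1namo",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CleaningConfig:
    min_intensity: int = 2  # self-reported episodes below this are unlabeled
    activity_threshold: float = 0.2  # strict > threshold -> exercise
    max_gap: float = 7.5  # min; largest tolerated intra-day CGM gap
    min_day_coverage: float = 0.9  # fraction of the nominal daily grid
    require_hr: bool = False

    def validate(self) -> None:
        if self.max_gap <= 0 or self.activity_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if not 0.0 < self.min_day_coverage <= 1.0:
            raise ValueError("min_day_coverage must lie in (0, 1]")


@dataclass
class DayBlock:
    """One retained midnight-to-midnight day of labeled registrations."""

    subject_id: str
    date: object  # datetime.date
    records: pd.DataFrame = field(repr=False)  # [ts, bg_mgdl, hr_bpm, exercise]
    has_hr: bool = False
    weight: float = float("nan")

    @property
    def n_positive(self) -> int:
        return int(self.records["exercise"].sum())

    def __len__(self) -> int:
        return len(self.records)


def label_exercise(grid_ts, exercise_events, config: CleaningConfig) -> np.ndarray:
    """Binary label per grid timestamp: 1 iff inside [start, start+duration)
    of an event whose intensity is at least ``min_intensity``.

    Events without a duration cannot define an interval; they are rejected
    with a warning and contribute no labels.
    """
    grid = pd.DatetimeIndex(grid_ts)
    labels = np.zeros(len(grid), dtype=np.int8)
    for ev in exercise_events:
        if ev.duration_min is None or not math.isfinite(ev.duration_min):
            log.warning("exercise event at %s has no duration; skipped", ev.ts)
            continue
        if ev.intensity is not None and ev.intensity < config.min_intensity:
            continue
        start = pd.Timestamp(ev.ts)
        end = start + pd.Timedelta(minutes=ev.duration_min)
        labels |= ((grid >= start) & (grid < end)).astype(np.int8)
    return labels


def aggregate_highrate(
    highrate: pd.DataFrame, grid_ts, config: CleaningConfig
) -> pd.DataFrame:
    """Average the 1 Hz stream between consecutive glucose registrations.

    Samples in the half-open interval (t_{i-1}, t_i] are assigned to
    registration i; the first registration collects the nominal 5 minutes
    preceding it. Returns one row per registration with the mean heart rate
    (rounded to an integer, NaN when no samples fell in the interval), the
    mean activity level, the threshold label (mean activity strictly above
    ``activity_threshold``) and the sample count.
    """
    grid = pd.DatetimeIndex(grid_ts)
    n = len(grid)
    out = pd.DataFrame(
        {
            "ts": grid,
            "hr_bpm": np.full(n, np.nan),
            "activity": np.full(n, np.nan),
            "exercise": np.zeros(n, dtype=np.int8),
            "n_samples": np.zeros(n, dtype=int),
        }
    )
    if n == 0 or len(highrate) == 0:
        return out

    ts = highrate["ts"].to_numpy()
    grid_np = grid.to_numpy()
    # interval lower edge for registration 0: one nominal step before it
    step = grid_np[1] - grid_np[0] if n > 1 else np.timedelta64(5, "m")
    lower = grid_np[0] - step
    idx = np.searchsorted(grid_np, ts, side="left")  # (t_{i-1}, t_i] -> i
    valid = (ts > lower) & (idx < n)
    idx = idx[valid]

    hr = highrate["hr_bpm"].to_numpy()[valid]
    act = highrate["activity"].to_numpy()[valid]
    counts = np.bincount(idx, minlength=n)
    hr_ok = np.isfinite(hr)
    act_ok = np.isfinite(act)
    hr_sum = np.bincount(idx[hr_ok], weights=hr[hr_ok], minlength=n)
    hr_n = np.bincount(idx[hr_ok], minlength=n)
    act_sum = np.bincount(idx[act_ok], weights=act[act_ok], minlength=n)
    act_n = np.bincount(idx[act_ok], minlength=n)

    with np.errstate(invalid="ignore", divide="ignore"):
        hr_mean = np.where(hr_n > 0, hr_sum / np.maximum(hr_n, 1), np.nan)
        act_mean = np.where(act_n > 0, act_sum / np.maximum(act_n, 1), np.nan)

    out["hr_bpm"] = np.where(np.isfinite(hr_mean), np.rint(hr_mean), np.nan)
    out["activity"] = act_mean
    # round before the strict comparison so float accumulation in the mean
    # cannot flip a value sitting exactly on the threshold
    out["exercise"] = (
        np.round(np.nan_to_num(act_mean, nan=0.0), 9) > config.activity_threshold
    ).astype(np.int8)
    out["n_samples"] = counts
    n_empty = int((counts == 0).sum())
    if n_empty:
        log.info("%d registrations had no 1 Hz samples in their interval", n_empty)
    return out


def extract_day_blocks(series: SubjectSeries, config: CleaningConfig) -> list[DayBlock]:
    """Retain midnight-to-midnight days that are analyzable.

    A day survives iff (a) CGM coverage is at least ``min_day_coverage`` of
    the nominal grid and no gap — including the margins to midnight —
    exceeds ``max_gap``; (b) at least one registration is labeled as
    exercise; and (c) when ``require_hr`` is set, every registration of the
    day carries a heart-rate value. An empty result is valid.
    """
    config.validate()
    blocks: list[DayBlock] = []
    if len(series) == 0:
        return blocks
    data = series.data
    expected = (24 * 60) // series.nominal_interval
    for date, day in data.groupby(data["ts"].dt.date, sort=True):
        coverage = len(day) / expected
        if coverage < config.min_day_coverage:
            continue
        day_start = pd.Timestamp(date)
        edges = (
            [day_start]
            + list(day["ts"])
            + [day_start + pd.Timedelta(days=1)]
        )
        gaps_min = np.diff(pd.DatetimeIndex(edges).asi8) / 60e9
        if gaps_min.max() > config.max_gap:
            continue
        if int(day["exercise"].sum()) == 0:
            continue
        has_hr = bool(day["hr_bpm"].notna().all()) and len(day) > 0
        if config.require_hr and not has_hr:
            continue
        blocks.append(
            DayBlock(
                subject_id=series.subject_id,
                date=date,
                records=day.reset_index(drop=True),
                has_hr=has_hr,
                weight=series.weight,
            )
        )
    return blocks


def series_from_ohio(raw: RawSubjectData, config: CleaningConfig) -> SubjectSeries:
    """Assemble a labeled 5-minute series from Ohio-style raw events.

    The CGM grid defines the registrations; heart-rate events are matched
    to registrations by nearest timestamp within half the nominal interval;
    labels come from the self-reported episodes via :func:`label_exercise`.
    """
    config.validate()
    if raw.weight is None:
        raise ValueError(f"{raw.subject_id}: weight unavailable")
    glucose = raw.glucose_events
    cgm = glucose[glucose["kind"] == "cgm"].reset_index(drop=True)
    grid = pd.DatetimeIndex(cgm["ts"])
    bg = cgm["value"].to_numpy(dtype=float)

    hr = np.full(len(grid), np.nan)
    if len(raw.hr_events) > 0:
        matched = pd.merge_asof(
            pd.DataFrame({"ts": grid}),
            raw.hr_events.rename(columns={"hr_bpm": "hr"}),
            on="ts",
            direction="nearest",
            tolerance=pd.Timedelta(minutes=2.5),
        )
        hr = matched["hr"].to_numpy(dtype=float)

    labels = label_exercise(grid, raw.exercise_events, config)
    frame = make_series_frame(grid, bg, hr, labels)
    return SubjectSeries(
        subject_id=raw.subject_id,
        weight=float(raw.weight),
        data=frame,
        unit_system="mg/dL",
    )


def series_from_d1namo(
    raw: RawSubjectData, config: CleaningConfig, convert_units: bool = True
) -> SubjectSeries:
    """Assemble a labeled 5-minute series from D1namo-style raw data.

    Only CGM-type registrations form the grid (manual finger sticks are
    excluded); concentrations are converted mmol/L -> mg/dL unless
    ``convert_units`` is False; heart rate and labels come from the 1 Hz
    stream via :func:`aggregate_highrate`.
    """
    config.validate()
    if raw.weight is None:
        raise ValueError(f"{raw.subject_id}: weight unavailable")
    glucose = raw.glucose_events
    cgm = glucose[glucose["kind"] == "cgm"].reset_index(drop=True)
    grid = pd.DatetimeIndex(cgm["ts"])
    bg = cgm["value"].to_numpy(dtype=float)
    unit_system = "mmol/L"
    if convert_units:
        bg = bg * MMOL_TO_MGDL
        unit_system = "mmol/L->mg/dL"

    agg = aggregate_highrate(raw.highrate_stream, grid, config)
    frame = make_series_frame(grid, bg, agg["hr_bpm"], agg["exercise"])
    return SubjectSeries(
        subject_id=raw.subject_id,
        weight=float(raw.weight),
        data=frame,
        unit_system=unit_system,
    )
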