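"""Core record containers shared by the simulator, ingest and cleaning stages.

The canonical in-memory object is :class:`SubjectSeries`: one subject's
chronologically ordered 5-minute registrations, each carrying blood glucose
(mg/dL), an optional heart rate (bpm, integer-valued) and a binary exercise
label, plus the subject's body weight which is recorded once and handled
separately from the time series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: mmol/L -> mg/dL conversion factor for glucose (molar mass of glucose / 10).
MMOL_TO_MGDL = 18.0182

#: Nominal CGM sampling interval in minutes.
CGM_INTERVAL_MIN = 5

#: Columns of the tabular record model, in canonical order.
RECORD_COLUMNS = ["ts", "bg_mgdl", "hr_bpm", "exercise"]


@dataclass
class SubjectSeries:
    """Chronological 5-minute registrations for one subject.

    ``data`` holds one row per registration with columns ``ts`` (timestamp),
    ``bg_mgdl`` (float), ``hr_bpm`` (float, NaN when the heart-rate channel is
    absent) and ``exercise`` (0/1). Rows are strictly increasing in ``ts``.
    """

    subject_id: str
    weight: float
    data: pd.DataFrame = field(repr=False)
    nominal_interval: int = CGM_INTERVAL_MIN
    unit_system: str = "mg/dL"  # "mg/dL" (native) or "mmol/L->mg/dL" (converted)

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValueError(f"weight must be positive, got {self.weight}")
        missing = [c for c in RECORD_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"series data missing columns {missing}")
        ts = self.data["ts"].to_numpy()
        if len(ts) > 1 and not (ts[1:] > ts[:-1]).all():
            raise ValueError("series records must be strictly increasing in time")

    @property
    def has_hr(self) -> bool:
        hr = self.data["hr_bpm"]
        return len(hr) > 0 and hr.notna().all()

    def __len__(self) -> int:
        return len(self.data)

    def equals(self, other: "SubjectSeries") -> bool:
        """Value equality: same id, weight, interval and identical records."""
        if (
            self.subject_id != other.subject_id
            or self.nominal_interval != other.nominal_interval
            or not np.isclose(self.weight, other.weight)
        ):
            return False
        a = self.data.reset_index(drop=True)
        b = other.data.reset_index(drop=True)
        if len(a) != len(b):
            return False
        if not (a["ts"].to_numpy() == b["ts"].to_numpy()).all():
            return False
        if not np.allclose(a["bg_mgdl"], b["bg_mgdl"], atol=1e-9):
            return False
        if not (a["exercise"].to_numpy() == b["exercise"].to_numpy()).all():
            return False
        na_a, na_b = a["hr_bpm"].isna(), b["hr_bpm"].isna()
        if not (na_a.to_numpy() == na_b.to_numpy()).all():
            return False
        mask = ~na_a
        return np.allclose(a.loc[mask, "hr_bpm"], b.loc[mask, "hr_bpm"], atol=1e-9)


def make_series_frame(ts, bg_mgdl, hr_bpm=None, exercise=None) -> pd.DataFrame:
    """Assemble a record DataFrame in canonical column order."""
    n = len(ts)
    if hr_bpm is None:
        hr_bpm = np.full(n, np.nan)
    if exercise is None:
        exercise = np.zeros(n, dtype=np.int8)
    return pd.DataFrame(
        {
            "ts": pd.to_datetime(ts),
            "bg_mgdl": np.asarray(bg_mgdl, dtype=float),
            "hr_bpm": np.asarray(hr_bpm, dtype=float),
            "exercise": np.asarray(exercise, dtype=np.int8),
        }
    )
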