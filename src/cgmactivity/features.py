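"""Windowed glycemic-dynamics features (FS1/FS2) over a 15-registration window.

Every registration is classified from the 15-record causal history ending at
it (70 minutes of CGM at 5-minute sampling). From the window's glucose
values bg(0..14) — index 0 oldest, 14 newest — the features are:

* ``w``        body weight (kg), the only window-independent feature;
* ``d``        end-to-end difference, bg(14) - bg(0);
* ``dp(i)``    consecutive differences, bg(i+1) - bg(i), i = 0..13;
* ``dpp(i)``   mini-window differences over the three 5-record sub-windows,
               bg(5i+4) - bg(5i), i = 0..2;
* ``v``        end-to-end rate of change, d / (14 dt);
* ``vp(i)``    consecutive rates, dp(i) / dt;
* ``vpp(i)``   mini-window rates, dpp(i) / (4 dt);
* ``ap(i)``    second-order "acceleration" terms,
               (bg(i+2) - bg(i)) / (2 dt)^2, i = 0..12.

FS1 is the 50-entry glucose-only set; FS2 appends the heart rate at the
newest registration (``hr``) and its last consecutive difference (``hrp``)
for 52 entries. The first 14 rows of any contiguous block cannot fill a
window; they are emitted with all window-derived features zero (weight kept)
so a deployed model can run from the first registration, at the cost of a
75-minute warm-up before estimates are trustworthy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd

from .cleaning import DayBlock
from .records import SubjectSeries

__all__ = [
    "WINDOW",
    "DELTA_T_MIN",
    "FS1_COLUMNS",
    "FS2_COLUMNS",
    "FeatureWindow",
    "extract_features",
    "build_design_matrix",
    "matrix_from_blocks",
]

#: Window length in registrations and nominal sampling step in minutes.
WINDOW = 15
DELTA_T_MIN = 5.0

FS1_COLUMNS: list[str] = (
    ["w", "d"]
    + [f"dp{i}" for i in range(14)]
    + [f"dpp{i}" for i in range(3)]
    + ["v"]
    + [f"vp{i}" for i in range(14)]
    + [f"vpp{i}" for i in range(3)]
    + [f"ap{i}" for i in range(13)]
)
FS2_COLUMNS: list[str] = FS1_COLUMNS + ["hr", "hrp"]

assert len(FS1_COLUMNS) == 50 and len(FS2_COLUMNS) == 52

#: Non-feature columns carried through the design matrix.
META_COLUMNS = ["subject", "ts", "label", "padded"]


@dataclass
class FeatureWindow:
    """One 15-registration window: glucose, timestamps (minutes), optional HR."""

    bg: np.ndarray
    t: np.ndarray  # minutes
    hr: Optional[np.ndarray] = None
    delta_t: float = DELTA_T_MIN

    def validate(self, spacing_tol: float = 1e-6) -> None:
        if len(self.bg) != WINDOW or len(self.t) != WINDOW:
            raise ValueError(
                f"window must have exactly {WINDOW} records, got {len(self.bg)}"
            )
        diffs = np.diff(np.asarray(self.t, dtype=float))
        if not np.all(np.abs(diffs - self.delta_t) <= spacing_tol * max(self.delta_t, 1.0)):
            raise ValueError("window timestamps are not uniformly spaced at delta_t")
        if self.hr is not None and len(self.hr) != WINDOW:
            raise ValueError("hr channel must match window length")


def extract_features(
    win: FeatureWindow, weight: float, include_hr: bool = False
) -> pd.Series:
    """Evaluate the FS1 (or FS2) features on one window.

    Returns a Series indexed by the feature names in the canonical printed
    order. Raises when the window is malformed or HR is requested but absent.
    """
    win.validate()
    if weight <= 0:
        raise ValueError(f"weight must be positive, got {weight}")
    if include_hr and win.hr is None:
        raise ValueError("include_hr=True but the window has no heart-rate channel")

    bg = np.asarray(win.bg, dtype=float)
    dt = float(win.delta_t)

    d = bg[14] - bg[0]
    dp = bg[1:15] - bg[0:14]  # i = 0..13
    dpp = bg[[4, 9, 14]] - bg[[0, 5, 10]]  # i = 0..2
    v = d / (14.0 * dt)
    vp = dp / dt
    vpp = dpp / (4.0 * dt)
    ap = (bg[2:15] - bg[0:13]) / (2.0 * dt) ** 2  # i = 0..12

    values = np.concatenate(([weight, d], dp, dpp, [v], vp, vpp, ap))
    columns = FS1_COLUMNS
    if include_hr:
        hr = np.asarray(win.hr, dtype=float)
        values = np.concatenate((values, [hr[14], hr[14] - hr[13]]))
        columns = FS2_COLUMNS
    return pd.Series(values, index=columns)


def _records_frame(source) -> tuple[pd.DataFrame, float, str]:
    if isinstance(source, SubjectSeries):
        return source.data, source.weight, source.subject_id
    if isinstance(source, DayBlock):
        return source.records, source.weight, source.subject_id
    raise TypeError(f"unsupported input type {type(source).__name__}")


def build_design_matrix(
    source: Union[SubjectSeries, DayBlock],
    weight: Optional[float] = None,
    include_hr: bool = False,
    warmup_policy: str = "zero",
    spacing_tol: float = 1e-6,
) -> pd.DataFrame:
    """One feature row per registration, chronological, causal.

    Row i is computed from records i-14..i; its label is the exercise flag
    of record i (the newest window record). Rows whose window is incomplete
    (the first 14 of the stream) or would span a non-uniform stretch (a
    cleaned-out gap) get all window-derived features set to zero, keep the
    weight, and are flagged ``padded``. ``warmup_policy`` "zero" keeps those
    rows, "drop" removes them.

    Returns a DataFrame with columns ``subject, ts, label, padded`` followed
    by FS1 (or FS2) feature columns.
    """
    if warmup_policy not in ("zero", "drop"):
        raise ValueError(f"unknown warmup_policy {warmup_policy!r}")
    records, src_weight, subject = _records_frame(source)
    if weight is None:
        weight = src_weight
    if weight is None or not np.isfinite(weight) or weight <= 0:
        raise ValueError("a positive body weight is required")

    columns = FS2_COLUMNS if include_hr else FS1_COLUMNS
    n = len(records)
    if n == 0:
        return pd.DataFrame(columns=META_COLUMNS + columns)

    ts = pd.DatetimeIndex(records["ts"])
    bg = records["bg_mgdl"].to_numpy(dtype=float)
    hr = records["hr_bpm"].to_numpy(dtype=float)
    labels = records["exercise"].to_numpy()
    if include_hr and np.isnan(hr).any():
        raise ValueError("include_hr=True but heart rate is missing in the input")

    t_min = (ts.asi8 - ts.asi8[0]) / 60e9

    feats = np.zeros((n, len(columns)))
    feats[:, 0] = weight
    padded = np.ones(n, dtype=bool)

    if n >= WINDOW:
        bw = np.lib.stride_tricks.sliding_window_view(bg, WINDOW)
        tw = np.lib.stride_tricks.sliding_window_view(t_min, WINDOW)
        dtm = np.diff(tw, axis=1)
        uniform = np.all(
            np.abs(dtm - DELTA_T_MIN) <= spacing_tol * DELTA_T_MIN, axis=1
        )
        rows = np.arange(WINDOW - 1, n)

        d = bw[:, 14] - bw[:, 0]
        dp = bw[:, 1:15] - bw[:, 0:14]
        dpp = bw[:, [4, 9, 14]] - bw[:, [0, 5, 10]]
        v = d / (14.0 * DELTA_T_MIN)
        vp = dp / DELTA_T_MIN
        vpp = dpp / (4.0 * DELTA_T_MIN)
        ap = (bw[:, 2:15] - bw[:, 0:13]) / (2.0 * DELTA_T_MIN) ** 2
        block = np.column_stack(
            (np.full(len(d), weight), d, dp, dpp, v, vp, vpp, ap)
        )
        if include_hr:
            hw = np.lib.stride_tricks.sliding_window_view(hr, WINDOW)
            block = np.column_stack((block, hw[:, 14], hw[:, 14] - hw[:, 13]))
        ok = rows[uniform]
        feats[ok] = block[uniform]
        padded[ok] = False

    out = pd.DataFrame(feats, columns=columns)
    out.insert(0, "padded", padded)
    out.insert(0, "label", labels.astype(np.int8))
    out.insert(0, "ts", ts)
    out.insert(0, "subject", subject)
    if warmup_policy == "drop":
        out = out[~out["padded"]].reset_index(drop=True)
    return out


def matrix_from_blocks(
    blocks: Iterable[DayBlock],
    include_hr: bool = False,
    warmup_policy: str = "zero",
) -> pd.DataFrame:
    """Concatenate per-block design matrices.

    Windows never cross block boundaries — blocks are independent days — so
    the warm-up padding recurs at each block start.
    """
    parts = [
        build_design_matrix(b, include_hr=include_hr, warmup_policy=warmup_policy)
        for b in blocks
    ]
    columns = FS2_COLUMNS if include_hr else FS1_COLUMNS
    if not parts:
        return pd.DataFrame(columns=META_COLUMNS + columns)
    return pd.concat(parts, ignore_index=True)
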