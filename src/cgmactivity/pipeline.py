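"""End-to-end plumbing: cohort (simulated or on disk) -> blocks -> matrices.

Thin composition of the other stages so analysis drivers, tests and the
acceptance script share one code path for "run the whole thing".
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .cleaning import (
    CleaningConfig,
    DayBlock,
    extract_day_blocks,
    series_from_d1namo,
    series_from_ohio,
)
from .features import matrix_from_blocks
from .ingest import read_d1namo_subject, read_ohio_subject
from .records import SubjectSeries
from .synthetic import SubjectBundle

__all__ = [
    "blocks_from_series",
    "blocks_from_bundles",
    "design_matrix",
    "ingest_ohio_dir",
    "ingest_d1namo_dir",
    "block_manifest",
]


def blocks_from_series(
    series_list: Iterable[SubjectSeries], cleaning: CleaningConfig
) -> list[DayBlock]:
    blocks: list[DayBlock] = []
    for series in series_list:
        blocks.extend(extract_day_blocks(series, cleaning))
    return blocks


def blocks_from_bundles(
    bundles: Iterable[SubjectBundle], cleaning: CleaningConfig
) -> list[DayBlock]:
    """Day blocks straight from simulator output (no disk round-trip)."""
    return blocks_from_series((b.series for b in bundles), cleaning)


def design_matrix(
    blocks: Iterable[DayBlock],
    include_hr: bool = False,
    warmup_policy: str = "zero",
) -> pd.DataFrame:
    return matrix_from_blocks(blocks, include_hr=include_hr, warmup_policy=warmup_policy)


def ingest_ohio_dir(
    directory, cleaning: CleaningConfig
) -> list[SubjectSeries]:
    """Read every ``*.xml`` subject archive in a directory, cleaned and labeled."""
    directory = Path(directory)
    series = []
    for path in sorted(directory.glob("*.xml")):
        raw = read_ohio_subject(path)
        series.append(series_from_ohio(raw, cleaning))
    return series

def ingest_d1namo_dir(
    directory, cleaning: CleaningConfig, convert_units: bool = True
) -> list[SubjectSeries]:
    """Read every subject subfolder of a D1namo-style tree."""
    directory = Path(directory)
    series = []
    for sub in sorted(p for p in directory.iterdir() if p.is_dir()):
        raw = read_d1namo_subject(sub)
        series.append(series_from_d1namo(raw, cleaning, convert_units=convert_units))
    return series


def block_manifest(blocks: Iterable[DayBlock]) -> pd.DataFrame:
    """Summary table: one row per retained day block."""
    return pd.DataFrame(
        [
            {
                "subject": b.subject_id,
                "date": str(b.date),
                "n_records": len(b),
                "n_positive": b.n_positive,
                "has_hr": b.has_hr,
            }
            for b in blocks
        ]
    )
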