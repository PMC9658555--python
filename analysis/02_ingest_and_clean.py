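#!/usr/bin/env python
"""Ingest the raw cohort archives, apply the cleaning rules, write cleaned CSVs.

Reads the dialect archives produced by 01_simulate_cohorts.py, assembles
labeled 5-minute series (unit-converting the D1namo-style cohort from
mmol/L to mg/dL and deriving its labels from the 0.2 activity threshold),
extracts midnight-to-midnight day blocks, and writes the cleaned
interchange CSVs under scratch/cleaned/ plus the day-block manifest to
results/block_manifest.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from cgmactivity import pipeline
from cgmactivity.cleaning import CleaningConfig
from cgmactivity.ingest import write_cleaned

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--raw", type=Path, default=ROOT / "scratch" / "cohorts")
    parser.add_argument("--out", type=Path, default=ROOT / "scratch" / "cleaned")
    parser.add_argument("--require-hr", action="store_true", default=True)
    args = parser.parse_args()

    cleaning = CleaningConfig(require_hr=args.require_hr)
    manifests = []
    for cohort, loader in (
        ("A", lambda: pipeline.ingest_ohio_dir(args.raw / "ohio", cleaning)),
        ("B", lambda: pipeline.ingest_d1namo_dir(args.raw / "d1namo", cleaning)),
    ):
        series_list = loader()
        out_dir = args.out / cohort
        out_dir.mkdir(parents=True, exist_ok=True)
        for series in series_list:
            write_cleaned(series, out_dir / f"{series.subject_id}.csv")
        blocks = pipeline.blocks_from_series(series_list, cleaning)
        manifest = pipeline.block_manifest(blocks)
        manifest.insert(0, "cohort", cohort)
        manifests.append(manifest)
        kept = manifest["n_records"].sum() if len(manifest) else 0
        total = sum(len(s) for s in series_list)
        print(
            f"cohort {cohort}: {len(series_list)} subjects, {total} registrations, "
            f"{len(manifest)} exercise days kept ({kept} registrations, "
            f"{manifest['n_positive'].sum() if len(manifest) else 0} positive)"
        )

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    pd.concat(manifests, ignore_index=True).to_csv(
        results / "block_manifest.csv", index=False
    )
    print(f"\ncleaned series under {args.out}; manifest in results/block_manifest.csv")


if __name__ == "__main__":
    main()
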