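#!/usr/bin/env python
"""Build the FS1/FS2 design matrices from the cleaned series.

One feature row per registration (15-record causal window, zero-padded
during warm-up), written as CSVs under scratch/features/ with the subject,
timestamp and label columns first. Prints the class balance each cohort
ends up with.
"""

import argparse
from pathlib import Path

from cgmactivity import pipeline
from cgmactivity.cleaning import CleaningConfig
from cgmactivity.ingest import read_cleaned

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--cleaned", type=Path, default=ROOT / "scratch" / "cleaned")
    parser.add_argument("--out", type=Path, default=ROOT / "scratch" / "features")
    args = parser.parse_args()

    cleaning = CleaningConfig(require_hr=True)
    args.out.mkdir(parents=True, exist_ok=True)
    for cohort_dir in sorted(p for p in args.cleaned.iterdir() if p.is_dir()):
        series_list = [read_cleaned(p) for p in sorted(cohort_dir.glob("*.csv"))]
        blocks = pipeline.blocks_from_series(series_list, cleaning)
        for fs, include_hr in (("fs1", False), ("fs2", True)):
            matrix = pipeline.design_matrix(blocks, include_hr=include_hr)
            path = args.out / f"{cohort_dir.name}_{fs}.csv"
            matrix.to_csv(path, index=False)
            print(
                f"cohort {cohort_dir.name} {fs.upper()}: {matrix.shape[0]} rows x "
                f"{matrix.shape[1] - 4} features, "
                f"{matrix['label'].mean():.1%} positive, "
                f"{matrix['padded'].mean():.1%} warm-up rows -> {path.name}"
            )


if __name__ == "__main__":
    main()
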