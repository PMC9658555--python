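#!/usr/bin/env python
"""Multi-seed FS1-vs-FS2 comparison for the headline models.

Repeats the simulate/clean/featurize/train/test pipeline over 10 seeds and
tabulates the test AUC under glucose-only (FS1) and glucose+heart-rate
(FS2) features for logistic regression, AdaBoost and random forest. The
question: is the heart-rate improvement a property of the method, or of
one lucky cohort? Writes results/feature_set_comparison.csv.
"""

import argparse
from pathlib import Path

from cgmactivity.experiments import feature_set_comparison

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--n-seeds", type=int, default=10)
    args = parser.parse_args()

    table = feature_set_comparison(seeds=range(args.seed, args.seed + args.n_seeds))
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    table.round(4).to_csv(results / "feature_set_comparison.csv", index=False)

    summary = table.groupby("model").agg(
        seeds_improved=("gain", lambda g: int((g > 0).sum())),
        median_auc_fs1=("auc_fs1", "median"),
        median_auc_fs2=("auc_fs2", "median"),
        median_gain=("gain", "median"),
    )
    print(summary.round(3).to_string())
    n = args.n_seeds
    print(
        f"\nAcross {n} simulated cohorts the heart-rate features improved every "
        f"model in {int((table['gain'] > 0).sum())}/{len(table)} model-seed runs."
    )


if __name__ == "__main__":
    main()
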