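"""Headline experiments: feature-set comparison and cross-cohort transfer.

Two study-level questions drive the analysis:

1. Does adding the two heart-rate features (FS2) improve exercise detection
   over glucose-only features (FS1)? Answered by running the same cohort,
   split and models under both feature sets, across several simulation
   seeds.
2. Do models trained on one cohort/sensor dialect transfer to another?
   Answered by training on an Ohio-style cohort (mg/dL XML archives,
   self-reported labels) and testing on a D1namo-style cohort (mmol/L CSVs
   converted at ingest, activity-threshold labels), with both cohorts
   round-tripped through their on-disk dialects so the full ingest path is
   exercised.
"""

from __future__ import annotations

import tempfile
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import pipeline
from .cleaning import CleaningConfig
from .evaluation import UseCaseConfig, run_use_case
from .models import get_spec
from .synthetic import SimConfig, generate_cohort, write_d1namo_csv, write_ohio_xml

__all__ = ["feature_set_comparison", "cross_cohort_run"]

#: The three learners the feature-set comparison tracks (the consistently
#: strongest of the suite on both cohorts).
HEADLINE_MODELS = ("LR", "AdaBoost", "RandomForest")


def _usecase_auc(
    frame: pd.DataFrame, feature_set: str, seed: int, model_names: Sequence[str]
) -> dict[str, float]:
    cfg = UseCaseConfig(
        id=1 if feature_set == "FS1" else 3, feature_set=feature_set, seed=seed
    )
    specs = [get_spec(name) for name in model_names]
    table, _ = run_use_case(cfg, frame, specs=specs)
    return dict(zip(table["name"], table["AUC"]))


def feature_set_comparison(
    seeds: Sequence[int],
    model_names: Sequence[str] = HEADLINE_MODELS,
    n_subjects: int = 10,
    days_per_subject: int = 7,
    cleaning: Optional[CleaningConfig] = None,
) -> pd.DataFrame:
    """Per-seed test AUC under FS1 and FS2 for the given models.

    For each seed a fresh cohort is simulated at the default study
    conditions, cleaned, featurized both ways, split 75/25 chronologically
    per subject, and each model is trained and scored under each feature
    set. Returns one row per (seed, model) with ``auc_fs1`` and ``auc_fs2``.
    """
    cleaning = cleaning or CleaningConfig()
    rows = []
    for seed in seeds:
        cfg = SimConfig(
            n_subjects=n_subjects, days_per_subject=days_per_subject, seed=seed
        )
        cohort = generate_cohort(cfg, include_highrate=False)
        blocks = pipeline.blocks_from_bundles(cohort, cleaning)
        fs1 = pipeline.design_matrix(blocks, include_hr=False)
        fs2 = pipeline.design_matrix(blocks, include_hr=True)
        auc1 = _usecase_auc(fs1, "FS1", seed, model_names)
        auc2 = _usecase_auc(fs2, "FS2", seed, model_names)
        for name in model_names:
            rows.append(
                {
                    "seed": seed,
                    "model": name,
                    "auc_fs1": auc1[name],
                    "auc_fs2": auc2[name],
                    "gain": auc2[name] - auc1[name],
                }
            )
    return pd.DataFrame(rows)


def cross_cohort_run(
    seed: int,
    train_subjects: int = 8,
    train_days: int = 5,
    test_subjects: int = 5,
    test_days: int = 3,
    workdir: Optional[Path] = None,
) -> pd.DataFrame:
    """Train on an Ohio-dialect cohort, test on a D1namo-dialect cohort.

    Both cohorts are written to disk in their native dialects and read back
    through ingest, so unit conversion (mmol/L -> mg/dL), heart-rate
    aggregation and both labeling rules are all on the evaluated path.
    Returns the 14-model metrics table.
    """
    cleaning = CleaningConfig(require_hr=True)
    ctx = tempfile.TemporaryDirectory() if workdir is None else None
    root = Path(ctx.name) if ctx else Path(workdir)
    try:
        ohio_dir = root / "ohio"
        d1_dir = root / "d1namo"
        ohio_dir.mkdir(parents=True, exist_ok=True)
        d1_dir.mkdir(parents=True, exist_ok=True)

        train_cfg = SimConfig(
            n_subjects=train_subjects, days_per_subject=train_days, seed=seed
        )
        # offset keeps the two cohorts' random streams disjoint
        test_cfg = SimConfig(
            n_subjects=test_subjects, days_per_subject=test_days, seed=seed + 10_000
        )
        for bundle in generate_cohort(train_cfg, include_highrate=False):
            write_ohio_xml(bundle, ohio_dir / f"{bundle.series.subject_id}.xml")
        for bundle in generate_cohort(test_cfg, include_highrate=True):
            write_d1namo_csv(bundle, d1_dir / bundle.series.subject_id)

        train_series = pipeline.ingest_ohio_dir(ohio_dir, cleaning)
        test_series = pipeline.ingest_d1namo_dir(d1_dir, cleaning)
        train_blocks = pipeline.blocks_from_series(train_series, cleaning)
        test_blocks = pipeline.blocks_from_series(test_series, cleaning)
        train_mat = pipeline.design_matrix(train_blocks, include_hr=True)
        test_mat = pipeline.design_matrix(test_blocks, include_hr=True)

        cfg = UseCaseConfig(
            id=5, feature_set="FS2", train_source="ohio", test_source="d1namo", seed=seed
        )
        table, _ = run_use_case(cfg, train_mat, test_mat)
        return table
    finally:
        if ctx:
            ctx.cleanup()
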