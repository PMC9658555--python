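"""Binary-detection metrics, ROC/AUC and the five use-case protocols.

Metrics are the standard confusion-matrix rates — accuracy, sensitivity
(TPR), specificity (TNR), precision (PPV), false-positive rate and F1 —
evaluated exactly from integer counts; ratios with a zero denominator are
reported as 0 and flagged as degenerate. ROC curves are swept over the
distinct score thresholds and integrated by the trapezoidal rule, which
makes the AUC equal to the pairwise concordance probability.

A "use-case" is one evaluation protocol: cases 1-4 split a single cohort
75/25 into train and test (chronologically per subject by default, to keep
overlapping windows from leaking across the split), case 5 trains on one
cohort and tests on another entirely. Each use-case runs the whole
classifier registry and reports one metrics row per model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import train_test_split as _sk_split

from . import models as models_mod
from .features import FS1_COLUMNS, FS2_COLUMNS
from .models import ClassifierSpec, TrainedModel

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "RocCurve",
    "UseCaseConfig",
    "compute_metrics",
    "roc_and_auc",
    "split_train_test",
    "run_use_case",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsReport:
    acc: float
    tpr: float
    tnr: float
    ppv: float
    fpr: float
    f1: float
    degenerate: tuple[str, ...] = ()
    auc: Optional[float] = None
    model: Optional[str] = None
    use_case: Optional[int] = None


def _ratio(num: int, den: int, name: str, degenerate: list[str]) -> float:
    if den == 0:
        degenerate.append(name)
        return 0.0
    return num / den


def compute_metrics(y_true, y_pred) -> tuple[ConfusionCounts, MetricsReport]:
    """Exact confusion counts and rates for binary labels/predictions."""
    y_true = np.asarray(y_true).astype(int).ravel()
    y_pred = np.asarray(y_pred).astype(int).ravel()
    if len(y_true) != len(y_pred):
        raise ValueError(
            f"length mismatch: {len(y_true)} labels vs {len(y_pred)} predictions"
        )
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    counts = ConfusionCounts(tp, tn, fp, fn)

    degenerate: list[str] = []
    report = MetricsReport(
        acc=_ratio(tp + tn, counts.n, "ACC", degenerate),
        tpr=_ratio(tp, tp + fn, "TPR", degenerate),
        tnr=_ratio(tn, tn + fp, "TNR", degenerate),
        ppv=_ratio(tp, tp + fp, "PPV", degenerate),
        fpr=_ratio(fp, tn + fp, "FPR", degenerate),
        f1=_ratio(2 * tp, 2 * tp + fp + fn, "F1", degenerate),
    )
    return counts, MetricsReport(**{**report.__dict__, "degenerate": tuple(degenerate)})


@dataclass
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def roc_and_auc(y_true, scores) -> RocCurve:
    """ROC over distinct-score thresholds; AUC by the trapezoidal rule."""
    y_true = np.asarray(y_true).astype(int).ravel()
    scores = np.asarray(scores, dtype=float).ravel()
    if len(np.unique(y_true)) < 2:
        raise ValueError("ROC requires both classes in y_true")
    fpr, tpr, thresholds = _sk_roc_curve(y_true, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thresholds, auc=auc)


@dataclass(frozen=True)
class UseCaseConfig:
    """One evaluation protocol.

    ids 1-4 split a single cohort internally; id 5 trains on ``train_source``
    and tests on ``test_source`` (two different cohorts).
    """

    id: int
    feature_set: str  # "FS1" | "FS2"
    train_source: str = "cohort"
    test_source: Optional[str] = None
    split_fraction: float = 0.75
    split_mode: str = "chronological"  # or "random"
    seed: int = 0

    def validate(self) -> None:
        if self.id not in (1, 2, 3, 4, 5):
            raise ValueError("use-case id must be 1..5")
        if self.feature_set not in ("FS1", "FS2"):
            raise ValueError("feature_set must be FS1 or FS2")
        if not 0.0 < self.split_fraction < 1.0:
            raise ValueError("split_fraction must lie in (0, 1)")
        if self.split_mode not in ("chronological", "random"):
            raise ValueError("split_mode must be chronological or random")
        if self.id == 5:
            if self.test_source is None or self.test_source == self.train_source:
                raise ValueError("use-case 5 requires distinct train and test sources")
        elif self.test_source not in (None, self.train_source):
            raise ValueError("use-cases 1-4 use a single source with an internal split")


def split_train_test(
    frame: pd.DataFrame, config: UseCaseConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """75/25 split of a design matrix.

    Chronological mode takes the earliest ceil(0.75 n) rows of each subject
    for training (no window overlap across the boundary within a subject);
    random mode is a seeded stratified row split.
    """
    config.validate()
    if frame["label"].nunique() < 2:
        raise ValueError("cannot split: labels contain a single class")
    if config.split_mode == "random":
        train, test = _sk_split(
            frame,
            train_size=config.split_fraction,
            random_state=config.seed,
            stratify=frame["label"],
        )
    else:
        train_parts, test_parts = [], []
        for _, sub in frame.groupby("subject", sort=True):
            sub = sub.sort_values("ts", kind="stable")
            n_train = math.ceil(config.split_fraction * len(sub))
            train_parts.append(sub.iloc[:n_train])
            test_parts.append(sub.iloc[n_train:])
        train = pd.concat(train_parts, ignore_index=True)
        test = pd.concat(test_parts, ignore_index=True)
    if train["label"].nunique() < 2 or test["label"].nunique() < 2:
        raise ValueError("degenerate split: a partition contains a single class")
    return train.reset_index(drop=True), test.reset_index(drop=True)


def _feature_columns(feature_set: str) -> list[str]:
    return FS2_COLUMNS if feature_set == "FS2" else FS1_COLUMNS


def run_use_case(
    config: UseCaseConfig,
    frame: pd.DataFrame,
    test_frame: Optional[pd.DataFrame] = None,
    specs: Optional[list[ClassifierSpec]] = None,
    standardize: bool = False,
    balance: bool = True,
) -> tuple[pd.DataFrame, dict[str, RocCurve]]:
    """Run one use-case over the classifier registry.

    ``frame`` (and ``test_frame`` for use-case 5) are design matrices as
    produced by the features stage. Returns a table with one row per model
    (columns model, ACC, TPR, TNR, PPV, F1, AUC, in registry order) and the
    per-model ROC curves.
    """
    config.validate()
    columns = _feature_columns(config.feature_set)
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise ValueError(
            f"{config.feature_set} requested but columns missing: {missing[:3]}"
        )

    if config.id == 5:
        if test_frame is None:
            raise ValueError("use-case 5 requires a separate test frame")
        train, test = frame, test_frame
    else:
        if test_frame is not None:
            raise ValueError("use-cases 1-4 split a single frame internally")
        train, test = split_train_test(frame, config)

    X_train, y_train = train[columns], train["label"].to_numpy()
    X_test, y_test = test[columns], test["label"].to_numpy()

    if specs is None:
        specs = models_mod.registry(seed=config.seed)
    rows = []
    curves: dict[str, RocCurve] = {}
    for spec in specs:
        model: TrainedModel = models_mod.fit(
            spec, X_train, y_train,
            standardize=standardize, balance=balance, seed=config.seed,
        )
        y_pred = models_mod.predict(model, X_test)
        scores = models_mod.score(model, X_test)
        _, rep = compute_metrics(y_test, y_pred)
        roc = roc_and_auc(y_test, scores)
        curves[spec.name] = roc
        rows.append(
            {
                "model": spec.label,
                "name": spec.name,
                "ACC": rep.acc,
                "TPR": rep.tpr,
                "TNR": rep.tnr,
                "PPV": rep.ppv,
                "F1": rep.f1,
                "AUC": roc.auc,
            }
        )
    table = pd.DataFrame(rows)
    table.attrs["use_case"] = config.id
    table.attrs["feature_set"] = config.feature_set
    table.attrs["split_mode"] = config.split_mode
    table.attrs["seed"] = config.seed
    table.attrs["n_train"] = len(train)
    table.attrs["n_test"] = len(test)
    return table, curves
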