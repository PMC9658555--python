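"""The 14-classifier suite behind a uniform fit / score / predict contract.

The learners themselves are scikit-learn estimators; this module pins the
configurations used throughout the analysis (a logistic regression with an
L2 penalty and a 1000-iteration cap, a 50-tree AdaBoost, a depth-unlimited
decision tree, Gaussian naive Bayes, a k-d-tree KNN with k=5, five SVM
kernel variants capped at 1000 iterations, a 100-tree random forest, and
three four-hidden-layer MLPs of sizes 100/150/100/50 differing only in
activation) and a deterministic training protocol.

Feature scaling is off by default; optional seeded undersampling of the
majority class (default on) balances training data, and both choices are
recorded in the trained model's metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "ClassifierSpec",
    "TrainedModel",
    "registry",
    "get_spec",
    "build_estimator",
    "fit",
    "score",
    "predict",
]

_MLP_LAYERS = (100, 150, 100, 50)


@dataclass(frozen=True)
class ClassifierSpec:
    name: str
    label: str  # display name used in report tables
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def with_seed(self, seed: int) -> "ClassifierSpec":
        return ClassifierSpec(self.name, self.label, dict(self.hyperparameters), seed)


def registry(seed: int = 0) -> list[ClassifierSpec]:
    """The 14 classifier configurations, in stable report-table order."""
    specs = [
        ClassifierSpec("LR", "Logistic Regression",
                       {"max_iter": 1000, "penalty": "l2"}, seed),
        ClassifierSpec("AdaBoost", "AdaBoost", {"n_estimators": 50}, seed),
        ClassifierSpec("KNN", "KNN",
                       {"n_neighbors": 5, "algorithm": "kd_tree"}, seed),
        ClassifierSpec("DecisionTree", "Decision Tree", {"max_depth": None}, seed),
        ClassifierSpec("GaussianNB", "Gaussian", {}, seed),
        ClassifierSpec("SVM-rbf", "SVM kernel = rbf",
                       {"kernel": "rbf", "max_iter": 1000}, seed),
        ClassifierSpec("SVM-sigmoid", "SVM kernel = sigmoid",
                       {"kernel": "sigmoid", "max_iter": 1000}, seed),
        ClassifierSpec("SVM-poly3", "SVM kernel = poly, deg = 3",
                       {"kernel": "poly", "degree": 3, "max_iter": 1000}, seed),
        ClassifierSpec("SVM-poly5", "SVM kernel = poly, deg = 5",
                       {"kernel": "poly", "degree": 5, "max_iter": 1000}, seed),
        ClassifierSpec("SVM-poly10", "SVM kernel = poly, deg = 10",
                       {"kernel": "poly", "degree": 10, "max_iter": 1000}, seed),
        ClassifierSpec("RandomForest", "Random Forest", {"n_estimators": 100}, seed),
        ClassifierSpec("MLP-logistic", "MLP activation = logistic",
                       {"hidden_layer_sizes": _MLP_LAYERS, "activation": "logistic",
                        "max_iter": 1000}, seed),
        ClassifierSpec("MLP-relu", "MLP activation = ReLU",
                       {"hidden_layer_sizes": _MLP_LAYERS, "activation": "relu",
                        "max_iter": 1000}, seed),
        ClassifierSpec("MLP-tanh", "MLP activation = tanh",
                       {"hidden_layer_sizes": _MLP_LAYERS, "activation": "tanh",
                        "max_iter": 1000}, seed),
    ]
    assert len(specs) == 14
    return specs


def get_spec(name: str, seed: int = 0) -> ClassifierSpec:
    for spec in registry(seed):
        if spec.name == name:
            return spec
    raise KeyError(f"unknown classifier {name!r}")


def build_estimator(spec: ClassifierSpec):
    hp = dict(spec.hyperparameters)
    if spec.name == "LR":
        return LogisticRegression(random_state=spec.seed, **hp)
    if spec.name == "AdaBoost":
        return AdaBoostClassifier(random_state=spec.seed, **hp)
    if spec.name == "KNN":
        return KNeighborsClassifier(**hp)
    if spec.name == "DecisionTree":
        return DecisionTreeClassifier(random_state=spec.seed, **hp)
    if spec.name == "GaussianNB":
        return GaussianNB(**hp)
    if spec.name.startswith("SVM"):
        return SVC(random_state=spec.seed, **hp)
    if spec.name == "RandomForest":
        return RandomForestClassifier(random_state=spec.seed, **hp)
    if spec.name.startswith("MLP"):
        return MLPClassifier(random_state=spec.seed, **hp)
    raise KeyError(f"unknown classifier {spec.name!r}")


@dataclass
class TrainedModel:
    spec: ClassifierSpec
    estimator: object
    scaler: Optional[StandardScaler]
    metadata: dict


def _as_array(X) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float)
    return np.asarray(X, dtype=float)


def _undersample(X: np.ndarray, y: np.ndarray, seed: int):
    """Seeded random undersampling of the majority class to a 1:1 balance."""
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(y, return_counts=True)
    n_min = counts.min()
    keep = []
    for cls in classes:
        idx = np.flatnonzero(y == cls)
        if len(idx) > n_min:
            idx = rng.choice(idx, size=n_min, replace=False)
        keep.append(idx)
    keep = np.sort(np.concatenate(keep))
    return X[keep], y[keep]


def fit(
    spec: ClassifierSpec,
    X,
    y,
    standardize: bool = False,
    balance: bool = True,
    seed: Optional[int] = None,
) -> TrainedModel:
    """Train one configuration; deterministic given the seed.

    ``balance`` undersamples the majority class (training rows only) before
    fitting; ``standardize`` fits a scaler on the (balanced) training rows.
    Both are recorded in metadata together with the resulting class counts.
    """
    X = _as_array(X)
    y = np.asarray(y).astype(int).ravel()
    if X.shape[0] != len(y):
        raise ValueError(f"X has {X.shape[0]} rows but y has {len(y)} labels")
    bad = ~np.isfinite(X).all(axis=1)
    if bad.any():
        raise ValueError(f"non-finite feature values at row {int(np.flatnonzero(bad)[0])}")
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")

    if seed is not None:
        spec = spec.with_seed(seed)

    n_before = np.bincount(y, minlength=2)
    if balance:
        X, y = _undersample(X, y, spec.seed)
    n_after = np.bincount(y, minlength=2)

    scaler = None
    if standardize:
        scaler = StandardScaler().fit(X)
        X = scaler.transform(X)

    estimator = build_estimator(spec)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # iteration-capped learners may not converge
        estimator.fit(X, y)

    metadata = {
        "n_rows": int(X.shape[0]),
        "n_features": int(X.shape[1]),
        "class_counts_before": n_before.tolist(),
        "class_counts_after": n_after.tolist(),
        "balanced": bool(balance),
        "standardized": bool(standardize),
        "seed": int(spec.seed),
    }
    return TrainedModel(spec=spec, estimator=estimator, scaler=scaler, metadata=metadata)


def _check_width(model: TrainedModel, X: np.ndarray) -> None:
    if X.shape[1] != model.metadata["n_features"]:
        raise ValueError(
            f"feature width {X.shape[1]} does not match training width "
            f"{model.metadata['n_features']}"
        )


def score(model: TrainedModel, X) -> np.ndarray:
    """Continuous per-row score, higher = more likely exercise.

    Probability of the positive class when the learner exposes one, the
    decision-function margin otherwise (SVMs); either is a valid total
    ordering for ROC analysis.
    """
    X = _as_array(X)
    _check_width(model, X)
    if model.scaler is not None:
        X = model.scaler.transform(X)
    est = model.estimator
    if hasattr(est, "predict_proba"):
        return est.predict_proba(X)[:, 1]
    return est.decision_function(X)


def predict(model: TrainedModel, X) -> np.ndarray:
    """Hard 0/1 prediction at the learner's default operating point."""
    X = _as_array(X)
    _check_width(model, X)
    if model.scaler is not None:
        X = model.scaler.transform(X)
    return np.asarray(model.estimator.predict(X)).astype(int)
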