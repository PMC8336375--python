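"""Classic-classifier benchmark over the acoustic feature sets.

Four classifiers (random forest, k-nearest neighbours, RBF support
vector machine, linear discriminant analysis) are evaluated over any
selection of feature sets under one shared cross-validation protocol.
Each fold fits a fresh pipeline of zero-variance-column dropping,
z-scoring and the classifier, so no statistic leaks from test folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import VarianceThreshold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .crossval import CVProtocol, CVReport, cross_validate

CLASSIFIER_NAMES = ("rf", "knn", "svm", "lda")

DEFAULT_HYPERPARAMETERS: dict[str, dict] = {
    "rf": {"n_estimators": 500},
    "knn": {"n_neighbors": 5, "metric": "euclidean"},
    "svm": {"C": 1.0, "gamma": "auto"},   # gamma = 1 / n_features
    "lda": {},
}


@dataclass
class BaselineSpec:
    classifier: str
    feature_set: str
    cv: CVProtocol = field(default_factory=CVProtocol)
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.classifier not in CLASSIFIER_NAMES:
            raise ValueError(f"classifier must be one of {CLASSIFIER_NAMES}")


def make_pipeline(classifier: str, seed: int = 0,
                  hyperparameters: dict | None = None) -> Pipeline:
    """drop zero-variance columns -> z-score -> classifier."""
    hp = dict(DEFAULT_HYPERPARAMETERS[classifier])
    hp.update(hyperparameters or {})
    if classifier == "rf":
        clf = RandomForestClassifier(random_state=seed, **hp)
    elif classifier == "knn":
        clf = KNeighborsClassifier(**hp)
    elif classifier == "svm":
        clf = SVC(probability=True, random_state=seed, **hp)
    elif classifier == "lda":
        clf = LinearDiscriminantAnalysis(**hp)
    else:
        raise ValueError(f"classifier must be one of {CLASSIFIER_NAMES}")
    return Pipeline([("drop_constant", VarianceThreshold(0.0)),
                     ("scale", StandardScaler()),
                     ("clf", clf)])


def _baseline_fit_fn(spec: BaselineSpec):
    def fit(X_train: np.ndarray, y_train: np.ndarray, seed: int):
        n_dropped = int((X_train.var(axis=0) == 0).sum())
        if n_dropped:
            warnings.warn(f"dropping {n_dropped} zero-variance feature column(s)")
        pipe = make_pipeline(spec.classifier, seed, spec.hyperparameters)
        pipe.fit(X_train, y_train)
        pos = list(pipe.classes_).index(1)
        return lambda X: pipe.predict_proba(X)[:, pos]
    return fit


def run_baseline(X: np.ndarray, y: np.ndarray, spec: BaselineSpec,
                 groups: np.ndarray | None = None) -> CVReport:
    """Cross-validate one classifier on one feature matrix."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if np.unique(y).size < 2:
        raise ValueError("baseline evaluation needs both classes present")
    return cross_validate(X, y, _baseline_fit_fn(spec), spec.cv, groups=groups)


def benchmark_grid(features: dict[str, np.ndarray], y: np.ndarray,
                   classifiers: tuple[str, ...] = CLASSIFIER_NAMES,
                   cv: CVProtocol = CVProtocol(),
                   groups: np.ndarray | None = None) -> pd.DataFrame:
    """Classifier x feature-set grid of mean metrics (benchmark table shape).

    ``features`` maps feature-set name to its (n_clips, dim) matrix; an
    empty mapping yields an empty table.
    """
    rows = []
    for clf in classifiers:
        for set_name, X in features.items():
            spec = BaselineSpec(classifier=clf, feature_set=set_name, cv=cv)
            report = run_baseline(X, y, spec, groups=groups)
            summ = report.summary()
            rows.append({"classifier": clf, "feature_set": set_name,
                         **{m: summ[m]["mean"] for m in
                            ("accuracy", "precision", "recall", "f1")}})
    columns = ["classifier", "feature_set", "accuracy", "precision", "recall", "f1"]
    return pd.DataFrame(rows, columns=columns)
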