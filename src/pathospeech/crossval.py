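"""Repeated stratified k-fold cross-validation with a seven-metric report.

Protocol: 30 independent iterations of stratified 10-fold CV; each
iteration reseeds the fold partition (base seed + iteration), pools the
out-of-fold predictions and computes the seven metrics once.  The
report carries per-iteration values and normal-approximation 95%
confidence intervals (mean +/- 1.96 * sd / sqrt(n_iterations)).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedGroupKFold, StratifiedKFold

from .metrics import METRIC_NAMES, compute_metrics


class CVConfigError(ValueError):
    pass


@dataclass
class CVProtocol:
    n_folds: int = 10
    n_iterations: int = 30
    stratified: bool = True
    subject_disjoint: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_folds < 2:
            raise CVConfigError("n_folds must be >= 2")
        if self.n_iterations < 1:
            raise CVConfigError("n_iterations must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)

    def splitter(self, iteration: int):
        state = self.seed + iteration
        if self.subject_disjoint:
            return StratifiedGroupKFold(n_splits=self.n_folds, shuffle=True,
                                        random_state=state)
        if self.stratified:
            return StratifiedKFold(n_splits=self.n_folds, shuffle=True,
                                   random_state=state)
        return KFold(n_splits=self.n_folds, shuffle=True, random_state=state)


@dataclass
class CVReport:
    per_iteration: pd.DataFrame     # one row per iteration, columns = metrics
    protocol: CVProtocol

    def summary(self) -> dict[str, dict[str, float]]:
        out = {}
        n = len(self.per_iteration)
        for name in METRIC_NAMES:
            vals = self.per_iteration[name].to_numpy(dtype=float)
            if np.ptp(vals) == 0.0:
                # constant iterations: exactly zero-width, no summation fuzz
                mean, half = float(vals[0]), 0.0
            else:
                mean = float(np.mean(vals))
                half = 0.0 if n < 2 else float(1.96 * np.std(vals, ddof=1) / np.sqrt(n))
            out[name] = {"mean": mean, "ci_lo": mean - half, "ci_hi": mean + half}
        return out

    def to_csv(self, path: str | Path) -> None:
        self.per_iteration.to_csv(path, index=False)

    def summary_json(self) -> str:
        return json.dumps({"protocol": self.protocol.to_dict(),
                           "metrics": self.summary()}, indent=2)


# fit(X_train, y_train, seed) -> predict; predict(X) -> positive-class scores
FitFn = Callable[[np.ndarray, np.ndarray, int], Callable[[np.ndarray], np.ndarray]]


def iteration_scores(X: np.ndarray, y: np.ndarray, fit_fn: FitFn, cv: CVProtocol,
                     iteration: int, groups: np.ndarray | None = None) -> np.ndarray:
    """Pooled out-of-fold positive-class scores for one CV iteration."""
    scores = np.full(y.shape[0], np.nan)
    splitter = cv.splitter(iteration)
    split_args = (X, y, groups) if cv.subject_disjoint else (X, y)
    for fold, (tr, te) in enumerate(splitter.split(*split_args)):
        predict = fit_fn(X[tr], y[tr], cv.seed + 1000 * iteration + fold)
        scores[te] = predict(X[te])
    if np.isnan(scores).any():
        raise RuntimeError("fold test sets failed to partition the dataset")
    return scores


def cross_validate(X: np.ndarray, y: np.ndarray, fit_fn: FitFn, cv: CVProtocol,
                   groups: np.ndarray | None = None) -> CVReport:
    """Repeated stratified k-fold CV; metrics on pooled out-of-fold scores.

    ``fit_fn(X_train, y_train, seed)`` returns a score function mapping
    samples to positive-class probabilities.  ``groups`` (subject ids)
    are required when the protocol demands subject-disjoint folds.
    """
    X = np.asarray(X)
    y = np.asarray(y).astype(int)
    if y.shape[0] != X.shape[0]:
        raise ValueError("X and y disagree in length")
    if y.shape[0] < cv.n_folds:
        raise ValueError("dataset smaller than the number of folds")
    if cv.subject_disjoint and groups is None:
        raise CVConfigError("subject_disjoint protocol requires subject ids (groups)")
    if groups is not None:
        groups = np.asarray(groups)

    rows = []
    for it in range(cv.n_iterations):
        scores = iteration_scores(X, y, fit_fn, cv, it, groups)
        rec = compute_metrics(scores, y)
        rows.append({"iteration": it, **rec.values()})
    return CVReport(per_iteration=pd.DataFrame(rows), protocol=cv)
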