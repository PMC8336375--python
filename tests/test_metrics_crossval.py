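"""Metric arithmetic, AUC rank statistics and the CV protocol mechanics."""

from __future__ import annotations

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from pathospeech.crossval import (CVConfigError, CVProtocol, cross_validate,
                                  iteration_scores)
from pathospeech.metrics import (ConfusionCounts, auc_score, compute_metrics,
                                 metrics_from_counts)

try:
    from hypothesis import given, settings, strategies as st
    HAVE_HYPOTHESIS = True
except ImportError:  # pragma: no cover
    HAVE_HYPOTHESIS = False


def test_confusion_counts_reject_negative():
    with pytest.raises(ValueError):
        ConfusionCounts(tp=-1, fn=0, fp=0, tn=0)


def test_perfect_and_inverted_predictions():
    scores = np.array([0.9, 0.8, 0.1, 0.2])
    labels = np.array([1, 1, 0, 0])
    rec = compute_metrics(scores, labels)
    assert rec.accuracy == rec.f1 == rec.auc == 1.0
    rec_inv = compute_metrics(1 - scores, labels)
    assert rec_inv.accuracy == 0.0
    assert rec_inv.auc == 0.0


def test_zero_denominators_warn_and_report_zero():
    with pytest.warns(UserWarning, match="precision"):
        rec = metrics_from_counts(ConfusionCounts(tp=0, fn=5, fp=0, tn=5))
    assert rec.precision == 0.0
    assert rec.recall == 0.0
    assert rec.f1 == 0.0


def test_auc_matches_sklearn_and_ties_get_half_credit():
    rng = np.random.default_rng(0)
    scores = rng.random(200)
    labels = rng.integers(0, 2, 200)
    assert auc_score(scores, labels) == pytest.approx(
        roc_auc_score(labels, scores), abs=1e-12)
    # all-tied scores: exactly chance
    assert auc_score(np.full(10, 0.5), np.array([0, 1] * 5)) == 0.5


def test_one_class_auc_is_nan_with_warning():
    with pytest.warns(UserWarning, match="one-class"):
        assert np.isnan(auc_score(np.array([0.1, 0.9]), np.array([1, 1])))


def test_score_validation():
    with pytest.raises(ValueError, match="\\[0, 1\\]"):
        compute_metrics(np.array([1.2]), np.array([1]))
    with pytest.raises(ValueError, match="same shape"):
        compute_metrics(np.array([0.5, 0.5]), np.array([1]))
    with pytest.raises(ValueError, match="empty"):
        compute_metrics(np.array([]), np.array([]))


if HAVE_HYPOTHESIS:
    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(tp=st.integers(0, 50), fn=st.integers(0, 50),
           fp=st.integers(0, 50), tn=st.integers(1, 50))
    def test_metric_identities_hold_for_any_counts(tp, fn, fp, tn):
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rec = metrics_from_counts(ConfusionCounts(tp, fn, fp, tn))
        for v in (rec.accuracy, rec.precision, rec.recall, rec.f1,
                  rec.specificity):
            assert 0.0 <= v <= 1.0
        assert rec.sensitivity == rec.recall
        assert rec.accuracy == pytest.approx((tp + tn) / (tp + fn + fp + tn))


def _nearest_centroid_fit(X_train, y_train, seed):
    mu0 = X_train[y_train == 0].mean(axis=0)
    mu1 = X_train[y_train == 1].mean(axis=0)

    def predict(X):
        d0 = np.linalg.norm(X - mu0, axis=1)
        d1 = np.linalg.norm(X - mu1, axis=1)
        return d0 / (d0 + d1 + 1e-12)
    return predict


def _separable_data(n=60, seed=0):
    rng = np.random.default_rng(seed)
    y = np.arange(n) % 2
    X = rng.standard_normal((n, 3)) + 6.0 * y[:, None]
    return X, y


def test_out_of_fold_scores_partition_the_dataset():
    X, y = _separable_data()
    cv = CVProtocol(n_folds=5, n_iterations=1)
    scores = iteration_scores(X, y, _nearest_centroid_fit, cv, iteration=0)
    assert scores.shape == (60,)
    assert np.isfinite(scores).all()


def test_cross_validation_report_shape_and_quality():
    X, y = _separable_data()
    cv = CVProtocol(n_folds=5, n_iterations=3, seed=1)
    report = cross_validate(X, y, _nearest_centroid_fit, cv)
    assert len(report.per_iteration) == 3
    summ = report.summary()
    assert summ["accuracy"]["mean"] == 1.0     # cleanly separable
    assert summ["accuracy"]["ci_lo"] <= summ["accuracy"]["mean"]
    assert "protocol" in report.summary_json()


def test_iterations_redraw_folds():
    X, y = _separable_data()
    cv = CVProtocol(n_folds=5, n_iterations=2, seed=0)
    folds0 = [te for _, te in cv.splitter(0).split(X, y)]
    folds1 = [te for _, te in cv.splitter(1).split(X, y)]
    assert not all(np.array_equal(a, b) for a, b in zip(folds0, folds1))


def test_subject_disjoint_protocol_separates_groups():
    X, y = _separable_data(n=80)
    groups = np.repeat(np.arange(20), 4)
    cv = CVProtocol(n_folds=4, n_iterations=1, subject_disjoint=True)
    for tr, te in cv.splitter(0).split(X, y, groups):
        assert not set(groups[tr]) & set(groups[te])
    with pytest.raises(CVConfigError, match="groups"):
        cross_validate(X, y, _nearest_centroid_fit, cv)


def test_protocol_validation():
    with pytest.raises(CVConfigError):
        CVProtocol(n_folds=1)
    with pytest.raises(CVConfigError):
        CVProtocol(n_iterations=0)
    with pytest.raises(ValueError, match="smaller"):
        cross_validate(np.zeros((3, 2)), np.array([0, 1, 0]),
                       _nearest_centroid_fit, CVProtocol(n_folds=10))
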