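"""ROC construction, AUC, operating-point rule, confusion metrics,
stratified CV and tuning — each against brute-force oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from readmitnet.baselines import LogisticBaseline
from readmitnet.evaluation import (auc, confusion_metrics, kfold_cv,
                                   optimal_threshold, roc_curve, tune_hyperparams)
from readmitnet.synthetic import CohortConfig, sample_risk_dataset


def _brute_force_points(scores, labels):
    """Oracle: evaluate (fpr, tpr, tp, pp) at +inf and every distinct score."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pts = set()
    for theta in [np.inf, *np.unique(scores)]:
        pred = scores >= theta
        tp = int((pred & (labels == 1)).sum())
        fp = int((pred & (labels == 0)).sum())
        pts.add((tp, fp, int(pred.sum())))
    return pts


def _concordance_auc(scores, labels):
    """Oracle: pairwise concordance with half credit for ties."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


def test_roc_points_match_exhaustive_enumeration():
    scores = [0.1, 0.4, 0.35, 0.8]
    labels = [0, 0, 1, 1]
    c = roc_curve(scores, labels)
    got = set(zip(c.tp.tolist(), c.fp.tolist(), c.predicted_positive.tolist()))
    assert got == _brute_force_points(scores, labels)
    assert c.thresholds[0] == np.inf and c.fpr[0] == c.tpr[0] == 0
    assert c.fpr[-1] == c.tpr[-1] == 1.0
    assert (np.diff(c.fpr) >= 0).all() and (np.diff(c.tpr) >= 0).all()


def test_roc_exhaustive_small_instances():
    """Every label pattern with n <= 8 (both classes present), random tied
    scores: points, monotonicity and AUC all match brute force."""
    rng = np.random.default_rng(0)
    for n in (2, 4, 6, 8):
        for labels in itertools.product([0, 1], repeat=n):
            if len(set(labels)) < 2:
                continue
            scores = rng.choice([0.1, 0.3, 0.5, 0.9], size=n)
            c = roc_curve(scores, labels)
            got = set(zip(c.tp.tolist(), c.fp.tolist(),
                          c.predicted_positive.tolist()))
            assert got == _brute_force_points(scores, labels)
            assert auc(c) == pytest.approx(_concordance_auc(scores, labels), abs=1e-12)


def test_auc_random_instances_match_concordance(rng):
    for _ in range(100):
        n = int(rng.integers(4, 30))
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        scores = np.round(rng.random(n), 2)  # rounding forces ties
        c = roc_curve(scores, labels)
        assert auc(c) == pytest.approx(_concordance_auc(scores, labels), abs=1e-12)


def test_auc_worked_example_and_symmetries():
    c = roc_curve([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
    assert auc(c) == pytest.approx(0.75)
    perfect = roc_curve([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
    assert auc(perfect) == 1.0
    # label swap: AUC(s, y) = 1 - AUC(s, 1-y)
    sw = roc_curve([0.1, 0.4, 0.35, 0.8], [1, 1, 0, 0])
    assert auc(sw) == pytest.approx(0.25)


def test_all_equal_scores_is_the_diagonal():
    c = roc_curve([0.5] * 6, [0, 1, 0, 1, 0, 1])
    assert len(c) == 2
    assert auc(c) == pytest.approx(0.5)


def test_roc_input_validation():
    with pytest.raises(ValueError):
        roc_curve([0.1, np.nan], [0, 1])
    with pytest.raises(ValueError):
        roc_curve([0.1, 0.2], [1, 1])


def test_optimal_threshold_worked_example():
    """Points {(0,0),(0.2,0.9),(1,1)}: the middle point wins with distance
    sqrt(0.04 + 0.01) ~= 0.2236."""
    scores = [0.9] * 11 + [0.5] * 9
    # at theta=0.9: tp=9 of 10, fp=2 of 10 -> the (0.2, 0.9) point
    labels = [1] * 9 + [0] * 2 + [1] + [0] * 8
    c = roc_curve(scores, labels)
    assert np.hypot(c.fpr, 1 - c.tpr).min() == pytest.approx(np.sqrt(0.05))
    assert optimal_threshold(c) == 0.9


def test_optimal_threshold_equals_enumeration(rng):
    for _ in range(100):
        n = int(rng.integers(4, 25))
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        scores = np.round(rng.random(n), 1)
        c = roc_curve(scores, labels)
        theta = optimal_threshold(c)
        d = np.hypot(c.fpr, 1 - c.tpr)
        i = int(np.flatnonzero(c.thresholds == theta)[0])
        assert d[i] == pytest.approx(d.min(), abs=1e-12)


def test_perfect_curve_contains_ideal_corner():
    c = roc_curve([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
    theta = optimal_threshold(c)
    i = int(np.flatnonzero(c.thresholds == theta)[0])
    assert (c.fpr[i], c.tpr[i]) == (0.0, 1.0)


def test_confusion_metrics_hand_example():
    """TP=3, FP=1, FN=1, TN=5 -> precision .75, recall .75, f1 .75, acc .8."""
    scores = [0.9, 0.9, 0.9, 0.9, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1]
    labels = [1, 1, 1, 0, 1, 0, 0, 0, 0, 0]
    m = confusion_metrics(scores, labels, 0.5)
    assert (m["tp"], m["fp"], m["fn"], m["tn"]) == (3, 1, 1, 5)
    assert m["precision"] == m["recall"] == m["f1"] == 0.75
    assert m["accuracy"] == 0.8


def test_confusion_metrics_edge_cases():
    m = confusion_metrics([1.0, 1.0], [1, 0], 0.5)
    assert m["accuracy"] == 0.5 and m["recall"] == 1.0
    with pytest.warns(UserWarning, match="precision"):
        m = confusion_metrics([0.1, 0.2], [1, 0], 0.9)
    assert m["precision"] == 0.0 and m["recall"] == 0.0


class _ConstantModel:
    def fit(self, X, y):
        return self

    def predict_proba(self, X):
        return np.column_stack([np.full(len(X), 0.5)] * 2)


def test_constant_score_model_cv_auc_half(rng):
    X = rng.random((120, 3))
    y = (rng.random(120) < 0.4).astype(int)
    report = kfold_cv(_ConstantModel, X, y, k=5, seed=0)
    assert report.mean["auc"] == pytest.approx(0.5)


def test_cv_bookkeeping_and_fold_partition(rng):
    X = rng.random((150, 4))
    y = (rng.random(150) < 0.3).astype(int)
    report = kfold_cv(lambda: LogisticBaseline(), X, y, k=5, seed=1)
    # mean/sd recomputed from the per-fold table must match
    assert report.mean["auc"] == pytest.approx(report.per_fold["auc"].mean())
    assert report.sd["f1"] == pytest.approx(report.per_fold["f1"].std(ddof=1))
    # fold curves: every row appears in exactly one test fold
    assert sum(c.n_pos + c.n_neg for c in report.fold_curves) == 150
    assert sum(c.n_pos for c in report.fold_curves) == y.sum()


def test_cv_recovers_known_generator_auc():
    """Logistic CV AUC within 0.03 of the generator's true-risk concordance
    (independent oracle: sklearn's AUC of the true risk on a large draw)."""
    from sklearn.metrics import roc_auc_score
    cfg = CohortConfig(n_binary_codes=6, n_continuous_vars=2, binary_code_prob=0.5,
                       linear_weights=(1.5, -1.0, 0.8, 0.5, 0, 0, 2.0, -2.0), seed=3)
    Xb, yb, pb = sample_risk_dataset(cfg, 60_000, seed=99)
    bayes = roc_auc_score(yb, pb)
    X, y, _ = sample_risk_dataset(cfg, 6000, seed=4)
    report = kfold_cv(lambda: LogisticBaseline(), X, y, k=10, seed=5)
    assert report.mean["auc"] == pytest.approx(bayes, abs=0.03)


class _SpyPreprocessor:
    """Records exactly which rows were used for fitting."""

    fitted_rows: list = []

    def __init__(self):
        self.seen = None

    def fit(self, X, y):
        self.seen = {tuple(row) for row in np.asarray(X)}
        _SpyPreprocessor.fitted_rows.append(self.seen)
        return self

    def transform(self, X):
        return np.asarray(X)


def test_no_leakage_preprocessor_fit_on_training_folds_only(rng):
    X = np.arange(200, dtype=float).reshape(100, 2)  # all rows distinct
    y = np.array([0, 1] * 50)
    _SpyPreprocessor.fitted_rows = []
    report = kfold_cv(lambda: LogisticBaseline(), X, y, k=5, seed=2,
                      preprocess_factory=_SpyPreprocessor)
    assert len(_SpyPreprocessor.fitted_rows) == 5
    # reconstruct the folds: rows NOT fitted in fold i are its test rows
    all_rows = {tuple(r) for r in X}
    test_folds = [all_rows - seen for seen in _SpyPreprocessor.fitted_rows]
    assert sum(len(f) for f in test_folds) == 100
    assert set().union(*test_folds) == all_rows  # a partition
    for seen, test in zip(_SpyPreprocessor.fitted_rows, test_folds):
        assert not (seen & test)


def test_kfold_validation_errors(rng):
    X, y = rng.random((10, 2)), np.array([0, 1] * 5)
    with pytest.raises(ValueError):
        kfold_cv(_ConstantModel, X, y, k=1)
    with pytest.raises(ValueError):
        kfold_cv(_ConstantModel, X, y, k=5, theta_on="elsewhere")


# -- hyper-parameter search ----------------------------------------------------

def test_tune_single_point_space(rng):
    X = rng.random((60, 3))
    y = np.array([0, 1] * 30)
    best, trials = tune_hyperparams({"lam": ("choice", [0.5])},
                                    lambda lam: LogisticBaseline(lam=lam),
                                    X, y, n_iter=1, subsample=1.0, k=3, seed=0)
    assert best == {"lam": 0.5}
    assert len(trials) == 1


def test_tune_trial_log_length(rng):
    X = rng.random((80, 3))
    y = np.array([0, 1] * 40)
    _, trials = tune_hyperparams({"lam": ("loguniform", -15, 0)},
                                 lambda lam: LogisticBaseline(lam=lam),
                                 X, y, n_iter=7, subsample=0.5, k=3, seed=1)
    assert len(trials) == 7
    assert (np.exp(-15) <= trials["lam"]).all() and (trials["lam"] <= 1).all()


def test_tune_recovers_dominant_regularization():
    """5-point grid where tiny lam dominates by construction (strong linear
    signal destroyed by heavy shrinkage): the best config recovers it."""
    cfg = CohortConfig(n_binary_codes=4, n_continuous_vars=0, binary_code_prob=0.5,
                       linear_weights=(3.0, -3.0, 2.0, -2.0), seed=6)
    X, y, _ = sample_risk_dataset(cfg, 2000)
    grid = [1e-5, 1e-3, 1e-1, 10.0, 1000.0]
    best, trials = tune_hyperparams({"lam": ("choice", grid)},
                                    lambda lam: LogisticBaseline(lam=lam),
                                    X, y, n_iter=15, subsample=0.5, k=4, seed=2)
    assert best["lam"] <= 1e-1
    # oracle: exhaustive evaluation ranks heavy shrinkage strictly worse
    by_lam = trials.groupby("lam")["auc"].mean()
    assert by_lam.loc[1000.0] < by_lam.loc[best["lam"]]


def test_tune_empty_space_errors(rng):
    with pytest.raises(ValueError):
        tune_hyperparams({}, lambda: None, rng.random((10, 2)), np.array([0, 1] * 5))
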