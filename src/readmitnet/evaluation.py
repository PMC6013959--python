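"""Threshold-sweep ROC analysis, operating-point selection, stratified
cross-validation, and random-search hyper-parameter tuning.

The ROC curve is built by shifting the classification threshold over
every distinct score (ties enter together) and carries raw TP / FP /
predicted-positive *counts* at every point, so downstream cost modelling
needs no re-scoring. The operating point follows the
distance-to-the-ideal-corner rule: the threshold minimizing
``sqrt(FP_rate^2 + (1 - TP_rate)^2)``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

__all__ = ["ROCCurve", "EvalReport", "roc_curve", "auc", "optimal_threshold",
           "confusion_metrics", "kfold_cv", "tune_hyperparams"]

logger = logging.getLogger(__name__)


@dataclass
class ROCCurve:
    """Ordered operating points for predicted-positive rule ``score >= threshold``.

    Points run from the all-negative endpoint (threshold +inf, FPR=TPR=0)
    to the all-positive endpoint (lowest score, FPR=TPR=1); thresholds are
    nonincreasing and rates nondecreasing.
    """

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    tp: np.ndarray
    fp: np.ndarray
    predicted_positive: np.ndarray
    n_pos: int
    n_neg: int

    def __len__(self):
        return len(self.thresholds)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "threshold": self.thresholds, "fpr": self.fpr, "tpr": self.tpr,
            "tp": self.tp, "fp": self.fp,
            "predicted_positive": self.predicted_positive})


def roc_curve(scores, labels) -> ROCCurve:
    """ROC operating points over every distinct score threshold.

    Equal scores enter the curve together (exact tie handling); an
    explicit all-negative endpoint is prepended.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel().astype(int)
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    order = np.argsort(-scores, kind="stable")
    s, l = scores[order], labels[order]
    # last index of each tie block = cumulative counts at that threshold
    distinct = np.nonzero(np.diff(s))[0]
    block_ends = np.r_[distinct, s.size - 1]
    tp = np.cumsum(l)[block_ends]
    pp = block_ends + 1
    fp = pp - tp
    thresholds = np.r_[np.inf, s[block_ends]]
    tp = np.r_[0, tp]
    fp = np.r_[0, fp]
    pp = np.r_[0, pp]
    return ROCCurve(thresholds=thresholds, fpr=fp / n_neg, tpr=tp / n_pos,
                    tp=tp, fp=fp, predicted_positive=pp,
                    n_pos=n_pos, n_neg=n_neg)


def auc(curve: ROCCurve) -> float:
    """Trapezoidal area under the ROC curve; equals the pairwise
    concordance probability with half credit for score ties."""
    return float(np.trapezoid(curve.tpr, curve.fpr))


def optimal_threshold(curve: ROCCurve) -> float:
    """Threshold minimizing the distance ``sqrt(FPR^2 + (1-TPR)^2)`` to the
    ideal corner (0, 1); ties broken toward higher TPR, then lower
    threshold (logged)."""
    d = np.hypot(curve.fpr, 1.0 - curve.tpr)
    best = 0
    for i in range(1, len(curve)):
        key = (d[i], -curve.tpr[i], curve.thresholds[i])
        if key < (d[best], -curve.tpr[best], curve.thresholds[best]):
            best = i
    if (d == d[best]).sum() > 1:
        logger.info("operating-point tie at distance %.6f broken toward "
                    "higher TPR then lower threshold", d[best])
    return float(curve.thresholds[best])


def confusion_metrics(scores, labels, theta: float) -> dict:
    """Accuracy, precision, recall and F1 at ``score >= theta``.

    With no predicted positives, precision is reported as 0 with a warning.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel().astype(int)
    pred = (scores >= theta).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    n = tp + fp + fn + tn
    if tp + fp == 0:
        warnings.warn("no predicted positives at this threshold; precision set to 0")
        precision = 0.0
    else:
        precision = tp / (tp + fp)
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    return {"accuracy": (tp + tn) / n, "precision": precision,
            "recall": recall, "f1": f1,
            "tp": tp, "fp": fp, "fn": fn, "tn": tn}


@dataclass
class EvalReport:
    """Per-fold metrics plus mean +/- sd, in the layout of a CV results table."""

    per_fold: pd.DataFrame
    fold_curves: list = field(default_factory=list)

    METRICS = ("auc", "accuracy", "precision", "recall", "f1")

    @property
    def mean(self) -> dict:
        return {m: float(self.per_fold[m].mean()) for m in self.METRICS}

    @property
    def sd(self) -> dict:
        return {m: float(self.per_fold[m].std(ddof=1)) for m in self.METRICS}

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({"mean": self.mean, "sd": self.sd})


def _scores_of(model, X):
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    return model.decision_function(X)


def kfold_cv(model_factory, X, y, k: int = 10, seed: int = 0,
             preprocess_factory=None, theta_on: str = "test") -> EvalReport:
    """Stratified k-fold cross-validation with leakage-free preprocessing.

    ``model_factory()`` builds a fresh estimator per fold;
    ``preprocess_factory()`` (optional) builds a transformer (e.g. scaler +
    KL filter) that is **fit on the training folds only** and applied to
    both. Per fold: AUC of the held-out scores, the operating threshold
    selected on the held-out (default) or training curve, and the
    confusion metrics at that threshold.
    """
    X = np.asarray(X)
    y = np.asarray(y).ravel().astype(int)
    if k < 2 or len(y) < k:
        raise ValueError("need k >= 2 and n >= k")
    if theta_on not in ("test", "train"):
        raise ValueError("theta_on must be 'test' or 'train'")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    rows, curves = [], []
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        Xtr, Xte = X[tr], X[te]
        if preprocess_factory is not None:
            prep = preprocess_factory()
            prep.fit(Xtr, y[tr])
            Xtr, Xte = prep.transform(Xtr), prep.transform(Xte)
        model = model_factory()
        model.fit(Xtr, y[tr])
        s_te = _scores_of(model, Xte)
        curve = roc_curve(s_te, y[te])
        if theta_on == "train":
            theta = optimal_threshold(roc_curve(_scores_of(model, Xtr), y[tr]))
        else:
            theta = optimal_threshold(curve)
        m = confusion_metrics(s_te, y[te], theta)
        rows.append({"fold": fold, "auc": auc(curve), "theta": theta,
                     **{k_: m[k_] for k_ in ("accuracy", "precision", "recall", "f1")}})
        curves.append(curve)
    return EvalReport(per_fold=pd.DataFrame(rows), fold_curves=curves)


# -- hyper-parameter search ---------------------------------------------------

def _draw(rng: np.random.Generator, spec):
    """Sample one value from a space leaf: ('uniform', a, b),
    ('loguniform', log_a, log_b), ('randint', a, b incl.), ('choice', [..])."""
    kind = spec[0]
    if kind == "uniform":
        return float(rng.uniform(spec[1], spec[2]))
    if kind == "loguniform":
        return float(np.exp(rng.uniform(spec[1], spec[2])))
    if kind == "randint":
        return int(rng.integers(spec[1], spec[2] + 1))
    if kind == "choice":
        return spec[1][int(rng.integers(0, len(spec[1])))]
    raise ValueError(f"unknown space kind {kind!r}")


def tune_hyperparams(space: dict, make_model, X, y, n_iter: int = 100,
                     subsample: float = 0.10, k: int = 10, seed: int = 0):
    """Seeded random-search hyper-parameter optimization.

    A ``subsample`` fraction of the data is drawn once (stratified by
    outcome); each trial samples a configuration from ``space``, builds a
    model via ``make_model(**config)``, and scores it by mean k-fold CV
    AUC on the subset. Returns ``(best_config, trials)`` where ``trials``
    is a DataFrame with one row per iteration.
    """
    if not space:
        raise ValueError("empty search space")
    X = np.asarray(X)
    y = np.asarray(y).ravel().astype(int)
    rng = np.random.default_rng(seed)
    if subsample < 1.0:
        idx = []
        for c in np.unique(y):
            cls = np.flatnonzero(y == c)
            take = max(2, int(round(subsample * cls.size)))
            idx.append(rng.choice(cls, size=min(take, cls.size), replace=False))
        idx = np.concatenate(idx)
        Xs, ys = X[idx], y[idx]
    else:
        Xs, ys = X, y
    logger.info("random search over %d iterations on %d samples", n_iter, len(ys))
    rows = []
    best_cfg, best_auc = None, -np.inf
    for it in range(n_iter):
        cfg = {name: _draw(rng, spec) for name, spec in space.items()}
        trial_seed = int(rng.integers(0, 2**31))
        report = kfold_cv(lambda: make_model(**cfg), Xs, ys,
                          k=min(k, int(np.bincount(ys).min())), seed=trial_seed)
        score = report.mean["auc"]
        rows.append({"iteration": it, "auc": score, **cfg})
        if score > best_auc:
            best_cfg, best_auc = cfg, score
    return best_cfg, pd.DataFrame(rows)
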