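"""Telemonitoring net-savings model swept along ROC curves.

For a candidate enrollment threshold, enrolling every predicted-positive
index admission in the telemonitoring program yields

    net savings = readmission_cost_per_patient * TP * response_rate
                  - program_cost_per_patient * PP,

where TP is the number of true positives (readmissions averted with
probability ``response_rate``) and PP the number of predicted positives
(every enrollee incurs the program cost). Sweeping the classification
threshold along a ROC curve that carries raw counts gives the savings
curve, its maximum, and the classification accuracy at the maximizing
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluation import ROCCurve

__all__ = ["CostParams", "CostCurve", "net_savings", "savings_sweep",
           "summarize_fold_maxima"]


@dataclass(frozen=True)
class CostParams:
    readmission_cost_per_patient: float = 9655.0
    program_cost_per_patient: float = 1500.0
    response_rate: float = 0.5

    def __post_init__(self):
        if self.readmission_cost_per_patient < 0 or self.program_cost_per_patient < 0:
            raise ValueError("costs must be nonnegative")
        if not 0.0 <= self.response_rate <= 1.0:
            raise ValueError("response_rate must be in [0, 1]")


def net_savings(tp_count: float, predicted_positive_count: float,
                params: CostParams = CostParams()) -> float:
    """Net savings from readmission reduction at one operating point."""
    if not 0 <= tp_count <= predicted_positive_count:
        raise ValueError("need 0 <= tp_count <= predicted_positive_count")
    return (params.readmission_cost_per_patient * tp_count * params.response_rate
            - params.program_cost_per_patient * predicted_positive_count)


@dataclass
class CostCurve:
    """Per-threshold savings along one ROC curve plus the argmax point."""

    thresholds: np.ndarray
    savings: np.ndarray
    best_threshold: float
    max_savings: float
    accuracy_at_best: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold": self.thresholds, "savings": self.savings})


def savings_sweep(curve: ROCCurve, params: CostParams = CostParams()) -> CostCurve:
    """Evaluate net savings at every point of a count-bearing ROC curve.

    The argmax is returned together with the classification accuracy at
    the maximizing threshold (TN recovered from the curve's counts); ties
    are broken toward the smaller program (fewer predicted positives).
    The all-negative endpoint (PP=0, savings 0) is always on the curve,
    so the maximum is never negative.
    """
    if curve.tp is None or curve.predicted_positive is None:
        raise ValueError("ROC curve must carry raw TP / predicted-positive counts")
    savings = np.array([
        net_savings(tp, pp, params)
        for tp, pp in zip(curve.tp, curve.predicted_positive)])
    # lexicographic argmax: highest savings, then fewer predicted positives
    best = 0
    for i in range(1, len(savings)):
        if (savings[i], -curve.predicted_positive[i]) > \
           (savings[best], -curve.predicted_positive[best]):
            best = i
    n = curve.n_pos + curve.n_neg
    tn = curve.n_neg - curve.fp[best]
    accuracy = (curve.tp[best] + tn) / n
    return CostCurve(thresholds=curve.thresholds.copy(), savings=savings,
                     best_threshold=float(curve.thresholds[best]),
                     max_savings=float(savings[best]),
                     accuracy_at_best=float(accuracy))


def summarize_fold_maxima(cost_curves: list[CostCurve]) -> dict:
    """Mean +/- sd of per-fold maximum savings and corresponding accuracy."""
    if not cost_curves:
        raise ValueError("no cost curves given")
    sav = np.array([c.max_savings for c in cost_curves])
    acc = np.array([c.accuracy_at_best for c in cost_curves])
    sd = lambda a: float(a.std(ddof=1)) if a.size > 1 else 0.0
    return {"max_savings_mean": float(sav.mean()), "max_savings_sd": sd(sav),
            "accuracy_mean": float(acc.mean()), "accuracy_sd": sd(acc)}
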