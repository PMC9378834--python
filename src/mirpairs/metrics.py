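"""Diagnostic performance metrics (case = positive class throughout).

sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), accuracy = (TP+TN)/total,
PPV = TP/(TP+FP), NPV = TN/(TN+FN), and the panel-selection evaluation index
sqrt(PPV x NPV).  AUC is the rank-based (Mann-Whitney) statistic with midranks
for tied scores, which is exact in the presence of ties — vote-fraction scores
tie heavily, so trapezoidal ROC integration is deliberately avoided.

A metric whose denominator is zero is reported as NaN and listed in
``undefined``, never silently coerced to 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import CASE, CONTROL, LabelMap

__all__ = [
    "ConfusionCounts",
    "ClassificationMetrics",
    "confusion",
    "diagnostic_metrics",
    "auc",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self):
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n_cases(self) -> int:
        return self.tp + self.fn

    @property
    def n_controls(self) -> int:
        return self.tn + self.fp

    @property
    def total(self) -> int:
        return self.n_cases + self.n_controls


@dataclass(frozen=True)
class ClassificationMetrics:
    """Proportions in [0, 1]; NaN entries are named in ``undefined``."""

    sensitivity: float
    specificity: float
    accuracy: float
    ppv: float
    npv: float
    eval_index: float
    auc: float | None = None
    undefined: tuple[str, ...] = ()

    def as_row(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "SEN": self.sensitivity,
                    "SPE": self.specificity,
                    "ACC": self.accuracy,
                    "PPV": self.ppv,
                    "NPV": self.npv,
                    "EVAL_INDEX": self.eval_index,
                    "AUC": self.auc,
                }
            ]
        )


def confusion(predicted: Mapping[str, str], truth: LabelMap) -> ConfusionCounts:
    """Cross-tabulate predicted vs true labels over an identical sample set."""
    pred_ids = set(predicted)
    true_ids = set(truth)
    if pred_ids != true_ids:
        only_pred = sorted(pred_ids - true_ids)[:5]
        only_true = sorted(true_ids - pred_ids)[:5]
        raise ValueError(
            f"sample id mismatch between predictions and truth "
            f"(only in predictions: {only_pred}, only in truth: {only_true})"
        )
    tp = fn = tn = fp = 0
    for sid, true_label in truth.items():
        pred_label = predicted[sid]
        if pred_label not in (CASE, CONTROL):
            raise ValueError(f"predicted label for {sid!r} must be case/control")
        if true_label == CASE:
            tp, fn = (tp + 1, fn) if pred_label == CASE else (tp, fn + 1)
        else:
            tn, fp = (tn + 1, fp) if pred_label == CONTROL else (tn, fp + 1)
    return ConfusionCounts(tp=tp, fn=fn, tn=tn, fp=fp)


def _ratio(num: int, denom: int, name: str, undefined: list[str]) -> float:
    if denom == 0:
        undefined.append(name)
        return float("nan")
    return num / denom


def diagnostic_metrics(c: ConfusionCounts, scores_auc: float | None = None) -> ClassificationMetrics:
    """All reported diagnostic quantities from one confusion table."""
    undefined: list[str] = []
    sen = _ratio(c.tp, c.tp + c.fn, "sensitivity", undefined)
    spe = _ratio(c.tn, c.tn + c.fp, "specificity", undefined)
    acc = _ratio(c.tp + c.tn, c.total, "accuracy", undefined)
    ppv = _ratio(c.tp, c.tp + c.fp, "ppv", undefined)
    npv = _ratio(c.tn, c.tn + c.fn, "npv", undefined)
    if math.isnan(ppv) or math.isnan(npv):
        undefined.append("eval_index")
        eval_index = float("nan")
    else:
        eval_index = math.sqrt(ppv * npv)
    return ClassificationMetrics(
        sensitivity=sen,
        specificity=spe,
        accuracy=acc,
        ppv=ppv,
        npv=npv,
        eval_index=eval_index,
        auc=scores_auc,
        undefined=tuple(undefined),
    )


def auc(scores: Mapping[str, float] | Sequence[float], truth: LabelMap) -> float:
    """Mann-Whitney AUC of case-vs-control score separation (midranks for ties).

    AUC = (R_case - n_case(n_case+1)/2) / (n_case * n_control), with R_case the
    midrank sum of case scores.  Equals the probability that a random case
    outscores a random control, counting ties as one half.
    """
    if hasattr(scores, "keys"):
        ids = list(truth)
        missing = [s for s in ids if s not in scores]
        if missing:
            raise ValueError(f"scores missing for samples: {missing[:5]}")
        s = np.array([float(scores[i]) for i in ids])
        y = np.array([truth[i] == CASE for i in ids])
    else:
        s = np.asarray(list(scores), dtype=float)
        ids = list(truth)
        if len(s) != len(ids):
            raise ValueError("score vector length does not match label map")
        y = np.array([truth[i] == CASE for i in ids])
    n_case = int(y.sum())
    n_control = len(y) - n_case
    if n_case == 0 or n_control == 0:
        raise ValueError("AUC requires at least one case and one control")
    ranks = rankdata(s)  # midranks
    r_case = ranks[y].sum()
    return float((r_case - n_case * (n_case + 1) / 2) / (n_case * n_control))
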