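"""Classification performance statistics computed from confusion counts and scores.

The suite used throughout the pipeline: sensitivity (SE), specificity (SP),
classification accuracy (CA), Matthews correlation coefficient (MCC),
balanced accuracy (BA, the mean of SE and SP) and the area under the ROC
curve (AUC).  Degenerate confusion tables (an empty margin) yield an explicit
``UNDEFINED`` marker rather than raising, because published result tables
contain such rows (e.g. a validation split with no true negatives) and render
them as ``-``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence, Union

import numpy as np


class _Undefined:
    """Singleton marker for a metric whose defining ratio has a zero margin."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "UNDEFINED"

    def __bool__(self) -> bool:
        return False


UNDEFINED = _Undefined()

MetricValue = Union[float, _Undefined]


def round_half_up(x: float, ndigits: int = 3) -> float:
    """Round with ties away from zero, the convention of printed result tables.

    Python's ``round`` is banker's rounding; published 3-decimal tables use
    half-up (0.8695 -> 0.870), so reports go through this helper.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionTable:
    """TP/TN/FP/FN counts for one model on one split (positive class = potent)."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        for name in ("tp", "tn", "fp", "fn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_predictions(
        cls, y_true: Sequence, y_pred: Sequence, positive="P"
    ) -> "ConfusionTable":
        yt = np.asarray(y_true)
        yp = np.asarray(y_pred)
        if yt.shape != yp.shape:
            raise ValueError("y_true and y_pred must have equal length")
        t = yt == positive
        p = yp == positive
        return cls(
            tp=int(np.sum(t & p)),
            tn=int(np.sum(~t & ~p)),
            fp=int(np.sum(~t & p)),
            fn=int(np.sum(t & ~p)),
        )


def sensitivity(ct: ConfusionTable) -> MetricValue:
    """SE = TP / (TP + FN), the recall of the potent class."""
    if ct.tp + ct.fn == 0:
        return UNDEFINED
    return ct.tp / (ct.tp + ct.fn)


def specificity(ct: ConfusionTable) -> MetricValue:
    """SP = TN / (TN + FP), the recall of the non-potent class."""
    if ct.tn + ct.fp == 0:
        return UNDEFINED
    return ct.tn / (ct.tn + ct.fp)


def accuracy(ct: ConfusionTable) -> float:
    """CA = (TP + TN) / total."""
    if ct.total == 0:
        raise ValueError("cannot compute accuracy of an empty confusion table")
    return (ct.tp + ct.tn) / ct.total


def mcc(ct: ConfusionTable) -> MetricValue:
    """Matthews correlation coefficient.

    (TP*TN - FP*FN) / sqrt((TN+FN)(TN+FP)(TP+FN)(TP+FP)); UNDEFINED when any
    marginal factor vanishes (an all-one-class truth or prediction).
    """
    denom = (
        (ct.tn + ct.fn) * (ct.tn + ct.fp) * (ct.tp + ct.fn) * (ct.tp + ct.fp)
    )
    if denom == 0:
        return UNDEFINED
    return (ct.tp * ct.tn - ct.fp * ct.fn) / math.sqrt(denom)


def balanced_accuracy(ct: ConfusionTable) -> MetricValue:
    """BA = (SE + SP) / 2, full precision (display rounding lives in reports)."""
    se = sensitivity(ct)
    sp = specificity(ct)
    if se is UNDEFINED or sp is UNDEFINED:
        return UNDEFINED
    return (se + sp) / 2.0


def _score_label_arrays(scores, labels, positive):
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D sequences")
    pos = y == positive
    if pos.all() or (~pos).all():
        raise ValueError("AUC requires both classes present")
    return s, pos


def roc_auc(scores: Sequence[float], labels: Sequence, positive="P") -> float:
    """AUC as the Mann-Whitney concordance probability, ties counted 1/2.

    Equals the probability that a random positive outranks a random negative,
    and the trapezoidal area under the empirical ROC curve.
    """
    from scipy.stats import rankdata

    s, pos = _score_label_arrays(scores, labels, positive)
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    ranks = rankdata(s)  # midranks handle ties as half-concordances
    return (ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def roc_points(scores: Sequence[float], labels: Sequence, positive="P"):
    """Empirical ROC curve: (FPR, TPR) arrays over descending score thresholds."""
    s, pos = _score_label_arrays(scores, labels, positive)
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    pos_sorted = pos[order]
    tps = np.cumsum(pos_sorted)
    fps = np.cumsum(~pos_sorted)
    # keep only the last point of each tied-score run
    keep = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    tpr = np.r_[0.0, tps[keep] / pos.sum()]
    fpr = np.r_[0.0, fps[keep] / (~pos).sum()]
    return fpr, tpr


def roc_auc_trapezoid(scores: Sequence[float], labels: Sequence, positive="P") -> float:
    """AUC by trapezoidal integration of the empirical ROC (cross-check route)."""
    fpr, tpr = roc_points(scores, labels, positive)
    return float(np.trapezoid(tpr, fpr))


@dataclass(frozen=True)
class MetricsBundle:
    """SE/SP/CA/MCC/BA(/AUC) for one (fingerprint, algorithm, split)."""

    se: MetricValue
    sp: MetricValue
    ca: float
    mcc: MetricValue
    ba: MetricValue
    auc: Optional[float] = None

    @classmethod
    def from_confusion(
        cls, ct: ConfusionTable, auc: Optional[float] = None
    ) -> "MetricsBundle":
        return cls(
            se=sensitivity(ct),
            sp=specificity(ct),
            ca=accuracy(ct),
            mcc=mcc(ct),
            ba=balanced_accuracy(ct),
            auc=auc,
        )
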