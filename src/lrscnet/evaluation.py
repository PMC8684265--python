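"""Confusion-matrix metrics and ROC area, with benign as the positive class.

The positive class is *benign* throughout (TP = benign called benign).
That inverts the common clinical convention, and is kept deliberately:
sensitivity here is the benign detection rate, specificity the
malignant detection rate.

A metric with a zero denominator (possible on small test splits) is
reported as ``None`` — explicitly undefined, never silently coerced to
zero.  AUC is the rank-based (Mann-Whitney) statistic with half credit
for ties, computed on a continuous benign-likelihood score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

from .exceptions import ValidationError
from .patches import LABELS, normalize_label

__all__ = ["ConfusionCounts", "confusion", "classification_metrics", "auc"]


@dataclass
class ConfusionCounts:
    """TP/TN/FP/FN with benign as the positive class."""

    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def as_dict(self) -> dict[str, int]:
        return {"TP": self.tp, "TN": self.tn, "FP": self.fp, "FN": self.fn}


def _normalize_all(labels: Sequence[str], name: str) -> list[str]:
    try:
        return [normalize_label(x) for x in labels]
    except ValidationError as exc:
        raise ValidationError(f"{name}: {exc}") from exc


def confusion(truth: Sequence[str], predicted: Sequence[str]) -> ConfusionCounts:
    """Count TP (benign->benign), TN (malignant->malignant), FP
    (malignant->benign), FN (benign->malignant)."""
    if len(truth) != len(predicted):
        raise ValidationError(
            f"truth has {len(truth)} labels but predictions have {len(predicted)}"
        )
    t = _normalize_all(truth, "truth")
    p = _normalize_all(predicted, "predicted")
    c = ConfusionCounts()
    for ti, pi in zip(t, p):
        if ti == "benign":
            if pi == "benign":
                c.tp += 1
            else:
                c.fn += 1
        else:
            if pi == "malignant":
                c.tn += 1
            else:
                c.fp += 1
    return c


def _ratio(num: int, den: int) -> Optional[float]:
    return num / den if den > 0 else None


def classification_metrics(c: ConfusionCounts) -> dict[str, Optional[float]]:
    """Accuracy, sensitivity, specificity, PPV and NPV from the counts.

    Accuracy = (TP+TN)/total, Sensitivity = TP/(TP+FN),
    Specificity = TN/(TN+FP), PPV = TP/(TP+FP), NPV = TN/(TN+FN).
    Undefined ratios (zero denominator) come back as None.
    """
    return {
        "accuracy": _ratio(c.tp + c.tn, c.total),
        "sensitivity": _ratio(c.tp, c.tp + c.fn),
        "specificity": _ratio(c.tn, c.tn + c.fp),
        "ppv": _ratio(c.tp, c.tp + c.fp),
        "npv": _ratio(c.tn, c.tn + c.fn),
    }


def auc(scores: Sequence[float], truth: Sequence[str]) -> float:
    """Rank-based ROC area of benign-likelihood scores (benign positive).

    Equals the probability that a random benign image outscores a random
    malignant one, ties counting 1/2.  Requires both classes present.
    """
    if len(scores) != len(truth):
        raise ValidationError(
            f"{len(scores)} scores but {len(truth)} truth labels"
        )
    t = _normalize_all(truth, "truth")
    y = np.array([1 if x == "benign" else 0 for x in t])
    if y.min() == y.max():
        raise ValidationError("AUC needs both classes present in the truth labels")
    s = np.asarray(scores, dtype=np.float64)
    if not np.isfinite(s).all():
        raise ValidationError("scores must be finite")
    return float(roc_auc_score(y, s))
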