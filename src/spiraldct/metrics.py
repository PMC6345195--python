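"""Confusion-matrix tallies and sensitivity/specificity/accuracy percentages.

Essential tremor (label ``"ET"``) is the positive class throughout:
SEN = TP/(TP+FN), SPE = TN/(TN+FP), ACC = (TP+TN)/total, all in percent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np


class UndefinedMetricError(ZeroDivisionError):
    """Requested rate has an empty denominator."""


@dataclass(frozen=True)
class ConfusionMatrix:
    TP: int
    FN: int
    FP: int
    TN: int

    def __post_init__(self):
        for name in ("TP", "FN", "FP", "TN"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.total < 1:
            raise ValueError("confusion matrix must count at least one sample")

    @property
    def total(self) -> int:
        return self.TP + self.FN + self.FP + self.TN


def confusion_from_predictions(
    true_labels, predicted_labels, positive: str = "ET"
) -> ConfusionMatrix:
    """Tally a 2x2 confusion matrix with ``positive`` as the positive class."""
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.shape != p.shape:
        raise ValueError("label vectors must have equal length")
    tpos = t == positive
    ppos = p == positive
    return ConfusionMatrix(
        TP=int(np.sum(tpos & ppos)),
        FN=int(np.sum(tpos & ~ppos)),
        FP=int(np.sum(~tpos & ppos)),
        TN=int(np.sum(~tpos & ~ppos)),
    )


def sensitivity(cm: ConfusionMatrix) -> float:
    """100 * TP / (TP + FN)."""
    if cm.TP + cm.FN == 0:
        raise UndefinedMetricError("no positive samples: sensitivity undefined")
    return 100.0 * cm.TP / (cm.TP + cm.FN)


def specificity(cm: ConfusionMatrix) -> float:
    """100 * TN / (TN + FP)."""
    if cm.TN + cm.FP == 0:
        raise UndefinedMetricError("no negative samples: specificity undefined")
    return 100.0 * cm.TN / (cm.TN + cm.FP)


def accuracy(cm: ConfusionMatrix) -> float:
    """100 * (TP + TN) / total."""
    return 100.0 * (cm.TP + cm.TN) / cm.total


def report(cm: ConfusionMatrix, config: dict | None = None) -> dict:
    """JSON-serializable summary; percentages at full precision."""
    return {
        "TP": cm.TP,
        "FN": cm.FN,
        "FP": cm.FP,
        "TN": cm.TN,
        "accuracy": accuracy(cm),
        "sensitivity": sensitivity(cm),
        "specificity": specificity(cm),
        "config": config or {},
    }


def write_report(cm: ConfusionMatrix, path, config: dict | None = None) -> None:
    with open(path, "w") as fh:
        json.dump(report(cm, config), fh, indent=2)
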