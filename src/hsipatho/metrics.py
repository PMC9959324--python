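"""Confusion-matrix construction and imbalance-aware evaluation metrics.

The positive class is "unhealthy" (tumor).  Five metrics are reported:
accuracy, precision, recall, F1 and the Matthews correlation coefficient

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)),

which stays informative under heavy class imbalance: 1 is perfect agreement,
0 a chance-level predictor, -1 total disagreement.  Degenerate denominators
use the standard conventions: precision/recall/F1 are 0 when undefined, and
MCC is 0 when any factor under the root vanishes.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = ["ConfusionCounts", "MetricsReport", "confusion_from_labels", "compute_metrics"]

POSITIVE_LABEL = "unhealthy"


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise InputError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def swapped(self) -> "ConfusionCounts":
        """The same predictions under the opposite positive-class convention."""
        return ConfusionCounts(tp=self.tn, tn=self.tp, fp=self.fn, fn=self.fp)


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    mcc: float

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    def as_row(self, **config) -> dict:
        return {**config, **asdict(self)}


def confusion_from_labels(y_true, y_pred, positive: str = POSITIVE_LABEL) -> ConfusionCounts:
    """Count TP/TN/FP/FN from two equal-length label sequences."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise InputError(
            f"label vectors must be non-empty and equal-length, got {y_true.shape} vs {y_pred.shape}"
        )
    t = y_true == positive
    p = y_pred == positive
    return ConfusionCounts(
        tp=int(np.sum(t & p)),
        tn=int(np.sum(~t & ~p)),
        fp=int(np.sum(~t & p)),
        fn=int(np.sum(t & ~p)),
    )


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    """Accuracy, precision, recall, F1 and MCC from confusion counts."""
    if c.total == 0:
        raise InputError("cannot compute metrics from an empty confusion matrix")
    tp, tn, fp, fn = float(c.tp), float(c.tn), float(c.fp), float(c.fn)
    accuracy = (tp + tn) / (tp + tn + fp + fn)
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = (
        2.0 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    factors = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(factors) if factors > 0 else 0.0
    return MetricsReport(accuracy=accuracy, precision=precision, recall=recall, f1=f1, mcc=mcc)


def append_results_row(path: str | Path, row: dict) -> pd.DataFrame:
    """Append one experiment row to a CSV results table, creating it if needed."""
    path = Path(path)
    frame = pd.DataFrame([row])
    if path.exists():
        frame = pd.concat([pd.read_csv(path), frame], ignore_index=True)
    frame.to_csv(path, index=False)
    return frame
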