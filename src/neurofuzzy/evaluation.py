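"""Confusion-matrix metrics and classifier comparison tables.

Per class ``c`` (one-vs-rest), from counts tp, fp, fn, tn:

    accuracy  = (tp + tn) / (tp + tn + fp + fn)
    precision = tp / (tp + fp)
    recall    = tp / (tp + fn)          (the tp-rate)
    fp_rate   = fp / (fp + tn)
    F         = 2 * precision * recall / (precision + recall)

A metric whose denominator is zero is reported as undefined (NaN), never
silently as 0.  ``paper_literal=True`` switches recall to tp / (tp + tn),
the printed form of the source formula, for auditing only — it is
inconsistent with the accuracy identity and not the default.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion

from .exceptions import NeuroFuzzyError


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest counts for a single class."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion(actual, predicted, n_classes: int | None = None):
    """k x k confusion matrix (rows = actual, columns = predicted) and the
    per-class one-vs-rest :class:`ConfusionCounts` derived from it."""
    actual = np.asarray(actual, dtype=int)
    predicted = np.asarray(predicted, dtype=int)
    if actual.shape != predicted.shape:
        raise NeuroFuzzyError("actual and predicted must have equal lengths")
    if n_classes is None:
        n_classes = int(max(actual.max(), predicted.max())) + 1
    if actual.min() < 0 or predicted.min() < 0 or \
            max(actual.max(), predicted.max()) >= n_classes:
        raise NeuroFuzzyError("labels outside the known classes")
    matrix = _sk_confusion(actual, predicted, labels=np.arange(n_classes))
    counts = []
    n = matrix.sum()
    for c in range(n_classes):
        tp = int(matrix[c, c])
        fn = int(matrix[c].sum() - tp)
        fp = int(matrix[:, c].sum() - tp)
        counts.append(ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=int(n - tp - fn - fp)))
    return matrix, counts


def _ratio(num, den):
    return float(num) / float(den) if den > 0 else math.nan


def metrics(c: ConfusionCounts, paper_literal: bool = False) -> dict:
    """The metric suite for one one-vs-rest table; NaN marks undefined."""
    accuracy = _ratio(c.tp + c.tn, c.n)
    precision = _ratio(c.tp, c.tp + c.fp)
    recall = _ratio(c.tp, c.tp + c.tn) if paper_literal else _ratio(c.tp, c.tp + c.fn)
    fp_rate = _ratio(c.fp, c.fp + c.tn)
    if math.isnan(precision) or math.isnan(recall) or precision + recall == 0:
        f_measure = math.nan
    else:
        f_measure = 2.0 * precision * recall / (precision + recall)
    return {"accuracy": accuracy, "precision": precision, "recall": recall,
            "fp_rate": fp_rate, "f_measure": f_measure}


def rmse(targets, outputs) -> float:
    """Root of the mean squared element-wise residual."""
    targets = np.asarray(targets, dtype=float)
    outputs = np.asarray(outputs, dtype=float)
    if targets.shape != outputs.shape:
        raise NeuroFuzzyError("targets and outputs must have equal shapes")
    return float(np.sqrt(np.mean((targets - outputs) ** 2)))


@dataclass
class MetricsReport:
    """Per-class metrics plus macro averages and overall accuracy/RMSE."""

    matrix: np.ndarray
    per_class: list          # list of metric dicts
    macro: dict
    overall_accuracy: float
    rmse: float | None = None

    def row(self) -> dict:
        """One comparison-table row: percentages plus RMSE."""
        return {
            "accuracy_pct": 100.0 * self.overall_accuracy,
            "tp_rate_pct": 100.0 * self.macro["recall"],
            "fp_rate_pct": 100.0 * self.macro["fp_rate"],
            "precision_pct": 100.0 * self.macro["precision"],
            "f_measure_pct": 100.0 * self.macro["f_measure"],
            "rmse": self.rmse,
        }


def evaluate(actual, predicted, outputs=None, targets=None,
             n_classes: int | None = None, paper_literal: bool = False) -> MetricsReport:
    """Full report for one classifier run.

    ``outputs``/``targets`` (activation and one-hot matrices) are optional
    and only feed the RMSE column.
    """
    matrix, counts = confusion(actual, predicted, n_classes)
    per_class = [metrics(c, paper_literal) for c in counts]
    macro = {key: float(np.nanmean([m[key] for m in per_class]))
             for key in per_class[0]}
    overall = float(np.trace(matrix)) / float(matrix.sum())
    err = rmse(targets, outputs) if outputs is not None and targets is not None else None
    return MetricsReport(matrix=matrix, per_class=per_class, macro=macro,
                         overall_accuracy=overall, rmse=err)


COMPARE_COLUMNS = ["dataset", "classifier", "accuracy_pct", "tp_rate_pct",
                   "fp_rate_pct", "precision_pct", "f_measure_pct", "rmse"]


def compare_report(results: dict) -> pd.DataFrame:
    """Comparison table over classifiers and datasets.

    ``results`` maps (dataset name -> classifier name -> MetricsReport).
    Percentage columns are rounded to one decimal.
    """
    rows = []
    for dataset, by_clf in results.items():
        for clf, report in by_clf.items():
            row = {"dataset": dataset, "classifier": clf}
            for key, val in report.row().items():
                if key.endswith("_pct"):
                    row[key] = round(val, 1) if val is not None and not math.isnan(val) else math.nan
                else:
                    row[key] = round(val, 4) if val is not None else math.nan
            rows.append(row)
    return pd.DataFrame(rows, columns=COMPARE_COLUMNS)


def write_report(table: pd.DataFrame, csv_path=None, json_path=None):
    if csv_path is not None:
        table.to_csv(csv_path, index=False)
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(table.to_dict(orient="records"), fh, indent=2, sort_keys=True)
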