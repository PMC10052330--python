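"""Confusion-matrix construction and the classifier evaluation suite.

For a declared positive class the 2x2 cross-tabulation yields TP, FP, TN,
FN, from which the standard rates follow:

    accuracy    = (TP + TN) / total
    precision   = TP / (TP + FP)
    sensitivity = recall = TP / (TP + FN)
    specificity = TN / (TN + FP)
    F1          = 2 * precision * recall / (precision + recall)

Cohen's kappa corrects observed agreement for the agreement expected from
the marginal frequencies alone. MAE and RMSE are computed between the
positive-class probability and the 0/1 label. Ratios with a zero
denominator are reported as 0 and flagged, so degenerate cross-validation
folds never abort a tuning run. Multiclass problems are reduced
one-vs-rest and macro-averaged; the binary case is unchanged by this.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion",
    "compute_metrics",
    "mae_rmse",
    "macro_metrics",
    "report_tables",
]


@dataclass
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricsReport:
    accuracy: float
    precision: float
    sensitivity: float
    specificity: float
    recall: float
    f1: float
    kappa: float
    tp_rate: float
    fp_rate: float
    proper_classified: float
    improper_classified: float
    mae: float | None = None
    rmse: float | None = None
    training_time_s: float | None = None
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "MetricsReport":
        return cls(**d)


def confusion(y_true: np.ndarray, y_pred: np.ndarray, positive_class) -> ConfusionMatrix:
    """Standard 2x2 cross-tabulation with respect to ``positive_class``."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have the same length")
    classes = set(np.unique(y_true)) | set(np.unique(y_pred))
    if positive_class not in classes:
        raise ValueError(f"positive class {positive_class!r} not among observed classes")
    tp = int(np.sum((y_true == positive_class) & (y_pred == positive_class)))
    fn = int(np.sum((y_true == positive_class) & (y_pred != positive_class)))
    fp = int(np.sum((y_true != positive_class) & (y_pred == positive_class)))
    tn = int(np.sum((y_true != positive_class) & (y_pred != positive_class)))
    return ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn)


def _ratio(num: float, den: float, name: str, warnings: list[str]) -> float:
    if den == 0:
        warnings.append(f"{name} undefined (zero denominator); reported as 0")
        return 0.0
    return num / den


def compute_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """All rate metrics from one confusion matrix (values in [0, 1])."""
    n = cm.total
    if n < 1:
        raise ValueError("empty confusion matrix")
    warnings: list[str] = []
    accuracy = (cm.tp + cm.tn) / n
    precision = _ratio(cm.tp, cm.tp + cm.fp, "precision", warnings)
    recall = _ratio(cm.tp, cm.tp + cm.fn, "recall", warnings)
    specificity = _ratio(cm.tn, cm.tn + cm.fp, "specificity", warnings)
    f1 = _ratio(2 * precision * recall, precision + recall, "f1", warnings)
    p_o = accuracy
    p_e = ((cm.tp + cm.fp) * (cm.tp + cm.fn) + (cm.fn + cm.tn) * (cm.fp + cm.tn)) / (n * n)
    kappa = _ratio(p_o - p_e, 1 - p_e, "kappa", warnings)
    fp_rate = _ratio(cm.fp, cm.fp + cm.tn, "fp_rate", warnings)
    return MetricsReport(
        accuracy=accuracy, precision=precision, sensitivity=recall, specificity=specificity,
        recall=recall, f1=f1, kappa=kappa, tp_rate=recall, fp_rate=fp_rate,
        proper_classified=accuracy, improper_classified=1 - accuracy, warnings=warnings,
    )


def mae_rmse(y_true_binary: np.ndarray, y_score: np.ndarray) -> tuple[float, float]:
    """Mean absolute and root-mean-square error of positive-class probabilities."""
    y = np.asarray(y_true_binary, dtype=float)
    p = np.asarray(y_score, dtype=float)
    if y.shape != p.shape:
        raise ValueError("label and score vectors must have the same length")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("scores must lie in [0, 1]")
    err = y - p
    return float(np.mean(np.abs(err))), float(np.sqrt(np.mean(err**2)))


def macro_metrics(y_true: np.ndarray, y_pred: np.ndarray, classes) -> MetricsReport:
    """One-vs-rest macro average over the given classes."""
    reports = [compute_metrics(confusion(y_true, y_pred, c)) for c in classes]
    mean = lambda attr: float(np.mean([getattr(r, attr) for r in reports]))
    warnings = [w for r in reports for w in r.warnings]
    return MetricsReport(
        accuracy=mean("accuracy"), precision=mean("precision"), sensitivity=mean("sensitivity"),
        specificity=mean("specificity"), recall=mean("recall"), f1=mean("f1"), kappa=mean("kappa"),
        tp_rate=mean("tp_rate"), fp_rate=mean("fp_rate"),
        proper_classified=mean("proper_classified"), improper_classified=mean("improper_classified"),
        warnings=warnings,
    )


_PERCENT_ROWS = [
    ("Proper classified data", "proper_classified"),
    ("Improper classified data", "improper_classified"),
    ("Accuracy", "accuracy"),
    ("Precision", "precision"),
    ("Sensitivity", "sensitivity"),
    ("Recall", "recall"),
    ("Specificity", "specificity"),
    ("F1-score", "f1"),
    ("TP rate", "tp_rate"),
    ("FP rate", "fp_rate"),
    ("Kappa", "kappa"),
    ("MAE", "mae"),
    ("RMSE", "rmse"),
]


def format_percent(value: float) -> str:
    return f"{value * 100:.2f}%"


def report_tables(reports: dict[str, MetricsReport]) -> tuple[str, str]:
    """(JSON document, aligned text table) with one column per method."""
    doc = {name: r.to_dict() for name, r in reports.items()}
    names = list(reports)
    header = ["Metric"] + names
    rows = [header]
    for label, attr in _PERCENT_ROWS:
        cells = [label]
        for name in names:
            v = getattr(reports[name], attr)
            cells.append("-" if v is None else format_percent(v))
        rows.append(cells)
    cells = ["Training time"]
    for name in names:
        t = reports[name].training_time_s
        cells.append("-" if t is None else f"{t:.3f} s")
    rows.append(cells)
    widths = [max(len(r[i]) for r in rows) for i in range(len(header))]
    text = "\n".join("  ".join(c.ljust(w) for c, w in zip(r, widths)).rstrip() for r in rows)
    return json.dumps(doc, indent=2), text
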