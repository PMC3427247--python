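"""Binary-classification performance measures.

Sensitivity, specificity, precision, accuracy, the Matthews correlation
coefficient and the ROC AUC, on the disease=+1 / neutral=−1 label encoding
used throughout the package.  Metrics with a zero denominator are defined
as 0 and flagged, so degenerate cross-validation folds aggregate cleanly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_curve


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_scores(cls, scores, labels, threshold: float = 0.5) -> "ConfusionCounts":
        """Counts at a score threshold; labels in {1, −1}, score = P(disease)."""
        scores = np.asarray(scores, dtype=float)
        labels = np.asarray(labels)
        pred = np.where(scores >= threshold, 1, -1)
        return cls(
            tp=int(((pred == 1) & (labels == 1)).sum()),
            tn=int(((pred == -1) & (labels == -1)).sum()),
            fp=int(((pred == 1) & (labels == -1)).sum()),
            fn=int(((pred == -1) & (labels == 1)).sum()),
        )


@dataclass
class MetricsReport:
    sen: float
    spe: float
    pre: float
    acc: float
    mcc: float
    auc: float | None = None
    roc_points: list | None = None
    zero_denominator: set = field(default_factory=set)

    def to_dict(self) -> dict:
        d = {"SEN": self.sen, "SPE": self.spe, "PRE": self.pre,
             "ACC": self.acc, "MCC": self.mcc}
        if self.auc is not None:
            d["AUC"] = self.auc
        if self.zero_denominator:
            d["zero_denominator"] = sorted(self.zero_denominator)
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _ratio(num: float, den: float, name: str, flags: set) -> float:
    if den == 0:
        flags.add(name)
        return 0.0
    return num / den


def binary_metrics(counts: ConfusionCounts) -> MetricsReport:
    """SEN, SPE, PRE, ACC and MCC from confusion counts.

    MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)); any zero
    denominator yields 0 with the metric name recorded in
    ``zero_denominator``.
    """
    if counts.total == 0:
        raise ValueError("empty confusion table")
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    flags: set = set()
    sen = _ratio(tp, tp + fn, "SEN", flags)
    spe = _ratio(tn, tn + fp, "SPE", flags)
    pre = _ratio(tp, tp + fp, "PRE", flags)
    acc = (tp + tn) / counts.total
    denom = math.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = _ratio(tp * tn - fp * fn, denom, "MCC", flags)
    return MetricsReport(sen=sen, spe=spe, pre=pre, acc=acc, mcc=mcc,
                         zero_denominator=flags)


def roc_auc(scores, labels) -> tuple[float, list[tuple[float, float]]]:
    """Trapezoidal ROC AUC with tied scores grouped.

    Equivalent to the normalized Mann–Whitney U statistic (ties count 1/2).
    Returns (auc, [(fpr, tpr), …]).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    classes = set(np.unique(labels).tolist())
    if classes != {1, -1}:
        raise ValueError(f"labels must contain both classes 1 and -1, got {sorted(classes)}")
    fpr, tpr, _ = roc_curve(labels, scores, pos_label=1)
    auc = float(np.trapezoid(tpr, fpr))
    return auc, list(zip(fpr.tolist(), tpr.tolist()))


def metrics_from_scores(scores, labels, threshold: float = 0.5) -> MetricsReport:
    """Full report (threshold metrics + AUC) from continuous scores."""
    report = binary_metrics(ConfusionCounts.from_scores(scores, labels, threshold))
    report.auc, report.roc_points = roc_auc(scores, labels)
    return report


def write_roc_points(points, path) -> None:
    with open(path, "w") as fh:
        fh.write("fpr\ttpr\n")
        for x, y in points:
            fh.write(f"{x:.6g}\t{y:.6g}\n")
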