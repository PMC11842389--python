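"""Binary-classification evaluation: confusion metrics and ROC/PR areas.

The report carries precision (PRE), sensitivity/recall (SEN), specificity
(SPE), accuracy (ACC), error rate (ER = 1 - ACC), F1, ROC-AUC and PR-AUC.
Curve areas delegate to scikit-learn: ROC-AUC via the rank (Mann-Whitney)
statistic, which handles tied scores as half-wins, and PR-AUC via the
average-precision convention (right-continuous steps) rather than PR-space
trapezoids, which would interpolate optimistically.

Zero-denominator ratios are reported as 0 with ``degenerate=True`` so that
a degenerate fold never crashes a batch evaluation.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import average_precision_score

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion_counts",
    "classification_metrics",
    "roc_auc",
    "pr_auc",
    "evaluate_scores",
    "report_csv_header",
    "report_csv_row",
]

REPORT_COLUMNS = ("PRE", "SEN", "SPE", "ACC", "ER", "F1", "ROC_AUC", "PR_AUC")


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def n(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass
class MetricsReport:
    PRE: float
    SEN: float
    SPE: float
    ACC: float
    ER: float
    F1: float
    ROC_AUC: float | None = None
    PR_AUC: float | None = None
    degenerate: bool = False  # some ratio had a zero denominator


def _as_binary(v) -> np.ndarray:
    arr = np.asarray(v).astype(int)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("labels must be binary (0/1)")
    return arr


def confusion_counts(y, y_hat) -> ConfusionCounts:
    y, y_hat = _as_binary(y), _as_binary(y_hat)
    if y.shape != y_hat.shape:
        raise ValueError("label vectors must have equal length")
    return ConfusionCounts(
        TP=int(np.sum((y == 1) & (y_hat == 1))),
        FP=int(np.sum((y == 0) & (y_hat == 1))),
        TN=int(np.sum((y == 0) & (y_hat == 0))),
        FN=int(np.sum((y == 1) & (y_hat == 0))),
    )


def _ratio(num: float, den: float) -> tuple[float, bool]:
    return (num / den, False) if den > 0 else (0.0, True)


def classification_metrics(c: ConfusionCounts) -> MetricsReport:
    sen, d1 = _ratio(c.TP, c.TP + c.FN)
    pre, d2 = _ratio(c.TP, c.TP + c.FP)
    spe, d3 = _ratio(c.TN, c.TN + c.FP)
    acc, d4 = _ratio(c.TP + c.TN, c.n)
    f1, d5 = _ratio(2.0 * pre * sen, pre + sen)
    return MetricsReport(
        PRE=pre,
        SEN=sen,
        SPE=spe,
        ACC=acc,
        ER=1.0 - acc,
        F1=f1,
        degenerate=any((d1, d2, d3, d4, d5)),
    )


def roc_auc(y, s) -> float:
    """Area under the ROC curve via the Mann-Whitney rank statistic
    (tied scores count one half; equivalent to the trapezoidal ROC area)."""
    y = _as_binary(y)
    s = np.asarray(s, dtype=float)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes required for ROC-AUC")
    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def pr_auc(y, s) -> float:
    """Area under the precision-recall step curve (average precision)."""
    return float(average_precision_score(_as_binary(y), np.asarray(s, dtype=float)))


def evaluate_scores(y, s, threshold: float = 0.5) -> MetricsReport:
    """Full report: threshold the scores for the confusion metrics, keep the
    continuous scores for the curve areas."""
    s = np.asarray(s, dtype=float)
    report = classification_metrics(confusion_counts(y, (s >= threshold).astype(int)))
    report.ROC_AUC = roc_auc(y, s)
    report.PR_AUC = pr_auc(y, s)
    return report


def report_csv_header(label: str = "model") -> str:
    return ",".join((label,) + REPORT_COLUMNS)


def report_csv_row(name: str, r: MetricsReport) -> str:
    buf = io.StringIO()
    vals = (r.PRE, r.SEN, r.SPE, r.ACC, r.ER, r.F1, r.ROC_AUC, r.PR_AUC)
    buf.write(name)
    for v in vals:
        buf.write("," + ("" if v is None else f"{v:.4f}"))
    return buf.getvalue()
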