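"""Binary-classification metrics for site prediction.

Threshold metrics (Sn, Sp, Pre, Acc — reported as percentages — and MCC)
are computed from the 2×2 confusion table:

    Sn  = TP/(TP+FN)        Sp  = TN/(FP+TN)
    Pre = TP/(FP+TP)        Acc = (TP+TN)/(TP+TN+FP+FN)
    MCC = (TP·TN − FP·FN) / sqrt((TP+FN)(TP+FP)(TN+FP)(TN+FN))

Any metric whose denominator is zero is reported as 0 and flagged in
``MetricsReport.zero_denominator``. Ranking metrics use scikit-learn:
AUROC is the trapezoidal area under the ROC curve (ties grouped at one
threshold), AUPRC the step-rule (average-precision) area under the
precision–recall curve — PR trapezoids would overestimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import (
    auc as _auc,
    average_precision_score,
    precision_recall_curve,
    roc_curve,
)

from .errors import ParameterError, SixmaError

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion",
    "compute_metrics",
    "roc_points",
    "auroc",
    "pr_points",
    "auprc",
    "evaluate_scores",
]

METRIC_NAMES = ("sn", "sp", "pre", "acc", "mcc", "auroc", "auprc")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    """Sn/Sp/Pre/Acc on a 0–100 scale, MCC in [−1,1], AUCs in [0,1].

    The mixed scale (percent for threshold metrics, fraction for areas)
    matches the field's reporting convention. ``auroc``/``auprc`` are None
    when no scores were supplied.
    """

    sn: float
    sp: float
    pre: float
    acc: float
    mcc: float
    counts: ConfusionCounts
    auroc: float | None = None
    auprc: float | None = None
    zero_denominator: list[str] = field(default_factory=list)

    def to_dict(self, ndigits: int = 4) -> dict:
        d = {
            "sn": round(self.sn, ndigits), "sp": round(self.sp, ndigits),
            "pre": round(self.pre, ndigits), "acc": round(self.acc, ndigits),
            "mcc": round(self.mcc, ndigits),
            "auroc": None if self.auroc is None else round(self.auroc, ndigits),
            "auprc": None if self.auprc is None else round(self.auprc, ndigits),
            "counts": {"tp": self.counts.tp, "tn": self.counts.tn,
                       "fp": self.counts.fp, "fn": self.counts.fn},
        }
        if self.zero_denominator:
            d["zero_denominator"] = list(self.zero_denominator)
        return d


def _as_binary(v, name: str) -> np.ndarray:
    arr = np.asarray(v)
    if not np.isin(arr, (0, 1)).all():
        raise ParameterError(f"{name} must contain only 0/1 values")
    return arr.astype(int).ravel()


def confusion(y_true, y_pred) -> ConfusionCounts:
    """Standard 2×2 cross-tabulation of binary truth vs. prediction."""
    yt, yp = _as_binary(y_true, "y_true"), _as_binary(y_pred, "y_pred")
    if yt.size != yp.size:
        raise ParameterError(f"length mismatch: y_true has {yt.size}, y_pred has {yp.size}")
    return ConfusionCounts(
        tp=int(np.sum((yt == 1) & (yp == 1))),
        tn=int(np.sum((yt == 0) & (yp == 0))),
        fp=int(np.sum((yt == 0) & (yp == 1))),
        fn=int(np.sum((yt == 1) & (yp == 0))),
    )


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    """Threshold metrics from confusion counts (AUCs left unset)."""
    if c.total == 0:
        raise ParameterError("cannot compute metrics from all-zero counts")
    flags: list[str] = []

    def ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            flags.append(name)
            return 0.0
        return num / den

    sn = 100.0 * ratio(c.tp, c.tp + c.fn, "sn")
    sp = 100.0 * ratio(c.tn, c.fp + c.tn, "sp")
    pre = 100.0 * ratio(c.tp, c.fp + c.tp, "pre")
    acc = 100.0 * (c.tp + c.tn) / c.total
    denom = math.sqrt(
        float(c.tp + c.fn) * (c.tp + c.fp) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if denom == 0:
        flags.append("mcc")
        mcc = 0.0
    else:
        mcc = (c.tp * c.tn - c.fp * c.fn) / denom
    return MetricsReport(sn=sn, sp=sp, pre=pre, acc=acc, mcc=mcc, counts=c,
                         zero_denominator=flags)


def roc_points(y_true, scores) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(fpr, tpr, thresholds) swept over the distinct scores, ties grouped."""
    yt = _as_binary(y_true, "y_true")
    if len(np.unique(yt)) < 2:
        raise SixmaError("AUROC is undefined when y_true contains a single class")
    fpr, tpr, thr = roc_curve(yt, np.asarray(scores, float))
    return fpr, tpr, thr


def auroc(y_true, scores) -> float:
    """Trapezoidal area under the ROC curve."""
    fpr, tpr, _ = roc_points(y_true, scores)
    return float(_auc(fpr, tpr))


def pr_points(y_true, scores) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(precision, recall, thresholds) at the distinct-score thresholds."""
    yt = _as_binary(y_true, "y_true")
    if yt.sum() == 0:
        raise SixmaError("the PR curve is undefined without positive samples")
    precision, recall, thr = precision_recall_curve(yt, np.asarray(scores, float))
    return precision, recall, thr

def auprc(y_true, scores) -> float:
    """Step-rule (average precision) area under the PR curve."""
    yt = _as_binary(y_true, "y_true")
    if yt.sum() == 0:
        raise SixmaError("the PR curve is undefined without positive samples")
    return float(average_precision_score(yt, np.asarray(scores, float)))


def evaluate_scores(y_true, scores, threshold: float = 0.5) -> MetricsReport:
    """Full report from continuous scores: threshold metrics at the given
    cutoff (label 1 iff score >= threshold) plus AUROC/AUPRC from the raw
    scores."""
    scores = np.asarray(scores, float)
    y_pred = (scores >= threshold).astype(int)
    report = compute_metrics(confusion(y_true, y_pred))
    yt = _as_binary(y_true, "y_true")
    if len(np.unique(yt)) == 2:
        report.auroc = auroc(y_true, scores)
        report.auprc = auprc(y_true, scores)
    return report


def plot_curves(y_true, scores, png_path) -> None:
    """ROC and PR curves side by side, written to *png_path*."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fpr, tpr, _ = roc_points(y_true, scores)
    precision, recall, _ = pr_points(y_true, scores)
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
    ax1.plot(fpr, tpr, label=f"AUROC = {auroc(y_true, scores):.4f}")
    ax1.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax1.set_xlabel("false-positive rate")
    ax1.set_ylabel("true-positive rate")
    ax1.legend(loc="lower right")
    ax2.step(recall, precision, where="post",
             label=f"AUPRC = {auprc(y_true, scores):.4f}")
    ax2.set_xlabel("recall")
    ax2.set_ylabel("precision")
    ax2.legend(loc="lower left")
    fig.tight_layout()
    fig.savefig(png_path, dpi=120)
    plt.close(fig)
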