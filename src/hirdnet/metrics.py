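"""Confusion-matrix construction and per-class / weighted / macro metrics.

Conventions: CM[i][j] counts samples of true class i predicted as class j.
For class i, TP = CM[i][i], FP = Σ_{j≠i} CM[j][i] (column off-diagonal),
FN = Σ_{j≠i} CM[i][j] (row off-diagonal), TN = the rest.  All rates are
expressed in percent.  Weighted aggregates weight per-class metrics by class
support Σ_j CM[i][j]; macro aggregates are unweighted means.  Weighted recall
is algebraically identical to overall accuracy trace(CM)/ΣCM.

Zero denominators (a class never predicted, or with no support) yield 0 with
the ``degenerate`` flag set rather than an error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConfusionMatrix",
    "ClassMetrics",
    "MetricsReport",
    "confusion",
    "class_metrics",
    "class_metrics_from_counts",
    "aggregate",
    "report_from_class_counts",
    "screening_metrics",
]


@dataclass
class ConfusionMatrix:
    counts: np.ndarray
    class_names: tuple[str, ...] | None = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        n = self.counts.shape[0]
        if self.counts.ndim != 2 or self.counts.shape[1] != n or n < 2:
            raise ValueError("confusion matrix must be square with n >= 2")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")
        if self.class_names is None:
            self.class_names = tuple(f"class{i}" for i in range(n))
        elif len(self.class_names) != n:
            raise ValueError("class_names length mismatch")

    @property
    def n(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def support(self, i: int) -> int:
        return int(self.counts[i].sum())

    def render(self) -> str:
        names = self.class_names
        width = max(max(len(s) for s in names), len(str(self.counts.max()))) + 2
        head = " " * width + "".join(f"{s:>{width}}" for s in names)
        rows = [head]
        for i, name in enumerate(names):
            rows.append(f"{name:>{width}}" + "".join(f"{c:>{width}}" for c in self.counts[i]))
        return "\n".join(rows)


@dataclass
class ClassMetrics:
    tp: int
    fp: int
    fn: int
    tn: int
    precision: float  # percent
    recall: float
    f1: float
    degenerate: bool = False

    @property
    def support(self) -> int:
        return self.tp + self.fn


@dataclass
class MetricsReport:
    per_class: list[ClassMetrics]
    weighted_precision: float
    weighted_recall: float
    weighted_f1: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    accuracy: float
    class_names: tuple[str, ...] = ()

    def rounded(self) -> dict:
        """Values at the conventional printed precision: per-class precision
        and recall to 1 decimal, F1 and aggregates to 2 decimals."""
        return {
            "per_class": [
                {"class": (self.class_names[i] if self.class_names else f"class{i}"),
                 "tp": m.tp, "fp": m.fp, "fn": m.fn, "tn": m.tn,
                 "precision": round(m.precision, 1), "recall": round(m.recall, 1),
                 "f1": round(m.f1, 2)}
                for i, m in enumerate(self.per_class)
            ],
            "weighted_precision": round(self.weighted_precision, 2),
            "weighted_recall": round(self.weighted_recall, 2),
            "weighted_f1": round(self.weighted_f1, 2),
            "macro_precision": round(self.macro_precision, 2),
            "macro_recall": round(self.macro_recall, 2),
            "macro_f1": round(self.macro_f1, 2),
            "accuracy": round(self.accuracy, 2),
        }


def confusion(true_labels, predicted_labels, n: int,
              class_names: tuple[str, ...] | None = None) -> ConfusionMatrix:
    t = np.asarray(true_labels, dtype=np.int64)
    p = np.asarray(predicted_labels, dtype=np.int64)
    if t.shape != p.shape:
        raise ValueError(f"label length mismatch: {t.shape} vs {p.shape}")
    if ((t < 0) | (t >= n) | (p < 0) | (p >= n)).any():
        raise ValueError(f"labels must lie in [0, {n})")
    counts = np.zeros((n, n), dtype=np.int64)
    np.add.at(counts, (t, p), 1)
    return ConfusionMatrix(counts, class_names)


def class_metrics_from_counts(tp: int, fp: int, fn: int, tn: int) -> ClassMetrics:
    """Per-class precision/recall/F1 (percent) from raw counts."""
    degenerate = False
    if tp + fp > 0:
        precision = 100.0 * tp / (tp + fp)
    else:
        precision, degenerate = 0.0, True
    if tp + fn > 0:
        recall = 100.0 * tp / (tp + fn)
    else:
        recall, degenerate = 0.0, True
    if precision + recall > 0:
        f1 = 2.0 * precision * recall / (precision + recall)
    else:
        f1, degenerate = 0.0, True
    return ClassMetrics(tp, fp, fn, tn, precision, recall, f1, degenerate)


def class_metrics(cm: ConfusionMatrix, i: int) -> ClassMetrics:
    tp = int(cm.counts[i, i])
    fp = int(cm.counts[:, i].sum() - tp)
    fn = int(cm.counts[i, :].sum() - tp)
    tn = cm.total - tp - fp - fn
    return class_metrics_from_counts(tp, fp, fn, tn)


def aggregate(cm: ConfusionMatrix) -> MetricsReport:
    per_class = [class_metrics(cm, i) for i in range(cm.n)]
    supports = np.array([cm.support(i) for i in range(cm.n)], dtype=float)
    weights = supports / supports.sum() if supports.sum() else np.zeros_like(supports)
    prec = np.array([m.precision for m in per_class])
    rec = np.array([m.recall for m in per_class])
    f1 = np.array([m.f1 for m in per_class])
    accuracy = 100.0 * np.trace(cm.counts) / cm.total if cm.total else 0.0
    return MetricsReport(
        per_class=per_class,
        weighted_precision=float(prec @ weights),
        weighted_recall=float(rec @ weights),
        weighted_f1=float(f1 @ weights),
        macro_precision=float(prec.mean()),
        macro_recall=float(rec.mean()),
        macro_f1=float(f1.mean()),
        accuracy=float(accuracy),
        class_names=cm.class_names,
    )


def report_from_class_counts(counts, class_names: tuple[str, ...] | None = None) -> MetricsReport:
    """Full report from per-class (TP, FP, FN, TN) tuples.

    Useful when only class-wise counts are available (e.g. published result
    tables) rather than the full matrix.  Supports are TP+FN; the overall
    accuracy uses the single-label identity accuracy = ΣTP / Σsupport.
    """
    per_class = [class_metrics_from_counts(*c) for c in counts]
    supports = np.array([m.support for m in per_class], dtype=float)
    total = supports.sum()
    weights = supports / total if total else np.zeros_like(supports)
    prec = np.array([m.precision for m in per_class])
    rec = np.array([m.recall for m in per_class])
    f1 = np.array([m.f1 for m in per_class])
    tp_sum = sum(m.tp for m in per_class)
    return MetricsReport(
        per_class=per_class,
        weighted_precision=float(prec @ weights),
        weighted_recall=float(rec @ weights),
        weighted_f1=float(f1 @ weights),
        macro_precision=float(prec.mean()),
        macro_recall=float(rec.mean()),
        macro_f1=float(f1.mean()),
        accuracy=100.0 * tp_sum / total if total else 0.0,
        class_names=class_names or tuple(f"class{i}" for i in range(len(per_class))),
    )


def screening_metrics(cm: ConfusionMatrix) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy) percent of a 2×2 screening matrix
    with rows/columns ordered (Normal, Abnormal)."""
    if cm.n != 2:
        raise ValueError("screening metrics require a 2×2 matrix")
    sensitivity = class_metrics(cm, 1).recall
    specificity = class_metrics(cm, 0).recall
    accuracy = 100.0 * np.trace(cm.counts) / cm.total
    return sensitivity, specificity, float(accuracy)
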