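"""Confusion-matrix metric suite and one-vs-rest ROC/AUC for the 3-class task.

Per-class TP/TN/FP/FN are obtained by one-vs-rest reduction of the 3x3
confusion matrix; accuracy and misclassification rate are global.  Headline
precision/recall/F1 use support-weighted averaging — the convention under
which weighted recall is algebraically identical to accuracy for any
confusion matrix.  Headline FNR/FPR default to macro averaging (a
``micro`` option exists).  AUC is the pairwise-concordance (Mann-Whitney)
statistic: ties between a positive and negative score count one half.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .features import N_CLASSES

__all__ = [
    "ConfusionMatrix", "MetricsRow", "confusion_matrix",
    "classification_metrics", "roc_auc_ovr",
]


@dataclass
class ConfusionMatrix:
    """3x3 integer matrix; rows = true class, columns = predicted class."""

    table: np.ndarray

    def __post_init__(self) -> None:
        self.table = np.asarray(self.table, dtype=int)
        if self.table.shape != (N_CLASSES, N_CLASSES):
            raise ValueError(f"expected {N_CLASSES}x{N_CLASSES} matrix")
        if (self.table < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return int(self.table.sum())

    def ovr_counts(self, cls: int) -> tuple[int, int, int, int]:
        """(TP, TN, FP, FN) for class ``cls`` against the rest."""
        tp = int(self.table[cls, cls])
        fn = int(self.table[cls].sum() - tp)
        fp = int(self.table[:, cls].sum() - tp)
        tn = self.n - tp - fn - fp
        return tp, tn, fp, fn


@dataclass
class MetricsRow:
    """Headline + per-class metric bundle for one evaluation.

    ``mc_rate`` is exactly ``1 - accuracy``; ``recall`` (support-weighted)
    equals ``accuracy`` by construction.
    """

    accuracy: float
    precision: float
    recall: float
    f1: float
    fnr: float
    fpr: float
    mc_rate: float
    loss: float | None = None
    auc: float | None = None
    per_class: dict = field(default_factory=dict)
    zero_division_hit: bool = False

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy, "f1": self.f1, "fnr": self.fnr,
            "fpr": self.fpr, "loss": self.loss, "mc_rate": self.mc_rate,
            "precision": self.precision, "recall": self.recall, "auc": self.auc,
        }


def confusion_matrix(y_true, y_pred) -> ConfusionMatrix:
    """Count matrix with entry (i, j) = records of true class i predicted j."""
    y_true = np.asarray(y_true, dtype=int).reshape(-1)
    y_pred = np.asarray(y_pred, dtype=int).reshape(-1)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred length mismatch")
    if y_true.size and (
        y_true.min() < 0 or y_true.max() >= N_CLASSES
        or y_pred.min() < 0 or y_pred.max() >= N_CLASSES
    ):
        raise ValueError(f"class codes must be in 0..{N_CLASSES - 1}")
    table = np.zeros((N_CLASSES, N_CLASSES), dtype=int)
    np.add.at(table, (y_true, y_pred), 1)
    return ConfusionMatrix(table)


def _safe_div(num: float, den: float) -> tuple[float, bool]:
    return (num / den, False) if den > 0 else (0.0, True)


def classification_metrics(
    cm: ConfusionMatrix,
    losses: np.ndarray | None = None,
    fnr_fpr_average: str = "macro",
) -> MetricsRow:
    """Full metric row from a confusion matrix.

    ``losses`` (per-record cross-entropies) fill the loss field with their
    mean.  Zero-denominator cells (e.g. a class never predicted) resolve to
    0 and set ``zero_division_hit``.
    """
    if fnr_fpr_average not in ("macro", "micro"):
        raise ValueError("fnr_fpr_average must be 'macro' or 'micro'")
    n = cm.n
    zero_hit = False
    per_class = {}
    support = cm.table.sum(axis=1)
    for c in range(N_CLASSES):
        tp, tn, fp, fn = cm.ovr_counts(c)
        prec, z1 = _safe_div(tp, tp + fp)
        rec, z2 = _safe_div(tp, tp + fn)
        f1, z3 = _safe_div(2 * prec * rec, prec + rec)
        fnr, z4 = _safe_div(fn, tp + fn)
        fpr, z5 = _safe_div(fp, fp + tn)
        zero_hit |= z1 or z2 or z3 or z4 or z5
        per_class[c] = {
            "tp": tp, "tn": tn, "fp": fp, "fn": fn,
            "precision": prec, "recall": rec, "f1": f1, "fnr": fnr, "fpr": fpr,
            "support": int(support[c]),
        }

    accuracy, _ = _safe_div(np.trace(cm.table), n)
    mc_rate = 1.0 - accuracy
    w = support / n if n else np.zeros(N_CLASSES)
    precision = float(sum(w[c] * per_class[c]["precision"] for c in range(N_CLASSES)))
    recall = float(sum(w[c] * per_class[c]["recall"] for c in range(N_CLASSES)))
    f1 = float(sum(w[c] * per_class[c]["f1"] for c in range(N_CLASSES)))
    if fnr_fpr_average == "macro":
        present = [c for c in range(N_CLASSES) if support[c] > 0] or list(range(N_CLASSES))
        fnr = float(np.mean([per_class[c]["fnr"] for c in present]))
        fpr = float(np.mean([per_class[c]["fpr"] for c in present]))
    else:  # micro: pool OvR counts
        tp = sum(per_class[c]["tp"] for c in range(N_CLASSES))
        fn = sum(per_class[c]["fn"] for c in range(N_CLASSES))
        fp = sum(per_class[c]["fp"] for c in range(N_CLASSES))
        tn = sum(per_class[c]["tn"] for c in range(N_CLASSES))
        fnr, _ = _safe_div(fn, tp + fn)
        fpr, _ = _safe_div(fp, fp + tn)

    loss = float(np.mean(losses)) if losses is not None and len(losses) else None
    return MetricsRow(
        accuracy=float(accuracy), precision=precision, recall=recall, f1=f1,
        fnr=fnr, fpr=fpr, mc_rate=float(mc_rate), loss=loss,
        per_class=per_class, zero_division_hit=zero_hit,
    )


def _binary_auc(y: np.ndarray, score: np.ndarray) -> float:
    """Mann-Whitney AUC: P(score_pos > score_neg) + 0.5 P(tie)."""
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    ranks = rankdata(score)  # average ranks handle ties as one half
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_auc_ovr(y_true, probas) -> dict:
    """Per-class one-vs-rest AUC plus their macro average.

    A class absent from ``y_true`` (or covering all of it) has no defined
    AUC and is reported as None; the macro average spans the defined ones.
    """
    y_true = np.asarray(y_true, dtype=int).reshape(-1)
    probas = np.asarray(probas, dtype=float)
    if probas.shape != (y_true.size, N_CLASSES):
        raise ValueError(f"probas must be (n, {N_CLASSES})")
    out: dict = {}
    defined = []
    for c in range(N_CLASSES):
        yb = (y_true == c).astype(int)
        if yb.sum() == 0 or yb.sum() == len(yb):
            out[c] = None
            continue
        out[c] = _binary_auc(yb, probas[:, c])
        defined.append(out[c])
    out["macro"] = float(np.mean(defined)) if defined else None
    return out


def roc_curve_ovr(y_true, probas, cls: int) -> tuple[np.ndarray, np.ndarray]:
    """(FPR, TPR) points for class ``cls`` vs rest, for plotting/export."""
    y_true = np.asarray(y_true, dtype=int)
    yb = (y_true == cls).astype(int)
    score = np.asarray(probas, float)[:, cls]
    order = np.argsort(-score, kind="mergesort")
    yb = yb[order]
    tps = np.cumsum(yb)
    fps = np.cumsum(1 - yb)
    # collapse threshold ties
    distinct = np.r_[np.flatnonzero(np.diff(score[order])), len(yb) - 1]
    tpr = np.r_[0.0, tps[distinct] / max(tps[-1], 1)]
    fpr = np.r_[0.0, fps[distinct] / max(fps[-1], 1)]
    return fpr, tpr
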