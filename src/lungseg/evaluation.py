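"""Pixel-level segmentation evaluation.

Confusion counts over {0,1} masks with lung as the positive class, the
derived accuracy / precision / recall / F1, the Dice similarity coefficient
2|E∩Q|/(|E|+|Q|), and a pooled-pixel ROC curve with trapezoidal AUC.
Division-by-zero cases yield NaN ("undefined") rather than raising.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn import metrics as _skm


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp,
            self.tn + other.tn, self.fn + other.fn,
        )


@dataclass(frozen=True)
class EvalReport:
    counts: ConfusionCounts
    accuracy: float
    precision: float
    recall: float
    f1: float
    dice: float
    auc: float
    n_images: int


def _check_pair(pred: np.ndarray, truth: np.ndarray):
    p, t = np.asarray(pred), np.asarray(truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs truth {t.shape}")
    return p.astype(bool), t.astype(bool)


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Pixelwise confusion counts; positive class = lung = 1."""
    p, t = _check_pair(pred, truth)
    tp = int(np.sum(p & t))
    fp = int(np.sum(p & ~t))
    fn = int(np.sum(~p & t))
    tn = int(np.sum(~p & ~t))
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def accuracy(c: ConfusionCounts) -> float:
    return _ratio(c.tp + c.tn, c.total)


def precision(c: ConfusionCounts) -> float:
    return _ratio(c.tp, c.tp + c.fp)


def recall(c: ConfusionCounts) -> float:
    return _ratio(c.tp, c.tp + c.fn)


def f1_score(c: ConfusionCounts) -> float:
    pr, re = precision(c), recall(c)
    if np.isnan(pr) or np.isnan(re) or pr + re == 0:
        return float("nan")
    return 2.0 * pr * re / (pr + re)


def metrics(c: ConfusionCounts) -> dict:
    """Accuracy, precision, recall and F1 from confusion counts."""
    return {
        "accuracy": accuracy(c),
        "precision": precision(c),
        "recall": recall(c),
        "f1": f1_score(c),
    }


def dice(pred: np.ndarray, truth: np.ndarray) -> float:
    """Dice similarity 2|E∩Q|/(|E|+|Q|); two empty masks agree perfectly (1)."""
    p, t = _check_pair(pred, truth)
    denom = int(p.sum()) + int(t.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int(np.sum(p & t)) / denom


def roc_auc(probabilities, truths) -> tuple[np.ndarray, float]:
    """Pooled-pixel ROC curve and trapezoidal AUC.

    ``probabilities`` and ``truths`` are matching lists of equal-sized maps
    (a single pair may be passed directly). All pixels are pooled into one
    score set; returns (curve, auc) where curve rows are (fpr, tpr). A
    single-class truth pool yields an empty curve and NaN.
    """
    if isinstance(probabilities, np.ndarray) and probabilities.ndim == 2:
        probabilities, truths = [probabilities], [truths]
    scores, labels = [], []
    for prob, truth in zip(probabilities, truths, strict=True):
        p, t = np.asarray(prob, dtype=float), np.asarray(truth)
        if p.shape != t.shape:
            raise ValueError(f"shape mismatch: prob {p.shape} vs truth {t.shape}")
        scores.append(p.ravel())
        labels.append(t.astype(int).ravel())
    y_score = np.concatenate(scores)
    y_true = np.concatenate(labels)
    if y_true.min() == y_true.max():
        return np.empty((0, 2)), float("nan")
    fpr, tpr, _ = _skm.roc_curve(y_true, y_score)
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


def evaluate_dataset(
    preds, truths, probabilities=None, per_image: bool = False
) -> EvalReport:
    """Dataset-level report: pooled pixel confusion (default) or per-image
    averaged metrics; AUC is always pooled over pixels when probabilities
    are given."""
    preds, truths = list(preds), list(truths)
    if len(preds) != len(truths) or not preds:
        raise ValueError("preds and truths must be non-empty and paired")
    counts = [confusion(p, t) for p, t in zip(preds, truths)]
    total = counts[0]
    for c in counts[1:]:
        total = total + c
    if per_image:
        per = [metrics(c) for c in counts]
        agg = {
            k: float(np.nanmean([m[k] for m in per]))
            for k in ("accuracy", "precision", "recall", "f1")
        }
        dsc = float(np.mean([dice(p, t) for p, t in zip(preds, truths)]))
    else:
        agg = metrics(total)
        dsc = _ratio(2 * total.tp, 2 * total.tp + total.fp + total.fn)
    if probabilities is not None:
        _, auc = roc_auc(list(probabilities), truths)
    else:
        auc = float("nan")
    return EvalReport(
        counts=total,
        accuracy=agg["accuracy"],
        precision=agg["precision"],
        recall=agg["recall"],
        f1=agg["f1"],
        dice=dsc,
        auc=auc,
        n_images=len(preds),
    )
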