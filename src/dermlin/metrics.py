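"""Evaluation metrics: pixel confusion counts, AC/JA/DI/SE/SP, ROC AUC, AP.

JA (Jaccard) is the primary segmentation metric; AUC is the primary metric
for feature extraction and classification, with FPR = 1 − SP. Undefined
ratios (zero denominators) are reported as NaN rather than silently zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .types import LESION_CLASSES, BinaryMask, LesionIndex

__all__ = [
    "ConfusionCounts", "confusion", "seg_metrics", "roc_auc",
    "average_precision", "multiclass_auc",
]


@dataclass(frozen=True)
class ConfusionCounts:
    ntp: int
    ntn: int
    nfp: int
    nfn: int

    def __post_init__(self) -> None:
        if min(self.ntp, self.ntn, self.nfp, self.nfn) < 0:
            raise ValueError("counts must be non-negative")
        if self.total == 0:
            raise ValueError("confusion counts must sum to a positive total")

    @property
    def total(self) -> int:
        return self.ntp + self.ntn + self.nfp + self.nfn


def _as_mask(m) -> np.ndarray:
    return (m.pixels if isinstance(m, BinaryMask) else np.asarray(m)).astype(bool)


def confusion(pred: BinaryMask, truth: BinaryMask) -> ConfusionCounts:
    """Pixel-wise confusion counts between predicted and true masks."""
    p, t = _as_mask(pred), _as_mask(truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs truth {t.shape}")
    return ConfusionCounts(
        ntp=int(np.sum(p & t)),
        ntn=int(np.sum(~p & ~t)),
        nfp=int(np.sum(p & ~t)),
        nfn=int(np.sum(~p & t)),
    )


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def seg_metrics(c: ConfusionCounts) -> dict[str, float]:
    """Accuracy, Jaccard, Dice, sensitivity and specificity from counts."""
    return {
        "AC": _ratio(c.ntp + c.ntn, c.total),
        "JA": _ratio(c.ntp, c.ntp + c.nfn + c.nfp),
        "DI": _ratio(2 * c.ntp, 2 * c.ntp + c.nfn + c.nfp),
        "SE": _ratio(c.ntp, c.ntp + c.nfn),
        "SP": _ratio(c.ntn, c.ntn + c.nfp),
    }


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve (TPR against FPR = 1 − SP over thresholds).

    Equals the rank statistic P(score⁺ > score⁻) + ½·P(tie). Requires both
    classes present.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("roc_auc needs both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=np.float64)))


def average_precision(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the precision–recall step curve (sum over recall
    increments of precision)."""
    labels = np.asarray(labels)
    if not np.any(labels == 1):
        raise ValueError("average_precision needs at least one positive")
    return float(average_precision_score(labels, np.asarray(scores, dtype=np.float64)))


#: Which one-vs-rest problems enter the default multiclass AUC: the two
#: clinically scored diseases (melanoma and seborrheic keratosis).
DEFAULT_SCORED_CLASSES = ("melanoma", "seborrheic_keratosis")


def multiclass_auc(
    indices: list[LesionIndex],
    truths: list[str],
    scored_classes: tuple[str, ...] = DEFAULT_SCORED_CLASSES,
) -> dict[str, float]:
    """Mean one-vs-rest ROC AUC over the scored lesion categories.

    ``truths`` are class names; returns per-class AUCs plus their unweighted
    mean under the key ``"mean"``. Pass all three categories for a macro
    3-class reduction.
    """
    if len(indices) != len(truths):
        raise ValueError("need one truth label per lesion index")
    per_class: dict[str, float] = {}
    for cls in scored_classes:
        k = LESION_CLASSES.index(cls)
        scores = np.array([li.index[k] for li in indices])
        labels = np.array([1 if t == cls else 0 for t in truths])
        per_class[cls] = roc_auc(scores, labels)
    per_class["mean"] = float(np.mean([per_class[c] for c in scored_classes]))
    return per_class
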