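"""Segmentation-quality metrics over label masks: IoU, Dice, precision, recall.

Binary masks are compared with the usual pixel-count definitions

    IoU = TP / (TP + FP + FN)          Dice = 2 TP / (2 TP + FP + FN)
    precision = TP / (TP + FP)         recall = TP / (TP + FN)

with the conventions that two empty masks score 1 on every metric (a
correctly predicted lesion-free leaf is a perfect prediction) and any other
0/0 ratio scores 0.  Multi-label masks are evaluated one-vs-rest per label
with macro averaging.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SegMetrics", "mask_metrics", "macro_metrics"]


@dataclass(frozen=True)
class SegMetrics:
    iou: float
    dice: float
    precision: float
    recall: float

    def as_dict(self, percent: bool = False) -> dict[str, float]:
        scale = 100.0 if percent else 1.0
        return {
            "iou": self.iou * scale,
            "dice": self.dice * scale,
            "precision": self.precision * scale,
            "recall": self.recall * scale,
        }


def _ratio(num: float, den: float, both_empty: bool) -> float:
    if den == 0:
        return 1.0 if both_empty else 0.0
    return num / den


def mask_metrics(pred: np.ndarray, truth: np.ndarray) -> SegMetrics:
    """Overlap metrics between two binary {0,1} masks of equal shape."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    for name, m in (("pred", pred), ("truth", truth)):
        if not np.isin(m, (0, 1)).all():
            raise ValueError(f"{name} mask must be binary (values in {{0, 1}})")
    p = pred.astype(bool)
    t = truth.astype(bool)
    tp = int((p & t).sum())
    fp = int((p & ~t).sum())
    fn = int((~p & t).sum())
    both_empty = not p.any() and not t.any()
    return SegMetrics(
        iou=_ratio(tp, tp + fp + fn, both_empty),
        dice=_ratio(2 * tp, 2 * tp + fp + fn, both_empty),
        precision=_ratio(tp, tp + fp, both_empty),
        recall=_ratio(tp, tp + fn, both_empty),
    )


def macro_metrics(
    pred: np.ndarray, truth: np.ndarray, labels: np.ndarray | None = None
) -> SegMetrics:
    """One-vs-rest metrics per label, macro-averaged.

    ``labels`` defaults to the union of labels present in either mask.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    if labels is None:
        labels = np.union1d(np.unique(pred), np.unique(truth))
    per_label = [
        mask_metrics((pred == lab).astype(np.uint8), (truth == lab).astype(np.uint8))
        for lab in labels
    ]
    return SegMetrics(
        iou=float(np.mean([m.iou for m in per_label])),
        dice=float(np.mean([m.dice for m in per_label])),
        precision=float(np.mean([m.precision for m in per_label])),
        recall=float(np.mean([m.recall for m in per_label])),
    )
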