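"""Scoring: localization accuracy, pixelwise segmentation P/R/F1,
classification accuracy.

A localization is a hit iff the predicted point falls inside the
ground-truth OD contour (i.e. the mask is 1 at the rounded location).
Segmentation is scored pixelwise; F1 is algebraically the Dice overlap.
Classification accuracy is (C_ede + C_non) / N.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EvaluationError
from .localization import ODLocation
from .retina_io import BinaryMask


@dataclass
class SegmentationScore:
    tp: int
    fp: int
    fn: int
    tn: int
    precision: float | None  # None when undefined (no positive predictions)
    recall: float | None
    f1: float | None


@dataclass
class LocalizationScore:
    n_correct: int
    n_total: int

    @property
    def acc_loc(self) -> float:
        return self.n_correct / self.n_total


@dataclass
class ClassificationScore:
    c_ede: int
    c_non: int
    n: int

    @property
    def acc_classify(self) -> float:
        return (self.c_ede + self.c_non) / self.n


def localization_hit(pred: ODLocation, gt_mask: BinaryMask) -> bool:
    """Hit iff the ground-truth mask is 1 at the rounded predicted center."""
    if not gt_mask.pixels.any():
        raise EvaluationError("empty ground-truth mask")
    h, w = gt_mask.shape
    r = int(round(pred.center[0]))
    c = int(round(pred.center[1]))
    if not (0 <= r < h and 0 <= c < w):
        return False
    return bool(gt_mask.pixels[r, c] == 1)


def score_localization(preds: list[ODLocation], gt_masks: list[BinaryMask]) -> LocalizationScore:
    if len(preds) != len(gt_masks) or not preds:
        raise EvaluationError("prediction/ground-truth length mismatch or empty")
    hits = sum(localization_hit(p, m) for p, m in zip(preds, gt_masks))
    return LocalizationScore(n_correct=int(hits), n_total=len(preds))


def score_segmentation(pred: BinaryMask, gt: BinaryMask) -> SegmentationScore:
    if pred.shape != gt.shape:
        raise EvaluationError(f"mask shapes differ: {pred.shape} vs {gt.shape}")
    p = pred.pixels.astype(bool)
    g = gt.pixels.astype(bool)
    tp = int((p & g).sum())
    fp = int((p & ~g).sum())
    fn = int((~p & g).sum())
    tn = int((~p & ~g).sum())
    precision = tp / (tp + fp) if tp + fp > 0 else None
    recall = tp / (tp + fn) if tp + fn > 0 else None
    if precision is not None and recall is not None and precision + recall > 0:
        f1 = 2 * precision * recall / (precision + recall)
    elif precision == recall == 0.0:
        f1 = 0.0
    else:
        f1 = None
    return SegmentationScore(tp=tp, fp=fp, fn=fn, tn=tn,
                             precision=precision, recall=recall, f1=f1)


def score_classification(preds: list[str], labels: list[str]) -> ClassificationScore:
    if len(preds) != len(labels):
        raise EvaluationError("prediction/label length mismatch")
    if not preds:
        raise EvaluationError("empty predictions")
    c_ede = sum(1 for p, t in zip(preds, labels) if p == t == "edematous")
    c_non = sum(1 for p, t in zip(preds, labels) if p == t == "non_edematous")
    return ClassificationScore(c_ede=c_ede, c_non=c_non, n=len(preds))


def mean_scores(scores: list[SegmentationScore]) -> dict[str, float | None]:
    """Average P/R/F1 over cases, excluding undefined entries (with a count)."""
    out: dict[str, float | None] = {}
    for key in ("precision", "recall", "f1"):
        vals = [getattr(s, key) for s in scores if getattr(s, key) is not None]
        out[key] = float(np.mean(vals)) if vals else None
        out[f"n_undefined_{key}"] = len(scores) - len(vals)
    return out
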