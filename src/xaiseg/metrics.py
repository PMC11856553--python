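"""Segmentation agreement metrics: Dice coefficient and IoU (Jaccard).

For binary masks P (predicted) and T (truth):

    Dice D = 2|P ∩ T| / (|P| + |T|)        IoU J = |P ∩ T| / |P ∪ T|

with the algebraic identity J = D / (2 − D).  A pair of empty masks scores
1.0 by convention — a correct "nothing to segment" prediction is perfect
agreement, which matters for tumour-free slices.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

__all__ = ["MetricsResult", "evaluate_masks", "iou_from_dice", "metrics_report"]


@dataclasses.dataclass(frozen=True)
class MetricsResult:
    dice: float
    iou: float
    tp: int
    fp: int
    fn: int
    tn: int


def evaluate_masks(predicted: np.ndarray, truth: np.ndarray) -> MetricsResult:
    """Pixel-wise confusion counts plus Dice and IoU for one mask pair."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise ValueError(
            f"shape mismatch: {predicted.shape} vs {truth.shape}")
    p = predicted.astype(bool)
    t = truth.astype(bool)
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = int(np.count_nonzero(~p & ~t))
    if tp + fp + fn == 0:  # both empty: perfect agreement
        dice = iou = 1.0
    else:
        dice = 2.0 * tp / (2.0 * tp + fp + fn)
        iou = tp / (tp + fp + fn)
    return MetricsResult(dice=dice, iou=iou, tp=tp, fp=fp, fn=fn, tn=tn)


def iou_from_dice(d: float) -> float:
    """IoU implied by a Dice score: J = D / (2 − D)."""
    if not 0.0 <= d <= 1.0:
        raise ValueError("Dice score must lie in [0, 1]")
    return d / (2.0 - d)


def metrics_report(results: dict) -> pd.DataFrame:
    """Tabulate {image_id: MetricsResult} as a tidy report."""
    rows = [{"image_id": k, **dataclasses.asdict(v)}
            for k, v in results.items()]
    return pd.DataFrame(rows, columns=["image_id", "dice", "iou",
                                       "tp", "fp", "fn", "tn"])
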