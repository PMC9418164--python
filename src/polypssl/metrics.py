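"""Segmentation evaluation: Dice, Jaccard, accuracy, recall, precision.

Scores are computed per image from confusion counts at a binarisation
threshold and macro-averaged across the set.  An image where a score's
denominator is empty scores 1 when the prediction is also empty (both sides
agree there is nothing) and 0 otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["EvalResult", "evaluate", "dice_coefficient", "per_image_scores"]


@dataclass
class EvalResult:
    dice: float
    jaccard: float
    accuracy: float
    recall: float
    precision: float
    n_images: int
    threshold: float = 0.5

    def to_dict(self) -> dict:
        return {
            "dice": self.dice, "jaccard": self.jaccard, "accuracy": self.accuracy,
            "recall": self.recall, "precision": self.precision,
            "n_images": self.n_images, "threshold": self.threshold,
        }


def _safe_ratio(num: float, den: float, pred_empty_and_true_empty: bool) -> float:
    if den == 0:
        return 1.0 if pred_empty_and_true_empty else 0.0
    return num / den


def _scores_one(pred_bin: np.ndarray, truth: np.ndarray) -> dict:
    tp = float(np.count_nonzero(pred_bin & truth))
    fp = float(np.count_nonzero(pred_bin & ~truth))
    fn = float(np.count_nonzero(~pred_bin & truth))
    tn = float(pred_bin.size - tp - fp - fn)
    both_empty = (tp + fp == 0) and (tp + fn == 0)
    return {
        "dice": _safe_ratio(2 * tp, 2 * tp + fp + fn, both_empty),
        "jaccard": _safe_ratio(tp, tp + fp + fn, both_empty),
        "accuracy": (tp + tn) / pred_bin.size,
        "recall": _safe_ratio(tp, tp + fn, tp + fp == 0),
        "precision": _safe_ratio(tp, tp + fp, tp + fn == 0),
    }


def dice_coefficient(pred: np.ndarray, truth: np.ndarray, threshold: float = 0.5) -> float:
    """Dice overlap of one probability map against one binary mask."""
    return _scores_one(np.asarray(pred) >= threshold, np.asarray(truth) > 0.5)["dice"]


def per_image_scores(pred_maps, truths, threshold: float = 0.5) -> pd.DataFrame:
    if len(pred_maps) != len(truths):
        raise ValueError(f"got {len(pred_maps)} predictions for {len(truths)} masks")
    if len(pred_maps) == 0:
        raise ValueError("nothing to evaluate")
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    rows = []
    for pred, truth in zip(pred_maps, truths):
        pred = np.asarray(pred)
        truth = np.asarray(truth) > 0.5
        if pred.shape != truth.shape:
            raise ValueError("prediction/mask shape mismatch")
        rows.append(_scores_one(pred >= threshold, truth))
    return pd.DataFrame(rows)


def evaluate(pred_maps, truths, threshold: float = 0.5) -> EvalResult:
    """Macro-averaged five-metric evaluation of probability maps vs masks."""
    df = per_image_scores(pred_maps, truths, threshold)
    m = df.mean()
    return EvalResult(
        dice=float(m["dice"]), jaccard=float(m["jaccard"]), accuracy=float(m["accuracy"]),
        recall=float(m["recall"]), precision=float(m["precision"]),
        n_images=len(df), threshold=threshold,
    )
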