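"""Pixel-level evaluation: precision/recall, PR curves, AP and mAP.

Precision and recall are set-cardinality ratios over foreground pixels:
``Prec = |SF ∩ GF| / |SF|`` and ``Rec = |SF ∩ GF| / |GF|`` where SF is the
predicted and GF the ground-truth foreground set. AP sweeps the score
threshold over every distinct predicted probability, applies the monotone
(non-increasing) precision envelope, and integrates precision over recall;
mAP is the arithmetic mean of per-class APs.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MetricReport", "precision_recall", "average_precision",
    "mean_average_precision", "binarize", "evaluate_model",
]


@dataclass
class MetricReport:
    """Evaluation summary for one run."""

    precision: float
    recall: float
    ap_per_class: list
    map: float
    pr_points: list = field(default_factory=list)  # [(recall, precision), ...]
    dice: "float | None" = None

    def to_json(self) -> str:
        return json.dumps({
            "precision": self.precision,
            "recall": self.recall,
            "ap_per_class": self.ap_per_class,
            "mAP": self.map,
            "dice": self.dice,
        }, indent=2)

    def pr_to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["recall", "precision"])
            writer.writerows(self.pr_points)


def _as_binary(mask, name):
    arr = np.asarray(mask)
    vals = np.unique(arr)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError(f"{name} must be binary 0/1, found values {vals[:5]}")
    return arr.astype(bool)


def precision_recall(pred_mask, gt_mask):
    """Pixel-set precision and recall of a binary prediction.

    Conventions for empty sets: an empty prediction has precision 1 when
    the ground truth is empty too, else 0; recall with an empty ground
    truth is 1 for an empty prediction and NaN (undefined) otherwise.
    """
    pred = _as_binary(pred_mask, "pred_mask")
    gt = _as_binary(gt_mask, "gt_mask")
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {gt.shape}")
    tp = np.logical_and(pred, gt).sum()
    n_pred, n_gt = pred.sum(), gt.sum()
    if n_pred == 0:
        precision = 1.0 if n_gt == 0 else 0.0
    else:
        precision = float(tp / n_pred)
    if n_gt == 0:
        recall = 1.0 if n_pred == 0 else float("nan")
    else:
        recall = float(tp / n_gt)
    return precision, recall


def average_precision(pred_probs, gt_mask):
    """AP and PR points from a probability map against a binary mask.

    The PR curve is swept over every distinct score; AP integrates the
    monotone non-increasing precision envelope over recall (so AP is
    invariant to strictly monotone transforms of the scores).
    """
    probs = np.asarray(pred_probs, dtype=np.float64).ravel()
    gt = _as_binary(gt_mask, "gt_mask").ravel()
    if probs.shape != gt.shape:
        raise ValueError(f"shape mismatch {probs.shape} vs {gt.shape}")
    n_pos = gt.sum()
    if n_pos == 0:
        raise ValueError("AP is undefined for an empty ground-truth mask")

    order = np.argsort(-probs, kind="stable")
    sorted_scores = probs[order]
    sorted_gt = gt[order].astype(np.float64)
    tp = np.cumsum(sorted_gt)
    fp = np.cumsum(1.0 - sorted_gt)
    # keep only the last index of each tied score block (threshold semantics)
    distinct = np.r_[sorted_scores[1:] != sorted_scores[:-1], True]
    tp, fp = tp[distinct], fp[distinct]
    precision = tp / (tp + fp)
    recall = tp / n_pos
    pr_points = list(zip(recall.tolist(), precision.tolist()))

    # monotone envelope, integrate over recall
    mpre = np.maximum.accumulate(precision[::-1])[::-1]
    mrec = np.r_[0.0, recall]
    ap = float(np.sum((mrec[1:] - mrec[:-1]) * mpre))
    return ap, pr_points


def mean_average_precision(ap_per_class) -> float:
    ap = list(ap_per_class)
    if not ap:
        raise ValueError("mAP of an empty class list is undefined")
    return float(np.mean(ap))


def binarize(prob_map, threshold: float = 0.5):
    """Threshold a probability map to a binary {0,1} mask."""
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie in (0,1), got {threshold}")
    return (np.asarray(prob_map) >= threshold).astype(np.uint8)


def evaluate_model(model, dataset, threshold: float = 0.5,
                   batch_size: int = 8) -> MetricReport:
    """Run the model over (image, mask[, class]) samples and summarize.

    AP is computed per class over the pooled pixels of that class's
    samples; overall precision/recall/Dice use the binarized maps at
    ``threshold``. Samples whose class lacks foreground pixels are skipped
    for AP (AP is undefined there).
    """
    from .autodiff import no_grad
    from .training import _stack, dice_coefficient

    X, Y = _stack(dataset)
    classes = [getattr(item, "class_id", 0) for item in dataset]
    model.eval()
    probs = []
    with no_grad():
        for i in range(0, X.shape[0], batch_size):
            probs.append(model(X[i:i + batch_size]).data)
    P = np.concatenate(probs, axis=0)
    pred = binarize(P, threshold)
    gt = Y.astype(np.uint8)
    precision, recall = precision_recall(pred, gt)
    dice = dice_coefficient(pred, gt)

    ap_per_class, pr_points = [], []
    for cls in sorted(set(classes)):
        sel = [i for i, c in enumerate(classes) if c == cls]
        gts = gt[sel]
        if gts.sum() == 0:
            continue
        ap, points = average_precision(P[sel], gts)
        ap_per_class.append(ap)
        if not pr_points:
            pr_points = points
    mapv = mean_average_precision(ap_per_class) if ap_per_class else float("nan")
    return MetricReport(precision=precision, recall=recall,
                        ap_per_class=ap_per_class, map=mapv,
                        pr_points=pr_points, dice=dice)
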