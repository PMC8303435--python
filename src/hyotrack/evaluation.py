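"""Evaluation metrics: pixelwise classification scores, ROC-AUC, bounding-box
average precision at a fixed IoU threshold, and trajectory RMSE.

Pixel metrics are micro-averaged (pooled counts over the whole evaluation
set) and also reported per class.  Average precision uses all-point
interpolation of the precision-recall curve with greedy confidence-ordered
matching (one detection may claim at most one ground-truth box per frame,
requiring IoU >= threshold); mAP is the unweighted mean over the three
object classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from sklearn.metrics import roc_auc_score

from .extraction import CLASS_NAMES, OBJECT_CLASSES

Box = Tuple[float, float, float, float]  # half-open (xmin, ymin, xmax, ymax)


@dataclass
class PixelConfusion:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def _safe_ratio(num: float, den: float, both_empty: bool) -> float:
    if den == 0:
        return 1.0 if both_empty else 0.0
    return num / den


def confusion_counts(pred: np.ndarray, truth: np.ndarray,
                     class_id: int) -> PixelConfusion:
    p = np.asarray(pred) == class_id
    t = np.asarray(truth) == class_id
    return PixelConfusion(
        tp=int((p & t).sum()), fp=int((p & ~t).sum()),
        fn=int((~p & t).sum()), tn=int((~p & ~t).sum()))


def metrics_from_confusion(c: PixelConfusion) -> Dict[str, float]:
    both_empty_pos = (c.tp + c.fn == 0) and (c.tp + c.fp == 0)
    return {
        "accuracy": _safe_ratio(c.tp + c.tn, c.total, both_empty=False),
        "recall": _safe_ratio(c.tp, c.tp + c.fn, both_empty_pos),
        "precision": _safe_ratio(c.tp, c.tp + c.fp, both_empty_pos),
        "dice": _safe_ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn, both_empty_pos),
    }


def pixel_metrics(pred: np.ndarray, truth: np.ndarray) -> Dict[str, Dict[str, float]]:
    """Accuracy/recall/precision/Dice per object class and pooled.

    The pooled row treats any object pixel (hyoid, spine or coin) as the
    positive class, micro-averaging counts over the whole evaluation set.
    """
    pred, truth = np.asarray(pred), np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    out: Dict[str, Dict[str, float]] = {}
    pooled = PixelConfusion()
    for cls in OBJECT_CLASSES:
        c = confusion_counts(pred, truth, cls)
        out[CLASS_NAMES[cls]] = metrics_from_confusion(c)
        pooled.tp += c.tp
        pooled.fp += c.fp
        pooled.fn += c.fn
        pooled.tn += c.tn
    out["pooled"] = metrics_from_confusion(pooled)
    return out


def roc_auc(scores: np.ndarray, truth: np.ndarray) -> float:
    """Area under the ROC curve of per-pixel positive-class scores.

    Equivalent to the Mann-Whitney rank statistic with midranks for ties.
    """
    truth = np.asarray(truth).ravel().astype(bool)
    scores = np.asarray(scores).ravel()
    if truth.all() or (~truth).all():
        raise ValueError("ROC-AUC requires both classes present in the truth")
    return float(roc_auc_score(truth, scores))


def iou(box_a: Box, box_b: Box) -> float:
    """Intersection over union of two half-open boxes (0 when disjoint)."""
    ax0, ay0, ax1, ay1 = box_a
    bx0, by0, bx1, by1 = box_b
    area_a = max(0.0, ax1 - ax0) * max(0.0, ay1 - ay0)
    area_b = max(0.0, bx1 - bx0) * max(0.0, by1 - by0)
    if area_a == 0 or area_b == 0:
        warnings.warn("degenerate (zero-area) box in IoU", stacklevel=2)
        return 0.0
    ix = max(0.0, min(ax1, bx1) - max(ax0, bx0))
    iy = max(0.0, min(ay1, by1) - max(ay0, by0))
    inter = ix * iy
    return inter / (area_a + area_b - inter)


def average_precision(detections: Sequence[Tuple[int, Box, float]],
                      truths: Sequence[Tuple[int, Box]],
                      iou_threshold: float = 0.5) -> float:
    """All-point-interpolated AP for one class.

    detections: (frame, box, confidence) triples; truths: (frame, box) pairs.
    Detections are processed in descending confidence; each may match at most
    one unmatched truth in its frame (best IoU, IoU >= threshold).
    """
    if len(truths) == 0:
        raise ValueError("average precision needs at least one ground-truth box")
    truth_by_frame: Dict[int, List[Box]] = {}
    for f, b in truths:
        truth_by_frame.setdefault(f, []).append(b)
    matched = {f: [False] * len(bs) for f, bs in truth_by_frame.items()}
    order = sorted(range(len(detections)), key=lambda i: -detections[i][2])
    tp = np.zeros(len(detections))
    fp = np.zeros(len(detections))
    for rank, i in enumerate(order):
        f, box, _ = detections[i]
        best_iou, best_j = 0.0, -1
        for j, tb in enumerate(truth_by_frame.get(f, [])):
            if matched[f][j]:
                continue
            v = iou(box, tb)
            if v > best_iou:
                best_iou, best_j = v, j
        if best_j >= 0 and best_iou >= iou_threshold:
            matched[f][best_j] = True
            tp[rank] = 1
        else:
            fp[rank] = 1
    if len(detections) == 0:
        return 0.0
    tp_cum = np.cumsum(tp)
    fp_cum = np.cumsum(fp)
    recall = tp_cum / len(truths)
    precision = tp_cum / np.maximum(tp_cum + fp_cum, 1e-12)
    # precision envelope, then area under the stepwise PR curve
    mrec = np.concatenate([[0.0], recall, [recall[-1]]])
    mpre = np.concatenate([[1.0], precision, [0.0]])
    for i in range(len(mpre) - 2, -1, -1):
        mpre[i] = max(mpre[i], mpre[i + 1])
    idx = np.flatnonzero(np.diff(mrec) > 0)
    return float(np.sum((mrec[idx + 1] - mrec[idx]) * mpre[idx + 1]))


def mean_average_precision(per_class_detections: Mapping[int, Sequence[Tuple[int, Box, float]]],
                           per_class_truths: Mapping[int, Sequence[Tuple[int, Box]]],
                           iou_threshold: float = 0.5) -> Tuple[float, Dict[str, float]]:
    """mAP over the object classes; returns (mAP, per-class AP dict)."""
    aps = {}
    for cls in OBJECT_CLASSES:
        aps[CLASS_NAMES[cls]] = average_precision(
            per_class_detections.get(cls, []), per_class_truths[cls], iou_threshold)
    return float(np.mean(list(aps.values()))), aps


def distance_rmse(pred_frames: Sequence[int], pred_values: Sequence[float],
                  truth_frames: Sequence[int], truth_values: Sequence[float]) -> float:
    """RMSE between predicted and true per-frame distances, on the frames
    retained by both (intersection)."""
    pmap = dict(zip(pred_frames, pred_values))
    tmap = dict(zip(truth_frames, truth_values))
    common = sorted(set(pmap) & set(tmap))
    if not common:
        raise ValueError("no common retained frames between prediction and truth")
    err = np.array([pmap[f] - tmap[f] for f in common], dtype=float)
    return float(np.sqrt(np.mean(err ** 2)))


def trajectory_rmse(pred_traj, truth_traj) -> Dict[str, float]:
    """Per-direction RMSE between two trajectories (horizontal, vertical,
    diagonal), each referenced to its own first retained frame."""
    out = {}
    for name, pv, tv in (
        ("horizontal", pred_traj.ndx_mm - pred_traj.ndx_mm[0],
         truth_traj.ndx_mm - truth_traj.ndx_mm[0]),
        ("vertical", pred_traj.ndy_mm - pred_traj.ndy_mm[0],
         truth_traj.ndy_mm - truth_traj.ndy_mm[0]),
        ("diagonal", np.hypot(pred_traj.ndx_mm - pred_traj.ndx_mm[0],
                              pred_traj.ndy_mm - pred_traj.ndy_mm[0]),
         np.hypot(truth_traj.ndx_mm - truth_traj.ndx_mm[0],
                  truth_traj.ndy_mm - truth_traj.ndy_mm[0])),
    ):
        out[name] = distance_rmse(pred_traj.retained_frames, pv,
                                  truth_traj.retained_frames, tv)
    return out
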