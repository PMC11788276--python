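"""Detection evaluation: IoU, NMS, precision/recall/F1, AP, mAP@0.5,
confusion matrix.

Conventions: boxes are pixel ``(x1, y1, x2, y2)``; internal precision/recall
values live in [0, 1] (a percentage is a display convention); detections match
a ground truth greedily in confidence order at an IoU threshold, each ground
truth at most once; AP integrates the all-point-interpolated precision
envelope over recall; mAP is the plain mean of per-class APs, where a class
with neither ground truth nor detections is undefined and excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


@dataclass
class Detection:
    class_id: int
    conf: float
    box: np.ndarray  # (4,) pixel xyxy


@dataclass
class MetricCounts:
    TP: int = 0
    FP: int = 0
    FN: int = 0
    TN: int = 0


@dataclass
class APTable:
    per_class: dict[int, float] = field(default_factory=dict)

    @property
    def C(self) -> int:
        return len(self.per_class)

    @property
    def mAP(self) -> float:
        return mean_ap(self)


def iou(a, b) -> float:
    """Intersection over union of two pixel xyxy boxes (symmetric)."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a[2] <= a[0] or a[3] <= a[1] or b[2] <= b[0] or b[3] <= b[1]:
        warnings.warn("degenerate box in IoU; returning 0", stacklevel=2)
        return 0.0
    ix = max(0.0, min(a[2], b[2]) - max(a[0], b[0]))
    iy = max(0.0, min(a[3], b[3]) - max(a[1], b[1]))
    inter = ix * iy
    union = ((a[2] - a[0]) * (a[3] - a[1]) + (b[2] - b[0]) * (b[3] - b[1]) - inter)
    return float(inter / union) if union > 0 else 0.0


def iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """(n, m) IoU between two box arrays (vectorised)."""
    a = np.asarray(a, dtype=np.float64).reshape(-1, 4)
    b = np.asarray(b, dtype=np.float64).reshape(-1, 4)
    ix = (np.minimum(a[:, None, 2], b[None, :, 2])
          - np.maximum(a[:, None, 0], b[None, :, 0])).clip(min=0)
    iy = (np.minimum(a[:, None, 3], b[None, :, 3])
          - np.maximum(a[:, None, 1], b[None, :, 1])).clip(min=0)
    inter = ix * iy
    area_a = ((a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])).clip(min=0)
    area_b = ((b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])).clip(min=0)
    union = area_a[:, None] + area_b[None, :] - inter
    return np.where(union > 0, inter / union, 0.0)


def nms(boxes: np.ndarray, scores: np.ndarray, iou_thr: float = 0.7,
        class_ids: np.ndarray | None = None) -> list[int]:
    """Greedy descending-score suppression; class-wise when ids are given."""
    boxes = np.asarray(boxes, dtype=np.float64).reshape(-1, 4)
    scores = np.asarray(scores, dtype=np.float64)
    if len(boxes) != len(scores):
        raise ValueError("boxes and scores length mismatch")
    if class_ids is not None:
        keep: list[int] = []
        for c in np.unique(class_ids):
            idx = np.flatnonzero(class_ids == c)
            keep.extend(idx[j] for j in nms(boxes[idx], scores[idx], iou_thr))
        return sorted(keep, key=lambda i: -scores[i])
    order = np.argsort(-scores, kind="stable")
    kept: list[int] = []
    ious = iou_matrix(boxes, boxes)
    suppressed = np.zeros(len(boxes), dtype=bool)
    for i in order:
        if suppressed[i]:
            continue
        kept.append(int(i))
        suppressed |= ious[i] > iou_thr
    return kept


def precision_recall_f1(counts: MetricCounts) -> tuple[float, float, float]:
    """P = TP/(TP+FP), R = TP/(TP+FN), F1 = 2PR/(P+R); 0 when undefined."""
    p = counts.TP / (counts.TP + counts.FP) if counts.TP + counts.FP else 0.0
    r = counts.TP / (counts.TP + counts.FN) if counts.TP + counts.FN else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f1


def match_detections(dets: list[Detection], gt_boxes: np.ndarray,
                     iou_thr: float = 0.5) -> np.ndarray:
    """Greedy confidence-ordered matching: boolean TP flag per detection
    (in the order given); each ground truth matches at most once."""
    flags = np.zeros(len(dets), dtype=bool)
    if len(gt_boxes) == 0 or not dets:
        return flags
    order = sorted(range(len(dets)), key=lambda i: -dets[i].conf)
    used = np.zeros(len(gt_boxes), dtype=bool)
    M = iou_matrix(np.stack([d.box for d in dets]), gt_boxes)
    for i in order:
        cand = np.where(~used, M[i], -1.0)
        j = int(cand.argmax())
        if cand[j] >= iou_thr:
            used[j] = True
            flags[i] = True
    return flags


def average_precision(confidences: np.ndarray, is_tp: np.ndarray,
                      n_gt: int) -> float | None:
    """All-point-interpolated AP from scored, matched detections of one class.

    Returns None (undefined) when there is neither ground truth nor detection.
    """
    confidences = np.asarray(confidences, dtype=np.float64)
    is_tp = np.asarray(is_tp, dtype=bool)
    if n_gt == 0 and len(confidences) == 0:
        return None
    if n_gt == 0 or len(confidences) == 0:
        return 0.0
    order = np.argsort(-confidences, kind="stable")
    tp = np.cumsum(is_tp[order])
    fp = np.cumsum(~is_tp[order])
    recall = tp / n_gt
    precision = tp / (tp + fp)
    # precision envelope: monotone non-increasing from the right
    env = np.maximum.accumulate(precision[::-1])[::-1]
    r_prev = np.concatenate(([0.0], recall[:-1]))
    return float(np.sum((recall - r_prev) * env))


def mean_ap(table: APTable) -> float:
    """Arithmetic mean of the defined per-class APs."""
    if not table.per_class:
        raise ValueError("mAP over an empty AP table")
    return float(np.mean(list(table.per_class.values())))


def evaluate_detections(dets_by_image: list[list[Detection]],
                        gts_by_image: list[list[tuple[int, np.ndarray]]],
                        iou_thr: float = 0.5,
                        num_classes: int | None = None
                        ) -> tuple[APTable, MetricCounts]:
    """Dataset-level AP table and pooled counts at one IoU threshold.

    `gts_by_image` holds (class_id, xyxy box) pairs per image. Matching is
    per image and per class. Pooled counts use every detection (TP or FP) and
    every unmatched ground truth (FN).
    """
    classes: set[int] = set()
    for gts in gts_by_image:
        classes.update(c for c, _ in gts)
    for dets in dets_by_image:
        classes.update(d.class_id for d in dets)
    if num_classes is not None:
        classes.update(range(num_classes))
    scores: dict[int, list[float]] = {c: [] for c in classes}
    flags: dict[int, list[bool]] = {c: [] for c in classes}
    n_gt = {c: 0 for c in classes}
    for dets, gts in zip(dets_by_image, gts_by_image):
        for c in classes:
            dc = [d for d in dets if d.class_id == c]
            gc = np.array([b for cc, b in gts if cc == c]).reshape(-1, 4)
            n_gt[c] += len(gc)
            tp = match_detections(dc, gc, iou_thr)
            scores[c].extend(d.conf for d in dc)
            flags[c].extend(bool(t) for t in tp)
    table = APTable()
    counts = MetricCounts()
    for c in classes:
        ap = average_precision(np.array(scores[c]), np.array(flags[c]), n_gt[c])
        if ap is not None:
            table.per_class[c] = ap
        tp = sum(flags[c])
        counts.TP += tp
        counts.FP += len(flags[c]) - tp
        counts.FN += n_gt[c] - tp
    return table, counts


def confusion_matrix(dets_by_image: list[list[Detection]],
                     gts_by_image: list[list[tuple[int, np.ndarray]]],
                     num_classes: int, iou_thr: float = 0.5,
                     conf_thr: float = 0.25) -> np.ndarray:
    """(C+1) x (C+1) counts; rows = ground-truth class, cols = predicted class,
    the extra index C = background. Matching is class-agnostic greedy IoU."""
    cm = np.zeros((num_classes + 1, num_classes + 1), dtype=np.int64)
    bg = num_classes
    for dets, gts in zip(dets_by_image, gts_by_image):
        dets = [d for d in dets if d.conf >= conf_thr]
        gt_boxes = np.array([b for _, b in gts]).reshape(-1, 4)
        used = np.zeros(len(gts), dtype=bool)
        order = sorted(range(len(dets)), key=lambda i: -dets[i].conf)
        M = (iou_matrix(np.stack([d.box for d in dets]), gt_boxes)
             if dets and len(gts) else np.zeros((len(dets), len(gts))))
        for i in order:
            cand = np.where(~used, M[i], -1.0) if len(gts) else np.array([])
            j = int(cand.argmax()) if cand.size else -1
            if j >= 0 and cand[j] >= iou_thr:
                used[j] = True
                cm[gts[j][0], dets[i].class_id] += 1
            else:
                cm[bg, dets[i].class_id] += 1
        for j, (c, _) in enumerate(gts):
            if not used[j]:
                cm[c, bg] += 1
    return cm


def summary_report(table: APTable, counts: MetricCounts,
                   per_class_f1: list[float] | None = None) -> dict[str, float]:
    """Headline fields of a detection report: F1 Score, Precision, Recall,
    mAP50 (pooled P/R; F1 from the pooled pair unless a macro list is given)."""
    p, r, f1 = precision_recall_f1(counts)
    if per_class_f1:
        f1 = float(np.mean(per_class_f1))
    return {"F1 Score": f1, "Precision": p, "Recall": r, "mAP50": table.mAP}
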