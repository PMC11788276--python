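"""Independent brute-force reference implementations used by the test suite.

Everything here is deliberately written as plain loops over definitions,
sharing no code with the package's vectorised implementations.
"""

import numpy as np


def iou_scalar(a, b):
    ix = max(0.0, min(a[2], b[2]) - max(a[0], b[0]))
    iy = max(0.0, min(a[3], b[3]) - max(a[1], b[1]))
    inter = ix * iy
    area = ((a[2] - a[0]) * (a[3] - a[1]) + (b[2] - b[0]) * (b[3] - b[1])
            - inter)
    return inter / area if area > 0 else 0.0


def brute_nms(boxes, scores, thr):
    """O(n^2) greedy suppression by descending score."""
    order = np.argsort(-np.asarray(scores), kind="stable")
    kept = []
    for i in order:
        if all(iou_scalar(boxes[i], boxes[j]) <= thr for j in kept):
            kept.append(int(i))
    return kept


def brute_ap(confs, tps, n_gt):
    """Exhaustive step-sum PR integration with right-max interpolation."""
    order = np.argsort(-np.asarray(confs), kind="stable")
    tp = fp = 0
    pts = []
    for i in order:
        tp += bool(tps[i])
        fp += not tps[i]
        pts.append((tp / n_gt, tp / (tp + fp)))
    ap = 0.0
    prev_r = 0.0
    for k, (r, _) in enumerate(pts):
        p_env = max(p for _, p in pts[k:])
        ap += (r - prev_r) * p_env
        prev_r = r
    return ap


def brute_match(dets, gt_boxes, thr):
    """Greedy confidence-ordered one-to-one matching; TP flag per detection."""
    flags = [False] * len(dets)
    used = [False] * len(gt_boxes)
    for i in sorted(range(len(dets)), key=lambda i: -dets[i].conf):
        best, best_iou = -1, -1.0
        for j, g in enumerate(gt_boxes):
            if used[j]:
                continue
            v = iou_scalar(dets[i].box, g)
            if v > best_iou:
                best, best_iou = j, v
        if best >= 0 and best_iou >= thr:
            used[best] = True
            flags[i] = True
    return flags


def brute_confusion(dets_by_image, gts_by_image, num_classes, iou_thr,
                    conf_thr):
    cm = np.zeros((num_classes + 1, num_classes + 1), dtype=np.int64)
    bg = num_classes
    for dets, gts in zip(dets_by_image, gts_by_image):
        dets = [d for d in dets if d.conf >= conf_thr]
        used = [False] * len(gts)
        for i in sorted(range(len(dets)), key=lambda i: -dets[i].conf):
            best, best_iou = -1, -1.0
            for j, (_, g) in enumerate(gts):
                if used[j]:
                    continue
                v = iou_scalar(dets[i].box, g)
                if v > best_iou:
                    best, best_iou = j, v
            if best >= 0 and best_iou >= iou_thr:
                used[best] = True
                cm[gts[best][0], dets[i].class_id] += 1
            else:
                cm[bg, dets[i].class_id] += 1
        for j, (c, _) in enumerate(gts):
            if not used[j]:
                cm[c, bg] += 1
    return cm
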