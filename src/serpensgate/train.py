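"""Desk-scale training and evaluation of the assembled detector.

The loss couples three terms in the conventional 7.5 : 0.5 : 1.5 weighting —
a Wise-IoU box regression term (distance-attention factor over the smallest
enclosing box and a dynamic, outlier-degree-driven focusing coefficient with
hyperparameters alpha and delta), binary cross-entropy on the class logits
against task-aligned soft targets, and a distribution-focal term on the
per-side bin distributions. Assignment is task-aligned top-k (alignment
cls^0.5 * IoU^6, k = 10, centre-inside), the optimiser SGD with momentum and
weight decay, and the mosaic augmentation is switched off for the final
`close_mosaic` epochs of a run.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from . import nn
from .data_io import Annotation, DatasetIndex, letterbox, load_image, \
    mosaic_augment, read_yolo_labels
from .engine import Tensor, no_grad, softmax
from .metrics import APTable, Detection, MetricCounts, confusion_matrix, \
    evaluate_detections, nms, precision_recall_f1, summary_report
from .model import ModelGraph


@dataclass
class TrainConfig:
    """Training hyperparameters; the defaults are the published recipe."""

    epochs: int = 500
    batch: int = 8
    optimizer: str = "SGD"
    lr0: float = 1e-2
    lrf: float = 1e-4          # final learning-rate value
    momentum: float = 0.937
    weight_decay: float = 5e-4
    nms_iou: float = 0.7
    wiou_alpha: float = 1.9
    wiou_delta: float = 3.0
    close_mosaic: int = 10
    image_size: int = 640
    seed: int = 0
    mosaic: bool = True
    conf_thr: float = 0.01     # decode threshold at evaluation time
    warmup_epochs: int = 3


def desk_config(epochs: int = 30, seed: int = 7) -> TrainConfig:
    """The 256x256 CPU profile: shorter schedule, no mosaic (tiny datasets
    converge faster on un-collaged scenes), higher floor learning rate."""
    return TrainConfig(epochs=epochs, image_size=256, seed=seed, mosaic=False,
                       lrf=1e-3, close_mosaic=10)


# ---------------------------------------------------------------------------
# differentiable box geometry
# ---------------------------------------------------------------------------

def _tmin(a, b):
    return b + (a - b).clamp(hi=0.0)


def _tmax(a, b):
    return b + (a - b).clamp(lo=0.0)


def box_iou_t(pred: Tensor, target: Tensor) -> Tensor:
    """Differentiable IoU between (..., 4) xyxy tensors."""
    ix = (_tmin(pred[..., 2], target[..., 2])
          - _tmax(pred[..., 0], target[..., 0])).clamp(lo=0.0)
    iy = (_tmin(pred[..., 3], target[..., 3])
          - _tmax(pred[..., 1], target[..., 1])).clamp(lo=0.0)
    inter = ix * iy
    area_p = ((pred[..., 2] - pred[..., 0]).clamp(lo=0.0)
              * (pred[..., 3] - pred[..., 1]).clamp(lo=0.0))
    area_t = ((target[..., 2] - target[..., 0])
              * (target[..., 3] - target[..., 1]))
    return inter / (area_p + area_t - inter + 1e-9)


def wise_iou_loss(pred: Tensor, target: Tensor, alpha: float = 1.9,
                  delta: float = 3.0, running_mean: float | None = None
                  ) -> tuple[Tensor, float]:
    """Per-box Wise-IoU loss L = r * R_wiou * (1 - IoU).

    R_wiou = exp(d^2 / (Wg^2 + Hg^2)) over the smallest enclosing box (the
    denominator is gradient-detached); the outlier degree beta = (1 - IoU) /
    running-mean(1 - IoU) (detached) drives the focusing factor
    r = beta / (delta * alpha^(beta - delta)), which is neutral (r = 1) at
    beta = delta. Returns the loss tensor and the batch mean of (1 - IoU) for
    updating the caller's running-mean state. Degenerate (zero-area) enclosing
    boxes contribute zero loss.
    """
    iou = box_iou_t(pred, target)
    l_iou = 1.0 - iou
    pcx = (pred[..., 0] + pred[..., 2]) * 0.5
    pcy = (pred[..., 1] + pred[..., 3]) * 0.5
    tcx = (target[..., 0] + target[..., 2]) * 0.5
    tcy = (target[..., 1] + target[..., 3]) * 0.5
    wg = _tmax(pred[..., 2], target[..., 2]) - _tmin(pred[..., 0], target[..., 0])
    hg = _tmax(pred[..., 3], target[..., 3]) - _tmin(pred[..., 1], target[..., 1])
    denom = (wg.data ** 2 + hg.data ** 2)          # gradient-detached
    valid = denom > 1e-9
    r_dist = (((pcx - tcx) ** 2 + (pcy - tcy) ** 2)
              / Tensor(np.where(valid, denom, 1.0))).exp()
    batch_mean = float(l_iou.data.mean()) if l_iou.size else 0.0
    rm = batch_mean if running_mean is None else running_mean
    beta = l_iou.data / max(rm, 1e-9)
    r = beta / (delta * np.power(alpha, beta - delta))
    loss = Tensor(r.astype(np.float32) * valid) * r_dist * l_iou
    return loss, batch_mean


# ---------------------------------------------------------------------------
# anchors + assignment
# ---------------------------------------------------------------------------

def make_anchors(shapes: list[tuple[int, int]], strides=(8, 16, 32)
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Anchor centre points (A, 2) in pixels and per-anchor strides (A,)."""
    pts, sts = [], []
    for (h, w), s in zip(shapes, strides):
        ys, xs = np.mgrid[0:h, 0:w]
        pts.append(np.stack([(xs.ravel() + 0.5) * s, (ys.ravel() + 0.5) * s], 1))
        sts.append(np.full(h * w, s, dtype=np.float64))
    return np.concatenate(pts).astype(np.float64), np.concatenate(sts)


def _iou_np(boxes: np.ndarray, gt: np.ndarray) -> np.ndarray:
    ix = (np.minimum(boxes[:, None, 2], gt[None, :, 2])
          - np.maximum(boxes[:, None, 0], gt[None, :, 0])).clip(min=0)
    iy = (np.minimum(boxes[:, None, 3], gt[None, :, 3])
          - np.maximum(boxes[:, None, 1], gt[None, :, 1])).clip(min=0)
    inter = ix * iy
    ap = ((boxes[:, 2] - boxes[:, 0]) * (boxes[:, 3] - boxes[:, 1])).clip(min=0)
    ag = (gt[:, 2] - gt[:, 0]) * (gt[:, 3] - gt[:, 1])
    return inter / (ap[:, None] + ag[None, :] - inter + 1e-9)


def assign_targets(anchor_points: np.ndarray, pred_scores: np.ndarray,
                   pred_boxes: np.ndarray, gt_classes: np.ndarray,
                   gt_boxes: np.ndarray, topk: int = 10,
                   align_alpha: float = 0.5, align_beta: float = 6.0):
    """Task-aligned top-k assignment (deterministic).

    Alignment = score[gt class]^align_alpha * IoU^align_beta; candidates are
    anchors whose centre lies inside the box; an anchor claimed by several
    ground truths goes to the highest alignment. Returns fg mask (A,), target
    class (A,), target boxes (A, 4) and normalised target scores (A,).
    """
    A = len(anchor_points)
    fg = np.zeros(A, dtype=bool)
    tcls = np.zeros(A, dtype=np.int64)
    tbox = np.zeros((A, 4))
    tscore = np.zeros(A)
    if len(gt_boxes) == 0:
        return fg, tcls, tbox, tscore
    inside = ((anchor_points[:, 0:1] > gt_boxes[None, :, 0])
              & (anchor_points[:, 0:1] < gt_boxes[None, :, 2])
              & (anchor_points[:, 1:2] > gt_boxes[None, :, 1])
              & (anchor_points[:, 1:2] < gt_boxes[None, :, 3]))  # (A, G)
    iou = _iou_np(pred_boxes, gt_boxes)
    align = (pred_scores[:, gt_classes].clip(min=1e-9) ** align_alpha
             * iou ** align_beta) * inside
    chosen = np.zeros_like(inside)
    for g in range(len(gt_boxes)):
        k = min(topk, int(inside[:, g].sum()))
        if k == 0:
            continue
        order = np.argsort(-align[:, g], kind="stable")[:k]
        chosen[order[align[order, g] > 0], g] = True
    best_gt = np.where(chosen.any(1), align.argmax(1), -1)
    for g in range(len(gt_boxes)):
        sel = (best_gt == g) & chosen[:, g]
        if not sel.any():
            continue
        a_max = align[sel, g].max()
        i_max = iou[sel, g].max()
        fg[sel] = True
        tcls[sel] = gt_classes[g]
        tbox[sel] = gt_boxes[g]
        tscore[sel] = align[sel, g] / max(a_max, 1e-9) * i_max
    return fg, tcls, tbox, tscore


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def _bce_with_logits(x: Tensor, y: np.ndarray) -> Tensor:
    """Elementwise stable binary cross-entropy from logits."""
    absx = x.relu() + (-x).relu()
    return x.clamp(lo=0.0) - x * Tensor(y) + (1.0 + (-absx).exp()).log()


@dataclass
class LossBreakdown:
    box: float
    cls: float
    dfl: float
    total: float


class DetectionLoss:
    """Raw head maps + ground truth -> weighted loss (box/cls/dfl)."""

    def __init__(self, model: ModelGraph, cfg: TrainConfig,
                 box_w: float = 7.5, cls_w: float = 0.5, dfl_w: float = 1.5):
        self.model = model
        self.cfg = cfg
        self.nc = model.detect.nc
        self.reg_max = model.detect.reg_max
        self.box_w, self.cls_w, self.dfl_w = box_w, cls_w, dfl_w
        self.wiou_running: float | None = None

    def flatten_maps(self, maps: list[Tensor]):
        """(B, A, 4*reg_max) distances and (B, A, nc) class logits across
        scales, plus anchor points/strides."""
        B = maps[0].shape[0]
        flat = [m.reshape(B, m.shape[1], m.shape[2] * m.shape[3]).transpose(0, 2, 1)
                for m in maps]
        from .engine import concat
        allm = concat(flat, axis=1)
        anchors, strides = make_anchors([(m.shape[2], m.shape[3]) for m in maps])
        return allm[:, :, :4 * self.reg_max], allm[:, :, 4 * self.reg_max:], \
            anchors, strides

    def decode_boxes(self, dist: Tensor, anchors: np.ndarray,
                     strides: np.ndarray) -> Tensor:
        """DFL expectation of the bin logits -> ltrb -> pixel xyxy boxes."""
        B, A, _ = dist.shape
        d = self.model.detect.dfl(dist.reshape(B, A, 4, self.reg_max))  # (B,A,4)
        s = Tensor(strides[None, :, None].astype(np.float32))
        d = d * s
        ax = Tensor(np.broadcast_to(anchors[None, :, 0], (B, A)).astype(np.float32))
        ay = Tensor(np.broadcast_to(anchors[None, :, 1], (B, A)).astype(np.float32))
        from .engine import stack
        return stack([ax - d[:, :, 0], ay - d[:, :, 1],
                      ax + d[:, :, 2], ay + d[:, :, 3]], axis=2)

    def __call__(self, maps: list[Tensor],
                 targets: list[list[tuple[int, np.ndarray]]]
                 ) -> tuple[Tensor, LossBreakdown]:
        dist, cls_logit, anchors, strides = self.flatten_maps(maps)
        boxes = self.decode_boxes(dist, anchors, strides)
        B, A = cls_logit.shape[:2]
        with no_grad():
            scores_np = 1.0 / (1.0 + np.exp(-cls_logit.data))
        tgt_scores = np.zeros((B, A, self.nc), dtype=np.float32)
        fg_rows, tb_rows, ts_rows = [], [], []
        for b in range(B):
            gc = np.array([c for c, _ in targets[b]], dtype=np.int64)
            gb = np.array([x for _, x in targets[b]], dtype=np.float64).reshape(-1, 4)
            fg, tcls, tbox, tsc = assign_targets(anchors, scores_np[b],
                                                 boxes.data[b].astype(np.float64),
                                                 gc, gb)
            tgt_scores[b, np.arange(A)[fg], tcls[fg]] = tsc[fg]
            fg_rows.append(fg)
            tb_rows.append(tbox)
            ts_rows.append(tsc)
        norm = max(float(tgt_scores.sum()), 1.0)
        cls_loss = _bce_with_logits(cls_logit, tgt_scores).sum() / norm

        fg_mask = np.stack(fg_rows)                       # (B, A)
        bi, ai = np.nonzero(fg_mask)
        if len(bi):
            tbox_fg = np.stack(tb_rows)[bi, ai].astype(np.float32)
            w_fg = np.stack(ts_rows)[bi, ai].astype(np.float32)
            pbox_fg = boxes[bi, ai]                       # (P, 4)
            wloss, bm = wise_iou_loss(pbox_fg, Tensor(tbox_fg),
                                      self.cfg.wiou_alpha, self.cfg.wiou_delta,
                                      self.wiou_running)
            self.wiou_running = bm if self.wiou_running is None else \
                0.9 * self.wiou_running + 0.1 * bm
            box_loss = (wloss * Tensor(w_fg)).sum() / norm
            # distribution-focal term on the two adjacent bins
            dist_fg = dist[bi, ai].reshape(len(bi), 4, self.reg_max)
            s_fg = strides[ai][:, None]
            lt = np.stack([anchors[ai, 0] - tbox_fg[:, 0],
                           anchors[ai, 1] - tbox_fg[:, 1],
                           tbox_fg[:, 2] - anchors[ai, 0],
                           tbox_fg[:, 3] - anchors[ai, 1]], axis=1) / s_fg
            t = np.clip(lt, 0, self.reg_max - 1.01)
            li = np.floor(t).astype(np.int64)
            wl = (li + 1 - t).astype(np.float32)
            logp = (softmax(dist_fg, axis=-1) + 1e-9).log()
            onehot_l = np.zeros((len(bi), 4, self.reg_max), dtype=np.float32)
            onehot_r = np.zeros_like(onehot_l)
            ii, jj = np.indices(li.shape)
            onehot_l[ii, jj, li] = wl
            onehot_r[ii, jj, li + 1] = 1.0 - wl
            dfl_loss = -(logp * Tensor(onehot_l + onehot_r)).sum(axis=2)
            dfl_loss = (dfl_loss.mean(axis=1) * Tensor(w_fg)).sum() / norm
        else:
            box_loss = Tensor(0.0)
            dfl_loss = Tensor(0.0)
        total = self.box_w * box_loss + self.cls_w * cls_loss + self.dfl_w * dfl_loss
        bd = LossBreakdown(float(box_loss.data), float(cls_loss.data),
                           float(dfl_loss.data), float(total.data))
        return total, bd


# ---------------------------------------------------------------------------
# prediction / evaluation
# ---------------------------------------------------------------------------

def decode_predictions(model: ModelGraph, maps: list[Tensor], cfg: TrainConfig,
                       max_det: int = 100) -> list[list[Detection]]:
    """Raw maps -> thresholded, class-wise-NMS detections per image (pixel
    xyxy in the network input frame)."""
    loss_helper = DetectionLoss(model, cfg)
    dist, cls_logit, anchors, strides = loss_helper.flatten_maps(maps)
    boxes = loss_helper.decode_boxes(dist, anchors, strides).data
    scores = 1.0 / (1.0 + np.exp(-cls_logit.data))
    out = []
    for b in range(boxes.shape[0]):
        conf = scores[b].max(axis=1)
        cls = scores[b].argmax(axis=1)
        keep = conf >= cfg.conf_thr
        bx, cf, cl = boxes[b][keep], conf[keep], cls[keep]
        kept = nms(bx, cf, cfg.nms_iou, class_ids=cl)[:max_det]
        out.append([Detection(int(cl[i]), float(cf[i]), bx[i].astype(np.float64))
                    for i in kept])
    return out


def _load_item(img_path, lbl_path) -> tuple[np.ndarray, list[Annotation]]:
    return load_image(img_path), read_yolo_labels(lbl_path)


def evaluate(model: ModelGraph, items: list, cfg: TrainConfig,
             num_classes: int | None = None):
    """Run the detector over (image, label) items and score it.

    Returns (APTable, MetricCounts, confusion matrix, headline report dict).
    """
    if not items:
        raise ValueError("cannot evaluate an empty split")
    model.eval()
    nc = num_classes if num_classes is not None else model.detect.nc
    dets_all, gts_all = [], []
    for img_path, lbl_path in items:
        img, anns = _load_item(img_path, lbl_path)
        canvas, tf = letterbox(img, cfg.image_size)
        x = Tensor(canvas.astype(np.float32).transpose(2, 0, 1)[None] / 255.0)
        with no_grad():
            maps = model(x)
            dets = decode_predictions(model, maps, cfg)[0]
        h, w = img.shape[:2]
        for d in dets:
            d.box = tf.invert_boxes(d.box)[0]
        gts_all.append([(a.class_id, a.to_xyxy(w, h)) for a in anns])
        dets_all.append(dets)
    table, counts = evaluate_detections(dets_all, gts_all, 0.5, num_classes=nc)
    cm = confusion_matrix(dets_all, gts_all, nc)
    per_class_f1 = []
    for c in table.per_class:
        tp = int(np.diag(cm)[c]) if c < nc else 0
        fp = int(cm[:, c].sum() - cm[c, c])
        fn = int(cm[c, :].sum() - cm[c, c])
        _, _, f1 = precision_recall_f1(MetricCounts(tp, fp, fn))
        per_class_f1.append(f1)
    report = summary_report(table, counts)
    report["F1 Score (macro)"] = float(np.mean(per_class_f1)) if per_class_f1 else 0.0
    return table, counts, cm, report


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def train(cfg: TrainConfig, data: DatasetIndex, model: ModelGraph,
          out_dir=None, log_every: int = 0, eval_every: int = 0,
          progress=None):
    """SGD training with the configured schedule.

    Learning rate decays linearly from lr0 to lrf (after `warmup_epochs` of
    linear warm-up); mosaic is disabled for the last `close_mosaic` epochs;
    per-epoch mean losses (and optional val metrics) are logged; the best
    checkpoint by val mAP@0.5 is kept when an output directory is given.
    Fully seeded and single-threaded deterministic.
    """
    if not data.splits.get("train"):
        raise ValueError("training split is empty")
    rng = np.random.default_rng(cfg.seed)
    init_bias(model)
    loss_fn = DetectionLoss(model, cfg)
    opt = nn.SGD(model.parameters(), cfg.lr0, cfg.momentum, cfg.weight_decay)
    train_items = data.split_items("train")
    cache = [_load_item(*it) for it in train_items]
    log: list[dict] = []
    best = {"mAP50": -1.0}
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    n = len(cache)
    for epoch in range(cfg.epochs):
        if epoch < cfg.warmup_epochs:
            lr = cfg.lr0 * (epoch + 1) / cfg.warmup_epochs
        else:
            t = (epoch - cfg.warmup_epochs) / max(cfg.epochs - cfg.warmup_epochs - 1, 1)
            lr = cfg.lr0 + (cfg.lrf - cfg.lr0) * t
        opt.lr = lr
        mosaic_on = cfg.mosaic and epoch < cfg.epochs - cfg.close_mosaic
        order = rng.permutation(n)
        model.train()
        sums = np.zeros(4)
        steps = 0
        for start in range(0, n, cfg.batch):
            idx = order[start:start + cfg.batch]
            ims, tgts = [], []
            for i in idx:
                picks = [cache[i]] + [cache[j] for j in rng.integers(0, n, 3)]
                img, anns = mosaic_augment(picks, int(rng.integers(2**31)),
                                           enabled=mosaic_on,
                                           target=cfg.image_size)
                ims.append(img.astype(np.float32).transpose(2, 0, 1) / 255.0)
                tgts.append([(a.class_id, a.to_xyxy(cfg.image_size, cfg.image_size))
                             for a in anns])
            x = Tensor(np.stack(ims))
            maps = model(x)
            total, bd = loss_fn(maps, tgts)
            if not math.isfinite(bd.total):
                raise RuntimeError(
                    f"divergence: non-finite loss at epoch {epoch} "
                    f"(box={bd.box:.3g} cls={bd.cls:.3g} dfl={bd.dfl:.3g})")
            opt.zero_grad()
            total.backward()
            opt.step()
            sums += (bd.box, bd.cls, bd.dfl, bd.total)
            steps += 1
        entry = {"epoch": epoch, "lr": lr, "mosaic": bool(mosaic_on),
                 "box": sums[0] / steps, "cls": sums[1] / steps,
                 "dfl": sums[2] / steps, "loss": sums[3] / steps}
        if eval_every and ((epoch + 1) % eval_every == 0 or epoch == cfg.epochs - 1):
            table, _, _, report = evaluate(model, data.split_items("val"), cfg)
            entry["mAP50"] = report["mAP50"]
            if report["mAP50"] > best["mAP50"]:
                best = {"mAP50": report["mAP50"], "epoch": epoch}
                if out_dir is not None:
                    np.savez(out_dir / "best.npz", **model.state_dict())
        log.append(entry)
        if progress:
            progress(entry)
        if log_every and (epoch + 1) % log_every == 0 and out_dir is not None:
            (out_dir / "log.jsonl").write_text(
                "\n".join(json.dumps(e) for e in log) + "\n")
    if out_dir is not None:
        np.savez(out_dir / "last.npz", **model.state_dict())
        (out_dir / "log.jsonl").write_text(
            "\n".join(json.dumps(e) for e in log) + "\n")
    return {"log": log, "best": best}


def init_bias(model: ModelGraph, prior: float = 8e-3) -> None:
    """Detection-head bias priors: class logits start near a small positive
    rate, box bins near the first cells — standard stabilisation for training
    from scratch."""
    for branch in model.detect.cls_branches:
        conv = branch[-1]
        conv.bias.data[:] = math.log(prior / (1 - prior))
    for branch in model.detect.box_branches:
        conv = branch[-1]
        conv.bias.data[:] = 1.0


# ---------------------------------------------------------------------------
# Grad-CAM
# ---------------------------------------------------------------------------

def grad_cam(model: ModelGraph, image: np.ndarray, target_layer: int,
             class_id: int, cfg: TrainConfig | None = None) -> np.ndarray:
    """Class-activation heatmap in [0, 1] at the image's resolution.

    Channel weights are the spatial mean of the class-score gradient at the
    target layer; the map is the rectified weighted activation sum, min-max
    normalised and bilinearly upsampled.
    """
    cfg = cfg or TrainConfig()
    model.eval()
    canvas, _ = letterbox(image, cfg.image_size)
    x = Tensor(canvas.astype(np.float32).transpose(2, 0, 1)[None] / 255.0)
    maps, act = model.forward(x, capture=target_layer)
    nc, rm = model.detect.nc, model.detect.reg_max
    score = None
    for m in maps:
        cls_logits = m[:, 4 * rm + class_id]
        s = cls_logits.sigmoid().sum()
        score = s if score is None else score + s
    model.zero_grad()
    score.backward()
    if act.grad is None or not np.any(act.grad):
        warnings.warn("zero gradient at target layer; returning empty heatmap",
                      stacklevel=2)
        return np.zeros(image.shape[:2], dtype=np.float32)
    weights = act.grad[0].mean(axis=(1, 2))
    cam = np.maximum((weights[:, None, None] * act.data[0]).sum(0), 0.0)
    if cam.max() > cam.min():
        cam = (cam - cam.min()) / (cam.max() - cam.min())
    h, w = image.shape[:2]
    cam_img = Image.fromarray((cam * 255).astype(np.uint8)).resize(
        (w, h), Image.BILINEAR)
    return np.asarray(cam_img).astype(np.float32) / 255.0
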