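"""Box loss, target assignment, the training loop contract, Grad-CAM."""

import math

import numpy as np
import pytest

from serpensgate import nn, synth
from serpensgate.data_io import Annotation
from serpensgate.engine import Tensor
from serpensgate.metrics import Detection, evaluate_detections
from serpensgate.model import build_model, default_table
from serpensgate.train import (TrainConfig, DetectionLoss, assign_targets,
                               _bce_with_logits, box_iou_t, desk_config,
                               evaluate, grad_cam, train, wise_iou_loss)


def desk_model():
    nn.seed_init(3)
    return build_model(default_table(nc=6, width=0.25, reg_max=8))


@pytest.fixture
def tiny_data(tmp_path):
    idx = synth.generate_dataset(10, seed=3, out=tmp_path,
                                 cfg=synth.desk_profile())
    return idx


class TestWiseIoU:
    def test_perfect_box_zero_loss(self):
        b = Tensor(np.array([[0, 0, 2, 2]], np.float32))
        loss, _ = wise_iou_loss(b, b, running_mean=0.5)
        assert loss.data[0] == pytest.approx(0.0, abs=1e-6)

    def test_focusing_factor_neutral_at_anchor(self):
        """beta == delta makes r = 1, so L = R_wiou * (1 - IoU) exactly."""
        pred = Tensor(np.array([[0, 0, 2, 2]], np.float32))
        tgt = Tensor(np.array([[1, 1, 3, 3]], np.float32))
        l_iou = 1 - 1 / 7
        # running mean = (1-IoU)/delta makes beta = delta
        loss, _ = wise_iou_loss(pred, tgt, alpha=1.9, delta=3.0,
                                running_mean=l_iou / 3.0)
        r_wiou = math.exp(2.0 / 18.0)
        assert loss.data[0] == pytest.approx(r_wiou * l_iou, rel=1e-5)

    def test_hand_evaluated_oracle(self):
        """Toy boxes with the running mean equal to the current value."""
        pred = Tensor(np.array([[0, 0, 2, 2]], np.float32))
        tgt = Tensor(np.array([[1, 1, 3, 3]], np.float32))
        l_iou = 1 - 1 / 7                       # IoU = 1/7
        loss, batch_mean = wise_iou_loss(pred, tgt, alpha=1.9, delta=3.0,
                                         running_mean=l_iou)
        assert batch_mean == pytest.approx(l_iou, rel=1e-6)
        beta = 1.0                              # (1-IoU)/mean = 1
        r = beta / (3.0 * 1.9 ** (beta - 3.0))
        r_wiou = math.exp(2.0 / 18.0)           # centre dist 2, enclosing 3x3
        assert loss.data[0] == pytest.approx(r * r_wiou * l_iou, rel=1e-5)

    def test_monotone_in_iou_when_centres_coincide(self):
        """With coincident centres and beta = delta the loss reduces to a
        monotone function of IoU."""
        tgt = Tensor(np.array([[0, 0, 4, 4]], np.float32))
        losses = []
        for shrink in (0.0, 0.5, 1.0, 1.5):
            pred = Tensor(np.array([[shrink, shrink, 4 - shrink, 4 - shrink]],
                                   np.float32))
            l_iou = 1 - float(box_iou_t(pred, tgt).data[0])
            loss, _ = wise_iou_loss(pred, tgt, running_mean=max(l_iou, 1e-9) / 3)
            losses.append(float(loss.data[0]))
        assert losses == sorted(losses)

    def test_gradient_flows_to_predictions(self):
        pred = Tensor(np.array([[0, 0, 2, 2]], np.float32), requires_grad=True)
        tgt = Tensor(np.array([[1, 1, 3, 3]], np.float32))
        loss, _ = wise_iou_loss(pred, tgt, running_mean=0.5)
        loss.sum().backward()
        assert pred.grad is not None and np.abs(pred.grad).sum() > 0


class TestAssignment:
    def anchors(self, size=64, stride=8):
        n = size // stride
        ys, xs = np.mgrid[0:n, 0:n]
        pts = np.stack([(xs.ravel() + .5) * stride, (ys.ravel() + .5) * stride], 1)
        return pts.astype(float)

    def test_assigned_anchors_inside_gt(self, rng):
        pts = self.anchors()
        scores = rng.uniform(0.1, 0.9, (len(pts), 3))
        boxes = np.hstack([pts - 6, pts + 6])
        gt = np.array([[16.0, 16.0, 48.0, 48.0]])
        fg, tcls, tbox, ts = assign_targets(pts, scores, boxes,
                                            np.array([1]), gt)
        assert fg.any()
        inside = (pts[fg, 0] > 16) & (pts[fg, 0] < 48) \
            & (pts[fg, 1] > 16) & (pts[fg, 1] < 48)
        assert inside.all()
        assert (tcls[fg] == 1).all()
        assert np.all(ts[fg] > 0) and np.all(ts[fg] <= 1 + 1e-9)

    def test_no_gt_no_positives(self, rng):
        pts = self.anchors()
        fg, *_ = assign_targets(pts, rng.uniform(size=(len(pts), 3)),
                                np.hstack([pts - 4, pts + 4]),
                                np.array([], dtype=int), np.zeros((0, 4)))
        assert not fg.any()

    def test_disjoint_gts_get_disjoint_anchors(self, rng):
        pts = self.anchors()
        scores = rng.uniform(0.1, 0.9, (len(pts), 2))
        boxes = np.hstack([pts - 6, pts + 6])
        gts = np.array([[0.0, 0.0, 24.0, 24.0], [40.0, 40.0, 64.0, 64.0]])
        fg, tcls, tbox, _ = assign_targets(pts, scores, boxes,
                                           np.array([0, 1]), gts)
        for a in np.flatnonzero(fg):
            box = tbox[a]
            assert (pts[a, 0] > box[0]) and (pts[a, 0] < box[2])

    def test_deterministic(self, rng):
        pts = self.anchors()
        scores = rng.uniform(0.1, 0.9, (len(pts), 2))
        boxes = np.hstack([pts - 5, pts + 5])
        gts = np.array([[10.0, 10.0, 40.0, 40.0]])
        a = assign_targets(pts, scores, boxes, np.array([0]), gts)
        b = assign_targets(pts, scores, boxes, np.array([0]), gts)
        for u, v in zip(a, b):
            np.testing.assert_array_equal(u, v)


def test_bce_matches_reference(rng):
    x = rng.normal(size=(4, 5)).astype(np.float32) * 3
    y = (rng.random((4, 5)) > 0.5).astype(np.float32)
    got = _bce_with_logits(Tensor(x), y).data
    p = 1 / (1 + np.exp(-x.astype(np.float64)))
    ref = -(y * np.log(p) + (1 - y) * np.log1p(-p))
    np.testing.assert_allclose(got, ref, atol=1e-5)


class TestTrainingLoop:
    def test_one_epoch_smoke(self, tiny_data, tmp_path):
        model = desk_model()
        cfg = desk_config(epochs=1, seed=3)
        res = train(cfg, tiny_data, model, out_dir=tmp_path / "run")
        assert math.isfinite(res["log"][0]["loss"])
        assert (tmp_path / "run" / "last.npz").exists()
        assert (tmp_path / "run" / "log.jsonl").exists()

    def test_same_seed_identical_loss_trace(self, tiny_data):
        traces = []
        for _ in range(2):
            model = desk_model()
            cfg = desk_config(epochs=2, seed=3)
            res = train(cfg, tiny_data, model)
            traces.append([e["loss"] for e in res["log"]])
        assert traces[0] == traces[1]

    def test_close_mosaic_switch(self, tiny_data):
        """The augmentation path flips at epoch (epochs - close_mosaic)."""
        model = desk_model()
        cfg = desk_config(epochs=12, seed=3)
        cfg.mosaic = True
        cfg.close_mosaic = 10
        res = train(cfg, tiny_data, model)
        flags = [e["mosaic"] for e in res["log"]]
        assert flags == [True] * 2 + [False] * 10

    def test_config_defaults_are_published_recipe(self):
        cfg = TrainConfig()
        assert (cfg.epochs, cfg.batch, cfg.optimizer) == (500, 8, "SGD")
        assert (cfg.lr0, cfg.lrf, cfg.momentum) == (1e-2, 1e-4, 0.937)
        assert (cfg.weight_decay, cfg.nms_iou) == (5e-4, 0.7)
        assert (cfg.wiou_alpha, cfg.wiou_delta, cfg.close_mosaic) == (1.9, 3.0, 10)

    def test_empty_split_rejected(self, tiny_data):
        model = desk_model()
        with pytest.raises(ValueError):
            evaluate(model, [], desk_config())


class TestEvaluation:
    def test_oracle_detector_scores_perfect_map(self, tiny_data):
        """Provenance-consistent labels: an oracle reading them back scores
        mAP@0.5 = 1.0."""
        from serpensgate.data_io import read_yolo_labels, load_image
        dets, gts = [], []
        for img_path, lbl_path in tiny_data.items:
            img = load_image(img_path)
            h, w = img.shape[:2]
            anns = read_yolo_labels(lbl_path)
            gts.append([(a.class_id, a.to_xyxy(w, h)) for a in anns])
            dets.append([Detection(a.class_id, 1.0, a.to_xyxy(w, h))
                         for a in anns])
        table, counts = evaluate_detections(dets, gts, 0.5)
        assert table.mAP == 1.0
        assert counts.FP == counts.FN == 0

    def test_untrained_model_near_zero(self, tiny_data):
        model = desk_model()
        cfg = desk_config()
        table, counts, cm, report = evaluate(
            model, tiny_data.split_items("val"), cfg)
        assert report["mAP50"] < 0.3

    def test_report_schema(self, tiny_data):
        model = desk_model()
        _, _, cm, report = evaluate(model, tiny_data.split_items("val"),
                                    desk_config())
        assert set(report) >= {"F1 Score", "Precision", "Recall", "mAP50"}
        assert cm.shape == (7, 7)


class TestGradCam:
    def test_heatmap_range_and_shape(self, tiny_data):
        model = desk_model()
        img = synth.generate_leaf_scene(3, synth.desk_profile()).image
        cam = grad_cam(model, img, target_layer=22, class_id=0,
                       cfg=desk_config())
        assert cam.shape == img.shape[:2]
        assert cam.min() >= 0.0 and cam.max() <= 1.0

    def test_normalisation_invariance_to_score_scale(self):
        """Scaling every class logit's gradient uniformly leaves the min-max
        normalised map unchanged (here: via the box/cls branch weights)."""
        nn.seed_init(5)
        model = build_model(default_table(nc=6, width=0.25, reg_max=8))
        img = synth.generate_leaf_scene(9, synth.desk_profile()).image
        a = grad_cam(model, img, 22, 1, desk_config())
        for branch in model.detect.cls_branches:
            branch[-1].weight.data *= 0.5
        b = grad_cam(model, img, 22, 1, desk_config())
        assert np.corrcoef(a.ravel(), b.ravel())[0, 1] > 0.98
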