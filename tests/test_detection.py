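"""Detection objective, evaluation protocol, patch cropping and the
training loop (overfit sanity, patience, cosine schedule)."""

import math

import numpy as np
import pytest

from icepose.detect import (
    Detection,
    DetectorConfig,
    ProbeDetector,
    crop_patch,
    detect_probe,
    detection_loss,
    evaluate_detection,
    train_detector,
)
from icepose.geometry import BoundingBox, box_iou
from icepose import nn


def _perfect_maps(det, box, g=None):
    """Raw maps that decode exactly to `box` with saturated scores.

    Box channels are written for every supervised cell of the 3x3
    neighborhood (those whose extended (-0.5, 1.5) center offset can reach
    the true center)."""
    g = det.grid if g is None else g
    maps = np.zeros((6, g, g), dtype=np.float32)
    maps[0] = -50.0
    maps[1] = -50.0
    s, base = det.stride, det.config.base_box_px
    j = int(box.cx // s)
    i = int(box.cy // s)
    maps[0, i, j] = 50.0
    maps[1, i, j] = 50.0
    logit = lambda p: math.log(p / (1 - p))
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            ii, jj = i + di, j + dj
            if not (0 <= ii < g and 0 <= jj < g):
                continue
            fx = box.cx / s - jj
            fy = box.cy / s - ii
            if not (-0.46 <= fx <= 1.46 and -0.46 <= fy <= 1.46):
                continue
            maps[2, ii, jj] = logit((fx + 0.5) / 2.0)
            maps[3, ii, jj] = logit((fy + 0.5) / 2.0)
            maps[4, ii, jj] = math.log(box.w / base)
            maps[5, ii, jj] = math.log(box.h / base)
    return maps


class TestDetectionLoss:
    def test_perfect_prediction_near_zero(self):
        cfg = DetectorConfig()
        det = ProbeDetector(cfg)
        box = BoundingBox(cx=250, cy=200, w=60, h=40)
        maps = _perfect_maps(det, box)[None]
        loss, _, parts = detection_loss(maps, [box], cfg, det.stride)
        assert parts["box"] == pytest.approx(0.0, abs=1e-6)
        assert loss < 1e-6  # scores saturated, box exact

    def test_objectness_bce_closed_form(self):
        """A positive cell with objectness probability p contributes
        pos_weight * -ln(p) / n_cells to the objectness term."""
        cfg = DetectorConfig()
        det = ProbeDetector(cfg)
        box = BoundingBox(cx=250, cy=200, w=60, h=40)
        maps = _perfect_maps(det, box)
        p = 0.3
        i, j = int(box.cy // det.stride), int(box.cx // det.stride)
        maps[0, i, j] = math.log(p / (1 - p))
        _, _, parts = detection_loss(maps[None], [box], cfg, det.stride)
        n_cells = det.grid * det.grid
        expected = cfg.obj_pos_weight * -math.log(p) / n_cells
        assert parts["obj"] == pytest.approx(expected, rel=1e-4)

    def test_hand_built_two_image_batch(self):
        """Total equals the hand-summed weighted components."""
        cfg = DetectorConfig(box_weight=5.0, obj_weight=1.0, cls_weight=1.0)
        det = ProbeDetector(cfg)
        # centers at cell midpoints: only the center cell is supervised
        boxes = [
            BoundingBox(cx=112, cy=112, w=50, h=50),
            BoundingBox(cx=336, cy=368, w=80, h=40),
        ]
        maps = np.stack([_perfect_maps(det, b) for b in boxes])
        # perturb image 0's box width channel
        i, j = int(boxes[0].cy // det.stride), int(boxes[0].cx // det.stride)
        maps[0, 4, i, j] += 0.3
        total, _, parts = detection_loss(maps, boxes, cfg, det.stride)
        from icepose.geometry import ciou_loss

        wrong = BoundingBox(cx=112, cy=112, w=50 * math.exp(0.3), h=50)
        expected_box = ciou_loss(wrong, boxes[0]) / 2  # two supervised cells
        assert parts["box"] == pytest.approx(expected_box, rel=1e-6)
        assert total == pytest.approx(
            5.0 * parts["box"] + parts["obj"] + parts["cls"], rel=1e-9
        )

    def test_finite_difference_grad_matches_loss(self):
        cfg = DetectorConfig()
        det = ProbeDetector(cfg)
        rng = np.random.default_rng(0)
        box = BoundingBox(cx=220, cy=180, w=70, h=50)
        maps = (_perfect_maps(det, box) + rng.normal(0, 0.5, (6, det.grid, det.grid))
                ).astype(np.float32)[None]
        loss, grad, _ = detection_loss(maps, [box], cfg, det.stride, compute_grad=True)
        eps = 1e-3
        for ch in range(6):
            i, j = int(box.cy // det.stride), int(box.cx // det.stride)
            mp = maps.copy(); mp[0, ch, i, j] += eps
            mm = maps.copy(); mm[0, ch, i, j] -= eps
            lp, _, _ = detection_loss(mp, [box], cfg, det.stride)
            lm, _, _ = detection_loss(mm, [box], cfg, det.stride)
            num = (lp - lm) / (2 * eps)
            assert num == pytest.approx(float(grad[0, ch, i, j]), rel=2e-2, abs=1e-4)


class TestEvaluateDetection:
    def _det(self, box, conf, img=0):
        return Detection(box=BoundingBox(box.cx, box.cy, box.w, box.h, conf), image_id=img)

    def test_all_perfect(self):
        truths = [BoundingBox(cx=10 * i + 20, cy=30, w=10, h=10) for i in range(5)]
        dets = [[self._det(t, 0.9, i)] for i, t in enumerate(truths)]
        m, _ = evaluate_detection(dets, truths)
        assert (m["precision"], m["recall"], m["f1"]) == (1.0, 1.0, 1.0)
        assert m["iou_threshold"] == 0.4

    def test_hand_confusion_matrix(self):
        """8 TPs, one bad-location top box, one miss: P=8/9, R=8/10."""
        truths = [BoundingBox(cx=50, cy=50, w=20, h=20) for _ in range(10)]
        dets = []
        for i in range(8):
            dets.append([self._det(truths[i], 0.9, i)])
        dets.append([self._det(BoundingBox(cx=200, cy=200, w=20, h=20), 0.8, 8)])
        dets.append([])
        m, outcomes = evaluate_detection(dets, truths)
        assert m["precision"] == pytest.approx(8 / 9)
        assert m["recall"] == pytest.approx(8 / 10)
        p, r = 8 / 9, 8 / 10
        assert m["f1"] == pytest.approx(2 * p * r / (p + r))
        assert [o["outcome"] for o in outcomes[-2:]] == ["fp", "fn"]

    def test_extra_detections_are_fps(self):
        truth = BoundingBox(cx=50, cy=50, w=20, h=20)
        dets = [[self._det(truth, 0.9), self._det(BoundingBox(cx=150, cy=150, w=20, h=20), 0.5)]]
        m, _ = evaluate_detection(dets, [truth])
        assert m["tp"] == 1 and m["fp"] == 1

    def test_matches_brute_force_enumeration(self):
        """Against an independent per-image confusion enumeration on
        randomized prediction sets."""
        rng = np.random.default_rng(1)
        for _ in range(500):
            truth = BoundingBox(cx=rng.uniform(30, 70), cy=rng.uniform(30, 70),
                                w=rng.uniform(10, 30), h=rng.uniform(10, 30))
            n_det = int(rng.integers(0, 3))
            dets = [
                self._det(
                    BoundingBox(
                        cx=truth.cx + rng.normal(0, 15), cy=truth.cy + rng.normal(0, 15),
                        w=truth.w * rng.uniform(0.5, 1.5), h=truth.h * rng.uniform(0.5, 1.5),
                    ),
                    rng.uniform(0.3, 1.0),
                )
                for _ in range(n_det)
            ]
            m, _ = evaluate_detection([dets], [truth], iou_threshold=0.4)
            # oracle
            tp = fp = fn = 0
            if not dets:
                fn = 1
            else:
                srt = sorted(dets, key=lambda d: -d.confidence)
                if box_iou(srt[0].box, truth) >= 0.4:
                    tp = 1
                else:
                    fp, fn = 1, 1
                fp += len(dets) - 1
            assert (m["tp"], m["fp"], m["fn"]) == (tp, fp, fn)

    def test_f1_between_precision_and_recall(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            tp, fp, fn = rng.integers(1, 20, size=3)
            p = tp / (tp + fp)
            r = tp / (tp + fn)
            f1 = 2 * p * r / (p + r)
            assert min(p, r) - 1e-12 <= f1 <= max(p, r) + 1e-12


class TestCropPatch:
    def test_centered_crop_origin(self):
        img = np.random.default_rng(3).uniform(size=(512, 512)).astype(np.float32)
        patch, geom = crop_patch(img, (256.0, 256.0), size=100)
        assert patch.shape == (100, 100)
        assert geom.origin == (206.0, 206.0)
        assert np.array_equal(patch, img[206:306, 206:306])

    def test_corner_crop_padded_with_median(self):
        img = np.random.default_rng(4).uniform(size=(256, 256)).astype(np.float32)
        patch, geom = crop_patch(img, (10.0, 10.0), size=100)
        assert geom.origin == (-40.0, -40.0)
        med = float(np.median(img))
        assert np.all(patch[:40, :] == med)
        assert np.all(patch[:, :40] == med)
        assert np.array_equal(patch[40:, 40:], img[:60, :60])

    def test_coordinates_round_trip(self):
        img = np.zeros((256, 256), np.float32)
        _, geom = crop_patch(img, (100.0, 120.0), size=100)
        fx, fy = geom.patch_to_frame(50.0, 50.0)
        assert (fx, fy) == (100.0, 120.0)

    def test_midpoint_outside_rejected(self):
        img = np.zeros((64, 64), np.float32)
        with pytest.raises(ValueError):
            crop_patch(img, (100.0, 10.0))


@pytest.fixture(scope="module")
def overfit_result(detection_samples_small):
    """Train the reference detector to memorize 8 small frames."""
    cfg = DetectorConfig(input_size=256, batch_size=8, max_epochs=160,
                         patience=160, lr=5e-3)
    train = detection_samples_small[:8]
    model, history = train_detector(train, train, cfg, seed=0)
    return model, history, train


class TestDetectorTraining:

    def test_overfit_recall_is_one(self, overfit_result):
        model, history, train = overfit_result
        dets = [detect_probe(model, s.image, image_id=k)[0] for k, s in enumerate(train)]
        m, _ = evaluate_detection(dets, [s.box for s in train])
        assert m["recall"] == 1.0

    def test_best_loss_non_increasing(self, overfit_result):
        _, history, _ = overfit_result
        losses = [e["train_loss"] for e in history["epochs"]]
        best_so_far = np.minimum.accumulate(losses)
        assert all(b2 <= b1 + 1e-12 for b1, b2 in zip(best_so_far, best_so_far[1:]))
        assert losses[-1] < losses[0]

    def test_detect_probe_deterministic(self, overfit_result):
        model, _, train = overfit_result
        a = detect_probe(model, train[0].image)
        b = detect_probe(model, train[0].image)
        assert a[1] == b[1]
        assert [d.box for d in a[0]] == [d.box for d in b[0]]

    def test_blank_image_never_raises(self):
        model = ProbeDetector(DetectorConfig())
        dets, midpoint = detect_probe(model, np.zeros((512, 512), np.float32))
        assert isinstance(dets, list)
        if not dets:
            assert midpoint is None

    def test_patience_stops_training(self, detection_samples_small):
        """With a frozen validation metric (untrainable setup), training
        stops after exactly `patience` epochs beyond the best."""
        with pytest.raises(ValueError):
            DetectorConfig(input_size=256, max_epochs=40, patience=100)
        cfg = DetectorConfig(input_size=256, batch_size=4, max_epochs=40,
                             patience=3, lr=1e-12)
        train = detection_samples_small[:4]
        _, history = train_detector(train, train, cfg, seed=0)
        assert history["stopped_early"] == history["best_epoch"] + 3

    def test_cosine_schedule_decays(self):
        lr0 = 1e-2
        total = 1000
        assert nn.cosine_lr(lr0, 0, total) == pytest.approx(lr0)
        assert nn.cosine_lr(lr0, total - 1, total) < 1e-4 * lr0 + 1e-12
        mid = nn.cosine_lr(lr0, total // 2, total)
        assert mid == pytest.approx(lr0 / 2, rel=0.01)

    def test_letterbox_inference_maps_back(self, overfit_result):
        model, _, train = overfit_result
        s = train[0]
        # embed the 256 frame in a 320 frame; detection should map back
        big = np.full((320, 320), float(np.median(s.image)), dtype=np.float32)
        big[32:288, 32:288] = s.image
        dets, midpoint = detect_probe(model, big)
        if midpoint is not None:
            assert 0 <= midpoint[0] < 320 and 0 <= midpoint[1] < 320
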