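"""Stage 1: coarse probe detection.

The detector is a *contract* — any callable mapping a grayscale frame to
scored boxes will do — and this module ships a small anchor-free reference
implementation trainable from scratch on a CPU: the 512x512 frame is
average-pooled 4x, passed through three strided conv blocks to a 16x16
grid (native stride 32), and a 1x1 head predicts per cell an objectness
logit, a class logit and a box (center offsets within the cell via a
sigmoid, log-scaled width/height around a base size).

Training follows the stated schedule: batch size 32, up to 300 epochs with
early stopping after 100 epochs without validation improvement, SGD at an
initial learning rate of 1e-2 under cosine annealing.  The objective is
complete-IoU (CIoU) for the matched box plus binary cross-entropy for
objectness and class.  Evaluation uses the IoU >= 0.4 true-positive rule
with precision / recall / F1.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import nn
from .augment import AugmentationConfig, augment_sample, standardize_image
from .geometry import BoundingBox, PatchGeometry, box_iou, ciou_loss
from .synth.scene import SceneSample

__all__ = [
    "DetectorConfig",
    "Detection",
    "ProbeDetector",
    "detection_loss",
    "train_detector",
    "detect_probe",
    "crop_patch",
    "evaluate_detection",
]


@dataclass(frozen=True)
class DetectorConfig:
    """Hyperparameters of the detection stage (defaults are the study
    schedule; the desk preset shrinks epochs/patience, never the rule)."""

    input_size: int = 512
    batch_size: int = 32
    max_epochs: int = 300
    patience: int = 100
    lr: float = 1e-2
    momentum: float = 0.9
    weight_decay: float = 5e-4
    box_weight: float = 5.0
    obj_weight: float = 1.0
    obj_pos_weight: float = 32.0  # rebalances 1 positive vs g*g-1 negative cells
    cls_weight: float = 1.0
    conf_threshold: float = 0.25
    downsample: int = 4
    base_box_px: float = 56.0
    augment_probability: float = 0.30

    def __post_init__(self):
        if self.patience > self.max_epochs:
            raise ValueError("patience must be <= max_epochs")
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")


@dataclass(frozen=True)
class Detection:
    """One scored detection on one image."""

    box: BoundingBox
    image_id: int = -1

    @property
    def confidence(self) -> float:
        return self.box.confidence if self.box.confidence is not None else 0.0


class ProbeDetector:
    """Reference single-class anchor-free detector (pure NumPy)."""

    def __init__(self, config: DetectorConfig = DetectorConfig(), seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        self.net = nn.Sequential(
            nn.Conv2d(1, 8, 5, 2, rng=rng), nn.ReLU(),
            nn.Conv2d(8, 16, 3, 2, rng=rng), nn.ReLU(),
            nn.Conv2d(16, 32, 3, 2, rng=rng), nn.ReLU(),
            nn.Conv2d(32, 64, 3, 1, rng=rng), nn.ReLU(),
            nn.Conv2d(64, 6, 1, 1, pad=0, rng=rng),
        )
        # native-pixel stride of one grid cell
        self.stride = config.downsample * 8
        self.grid = config.input_size // self.stride

    # -- raw network -------------------------------------------------------
    def forward(self, images: np.ndarray) -> np.ndarray:
        """images (N, H, W) standardized -> raw maps (N, 6, g, g):
        channels = (objectness, class, tx, ty, tw, th)."""
        x = images[:, None].astype(np.float32)
        x = nn.avg_pool(x, self.config.downsample)
        return self.net.forward(x)

    def decode_cell(self, maps: np.ndarray, i: int, j: int) -> BoundingBox:
        """Box of cell (i, j) from one image's raw maps (6, g, g).

        The center offset spans (-0.5, 1.5) cells so a cell bordering the
        object can still place the center exactly."""
        s, b = self.stride, self.config.base_box_px
        tx, ty, tw, th = (float(v) for v in maps[2:6, i, j])
        cx = (j + 2.0 * float(nn.sigmoid(np.array(tx))) - 0.5) * s
        cy = (i + 2.0 * float(nn.sigmoid(np.array(ty))) - 0.5) * s
        w = b * math.exp(min(max(tw, -4.0), 4.0))
        h = b * math.exp(min(max(th, -4.0), 4.0))
        conf = float(nn.sigmoid(np.array(maps[0, i, j])) * nn.sigmoid(np.array(maps[1, i, j])))
        return BoundingBox(cx=cx, cy=cy, w=w, h=h, confidence=conf)

    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.net.save(path)
        path.with_suffix(".json").write_text(json.dumps(asdict(self.config)))

    @classmethod
    def load(cls, path) -> "ProbeDetector":
        path = Path(path)
        cfg_path = path.with_suffix(".json")
        config = DetectorConfig(**json.loads(cfg_path.read_text())) if cfg_path.exists() \
            else DetectorConfig()
        det = cls(config)
        det.net.load(path)
        return det


# ---------------------------------------------------------------------------
# loss


def detection_loss(
    maps: np.ndarray,
    truth_boxes: Sequence[BoundingBox],
    config: DetectorConfig,
    stride: int,
    compute_grad: bool = False,
) -> Tuple[float, Optional[np.ndarray], Dict[str, float]]:
    """Single-class detection objective over a batch of raw maps.

    Per image the cell containing the ground-truth box center is the one
    positive: its objectness and class targets are 1 and its decoded box
    incurs the CIoU loss; all other cells carry objectness target 0.  The
    total is ``box_weight * CIoU + obj_weight * BCE_obj + cls_weight *
    BCE_cls``, zero exactly when every box is perfect and the score logits
    saturate at their targets.

    Box regression is additionally supervised at the 3x3 neighborhood of
    the positive cell (the extended center offset lets those cells reach
    the true center), so at inference a near-miss argmax still decodes a
    trained box.  The CIoU gradient w.r.t. the four raw box channels is
    obtained by central finite differences per supervised cell (four
    scalars each; the loss surface is smooth in them).
    """
    n, c, g, _ = maps.shape
    obj_t = np.zeros((n, g, g), dtype=np.float64)
    obj_w = np.ones((n, g, g), dtype=np.float64)
    cells = []
    for b, box in enumerate(truth_boxes):
        j = int(np.clip(box.cx // stride, 0, g - 1))
        i = int(np.clip(box.cy // stride, 0, g - 1))
        # ignore ring: the 8-neighborhood straddles the object boundary and
        # carries no clean positive/negative label
        obj_w[b, max(i - 1, 0) : i + 2, max(j - 1, 0) : j + 2] = 0.0
        obj_t[b, i, j] = 1.0
        obj_w[b, i, j] = config.obj_pos_weight
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                ii, jj = i + di, j + dj
                if not (0 <= ii < g and 0 <= jj < g):
                    continue
                # supervise only cells whose extended offset can reach the
                # true center without saturating
                fx = box.cx / stride - jj
                fy = box.cy / stride - ii
                if -0.46 <= fx <= 1.46 and -0.46 <= fy <= 1.46:
                    cells.append((b, ii, jj))

    obj_loss, obj_grad = nn.bce_with_logits(maps[:, 0], obj_t, weights=obj_w)
    # single class: the class head sees the same presence targets
    cls_loss_raw, cls_grad = nn.bce_with_logits(maps[:, 1], obj_t, weights=obj_w)

    grad = np.zeros_like(maps, dtype=np.float32) if compute_grad else None
    if compute_grad:
        grad[:, 0] = config.obj_weight * obj_grad
        grad[:, 1] = config.cls_weight * cls_grad

    def cell_ciou(raw4: np.ndarray, i: int, j: int, truth: BoundingBox) -> float:
        s, base = stride, config.base_box_px
        cx = (j + 2.0 * float(nn.sigmoid(raw4[0:1])[0]) - 0.5) * s
        cy = (i + 2.0 * float(nn.sigmoid(raw4[1:2])[0]) - 0.5) * s
        w = base * math.exp(min(max(float(raw4[2]), -4.0), 4.0))
        h = base * math.exp(min(max(float(raw4[3]), -4.0), 4.0))
        return ciou_loss(BoundingBox(cx=cx, cy=cy, w=w, h=h), truth)

    box_loss = 0.0
    for b, i, j in cells:
        truth = truth_boxes[b]
        raw4 = maps[b, 2:6, i, j].astype(np.float64)
        box_loss += cell_ciou(raw4, i, j, truth)
        if compute_grad:
            eps = 1e-3
            for k in range(4):
                rp = raw4.copy(); rp[k] += eps
                rm = raw4.copy(); rm[k] -= eps
                d = (cell_ciou(rp, i, j, truth) - cell_ciou(rm, i, j, truth)) / (2 * eps)
                grad[b, 2 + k, i, j] += config.box_weight * d / max(len(cells), 1)
    box_loss /= max(len(cells), 1)

    total = (config.box_weight * box_loss + config.obj_weight * obj_loss
             + config.cls_weight * cls_loss_raw)
    parts = {"box": box_loss, "obj": obj_loss, "cls": cls_loss_raw}
    return float(total), grad, parts


# ---------------------------------------------------------------------------
# training


def train_detector(
    train_samples: Sequence[SceneSample],
    val_samples: Sequence[SceneSample],
    config: DetectorConfig = DetectorConfig(),
    seed: int = 0,
    augment: Optional[AugmentationConfig] = None,
) -> Tuple[ProbeDetector, dict]:
    """Train the reference detector; returns (best model, history).

    The checkpoint achieving the best validation F1 (IoU 0.4) is returned;
    training stops early after ``patience`` epochs without improvement.
    Deterministic given ``seed`` (pure NumPy backend).
    """
    if not train_samples or not val_samples:
        raise ValueError("train and validation splits must be non-empty")
    rng = np.random.default_rng(seed)
    det = ProbeDetector(config, seed=seed)
    opt = nn.SGD(det.net.params(), lr=config.lr, momentum=config.momentum,
                 weight_decay=config.weight_decay)
    n = len(train_samples)
    steps_per_epoch = max(1, n // config.batch_size)
    total_steps = config.max_epochs * steps_per_epoch

    history = {"epochs": [], "config": asdict(config), "seed": seed}
    best = {"f1": -1.0, "epoch": -1, "state": det.net.state_dict()}
    step = 0
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        ep_loss, ep_parts = 0.0, {"box": 0.0, "obj": 0.0, "cls": 0.0}
        for s0 in range(0, n - config.batch_size + 1, config.batch_size) or [0]:
            idx = order[s0 : s0 + config.batch_size]
            if len(idx) == 0:
                idx = order
            batch, boxes = [], []
            for bi in idx:
                smp = train_samples[bi]
                if augment is not None:
                    smp = augment_sample(smp, augment, rng)
                img = smp.normalized if smp.normalized is not None else standardize_image(smp.image)
                batch.append(img)
                boxes.append(smp.box)
            x = np.stack(batch)
            maps = det.forward(x)
            loss, grad, parts = detection_loss(maps, boxes, config, det.stride,
                                              compute_grad=True)
            det.net.backward(grad)
            opt.step(lr=nn.cosine_lr(config.lr, step, total_steps))
            step += 1
            ep_loss += loss
            for k in ep_parts:
                ep_parts[k] += parts[k]
        nb = max(1, steps_per_epoch)
        metrics = _validate(det, val_samples)
        history["epochs"].append(
            {
                "epoch": epoch,
                "train_loss": ep_loss / nb,
                **{f"train_{k}": v / nb for k, v in ep_parts.items()},
                **{f"val_{k}": v for k, v in metrics.items()},
                "lr": nn.cosine_lr(config.lr, step, total_steps),
            }
        )
        if metrics["f1"] > best["f1"]:
            best = {"f1": metrics["f1"], "epoch": epoch, "state": det.net.state_dict()}
        elif epoch - best["epoch"] >= config.patience:
            history["stopped_early"] = epoch
            break
    det.net.load_state_dict(best["state"])
    history["best_epoch"] = best["epoch"]
    history["best_val_f1"] = best["f1"]
    return det, history


def _validate(det: ProbeDetector, samples: Sequence[SceneSample],
              batch: int = 32) -> Dict[str, float]:
    dets = []
    for s0 in range(0, len(samples), batch):
        chunk = samples[s0 : s0 + batch]
        x = np.stack([standardize_image(s.image) for s in chunk])
        maps = det.forward(x)
        for k in range(len(chunk)):
            dets.append(_decode_detections(det, maps[k], image_id=s0 + k))
    truths = [s.box for s in samples]
    return evaluate_detection(dets, truths)[0]


# ---------------------------------------------------------------------------
# inference


def _decode_detections(det: ProbeDetector, maps1: np.ndarray, image_id: int = -1,
                       max_dets: int = 5, nms_iou: float = 0.45) -> List[Detection]:
    conf = nn.sigmoid(maps1[0].astype(np.float64)) * nn.sigmoid(maps1[1].astype(np.float64))
    g = conf.shape[0]
    order = np.argsort(conf, axis=None)[::-1]
    picked: List[Detection] = []
    picked_cells: List[Tuple[int, int]] = []
    for flat in order[: 4 * max_dets]:
        i, j = divmod(int(flat), g)
        if conf[i, j] < det.config.conf_threshold:
            break
        box = det.decode_cell(maps1, i, j)
        # suppress duplicates: box overlap, center containment, or grid
        # adjacency (one cell spans a head-sized region at this stride)
        if any(box_iou(box, p.box) > nms_iou or p.box.contains(box.cx, box.cy)
               for p in picked):
            continue
        if any(abs(i - pi) <= 1 and abs(j - pj) <= 1 for pi, pj in picked_cells):
            continue
        picked.append(Detection(box=box, image_id=image_id))
        picked_cells.append((i, j))
        if len(picked) >= max_dets:
            break
    return picked


def detect_probe(
    det: ProbeDetector, image: np.ndarray, image_id: int = -1
) -> Tuple[List[Detection], Optional[Tuple[float, float]]]:
    """Run the detector on one frame.

    Returns the confidence-sorted detections above threshold plus the
    midpoint (x0, y0) of the top-confidence box in native coordinates —
    the hand-off to the pose stage.  An empty list (midpoint None) is a
    valid negative, never an exception.  Frames whose size differs from the
    input contract are letterbox-resized and boxes mapped back.
    """
    h, w = image.shape
    size = det.config.input_size
    scale, pad_x, pad_y = 1.0, 0, 0
    img = image
    if (h, w) != (size, size):
        scale = size / max(h, w)
        from scipy import ndimage as _ndi

        resized = _ndi.zoom(image.astype(np.float32), scale, order=1)
        rh, rw = resized.shape
        rh, rw = min(rh, size), min(rw, size)
        canvas = np.full((size, size), float(np.median(image)), dtype=np.float32)
        pad_y, pad_x = (size - rh) // 2, (size - rw) // 2
        canvas[pad_y : pad_y + rh, pad_x : pad_x + rw] = resized[:rh, :rw]
        img = canvas
    maps = det.forward(standardize_image(img)[None])[0]
    dets = _decode_detections(det, maps, image_id=image_id)
    if scale != 1.0 or pad_x or pad_y:
        mapped = []
        for d in dets:
            b = d.box
            mapped.append(
                Detection(
                    box=BoundingBox(
                        cx=(b.cx - pad_x) / scale,
                        cy=(b.cy - pad_y) / scale,
                        w=b.w / scale,
                        h=b.h / scale,
                        confidence=b.confidence,
                    ),
                    image_id=d.image_id,
                )
            )
        dets = mapped
    if not dets:
        return [], None
    top = dets[0].box
    return dets, (top.cx, top.cy)


def crop_patch(
    image: np.ndarray, midpoint: Tuple[float, float], size: int = 100
) -> Tuple[np.ndarray, PatchGeometry]:
    """Crop a ``size`` x ``size`` patch centered at ``midpoint`` at native
    resolution, padding out-of-frame regions with the image median.

    The returned :class:`PatchGeometry` records the patch origin in frame
    coordinates so patch-frame pose predictions map back exactly.  The
    geometry's pixel size is filled with 1.0 when unknown; callers carrying
    the frame's pixel size should replace it.
    """
    if size <= 0:
        raise ValueError("patch size must be positive")
    h, w = image.shape
    mx, my = midpoint
    if not (0 <= mx < w and 0 <= my < h):
        raise ValueError(f"midpoint {midpoint} outside image {w}x{h}")
    ox = int(round(mx)) - size // 2
    oy = int(round(my)) - size // 2
    patch = np.full((size, size), float(np.median(image)), dtype=np.float32)
    x0, x1 = max(ox, 0), min(ox + size, w)
    y0, y1 = max(oy, 0), min(oy + size, h)
    patch[y0 - oy : y1 - oy, x0 - ox : x1 - ox] = image[y0:y1, x0:x1]
    return patch, PatchGeometry(pixel_size=1.0, origin=(float(ox), float(oy)),
                                patch_size=size)


# ---------------------------------------------------------------------------
# evaluation


def evaluate_detection(
    detections: Sequence[Sequence[Detection]],
    truths: Sequence[Optional[BoundingBox]],
    iou_threshold: float = 0.4,
) -> Tuple[Dict[str, float], List[dict]]:
    """Precision / recall / F1 under the IoU >= threshold matching rule.

    One ground truth per image: the top-confidence detection is the
    candidate match (TP if IoU >= threshold, FP otherwise); any further
    detections on the same image count as FPs; no detection is a FN.
    Undefined ratios (zero denominators) are reported as 0.
    """
    tp = fp = fn = 0
    outcomes = []
    for img_id, (dets, truth) in enumerate(zip(detections, truths)):
        dets = sorted(dets, key=lambda d: -d.confidence)
        rec = {"image": img_id, "n_detections": len(dets)}
        if truth is None:
            fp += len(dets)
            rec["outcome"] = "fp" if dets else "tn"
        elif not dets:
            fn += 1
            rec["outcome"] = "fn"
        else:
            iou = box_iou(dets[0].box, truth)
            rec["iou"] = iou
            if iou >= iou_threshold:
                tp += 1
                rec["outcome"] = "tp"
            else:
                fp += 1
                fn += 1
                rec["outcome"] = "fp"
            fp += len(dets) - 1
        outcomes.append(rec)
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    f1 = 2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
    return (
        {
            "precision": precision,
            "recall": recall,
            "f1": f1,
            "tp": tp,
            "fp": fp,
            "fn": fn,
            "iou_threshold": iou_threshold,
        },
        outcomes,
    )
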