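"""Stage 2: 5-DoF pose regression on 100x100 patches.

The regressor is a contract (100x100 grayscale patch -> canonical pose);
the reference implementation is a two-pass cascade of compact conv nets,
trainable from scratch on a CPU in minutes:

1. the *main* net regresses the full encoded 6-vector (normalized
   position, plane-angle vector, roll, cosine tilt) from the raw patch;
2. the *refinement* net re-estimates the out-of-plane components (roll and
   cosine tilt) from the patch rotated by the main net's plane-angle
   estimate into a canonical orientation.

Aligning the patch removes the plane-angle confound from the roll cue (the
azimuthal shadow of the probe's internal asymmetry), which makes roll
far more sample-efficient to learn; the refinement net is trained on
truth-aligned patches with a small rotation jitter so it tolerates the
main net's plane-angle error at inference.

The objective is the weighted L1 of the encoded targets,

    L_total = w1 * L_xy + w2 * L_theta + w3 * L_alpha + w4 * L_phi,

with weights (1, 2, 6, 3): the out-of-plane rotations carry extra
emphasis.  The refinement net minimizes the same objective's roll and tilt
terms.  Training uses Adam (default learning rate 1e-4, the full-scale
schedule; the scaled-down desk preset uses 1e-3 for the small nets) with
cosine decay, batch size 32, and keeps the checkpoint with the lowest
validation loss per net.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from . import nn
from .augment import AugmentationConfig, augment_sample, standardize_image
from .geometry import (
    EncodedPoseTarget,
    PatchGeometry,
    Pose5DoF,
    decode_pose,
    encode_pose,
)
from .synth.scene import SceneSample

__all__ = [
    "PoseRegressorConfig",
    "PoseRegressor",
    "weighted_l1_loss",
    "train_pose_regressor",
    "predict_pose",
]

#: Loss weights (position, plane angle, roll, tilt).
DEFAULT_LOSS_WEIGHTS: Tuple[float, float, float, float] = (1.0, 2.0, 6.0, 3.0)


@dataclass(frozen=True)
class PoseRegressorConfig:
    input_size: int = 100
    batch_size: int = 32
    epochs: int = 300
    lr: float = 1e-4
    lr_schedule: str = "cosine"  # "cosine" | "constant"
    weight_decay: float = 0.0
    weights: Tuple[float, float, float, float] = DEFAULT_LOSS_WEIGHTS
    augment_probability: float = 0.20
    arch: str = "compact"  # "compact" | "wide"
    refine: bool = True            # aligned-patch refinement of roll/tilt
    align_jitter_deg: float = 2.0  # rotation jitter when training refinement
    refine_crop: int = 64          # central crop of the aligned patch

    def __post_init__(self):
        if any(w <= 0 for w in self.weights):
            raise ValueError("loss weights must be positive")
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")
        if self.arch not in ("compact", "wide"):
            raise ValueError(f"unknown arch {self.arch!r}")


def _backbone(config: PoseRegressorConfig, n_out: int, head_bias: Sequence[float],
              rng: np.random.Generator, input_size: Optional[int] = None) -> nn.Sequential:
    c = 16 if config.arch == "compact" else 32
    side = config.input_size if input_size is None else input_size
    for _ in range(4):
        side = (side + 1) // 2
    head = nn.Linear(128, n_out, rng=rng)
    # near-zero head: early predictions ride on the biases, which keeps the
    # regression outputs calm while the conv features form
    head.W *= 0.05
    head.b[:] = np.asarray(head_bias, dtype=np.float32)
    return nn.Sequential(
        nn.Conv2d(1, c, 3, 2, rng=rng), nn.ReLU(),
        nn.Conv2d(c, 2 * c, 3, 2, rng=rng), nn.ReLU(),
        nn.Conv2d(2 * c, 4 * c, 3, 2, rng=rng), nn.ReLU(),
        nn.Conv2d(4 * c, 4 * c, 3, 2, rng=rng), nn.ReLU(),
        nn.Flatten(),
        nn.Linear(4 * c * side * side, 128, rng=rng), nn.ReLU(),
        head,
    )


def align_patch(patch: np.ndarray, theta_deg: float,
                crop: Optional[int] = None) -> np.ndarray:
    """Rotate a patch by the plane angle into the canonical orientation,
    optionally keeping only the central ``crop`` x ``crop`` region (the
    roll/tilt cues live on the head, around the patch center)."""
    out = ndimage.rotate(patch, theta_deg, reshape=False, order=1, mode="nearest")
    if crop is not None and crop < out.shape[0]:
        o = (out.shape[0] - crop) // 2
        out = out[o : o + crop, o : o + crop]
    return out


class PoseRegressor:
    """Reference cascade pose regressor (pure NumPy)."""

    def __init__(self, config: PoseRegressorConfig = PoseRegressorConfig(), seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        self.net = _backbone(config, 6, [0.5, 0.5, 0.0, 0.0, 0.5, 0.75], rng)
        self.refine_net = (
            _backbone(config, 2, [0.5, 0.75], rng,
                      input_size=min(config.refine_crop, config.input_size))
            if config.refine else None
        )

    def forward(self, patches: np.ndarray) -> np.ndarray:
        """patches (N, H, W) standardized -> raw main-net 6-vectors (N, 6)."""
        return self.net.forward(patches[:, None].astype(np.float32))

    def forward_refine(self, aligned: np.ndarray) -> np.ndarray:
        """aligned patches (N, H, W) standardized -> raw (rn, ct) pairs."""
        if self.refine_net is None:
            raise RuntimeError("refinement net disabled in config")
        return self.refine_net.forward(aligned[:, None].astype(np.float32))

    # -- persistence -------------------------------------------------------
    def state_dict(self) -> dict:
        state = {f"main/{k}": v for k, v in self.net.state_dict().items()}
        if self.refine_net is not None:
            state.update({f"refine/{k}": v for k, v in self.refine_net.state_dict().items()})
        return state

    def load_state_dict(self, state: dict) -> None:
        self.net.load_state_dict(
            {k[5:]: v for k, v in state.items() if k.startswith("main/")}
        )
        if self.refine_net is not None:
            refine = {k[7:]: v for k, v in state.items() if k.startswith("refine/")}
            if refine:
                self.refine_net.load_state_dict(refine)

    def save(self, path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        np.savez(path, **self.state_dict())
        path.with_suffix(".json").write_text(json.dumps(asdict(self.config)))

    @classmethod
    def load(cls, path) -> "PoseRegressor":
        path = Path(path)
        cfg_path = path.with_suffix(".json")
        if cfg_path.exists():
            d = json.loads(cfg_path.read_text())
            d["weights"] = tuple(d["weights"])
            config = PoseRegressorConfig(**d)
        else:
            config = PoseRegressorConfig()
        reg = cls(config)
        with np.load(path) as data:
            reg.load_state_dict({k: data[k] for k in data.files})
        return reg


# ---------------------------------------------------------------------------
# loss


def weighted_l1_loss(
    pred: np.ndarray,
    truth: np.ndarray,
    weights: Tuple[float, float, float, float] = DEFAULT_LOSS_WEIGHTS,
    compute_grad: bool = False,
):
    """Weighted L1 over encoded targets; supports (6,) or (N, 6) arrays.

    Component terms: L_xy = |dxn| + |dyn|, L_theta = |dtx| + |dty|,
    L_alpha = |drn|, L_phi = |dct|; total = w1 L_xy + w2 L_theta +
    w3 L_alpha + w4 L_phi, averaged over the batch.  Zero iff identical.
    """
    p = np.atleast_2d(np.asarray(pred, dtype=np.float64))
    t = np.atleast_2d(np.asarray(truth, dtype=np.float64))
    if p.shape != t.shape or p.shape[1] != 6:
        raise ValueError(f"expected matching (N, 6) arrays, got {p.shape} vs {t.shape}")
    w1, w2, w3, w4 = weights
    comp_w = np.array([w1, w1, w2, w2, w3, w4])
    diff = p - t
    loss = float((np.abs(diff) * comp_w).sum(axis=1).mean())
    if not compute_grad:
        return loss
    grad = (np.sign(diff) * comp_w / p.shape[0]).astype(np.float32)
    return loss, grad


def _encode_batch(samples: Sequence[SceneSample]) -> np.ndarray:
    rows = []
    for s in samples:
        if s.patch_geom is None:
            raise ValueError("pose samples must carry a PatchGeometry")
        rows.append(encode_pose(s.pose, s.patch_geom).to_array())
    return np.stack(rows)


# ---------------------------------------------------------------------------
# training


def train_pose_regressor(
    train_samples: Sequence[SceneSample],
    val_samples: Sequence[SceneSample],
    config: PoseRegressorConfig = PoseRegressorConfig(),
    seed: int = 0,
    augment: Optional[AugmentationConfig] = None,
    snapshot_epochs: Sequence[int] = (),
) -> Tuple[PoseRegressor, dict]:
    """Train the reference cascade; returns (best model, history).

    The main net and (when enabled) the refinement net are trained in
    sequence for ``config.epochs`` each; per net the checkpoint with the
    lowest validation loss is kept (ties favor the earlier epoch).
    ``snapshot_epochs`` records the best-so-far states as of those epoch
    counts (1-based) in ``history['snapshots']``, so a shorter-budget model
    can be read out of a longer run.  Deterministic given ``seed``.
    """
    if not train_samples or not val_samples:
        raise ValueError("train and validation splits must be non-empty")
    rng = np.random.default_rng(seed)
    reg = PoseRegressor(config, seed=seed)
    n = len(train_samples)
    steps_per_epoch = max(1, math.ceil(n / config.batch_size))
    total_steps = config.epochs * steps_per_epoch

    val_targets = _encode_batch(val_samples)
    val_x = np.stack([standardize_image(s.image) for s in val_samples])
    train_targets = _encode_batch(train_samples)
    train_x = None
    if augment is None:
        train_x = np.stack([standardize_image(s.image) for s in train_samples])

    history = {"epochs": [], "config": asdict(config), "seed": seed, "snapshots": {}}

    # -- main net ----------------------------------------------------------
    opt = nn.Adam(reg.net.params(), lr=config.lr, weight_decay=config.weight_decay)
    best = {"val_loss": float("inf"), "epoch": -1, "state": reg.net.state_dict()}
    snapshots_main: Dict[int, dict] = {}
    step = 0
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        ep_loss, nb = 0.0, 0
        for s0 in range(0, n, config.batch_size):
            idx = order[s0 : s0 + config.batch_size]
            if augment is not None:
                imgs, targets = [], []
                for bi in idx:
                    smp = augment_sample(train_samples[bi], augment, rng)
                    targets.append(encode_pose(smp.pose, smp.patch_geom).to_array())
                    imgs.append(smp.normalized)
                x = np.stack(imgs)
                t = np.stack(targets)
            else:
                x = train_x[idx]
                t = train_targets[idx]
            out = reg.forward(x)
            loss, grad = weighted_l1_loss(out, t, config.weights, compute_grad=True)
            reg.net.backward(grad)
            lr = (nn.cosine_lr(config.lr, step, total_steps)
                  if config.lr_schedule == "cosine" else config.lr)
            opt.step(lr=lr)
            step += 1
            ep_loss += loss
            nb += 1
        val_loss = _val_loss_main(reg, val_x, val_targets, config)
        history["epochs"].append(
            {"epoch": epoch, "net": "main", "train_loss": ep_loss / max(nb, 1),
             "val_loss": val_loss, "weights": list(config.weights)}
        )
        if val_loss < best["val_loss"]:
            best = {"val_loss": val_loss, "epoch": epoch, "state": reg.net.state_dict()}
        if (epoch + 1) in snapshot_epochs:
            snapshots_main[epoch + 1] = {
                "state": {k: v.copy() for k, v in best["state"].items()},
                "val_loss": best["val_loss"], "epoch": best["epoch"],
            }
    reg.net.load_state_dict(best["state"])
    history["best_epoch"] = best["epoch"]
    history["best_val_loss"] = best["val_loss"]

    # -- refinement net ----------------------------------------------------
    snapshots_refine: Dict[int, dict] = {}
    if config.refine:
        w_refine = np.array([config.weights[2], config.weights[3]])
        rt_train = train_targets[:, 4:6]
        rt_val = val_targets[:, 4:6]
        # two pre-aligned variants with rotation jitter, alternated per
        # epoch: cheap stand-in for re-aligning every epoch
        variants = []
        for _ in range(2):
            variants.append(
                np.stack(
                    [
                        standardize_image(
                            align_patch(
                                s.image,
                                s.pose.theta
                                + (rng.normal(0.0, config.align_jitter_deg)
                                   if config.align_jitter_deg > 0 else 0.0),
                                crop=config.refine_crop,
                            )
                        )
                        for s in train_samples
                    ]
                ).astype(np.float32)
            )
        val_aligned = np.stack(
            [standardize_image(align_patch(s.image, s.pose.theta, crop=config.refine_crop))
             for s in val_samples]
        ).astype(np.float32)

        opt_r = nn.Adam(reg.refine_net.params(), lr=config.lr,
                        weight_decay=config.weight_decay)
        best_r = {"val_loss": float("inf"), "epoch": -1,
                  "state": reg.refine_net.state_dict()}
        step = 0
        for epoch in range(config.epochs):
            x_all = variants[epoch % len(variants)]
            order = rng.permutation(n)
            ep_loss, nb = 0.0, 0
            for s0 in range(0, n, config.batch_size):
                idx = order[s0 : s0 + config.batch_size]
                out = reg.forward_refine(x_all[idx])
                diff = out - rt_train[idx]
                loss = float((np.abs(diff) * w_refine).sum(axis=1).mean())
                grad = (np.sign(diff) * w_refine / len(idx)).astype(np.float32)
                reg.refine_net.backward(grad)
                lr = (nn.cosine_lr(config.lr, step, total_steps)
                      if config.lr_schedule == "cosine" else config.lr)
                opt_r.step(lr=lr)
                step += 1
                ep_loss += loss
                nb += 1
            vout = reg.forward_refine(val_aligned)
            val_loss = float((np.abs(vout - rt_val) * w_refine).sum(axis=1).mean())
            history["epochs"].append(
                {"epoch": epoch, "net": "refine", "train_loss": ep_loss / max(nb, 1),
                 "val_loss": val_loss}
            )
            if val_loss < best_r["val_loss"]:
                best_r = {"val_loss": val_loss, "epoch": epoch,
                          "state": reg.refine_net.state_dict()}
            if (epoch + 1) in snapshot_epochs:
                snapshots_refine[epoch + 1] = {
                    "state": {k: v.copy() for k, v in best_r["state"].items()},
                    "val_loss": best_r["val_loss"], "epoch": best_r["epoch"],
                }
        reg.refine_net.load_state_dict(best_r["state"])
        history["refine_best_epoch"] = best_r["epoch"]
        history["refine_best_val_loss"] = best_r["val_loss"]

    for ep in snapshot_epochs:
        if ep in snapshots_main:
            state = dict(snapshots_main[ep]["state"].items())
            state = {f"main/{k}": v for k, v in state.items()}
            if ep in snapshots_refine:
                state.update({f"refine/{k}": v
                              for k, v in snapshots_refine[ep]["state"].items()})
            history["snapshots"][ep] = {
                "state": state,
                "val_loss": snapshots_main[ep]["val_loss"],
                "epoch": snapshots_main[ep]["epoch"],
            }
    return reg, history


def _val_loss_main(reg: PoseRegressor, val_x: np.ndarray, val_t: np.ndarray,
                   config: PoseRegressorConfig, batch: int = 64) -> float:
    total, n = 0.0, 0
    for s0 in range(0, len(val_x), batch):
        out = reg.forward(val_x[s0 : s0 + batch])
        t = val_t[s0 : s0 + batch]
        total += weighted_l1_loss(out, t, config.weights) * len(t)
        n += len(t)
    return total / max(n, 1)


# ---------------------------------------------------------------------------
# inference


def predict_pose(
    reg: PoseRegressor, patch: np.ndarray, geom: PatchGeometry
) -> Pose5DoF:
    """Predict the canonical pose of one patch, in frame coordinates.

    The main net supplies position and plane angle; when the refinement net
    is enabled the patch is rotated by the estimated plane angle and the
    roll/tilt components re-estimated from the aligned view.  The raw
    outputs are decoded with clamping (off-manifold values are absorbed),
    so the result always satisfies the pose invariants.
    """
    if patch.shape != (geom.patch_size, geom.patch_size):
        raise ValueError(
            f"patch shape {patch.shape} does not match geometry {geom.patch_size}"
        )
    raw = reg.forward(standardize_image(patch)[None])[0].astype(np.float64)
    if reg.refine_net is not None:
        theta = math.degrees(math.atan2(raw[3], raw[2])) % 360.0
        aligned = standardize_image(
            align_patch(patch, theta, crop=reg.config.refine_crop)
        )
        raw[4:6] = reg.forward_refine(aligned[None])[0]
    return decode_pose(EncodedPoseTarget.from_array(raw), geom)
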