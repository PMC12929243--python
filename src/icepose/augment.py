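"""Training-time augmentations: photometric, geometric and X-ray noise
models, with exact label transforms.

The menu mirrors typical fluoroscopy training pipelines: random brightness
and contrast, translations (up to ±10% of the image size), scaling
(±50%), horizontal flipping, additive Gaussian noise (sigma on the
normalized [0, 1] intensity scale) and Poisson (photon counting) noise.
Each enabled augmentation is applied independently with the configured
probability — 0.30 for the detection stage, 0.20 for the pose stage.

Geometric augmentations transform the labels exactly: a flip maps
``x -> W-1-x``, ``theta -> (180 - theta) mod 360``, ``alpha -> -alpha``
(folded back to the canonical half-range) and leaves the tilt magnitude
unchanged; scaling about the image center rescales positions, box extents
and the effective pixel size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace as dc_replace
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage

from .geometry import BoundingBox, Pose5DoF, canonicalize_pose
from .synth.scene import SceneSample

__all__ = [
    "AugmentationConfig",
    "apply_gaussian_noise",
    "apply_poisson_noise",
    "apply_brightness_contrast",
    "apply_geometric",
    "augment_sample",
    "standardize_image",
]


@dataclass(frozen=True)
class AugmentationConfig:
    """Menu and ranges of the augmentation sampler.

    ``probability`` is the independent per-augmentation application chance
    (0.30 for detection, 0.20 for pose).  ``poisson_counts`` is the photon
    count corresponding to unit intensity in the Poisson model (8-bit
    photon-equivalent by default).
    """

    probability: float = 0.30
    brightness_delta: float = 0.2
    contrast_range: Tuple[float, float] = (0.8, 1.2)
    translate_frac: float = 0.10
    scale_range: Tuple[float, float] = (0.5, 1.5)
    hflip: bool = True
    gaussian_sigma_range: Tuple[float, float] = (0.0, 1.0)
    poisson_scale_range: Tuple[float, float] = (0.8, 1.2)
    poisson_counts: float = 255.0
    geometric_enabled: bool = True
    noise_enabled: bool = True
    photometric_enabled: bool = True

    def __post_init__(self):
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("probability must be in [0, 1]")
        for lo, hi in (self.contrast_range, self.scale_range,
                       self.gaussian_sigma_range, self.poisson_scale_range):
            if lo > hi:
                raise ValueError("range endpoints must be ordered")


# ---------------------------------------------------------------------------
# photometric / noise


def apply_gaussian_noise(image: np.ndarray, sigma: float,
                         rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Add zero-mean Gaussian noise of standard deviation ``sigma`` (on the
    [0, 1] intensity scale) and clip back to [0, 1]."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return image.copy()
    rng = rng or np.random.default_rng()
    noisy = image + rng.normal(0.0, sigma, size=image.shape)
    return np.clip(noisy, 0.0, 1.0).astype(np.float32)


def apply_poisson_noise(image: np.ndarray, scale: float,
                        rng: Optional[np.random.Generator] = None,
                        counts: float = 255.0) -> np.ndarray:
    """Photon-counting noise: sample Poisson(scale * counts * I) and rescale
    by the same factor, preserving the expected intensity (pre-clip)."""
    rng = rng or np.random.default_rng()
    lam = np.clip(image, 0.0, None).astype(np.float64) * (scale * counts)
    out = rng.poisson(lam) / (scale * counts)
    return np.clip(out, 0.0, 1.0).astype(np.float32)


def apply_brightness_contrast(image: np.ndarray, delta: float, factor: float) -> np.ndarray:
    """Contrast stretch about mid-gray then brightness shift, clipped."""
    out = (image - 0.5) * factor + 0.5 + delta
    return np.clip(out, 0.0, 1.0).astype(np.float32)


def standardize_image(image: np.ndarray) -> np.ndarray:
    """Per-image standardization to zero mean, unit variance (the network
    input normalization)."""
    m = float(image.mean())
    s = float(image.std())
    return ((image - m) / (s if s > 1e-8 else 1.0)).astype(np.float32)


# ---------------------------------------------------------------------------
# geometric


def _flip_pose(pose: Pose5DoF, width: int) -> Pose5DoF:
    return canonicalize_pose(
        Pose5DoF(
            x=(width - 1) - pose.x,
            y=pose.y,
            theta=(180.0 - pose.theta) % 360.0,
            alpha=-pose.alpha,
            phi=pose.phi,
        )
    )


def apply_geometric(
    sample: SceneSample,
    translate_px: Tuple[float, float] = (0.0, 0.0),
    scale: float = 1.0,
    hflip: bool = False,
    limits: Optional[AugmentationConfig] = None,
) -> SceneSample:
    """Warp the image and map every label through the same transform.

    The affine map is: optional horizontal flip, then scaling by ``scale``
    about the image center, then translation by ``translate_px``.  The pose
    position and box follow the map exactly; scaling divides the effective
    pixel size by ``scale`` (a zoomed-in probe subtends more pixels per mm).
    """
    h, w = sample.image.shape
    if limits is not None:
        tmax = limits.translate_frac * max(h, w) + 1e-9
        if abs(translate_px[0]) > tmax or abs(translate_px[1]) > tmax:
            raise ValueError(f"translation {translate_px} outside configured limit")
        lo, hi = limits.scale_range
        if not (lo - 1e-9 <= scale <= hi + 1e-9):
            raise ValueError(f"scale {scale} outside configured range {limits.scale_range}")

    img = sample.image
    pose = sample.pose
    box = sample.box

    if hflip:
        img = img[:, ::-1]
        pose = _flip_pose(pose, w)
        if box is not None:
            box = dc_replace(box, cx=(w - 1) - box.cx)

    cx_img, cy_img = (w - 1) / 2.0, (h - 1) / 2.0
    tx, ty = translate_px

    def fwd(x, y):
        return (
            (x - cx_img) * scale + cx_img + tx,
            (y - cy_img) * scale + cy_img + ty,
        )

    if scale != 1.0 or tx or ty:
        # inverse map for ndimage (output pixel -> input pixel), (row, col)
        inv_scale = 1.0 / scale
        matrix = np.array([[inv_scale, 0.0], [0.0, inv_scale]])
        # affine_transform computes input = matrix @ output + offset, (row, col)
        offset = np.array(
            [
                (0.0 - ty - cy_img) * inv_scale + cy_img + 0.0,
                (0.0 - tx - cx_img) * inv_scale + cx_img + 0.0,
            ]
        )
        fill = float(np.median(img))
        img = ndimage.affine_transform(
            img.astype(np.float32), matrix, offset=offset, order=1, mode="constant",
            cval=fill,
        )
        px, py = fwd(pose.x, pose.y)
        pose = dc_replace(pose, x=px, y=py)
        if box is not None:
            bx, by = fwd(box.cx, box.cy)
            box = dc_replace(box, cx=bx, cy=by, w=box.w * scale, h=box.h * scale)

    pixel_size = sample.pixel_size / scale
    patch_geom = sample.patch_geom
    if patch_geom is not None and scale != 1.0:
        patch_geom = dc_replace(patch_geom, pixel_size=pixel_size)
    return SceneSample(
        image=np.ascontiguousarray(img, dtype=np.float32),
        pixel_size=pixel_size,
        pose=pose,
        box=box,
        provenance={**sample.provenance, "augmented": True},
        patch_geom=patch_geom,
    )


# ---------------------------------------------------------------------------
# sampler


def augment_sample(
    sample: SceneSample,
    config: AugmentationConfig,
    rng: np.random.Generator,
) -> SceneSample:
    """Apply each enabled augmentation independently with probability
    ``config.probability``; the result carries the raw [0, 1] image plus the
    standardized network input in ``normalized``.

    Deterministic given the generator state; the menu decisions and their
    parameters are drawn in a fixed order.
    """
    p = config.probability
    out = sample

    if config.geometric_enabled:
        do_t = rng.uniform() < p
        t = rng.uniform(-config.translate_frac, config.translate_frac, size=2)
        do_s = rng.uniform() < p
        s = rng.uniform(*config.scale_range)
        do_f = config.hflip and (rng.uniform() < p)
        h, w = out.image.shape
        translate = (t[0] * w, t[1] * h) if do_t else (0.0, 0.0)
        scale = s if do_s else 1.0
        if do_t or do_s or do_f:
            out = apply_geometric(out, translate_px=translate, scale=scale,
                                  hflip=do_f, limits=config)

    if config.photometric_enabled:
        do_bc = rng.uniform() < p
        delta = rng.uniform(-config.brightness_delta, config.brightness_delta)
        factor = rng.uniform(*config.contrast_range)
        if do_bc:
            out = dc_replace(out, image=apply_brightness_contrast(out.image, delta, factor))

    if config.noise_enabled:
        do_g = rng.uniform() < p
        sigma = rng.uniform(*config.gaussian_sigma_range)
        if do_g:
            out = dc_replace(out, image=apply_gaussian_noise(out.image, sigma, rng))
        do_p = rng.uniform() < p
        scale = rng.uniform(*config.poisson_scale_range)
        if do_p:
            out = dc_replace(
                out,
                image=apply_poisson_noise(out.image, scale, rng, config.poisson_counts),
            )

    return dc_replace(out, normalized=standardize_image(out.image))
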