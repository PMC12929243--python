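"""Scene composition and the two labeled samplers (detection frames and
pose patches).

A scene is ``background * feathered(transmission)``: the probe only removes
intensity (X-ray attenuation), and the probe edge is feathered with a small
Gaussian so the composite transitions smoothly into the background, as the
hard silhouette of a resampled projection otherwise betrays itself.

Pose sampling emulates the admissible study conditions: pixel size uniform
on [0.25, 0.55] mm, plane angle uniform on [0, 360), roll uniform on
[-90, 90), tilt magnitude uniform on [0, 60]; positions keep the probe head
inside the field of view.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage

from ..geometry import (
    BoundingBox,
    PatchGeometry,
    Pose5DoF,
    TILT_LIMIT_DEG,
    canonicalize_pose,
)
from .background import ClutterConfig, generate_background
from .probe import (
    DetectorGeometry,
    ProbeModel,
    head_box_from_transmission,
    project_probe,
)

__all__ = [
    "SceneSample",
    "SceneConfig",
    "composite_scene",
    "make_detection_sample",
    "make_pose_sample",
]

#: Pixel-size sampling range (mm/px) of the study conditions.
PIXEL_SIZE_RANGE = (0.25, 0.55)

#: Transmission below this threshold counts as probe material.
PROBE_MASK_THRESHOLD = 0.995


@dataclass
class SceneSample:
    """One labeled synthetic frame or patch.

    ``image`` is float32 in [0, 1]; ``pose`` is expressed in the coordinates
    of ``image`` (for pose patches that means patch coordinates, with
    ``patch_geom`` recording the crop origin in the source frame); ``box``
    is the probe-head bounding box, present for detection frames.
    """

    image: np.ndarray
    pixel_size: float
    pose: Pose5DoF
    box: Optional[BoundingBox]
    provenance: dict
    patch_geom: Optional[PatchGeometry] = None
    normalized: Optional[np.ndarray] = None


@dataclass(frozen=True)
class SceneConfig:
    """Knobs of the scene sampler (study conditions as defaults)."""

    image_size: int = 512
    patch_size: int = 100
    pixel_size_range: Tuple[float, float] = PIXEL_SIZE_RANGE
    feather_width_px: float = 2.0
    midpoint_jitter_px: float = 8.0
    margin_frac: float = 0.15           # keep the head this far inside the frame
    max_wires: int = 3
    sheath_prob: float = 0.3
    anatomy_amplitude: float = 0.12
    background_enabled: bool = True


def composite_scene(
    transmission: np.ndarray,
    background: np.ndarray,
    feather_width_px: float = 2.0,
) -> np.ndarray:
    """Multiply the background by the edge-feathered probe transmission.

    Feathering blurs the transmission with a Gaussian of sigma =
    ``feather_width_px / 2`` so the probe edge ramps over roughly the stated
    width.  Attenuation only darkens: the output is <= background pixelwise
    and stays in [0, 1].
    """
    if transmission.shape != background.shape:
        raise ValueError(
            f"shape mismatch: transmission {transmission.shape} vs background {background.shape}"
        )
    t = transmission.astype(np.float64)
    if feather_width_px > 0:
        t = ndimage.gaussian_filter(t, feather_width_px / 2.0)
        np.clip(t, 0.0, 1.0, out=t)
    return np.clip(background.astype(np.float64) * t, 0.0, 1.0).astype(np.float32)


def _sample_pose_angles(rng: np.random.Generator) -> Tuple[float, float, float]:
    theta = rng.uniform(0.0, 360.0)
    alpha = rng.uniform(-90.0, 90.0)
    phi = rng.uniform(0.0, TILT_LIMIT_DEG)
    return theta, alpha, phi


def _sample_clutter(rng: np.random.Generator, cfg: SceneConfig) -> ClutterConfig:
    if not cfg.background_enabled:
        return ClutterConfig(n_wires=0, sheath=False, anatomy_amplitude=0.0,
                             vignette_strength=0.0, base_level=0.9)
    return ClutterConfig(
        n_wires=int(rng.integers(0, cfg.max_wires + 1)),
        sheath=bool(rng.uniform() < cfg.sheath_prob),
        anatomy_amplitude=cfg.anatomy_amplitude,
    )


def make_detection_sample(
    model: ProbeModel,
    rng: np.random.Generator,
    cfg: SceneConfig = SceneConfig(),
) -> SceneSample:
    """Sample one labeled 512x512 detection frame."""
    n = cfg.image_size
    pixel_size = rng.uniform(*cfg.pixel_size_range)
    margin = cfg.margin_frac * n
    theta, alpha, phi = _sample_pose_angles(rng)
    pose = canonicalize_pose(
        Pose5DoF(
            x=rng.uniform(margin, n - margin),
            y=rng.uniform(margin, n - margin),
            theta=theta,
            alpha=alpha,
            phi=phi,
        )
    )
    geom = DetectorGeometry(image_size=n, pixel_size=pixel_size)
    T, meta = project_probe(model, pose, geom)
    T_head, _ = project_probe(model, pose, geom, head_only=True)
    box = head_box_from_transmission(T_head, PROBE_MASK_THRESHOLD)
    bg_seed = int(rng.integers(0, 2**31 - 1))
    clutter = _sample_clutter(rng, cfg)
    background, inventory = generate_background(bg_seed, clutter, shape=(n, n))
    image = composite_scene(T, background, cfg.feather_width_px)
    provenance = {
        "background": inventory,
        "feather_width_px": cfg.feather_width_px,
        "out_of_fov": meta["out_of_fov"],
    }
    return SceneSample(
        image=image,
        pixel_size=pixel_size,
        pose=pose,
        box=box,
        provenance=provenance,
    )


def make_pose_sample(
    model: ProbeModel,
    rng: np.random.Generator,
    cfg: SceneConfig = SceneConfig(),
    midpoint_jitter_px: Optional[float] = None,
) -> SceneSample:
    """Sample one labeled 100x100 pose patch.

    A scene just larger than the patch is rendered around the transducer
    window center; the crop center is the true window center plus a uniform
    jitter within ``midpoint_jitter_px`` per axis, emulating the coarse
    detector's midpoint error.  The pose label is expressed in patch
    coordinates; ``patch_geom`` records the crop origin in the rendered
    frame.
    """
    jitter = cfg.midpoint_jitter_px if midpoint_jitter_px is None else midpoint_jitter_px
    if jitter < 0:
        raise ValueError("midpoint jitter must be >= 0")
    ps = cfg.patch_size
    pixel_size = rng.uniform(*cfg.pixel_size_range)
    frame = int(ps + 2 * math.ceil(jitter) + 8)
    c = frame / 2.0
    theta, alpha, phi = _sample_pose_angles(rng)
    pose_frame = canonicalize_pose(Pose5DoF(x=c, y=c, theta=theta, alpha=alpha, phi=phi))
    geom = DetectorGeometry(image_size=frame, pixel_size=pixel_size)
    T, meta = project_probe(model, pose_frame, geom)
    bg_seed = int(rng.integers(0, 2**31 - 1))
    clutter = _sample_clutter(rng, cfg)
    background, inventory = generate_background(bg_seed, clutter, shape=(frame, frame))
    scene = composite_scene(T, background, cfg.feather_width_px)

    jx = rng.uniform(-jitter, jitter) if jitter > 0 else 0.0
    jy = rng.uniform(-jitter, jitter) if jitter > 0 else 0.0
    ox = int(round(c + jx - ps / 2.0))
    oy = int(round(c + jy - ps / 2.0))
    ox = min(max(ox, 0), frame - ps)
    oy = min(max(oy, 0), frame - ps)
    patch = scene[oy : oy + ps, ox : ox + ps]
    # origin (0, 0): the pose label below is already in patch coordinates;
    # the crop origin within the rendered frame is kept in provenance.
    patch_geom = PatchGeometry(pixel_size=pixel_size, origin=(0.0, 0.0), patch_size=ps)
    pose_patch = Pose5DoF(
        x=pose_frame.x - ox,
        y=pose_frame.y - oy,
        theta=pose_frame.theta,
        alpha=pose_frame.alpha,
        phi=pose_frame.phi,
    )
    provenance = {
        "background": inventory,
        "feather_width_px": cfg.feather_width_px,
        "out_of_fov": meta["out_of_fov"],
        "jitter_px": (jx, jy),
        "crop_origin": (ox, oy),
        "frame_size": frame,
    }
    return SceneSample(
        image=np.ascontiguousarray(patch),
        pixel_size=pixel_size,
        pose=pose_patch,
        box=None,
        provenance=provenance,
        patch_geom=patch_geom,
    )
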