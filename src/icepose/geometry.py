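"""5-DoF pose representation, symmetry canonicalization, target encoding and
box-overlap mathematics.

The probe pose observable in a single parallel X-ray projection has five
degrees of freedom: the in-plane position of the transducer-window center
(``x``, ``y``, in detector pixels), the in-plane ("plane") angle ``theta``,
the roll ``alpha`` about the probe's long axis, and the out-of-plane tilt
``phi``.  Projection symmetry makes only part of the rotation space
observable:

* ``theta`` is fully recoverable and lives on [0, 360);
* the probe body is built with an exact 180-degree roll symmetry, so roll is
  only defined modulo 180 degrees; the canonical half-range is [-90, 90);
* the sign of the tilt (toward/away from the detector) is unobservable, so
  ``phi`` is a magnitude, restricted to [0, 60] degrees — beyond 60 degrees
  foreshortening makes the pose clinically irrelevant and the generator never
  produces it.

Angles are degrees throughout; positions are pixels unless a ``pixel_size``
(mm/px) is applied explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

__all__ = [
    "Pose5DoF",
    "EncodedPoseTarget",
    "BoundingBox",
    "PatchGeometry",
    "PoseError",
    "TILT_LIMIT_DEG",
    "canonicalize_pose",
    "encode_pose",
    "decode_pose",
    "pose_abs_error",
    "box_iou",
    "ciou_loss",
    "wrap_angle_diff",
]

#: Maximum admissible tilt magnitude (degrees).  Larger tilts foreshorten the
#: probe so strongly that the pose is not considered recoverable or relevant.
TILT_LIMIT_DEG = 60.0

_CANON_ATOL = 1e-9


class PoseRangeError(ValueError):
    """Raised when a pose parameter cannot be folded into its canonical range."""


@dataclass(frozen=True)
class Pose5DoF:
    """Canonical 5-DoF probe pose.

    Attributes
    ----------
    x, y:
        Position of the transducer-window center in image coordinates
        (pixels; origin top-left, x rightward, y downward).
    theta:
        In-plane angle in degrees, [0, 360).  theta = 0 points along +x,
        increasing toward +y (screen-clockwise).
    alpha:
        Roll about the long axis, degrees, canonical half-range [-90, 90).
    phi:
        Tilt magnitude out of the imaging plane, degrees, [0, 60].
    """

    x: float
    y: float
    theta: float = 0.0
    alpha: float = 0.0
    phi: float = 0.0

    def is_canonical(self, atol: float = 1e-6) -> bool:
        return (
            -atol <= self.theta < 360.0 + atol
            and self.theta < 360.0
            and -90.0 - atol <= self.alpha < 90.0
            and -atol <= self.phi <= TILT_LIMIT_DEG + atol
        )

    def to_json_dict(self, pixel_size: Optional[float] = None) -> dict:
        d = {
            "x_px": float(self.x),
            "y_px": float(self.y),
            "theta_deg": float(self.theta),
            "alpha_deg": float(self.alpha),
            "phi_deg": float(self.phi),
        }
        if pixel_size is not None:
            d["pixel_size_mm"] = float(pixel_size)
        return d

    @classmethod
    def from_json_dict(cls, d: dict) -> "Pose5DoF":
        return cls(
            x=float(d["x_px"]),
            y=float(d["y_px"]),
            theta=float(d["theta_deg"]),
            alpha=float(d["alpha_deg"]),
            phi=float(d["phi_deg"]),
        )


@dataclass(frozen=True)
class EncodedPoseTarget:
    """Network regression target: the 6-vector (xn, yn, tx, ty, rn, ct).

    ``xn, yn`` are the position as a fraction of the patch side; ``(tx, ty)``
    is the plane angle decomposed as (cos theta, sin theta); ``rn`` is the
    roll mapped linearly from [-90, 90] to [0, 1]; ``ct = cos(phi)`` lies in
    [0.5, 1.0] over the admissible tilt range [60, 0] degrees.
    """

    xn: float
    yn: float
    tx: float
    ty: float
    rn: float
    ct: float

    def to_array(self) -> np.ndarray:
        return np.array(
            [self.xn, self.yn, self.tx, self.ty, self.rn, self.ct], dtype=np.float64
        )

    @classmethod
    def from_array(cls, a) -> "EncodedPoseTarget":
        a = np.asarray(a, dtype=np.float64).reshape(6)
        return cls(*(float(v) for v in a))


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box in continuous pixel coordinates, center/size form."""

    cx: float
    cy: float
    w: float
    h: float
    confidence: Optional[float] = None

    def __post_init__(self):
        if not (self.w > 0 and self.h > 0):
            raise ValueError(f"box extents must be positive, got w={self.w}, h={self.h}")

    @property
    def x0(self) -> float:
        return self.cx - self.w / 2.0

    @property
    def x1(self) -> float:
        return self.cx + self.w / 2.0

    @property
    def y0(self) -> float:
        return self.cy - self.h / 2.0

    @property
    def y1(self) -> float:
        return self.cy + self.h / 2.0

    @property
    def area(self) -> float:
        return self.w * self.h

    def contains(self, x: float, y: float) -> bool:
        return self.x0 <= x <= self.x1 and self.y0 <= y <= self.y1

    def to_json_dict(self) -> dict:
        d = {"cx": float(self.cx), "cy": float(self.cy), "w": float(self.w), "h": float(self.h)}
        if self.confidence is not None:
            d["confidence"] = float(self.confidence)
        return d

    @classmethod
    def from_json_dict(cls, d: dict) -> "BoundingBox":
        return cls(
            cx=float(d["cx"]),
            cy=float(d["cy"]),
            w=float(d["w"]),
            h=float(d["h"]),
            confidence=float(d["confidence"]) if "confidence" in d else None,
        )


@dataclass(frozen=True)
class PatchGeometry:
    """Geometry of a crop taken from a full frame.

    ``origin`` is the (x, y) of the patch's top-left pixel in frame
    coordinates; ``pixel_size`` is mm per pixel (native resolution is kept
    when cropping, so the patch inherits the frame's pixel size).
    """

    pixel_size: float
    origin: tuple = (0.0, 0.0)
    patch_size: int = 100

    def __post_init__(self):
        if self.patch_size <= 0:
            raise ValueError("patch_size must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    def frame_to_patch(self, x: float, y: float) -> tuple:
        return (x - self.origin[0], y - self.origin[1])

    def patch_to_frame(self, x: float, y: float) -> tuple:
        return (x + self.origin[0], y + self.origin[1])


@dataclass(frozen=True)
class PoseError:
    """Per-parameter absolute errors: positions in mm, angles in degrees.

    Angular errors use the wrap metric of each parameter's canonical space:
    plane angle wraps at 360 (reported <= 180), roll on its 180-degree-
    periodic half-range (reported <= 90), tilt is a plain difference of
    magnitudes (<= 60).
    """

    ex: float
    ey: float
    etheta: float
    ealpha: float
    ephi: float

    def as_dict(self) -> dict:
        return {
            "x": self.ex,
            "y": self.ey,
            "theta": self.etheta,
            "alpha": self.ealpha,
            "phi": self.ephi,
        }


# ---------------------------------------------------------------------------
# canonicalization


def canonicalize_pose(pose: Pose5DoF) -> Pose5DoF:
    """Fold a raw pose into the canonical observable ranges.

    theta -> [0, 360) by modular reduction; alpha -> [-90, 90) by 180-degree
    periodic reduction; phi -> |phi| (the tilt sign is unobservable), after
    folding to (-180, 180].  A folded tilt magnitude beyond 60 degrees is
    outside the admissible envelope and raises :class:`PoseRangeError`.

    Idempotent: canonicalizing a canonical pose returns it unchanged.
    """
    for name in ("x", "y", "theta", "alpha", "phi"):
        v = getattr(pose, name)
        if not math.isfinite(v):
            raise ValueError(f"pose parameter {name} is not finite: {v}")

    # exact fast paths keep canonical values bit-identical (idempotence)
    if 0.0 <= pose.theta < 360.0:
        theta = pose.theta
    else:
        theta = pose.theta % 360.0
        if theta >= 360.0:  # float edge: -1e-16 % 360 == 360.0
            theta = 0.0

    if -90.0 <= pose.alpha < 90.0:
        alpha = pose.alpha
    else:
        alpha = (pose.alpha + 90.0) % 180.0 - 90.0
        if alpha >= 90.0:
            alpha = -90.0

    if 0.0 <= pose.phi <= TILT_LIMIT_DEG:
        phi = pose.phi
    else:
        phi = abs((pose.phi + 180.0) % 360.0 - 180.0)
    if phi > TILT_LIMIT_DEG + _CANON_ATOL:
        raise PoseRangeError(
            f"tilt magnitude {phi:.3f} deg exceeds the {TILT_LIMIT_DEG:.0f} deg limit"
        )
    phi = min(phi, TILT_LIMIT_DEG)

    return replace(pose, theta=theta, alpha=alpha, phi=phi)


# ---------------------------------------------------------------------------
# encoding / decoding


def encode_pose(pose: Pose5DoF, geom: PatchGeometry) -> EncodedPoseTarget:
    """Encode a canonical pose as the 6-component regression target.

    The position is normalized by the patch side (scale-invariant), the plane
    angle becomes the unit vector (cos theta, sin theta) to avoid the 0/360
    seam, the roll maps linearly from [-90, 90] to [0, 1], and the tilt is
    represented by cos(phi), which spans [0.5, 1.0] over the admissible range.
    """
    if not pose.is_canonical():
        raise ValueError(f"encode_pose requires a canonical pose, got {pose}")
    px, py = geom.frame_to_patch(pose.x, pose.y)
    if not (0.0 <= px <= geom.patch_size and 0.0 <= py <= geom.patch_size):
        raise ValueError(
            f"pose position ({px:.1f}, {py:.1f}) lies outside the "
            f"{geom.patch_size}x{geom.patch_size} patch"
        )
    t = math.radians(pose.theta)
    return EncodedPoseTarget(
        xn=px / geom.patch_size,
        yn=py / geom.patch_size,
        tx=math.cos(t),
        ty=math.sin(t),
        rn=(pose.alpha + 90.0) / 180.0,
        ct=math.cos(math.radians(pose.phi)),
    )


def decode_pose(target: EncodedPoseTarget, geom: PatchGeometry) -> Pose5DoF:
    """Decode a (possibly off-manifold) 6-vector into a canonical pose.

    Raw network outputs need not satisfy the target invariants: the plane
    vector is renormalized implicitly through atan2, and ``rn`` / ``ct`` are
    clamped to their valid intervals before inversion, so decoding never
    fails on finite inputs.
    """
    a = target.to_array()
    if not np.all(np.isfinite(a)):
        raise ValueError("encoded target has non-finite components")
    theta = math.degrees(math.atan2(target.ty, target.tx)) % 360.0
    rn = min(max(target.rn, 0.0), 1.0)
    alpha = 180.0 * rn - 90.0
    if alpha >= 90.0:
        alpha = -90.0
    ct = min(max(target.ct, math.cos(math.radians(TILT_LIMIT_DEG))), 1.0)
    phi = math.degrees(math.acos(ct))
    x, y = geom.patch_to_frame(target.xn * geom.patch_size, target.yn * geom.patch_size)
    return canonicalize_pose(Pose5DoF(x=x, y=y, theta=theta, alpha=alpha, phi=phi))


# ---------------------------------------------------------------------------
# error metrics


def wrap_angle_diff(a: float, b: float, period: float) -> float:
    """Minimal absolute difference between two angles on a circle of ``period``."""
    d = abs(a - b) % period
    return min(d, period - d)


def pose_abs_error(pred: Pose5DoF, truth: Pose5DoF, pixel_size: float) -> PoseError:
    """Per-parameter absolute errors between two canonical poses.

    Positions are converted to millimetres with ``pixel_size``; the plane
    angle wraps at 360 degrees, the roll on its 180-degree-periodic
    half-range, and tilt is compared directly (both magnitudes).
    """
    for p in (pred, truth):
        if not p.is_canonical():
            raise ValueError(f"pose_abs_error requires canonical poses, got {p}")
    return PoseError(
        ex=abs(pred.x - truth.x) * pixel_size,
        ey=abs(pred.y - truth.y) * pixel_size,
        etheta=wrap_angle_diff(pred.theta, truth.theta, 360.0),
        ealpha=wrap_angle_diff(pred.alpha, truth.alpha, 180.0),
        ephi=abs(pred.phi - truth.phi),
    )


# ---------------------------------------------------------------------------
# box overlap


def box_iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection-over-union of two axis-aligned boxes (continuous areas)."""
    iw = min(a.x1, b.x1) - max(a.x0, b.x0)
    ih = min(a.y1, b.y1) - max(a.y0, b.y0)
    if iw <= 0.0 or ih <= 0.0:
        return 0.0
    inter = iw * ih
    union = a.area + b.area - inter
    return inter / union


def ciou_loss(pred: BoundingBox, truth: BoundingBox) -> float:
    """Complete-IoU loss: ``1 - IoU + rho^2/c^2 + alpha * v``.

    ``rho`` is the distance between box centers, ``c`` the diagonal of the
    smallest box enclosing both, ``v = 4/pi^2 (arctan(wt/ht) - arctan(wp/hp))^2``
    penalizes aspect-ratio mismatch and ``alpha = v / ((1 - IoU) + v)`` is its
    trade-off weight.  Zero iff the boxes coincide.
    """
    iou = box_iou(pred, truth)
    # squared center distance over squared enclosing-box diagonal
    ew = max(pred.x1, truth.x1) - min(pred.x0, truth.x0)
    eh = max(pred.y1, truth.y1) - min(pred.y0, truth.y0)
    c2 = ew * ew + eh * eh
    rho2 = (pred.cx - truth.cx) ** 2 + (pred.cy - truth.cy) ** 2
    center_term = rho2 / c2 if c2 > 0 else 0.0

    dv = math.atan(truth.w / truth.h) - math.atan(pred.w / pred.h)
    v = (4.0 / math.pi**2) * dv * dv
    if v > 0:
        alpha = v / ((1.0 - iou) + v)
        aspect_term = alpha * v
    else:
        aspect_term = 0.0
    return (1.0 - iou) + center_term + aspect_term
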