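"""Parametric attenuating probe model and parallel-beam projector.

The probe is modelled as a rigid union of simple attenuating primitives on an
isotropic voxel lattice, in a local frame whose +x axis runs along the probe
from shaft to tip with the transducer-window center at the origin:

* a polymer *shaft* cylinder entering from -x;
* a *head* cylinder of ``head_length`` (20 mm) carrying the transducer,
  flattened by two parallel facet cuts — the acoustic window (3 mm x 2 cm)
  and its mirror twin, so the body keeps an exact 180-degree roll symmetry;
* a denser internal *stack* (transducer electronics) box, centered on the
  axis, and a dense azimuthal half-*shell* (azimuth [0, 90) plus its
  180-degree twin) emulating the asymmetric internal electronics whose
  projected shadow is the dominant roll cue;
* a rounded tip cap; and
* two diametric *marker* bead pairs at different axial positions and
  azimuths (0/180 and 45/225 degrees).  Each pair is invariant under a
  180-degree roll, preserving the half-range symmetry, while the two pairs
  together make the model chiral: no combination of a depth mirror and a
  roll maps the marker set onto itself, so roll is unambiguous within the
  canonical half-range [-90, 90).

Projection is parallel-beam along the detector normal: each occupied voxel
contributes ``mu * voxel_volume / pixel_area`` of optical depth to the pixel
column it lands in (bilinear splat), which discretizes the line integral
``exp(-integral mu dl)`` at the voxel pitch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage

from ..geometry import BoundingBox, Pose5DoF

__all__ = [
    "ProbeSpec",
    "ProbeModel",
    "DetectorGeometry",
    "build_probe_volume",
    "project_probe",
    "pose_rotation_matrix",
]

#: Gaussian smoothing (in detector pixels) applied to the splatted optical
#: depth to suppress voxel-lattice sampling noise; part of the projector, not
#: of the edge feathering applied at composition time.
_ANTIALIAS_SIGMA_PX = 0.6


@dataclass(frozen=True)
class ProbeSpec:
    """Dimensions (mm), attenuations (1/mm) and marker layout of the probe."""

    head_length: float = 20.0
    head_radius: float = 2.0
    window_width: float = 3.0          # chord width of the facet cut
    shaft_length: float = 45.0
    shaft_radius: float = 1.65
    tip_length: float = 2.0
    mu_body: float = 0.14
    mu_shaft: float = 0.10
    mu_stack: float = 0.40
    mu_marker: float = 2.5
    stack_half: Tuple[float, float, float] = (8.0, 1.4, 0.9)
    marker_radius: float = 0.7
    marker_offset: float = 1.1         # radial offset of bead centers
    marker_axial: Tuple[float, float] = (-6.0, 6.0)
    marker_azimuth: Tuple[float, float] = (0.0, 45.0)  # degrees
    markers_enabled: bool = True
    shell_mu: float = 0.7              # dense azimuthal half-shell (roll cue)
    shell_radial: Tuple[float, float] = (1.35, 1.85)
    shell_axial: Tuple[float, float] = (-8.0, 8.0)
    shell_azimuth_width: float = 90.0  # degrees; paired at +180 for symmetry
    voxel_pitch: float = 0.15

    @property
    def facet_distance(self) -> float:
        """Distance from the axis to the window facet plane."""
        return math.sqrt(max(self.head_radius**2 - (self.window_width / 2.0) ** 2, 0.0))


@dataclass
class ProbeModel:
    """Voxelized probe: attenuation grid plus the sparse form used to project.

    ``volume`` is the attenuation lattice (1/mm) with isotropic ``pitch``
    (mm); ``origin`` is the local-frame coordinate of voxel (0,0,0) center.
    ``points``/``weights`` are the occupied voxels as local coordinates (mm)
    and per-point optical-depth masses ``mu * pitch^3`` (mm^2 units, divided
    by the detector pixel area at projection time).  ``head_mask`` flags the
    points belonging to the head (head cylinder, stack, tip, markers), which
    define the detection box label.
    """

    spec: ProbeSpec
    volume: np.ndarray
    origin: np.ndarray
    pitch: float
    points: np.ndarray          # (N, 3) local mm
    weights: np.ndarray         # (N,)  mu * pitch^3
    head_mask: np.ndarray       # (N,) bool

    @property
    def window_center_local(self) -> np.ndarray:
        return np.zeros(3)


@dataclass(frozen=True)
class DetectorGeometry:
    """Parallel-beam detector: square image, isotropic pixel size (mm/px)."""

    image_size: int = 512
    pixel_size: float = 0.4

    def __post_init__(self):
        if self.image_size <= 0 or self.pixel_size <= 0:
            raise ValueError("image_size and pixel_size must be positive")


def build_probe_volume(spec: ProbeSpec = ProbeSpec()) -> ProbeModel:
    """Rasterize the probe primitives onto the voxel lattice.

    Deterministic: the same spec always yields bit-identical volumes.  A
    voxel pitch too coarse to resolve the 3 mm window (> 0.2 mm) is rejected.
    """
    if spec.voxel_pitch > 0.2:
        raise ValueError(
            f"voxel pitch {spec.voxel_pitch} mm too coarse to resolve the "
            f"{spec.window_width} mm transducer window (need <= 0.2 mm)"
        )
    h = spec.voxel_pitch
    half_head = spec.head_length / 2.0
    x_lo = -half_head - spec.shaft_length
    x_hi = half_head + spec.tip_length
    r_max = max(spec.head_radius, spec.shaft_radius) + h

    xs = np.arange(x_lo + h / 2.0, x_hi, h)
    # y/z lattice symmetric about the axis (voxel centered at 0) so the
    # rasterized body keeps the exact 180-degree roll symmetry of the design
    K = int(math.ceil(r_max / h))
    ys = np.arange(-K, K + 1) * h
    zs = ys.copy()
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")

    mu = np.zeros(X.shape, dtype=np.float32)
    head = np.zeros(X.shape, dtype=bool)
    r2_yz = Y**2 + Z**2

    # shaft
    shaft = (X < -half_head) & (r2_yz <= spec.shaft_radius**2)
    mu[shaft] = spec.mu_shaft

    # head cylinder with the two facet cuts (|z| <= facet distance)
    d = spec.facet_distance
    head_cyl = (
        (X >= -half_head)
        & (X <= half_head)
        & (r2_yz <= spec.head_radius**2)
        & (np.abs(Z) <= d)
    )
    mu[head_cyl] = spec.mu_body
    head |= head_cyl

    # rounded tip: hemisphere-ish cap, scaled to tip_length axially
    tip = (
        (X > half_head)
        & ((X - half_head) ** 2 / max(spec.tip_length, 1e-6) ** 2
           + r2_yz / spec.head_radius**2 <= 1.0)
        & (np.abs(Z) <= d)
    )
    mu[tip] = spec.mu_body
    head |= tip

    # internal transducer stack (denser), centered on the axis
    sx, sy, sz = spec.stack_half
    stack = (np.abs(X) <= sx) & (np.abs(Y) <= sy) & (np.abs(Z) <= sz)
    mu[stack] = spec.mu_stack
    head |= stack

    # dense azimuthal half-shell (chiral roll cue, emulating the asymmetric
    # internal electronics of a real probe head): azimuth [0, w) plus its
    # 180-degree twin, clipped to the faceted head silhouette
    if spec.shell_mu > 0:
        r_lo, r_hi = spec.shell_radial
        ax_lo, ax_hi = spec.shell_axial
        r_yz = np.sqrt(r2_yz)
        azim = np.degrees(np.arctan2(Z, Y)) % 180.0
        shell = (
            (X >= ax_lo) & (X <= ax_hi)
            & (r_yz >= r_lo) & (r_yz <= min(r_hi, spec.head_radius))
            & (azim < spec.shell_azimuth_width)
            & (np.abs(Z) <= d)
        )
        mu[shell] = spec.shell_mu
        head |= shell

    # marker bead pairs (each pair diametric -> exact 180-degree roll symmetry)
    if spec.markers_enabled:
        for ax, az_deg in zip(spec.marker_axial, spec.marker_azimuth):
            for flip in (0.0, 180.0):
                az = math.radians(az_deg + flip)
                cy = spec.marker_offset * math.cos(az)
                cz = spec.marker_offset * math.sin(az)
                bead = (X - ax) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2 <= spec.marker_radius**2
                mu[bead] = spec.mu_marker
                head |= bead

    occ = mu > 0
    idx = np.argwhere(occ)
    origin = np.array([xs[0], ys[0], zs[0]])
    points = origin + idx * h
    weights = (mu[occ] * h**3).astype(np.float64)
    return ProbeModel(
        spec=spec,
        volume=mu,
        origin=origin,
        pitch=h,
        points=points.astype(np.float64),
        weights=weights,
        head_mask=head[occ],
    )


def pose_rotation_matrix(theta: float, alpha: float, phi: float) -> np.ndarray:
    """Local-to-detector rotation for pose angles in degrees.

    Applied right-to-left: roll about the probe axis (+x), tilt about the
    in-plane +y axis (tips the probe out of the detector plane), then the
    plane angle about the beam axis (+z, x toward y i.e. screen-clockwise).
    """
    t, a, p = (math.radians(v) for v in (theta, alpha, phi))
    ca, sa = math.cos(a), math.sin(a)
    cp, sp = math.cos(p), math.sin(p)
    ct, st = math.cos(t), math.sin(t)
    R_roll = np.array([[1, 0, 0], [0, ca, -sa], [0, sa, ca]])
    R_tilt = np.array([[cp, 0, sp], [0, 1, 0], [-sp, 0, cp]])
    R_plane = np.array([[ct, -st, 0], [st, ct, 0], [0, 0, 1]])
    return R_plane @ R_tilt @ R_roll


def project_probe(
    model: ProbeModel,
    pose: Pose5DoF,
    geom: DetectorGeometry,
    head_only: bool = False,
    antialias_sigma_px: float = _ANTIALIAS_SIGMA_PX,
) -> Tuple[np.ndarray, dict]:
    """Parallel-beam transmission image of the probe at a canonical pose.

    Returns ``(T, meta)`` where ``T`` is the per-pixel transmission in
    (0, 1] (1 where no probe material crosses the column) and ``meta``
    records an ``out_of_fov`` flag when head material falls outside the
    detector (allowed: truncation mirrors clinical frames).

    With ``head_only`` the shaft is excluded — used to derive the detection
    box label, which frames the probe head.
    """
    if not pose.is_canonical():
        raise ValueError(f"project_probe requires a canonical pose, got {pose}")
    R = pose_rotation_matrix(pose.theta, pose.alpha, pose.phi)
    pts = model.points
    w = model.weights
    if head_only:
        pts = pts[model.head_mask]
        w = w[model.head_mask]
    rot = pts @ R.T  # (N, 3) in detector mm, window center at origin

    n = geom.image_size
    u = rot[:, 0] / geom.pixel_size + pose.x
    v = rot[:, 1] / geom.pixel_size + pose.y

    # head-visibility bookkeeping (before clipping)
    if head_only:
        head_u, head_v = u, v
    else:
        head_u = rot[model.head_mask, 0] / geom.pixel_size + pose.x
        head_v = rot[model.head_mask, 1] / geom.pixel_size + pose.y
    out_of_fov = bool(
        head_u.size
        and (head_u.min() < 0 or head_u.max() > n - 1 or head_v.min() < 0 or head_v.max() > n - 1)
    )

    depth = np.zeros(n * n, dtype=np.float64)
    # keep only points whose bilinear footprint can touch the detector
    inside = (u > -1.0) & (u < n) & (v > -1.0) & (v < n)
    u = u[inside]
    v = v[inside]
    mass = w[inside] / (geom.pixel_size**2)
    u0 = np.floor(u).astype(np.int64)
    v0 = np.floor(v).astype(np.int64)
    fu = u - u0
    fv = v - v0
    for du, dv, frac in (
        (0, 0, (1 - fu) * (1 - fv)),
        (1, 0, fu * (1 - fv)),
        (0, 1, (1 - fu) * fv),
        (1, 1, fu * fv),
    ):
        uu = u0 + du
        vv = v0 + dv
        ok = (uu >= 0) & (uu < n) & (vv >= 0) & (vv < n)
        if np.any(ok):
            depth += np.bincount(
                (vv[ok] * n + uu[ok]), weights=mass[ok] * frac[ok], minlength=n * n
            )
    depth = depth.reshape(n, n)
    if antialias_sigma_px > 0:
        depth = ndimage.gaussian_filter(depth, antialias_sigma_px)
    T = np.exp(-depth)
    return T.astype(np.float32), {"out_of_fov": out_of_fov}


def head_box_from_transmission(
    head_transmission: np.ndarray,
    threshold: float = 0.995,
    dilate_px: float = 2.0,
) -> Optional[BoundingBox]:
    """Tight axis-aligned box of the head mask, dilated by ``dilate_px``.

    The mask is the set of pixels whose head-only transmission falls below
    ``threshold``.  Returns None when the mask is empty (head fully outside
    the field of view).
    """
    mask = head_transmission < threshold
    if not mask.any():
        return None
    rows = np.any(mask, axis=1)
    cols = np.any(mask, axis=0)
    y0, y1 = np.argmax(rows), len(rows) - 1 - np.argmax(rows[::-1])
    x0, x1 = np.argmax(cols), len(cols) - 1 - np.argmax(cols[::-1])
    x0 -= dilate_px
    y0 -= dilate_px
    x1 += dilate_px
    y1 += dilate_px
    return BoundingBox(
        cx=(x0 + x1) / 2.0, cy=(y0 + y1) / 2.0, w=(x1 - x0) + 1.0, h=(y1 - y0) + 1.0
    )
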