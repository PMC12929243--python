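"""Procedural clinical-like X-ray backgrounds.

Real interventional fluoroscopy frames contain smooth soft-tissue/anatomy
gradients, dark curvilinear devices (guidewires), occasionally a wider
catheter sheath, and detector vignetting.  This generator emulates that
statistical structure as a transmission-style image in [0, 1]:

* *anatomy*: low-frequency lognormal-ish texture from a coarse Gaussian
  grid upsampled with a cubic spline;
* *wires*: dark smooth random curves — cubic splines through a handful of
  control points, rasterized with a tubular attenuation profile;
* *sheath*: one wider, fainter band of the same construction;
* *vignette*: radial intensity falloff.

Every frame is deterministic given its seed, and the drawn clutter is
recorded in an inventory so downstream provenance can reproduce or audit
the scene.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy import interpolate, ndimage

__all__ = ["ClutterConfig", "generate_background"]


@dataclass(frozen=True)
class ClutterConfig:
    """What the background should contain.

    ``n_wires`` dark guidewire-like curves; ``sheath`` adds one wider
    catheter-sheath band; ``anatomy_amplitude`` scales the low-frequency
    tissue texture (0 disables it); ``vignette_strength`` is the relative
    corner darkening.
    """

    n_wires: int = 2
    sheath: bool = False
    anatomy_amplitude: float = 0.12
    vignette_strength: float = 0.10
    base_level: float = 0.85
    wire_depth: Tuple[float, float] = (0.25, 0.6)   # optical depth range at core
    wire_sigma_px: Tuple[float, float] = (0.8, 1.6)  # tube half-width range
    sheath_depth: float = 0.18
    sheath_sigma_px: float = 4.0


def _random_curve(rng: np.random.Generator, shape: Tuple[int, int], n_ctrl: int) -> np.ndarray:
    """Sample points along a smooth random curve crossing the frame."""
    h, w = shape
    # endpoints on opposite-ish borders so wires traverse the frame
    margin = 0.05
    pts = rng.uniform([-margin * w, -margin * h], [(1 + margin) * w, (1 + margin) * h],
                      size=(n_ctrl, 2))
    order = np.argsort(pts[:, 0] + 0.3 * pts[:, 1])
    pts = pts[order]
    k = min(3, n_ctrl - 1)
    tck, _ = interpolate.splprep([pts[:, 0], pts[:, 1]], k=k, s=0)
    t = np.linspace(0, 1, 6 * max(h, w))
    x, y = interpolate.splev(t, tck)
    return np.column_stack([x, y])


def _splat_curve(depth: np.ndarray, curve: np.ndarray, amount: float) -> None:
    """Accumulate unit-density curve samples into the depth accumulator."""
    h, w = depth.shape
    xi = np.round(curve[:, 0]).astype(np.int64)
    yi = np.round(curve[:, 1]).astype(np.int64)
    ok = (xi >= 0) & (xi < w) & (yi >= 0) & (yi < h)
    if not np.any(ok):
        return
    flat = np.bincount(yi[ok] * w + xi[ok], minlength=h * w).astype(np.float64)
    depth += amount * flat.reshape(h, w)


def generate_background(
    seed: int,
    clutter: ClutterConfig = ClutterConfig(),
    shape: Tuple[int, int] = (512, 512),
) -> Tuple[np.ndarray, dict]:
    """Render one background frame.

    Returns ``(image, inventory)``; the image is float32 in [0, 1] and the
    inventory lists the generated clutter (wire count and control points,
    sheath flag, seed) for provenance.
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    inventory: dict = {"seed": int(seed), "wires": [], "sheath": bool(clutter.sheath)}

    # anatomy: coarse Gaussian grid -> cubic upsample
    img = np.full(shape, clutter.base_level, dtype=np.float64)
    if clutter.anatomy_amplitude > 0:
        coarse = rng.normal(0.0, 1.0, size=(10, 10))
        tex = ndimage.zoom(coarse, (h / 10, w / 10), order=3, mode="nearest")[:h, :w]
        tex /= max(np.abs(tex).max(), 1e-9)
        img *= np.exp(clutter.anatomy_amplitude * tex)

    # wires and sheath accumulate optical depth, applied multiplicatively
    depth = np.zeros(shape, dtype=np.float64)
    for i in range(clutter.n_wires):
        n_ctrl = int(rng.integers(4, 7))
        curve = _random_curve(rng, shape, n_ctrl)
        sigma = rng.uniform(*clutter.wire_sigma_px)
        core = rng.uniform(*clutter.wire_depth)
        d = np.zeros(shape, dtype=np.float64)
        _splat_curve(d, curve, 1.0)
        d = ndimage.gaussian_filter(d, sigma)
        if d.max() > 0:
            d *= core / d.max()
        depth += d
        inventory["wires"].append(
            {"sigma_px": float(sigma), "core_depth": float(core), "n_ctrl": n_ctrl}
        )
    if clutter.sheath:
        curve = _random_curve(rng, shape, 4)
        d = np.zeros(shape, dtype=np.float64)
        _splat_curve(d, curve, 1.0)
        d = ndimage.gaussian_filter(d, clutter.sheath_sigma_px)
        if d.max() > 0:
            d *= clutter.sheath_depth / d.max()
        depth += d
    img *= np.exp(-depth)

    # vignetting
    if clutter.vignette_strength > 0:
        yy, xx = np.mgrid[0:h, 0:w]
        r2 = ((xx - (w - 1) / 2) / (w / 2)) ** 2 + ((yy - (h - 1) / 2) / (h / 2)) ** 2
        img *= 1.0 - clutter.vignette_strength * r2 / 2.0

    return np.clip(img, 0.0, 1.0).astype(np.float32), inventory
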