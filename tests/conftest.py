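"""Shared fixtures: the probe model and small cached sample sets.

Heavy artifacts (the voxel model, rendered samples, trained desk-scale
models) are session-scoped so every test file shares one instance.
"""

import numpy as np
import pytest

from icepose.synth import (
    ProbeSpec,
    SceneConfig,
    build_probe_volume,
    make_detection_sample,
    make_pose_sample,
)


@pytest.fixture(scope="session")
def probe_model():
    return build_probe_volume(ProbeSpec())


@pytest.fixture(scope="session")
def clean_scene_config():
    """Scene sampler without background clutter (probe on plain field)."""
    return SceneConfig(background_enabled=False)


@pytest.fixture(scope="session")
def pose_samples_small(probe_model):
    """24 cluttered pose patches with the default jitter."""
    rng = np.random.default_rng(7)
    cfg = SceneConfig()
    return [make_pose_sample(probe_model, rng, cfg) for _ in range(24)]


@pytest.fixture(scope="session")
def detection_samples_small(probe_model):
    """12 cluttered 256x256 detection frames (small for speed)."""
    rng = np.random.default_rng(11)
    cfg = SceneConfig(image_size=256)
    return [make_detection_sample(probe_model, rng, cfg) for _ in range(12)]
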