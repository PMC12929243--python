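"""Probe model, projector, backgrounds, compositing and dataset generation:
determinism, physical invariants (shift/rotation equivariance,
foreshortening, 180-degree roll symmetry) and label soundness against a
silhouette-registration oracle."""

import dataclasses
import math

import numpy as np
import pytest

from icepose.geometry import Pose5DoF, canonicalize_pose, encode_pose, wrap_angle_diff
from icepose.synth import (
    ClutterConfig,
    DetectorGeometry,
    ProbeSpec,
    SceneConfig,
    build_probe_volume,
    composite_scene,
    generate_background,
    generate_dataset,
    head_box_from_transmission,
    load_manifest,
    make_detection_sample,
    make_pose_sample,
    project_probe,
)
from icepose.synth.scene import PROBE_MASK_THRESHOLD


class TestProbeVolume:
    def test_default_dimensions(self, probe_model):
        spec = probe_model.spec
        assert spec.head_length == 20.0
        assert spec.window_width == 3.0
        # the voxel grid spans the full probe
        extent_x = probe_model.volume.shape[0] * probe_model.pitch
        assert extent_x >= spec.head_length + spec.shaft_length

    def test_deterministic(self):
        a = build_probe_volume(ProbeSpec())
        b = build_probe_volume(ProbeSpec())
        assert np.array_equal(a.volume, b.volume)
        assert np.array_equal(a.points, b.points)

    def test_attenuation_nonnegative(self, probe_model):
        assert (probe_model.volume >= 0).all()
        assert (probe_model.weights > 0).all()

    def test_coarse_pitch_rejected(self):
        with pytest.raises(ValueError):
            build_probe_volume(ProbeSpec(voxel_pitch=0.3))

    def test_exact_180_degree_roll_symmetry(self, probe_model):
        """The attenuation lattice is invariant under a 180-degree roll
        (y, z) -> (-y, -z), so roll labels are well defined on [-90, 90)."""
        vol = probe_model.volume
        assert np.array_equal(vol, vol[:, ::-1, ::-1])

    def test_projection_differs_across_roll(self, probe_model):
        """Roll cues: projections at distinct canonical rolls differ, and
        +a vs -a are distinguishable (the marker layout is chiral)."""
        geom = DetectorGeometry(120, 0.3)
        imgs = {}
        for a in (-60.0, -30.0, 0.0, 30.0, 60.0):
            imgs[a], _ = project_probe(
                probe_model, Pose5DoF(x=60, y=60, theta=0, alpha=a), geom
            )
        for a in (30.0, 60.0):
            assert np.abs(imgs[a] - imgs[-a]).max() > 0.05


class TestProjection:
    def test_empty_volume_projects_to_unity(self):
        spec = ProbeSpec(mu_body=0, mu_shaft=0, mu_stack=0, mu_marker=0, shell_mu=0)
        model = build_probe_volume(spec)
        T, _ = project_probe(model, Pose5DoF(x=60, y=60), DetectorGeometry(120, 0.3))
        assert np.all(T == 1.0)

    def test_shift_equivariance(self, probe_model):
        geom = DetectorGeometry(200, 0.35)
        base = Pose5DoF(x=80, y=80, theta=25, alpha=20, phi=10)
        T0, _ = project_probe(probe_model, base, geom)
        for k in (3, 7, 15):
            Tk, _ = project_probe(probe_model, dataclasses.replace(base, x=80 + k), geom)
            # cross-correlation of depth profiles peaks at the shift
            row0 = (1 - T0).sum(axis=0)
            rowk = (1 - Tk).sum(axis=0)
            corr = np.correlate(rowk, row0, mode="full")
            assert np.argmax(corr) - (len(row0) - 1) == k

    def test_doubling_attenuation_squares_transmission(self):
        spec = ProbeSpec()
        double = dataclasses.replace(
            spec,
            mu_body=2 * spec.mu_body, mu_shaft=2 * spec.mu_shaft,
            mu_stack=2 * spec.mu_stack, mu_marker=2 * spec.mu_marker,
            shell_mu=2 * spec.shell_mu,
        )
        geom = DetectorGeometry(140, 0.3)
        pose = Pose5DoF(x=70, y=70, theta=40, alpha=30, phi=15)
        T1, _ = project_probe(build_probe_volume(spec), pose, geom)
        T2, _ = project_probe(build_probe_volume(double), pose, geom)
        assert np.allclose(T2, T1**2, atol=1e-5)

    def test_in_plane_rotation_equivariance(self, probe_model):
        """Rotating theta by delta rotates the probe silhouette by delta
        (principal-axis orientation of the mask within 2 degrees)."""

        def mask_orientation(theta):
            geom = DetectorGeometry(300, 0.35)
            T, _ = project_probe(
                probe_model, Pose5DoF(x=150, y=150, theta=theta), geom
            )
            mask = T < 0.9
            yy, xx = np.nonzero(mask)
            x = xx - xx.mean()
            y = yy - yy.mean()
            ang = 0.5 * math.degrees(
                math.atan2(2 * (x * y).mean(), (x * x).mean() - (y * y).mean())
            )
            return ang % 180.0

    # silhouette orientation is axial (mod 180)
        base = mask_orientation(10.0)
        for delta in (15.0, 45.0, 90.0):
            got = mask_orientation(10.0 + delta)
            assert wrap_angle_diff(got - base, delta, 180.0) < 2.0

    def test_monotone_foreshortening(self, probe_model):
        """Projected head length is non-increasing in tilt at fixed theta."""
        geom = DetectorGeometry(200, 0.3)
        lengths = []
        for phi in (0, 10, 20, 30, 40, 50, 60):
            Th, _ = project_probe(
                probe_model, Pose5DoF(x=100, y=100, theta=0, alpha=20, phi=phi),
                geom, head_only=True,
            )
            cols = np.any(Th < PROBE_MASK_THRESHOLD, axis=0)
            lengths.append(int(cols.sum()))
        assert all(a >= b - 1 for a, b in zip(lengths, lengths[1:]))
        assert lengths[0] > lengths[-1]  # strictly shorter by 60 degrees

    def test_out_of_fov_flagged(self, probe_model):
        geom = DetectorGeometry(100, 0.3)
        _, meta = project_probe(probe_model, Pose5DoF(x=5, y=50), geom)
        assert meta["out_of_fov"]
        _, meta = project_probe(probe_model, Pose5DoF(x=50, y=50, theta=90), geom)
        assert not meta["out_of_fov"]

    def test_non_canonical_pose_rejected(self, probe_model):
        with pytest.raises(ValueError):
            project_probe(probe_model, Pose5DoF(x=0, y=0, theta=400),
                          DetectorGeometry(64, 0.3))


class TestBackground:
    def test_deterministic_per_seed(self):
        a, inv_a = generate_background(123, ClutterConfig(n_wires=3, sheath=True))
        b, inv_b = generate_background(123, ClutterConfig(n_wires=3, sheath=True))
        assert np.array_equal(a, b)
        assert inv_a == inv_b
        c, _ = generate_background(124, ClutterConfig(n_wires=3, sheath=True))
        assert not np.array_equal(a, c)

    def test_empty_clutter_constant_up_to_vignette(self):
        img, inv = generate_background(
            5, ClutterConfig(n_wires=0, sheath=False, anatomy_amplitude=0.0,
                             vignette_strength=0.0), shape=(64, 64)
        )
        assert np.allclose(img, img[0, 0])
        assert inv["wires"] == []

    def test_wire_inventory_count(self):
        _, inv = generate_background(9, ClutterConfig(n_wires=3), shape=(128, 128))
        assert len(inv["wires"]) == 3

    def test_range(self):
        img, _ = generate_background(2, ClutterConfig(n_wires=2, sheath=True))
        assert img.min() >= 0.0 and img.max() <= 1.0


class TestComposite:
    def test_unit_transmission_returns_background(self):
        bg, _ = generate_background(1, ClutterConfig(), shape=(64, 64))
        out = composite_scene(np.ones((64, 64), np.float32), bg, feather_width_px=2)
        assert np.allclose(out, bg, atol=1e-6)

    def test_attenuation_only_darkens(self, probe_model):
        geom = DetectorGeometry(128, 0.3)
        T, _ = project_probe(probe_model, Pose5DoF(x=64, y=64, theta=30), geom)
        bg, _ = generate_background(3, ClutterConfig(), shape=(128, 128))
        out = composite_scene(T, bg, feather_width_px=2)
        assert (out <= bg + 1e-6).all()
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_feathering_softens_step_edge(self):
        T = np.ones((40, 40), np.float32)
        T[:, 20:] = 0.3
        bg = np.ones((40, 40), np.float32)
        hard = composite_scene(T, bg, feather_width_px=0)
        soft = composite_scene(T, bg, feather_width_px=2)
        g_hard = np.abs(np.diff(hard, axis=1)).max()
        g_soft = np.abs(np.diff(soft, axis=1)).max()
        assert g_soft < g_hard

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            composite_scene(np.ones((4, 4)), np.ones((5, 5)))


class TestSceneSamplers:
    def test_detection_sample_shape_and_label(self, probe_model):
        rng = np.random.default_rng(0)
        s = make_detection_sample(probe_model, rng, SceneConfig(image_size=512))
        assert s.image.shape == (512, 512)
        assert 0.25 <= s.pixel_size <= 0.55
        assert s.box is not None and s.box.contains(s.pose.x, s.pose.y)

    def test_box_encloses_head_mask(self, probe_model):
        rng = np.random.default_rng(1)
        cfg = SceneConfig(image_size=256)
        for _ in range(5):
            s = make_detection_sample(probe_model, rng, cfg)
            geom = DetectorGeometry(256, s.pixel_size)
            Th, _ = project_probe(probe_model, s.pose, geom, head_only=True)
            yy, xx = np.nonzero(Th < PROBE_MASK_THRESHOLD)
            assert xx.min() >= s.box.x0 and xx.max() <= s.box.x1
            assert yy.min() >= s.box.y0 and yy.max() <= s.box.y1

    def test_pose_patch_shape_and_centering(self, probe_model):
        rng = np.random.default_rng(2)
        s = make_pose_sample(probe_model, rng, SceneConfig(), midpoint_jitter_px=0.0)
        assert s.image.shape == (100, 100)
        enc = encode_pose(s.pose, s.patch_geom)
        assert enc.xn == pytest.approx(0.5, abs=1e-9)
        assert enc.yn == pytest.approx(0.5, abs=1e-9)

    def test_pose_patch_jitter_within_bounds(self, probe_model):
        rng = np.random.default_rng(3)
        for _ in range(5):
            s = make_pose_sample(probe_model, rng, SceneConfig(), midpoint_jitter_px=8.0)
            enc = encode_pose(s.pose, s.patch_geom)
            # window center within jitter + rounding of the patch center
            assert abs(enc.xn - 0.5) <= (8.0 + 1.0) / 100.0
            assert abs(enc.yn - 0.5) <= (8.0 + 1.0) / 100.0

    def test_pixel_size_sampling_range(self, probe_model, pose_samples_small):
        for s in pose_samples_small:
            assert 0.25 <= s.pixel_size <= 0.55

    def test_label_soundness_silhouette_registration(self, probe_model):
        """Exhaustive theta-grid registration against rendered templates
        recovers the label within one grid step: labels and rendering agree."""
        rng = np.random.default_rng(4)
        cfg = SceneConfig(background_enabled=False)
        grid = np.arange(0.0, 360.0, 7.5)
        for _ in range(3):
            s = make_pose_sample(probe_model, rng, cfg, midpoint_jitter_px=0.0)
            frame = s.provenance["frame_size"]
            ox, oy = s.provenance["crop_origin"]
            geom = DetectorGeometry(frame, s.pixel_size)
            target = s.image < 0.9 * np.median(s.image)
            best, best_score = None, -1.0
            for theta in grid:
                pose = Pose5DoF(
                    x=s.pose.x + ox, y=s.pose.y + oy,
                    theta=theta, alpha=s.pose.alpha, phi=s.pose.phi,
                )
                T, _ = project_probe(probe_model, pose, geom)
                tmpl = (T < 0.9)[oy : oy + 100, ox : ox + 100]
                inter = np.logical_and(tmpl, target).sum()
                union = np.logical_or(tmpl, target).sum()
                score = inter / union if union else 0.0
                if score > best_score:
                    best, best_score = theta, score
            assert wrap_angle_diff(best, s.pose.theta, 360.0) <= 7.5


class TestDatasetGeneration:
    def test_small_dataset_layout_and_determinism(self, probe_model, tmp_path):
        sizes = {"train": 6, "val": 2, "test": 2}
        cfg = SceneConfig(image_size=128)
        m1 = generate_dataset(probe_model, "detection", tmp_path / "a", sizes,
                              seed=5, scene_config=cfg)
        assert sorted(m1) == ["test", "train", "val"]
        assert {k: len(v) for k, v in m1.items()} == sizes
        n_files = sum(1 for p in (tmp_path / "a").rglob("*.png"))
        assert n_files == sum(sizes.values())
        for m in m1.values():
            m.validate()
            assert (m.root / "manifest.csv").exists()
            assert len(list((m.root / "labels").glob("*.txt"))) == len(m)
        m2 = generate_dataset(probe_model, "detection", tmp_path / "b", sizes,
                              seed=5, scene_config=cfg)
        for split in sizes:
            assert m1[split].records == m2[split].records
            for rec in m1[split].records:
                a = (m1[split].root / rec["image"]).read_bytes()
                b = (m2[split].root / rec["image"]).read_bytes()
                assert a == b

    def test_pose_dataset_round_trips_through_disk(self, probe_model, tmp_path):
        from icepose.synth import load_split_samples

        sizes = {"train": 3, "val": 1, "test": 1}
        generate_dataset(probe_model, "pose", tmp_path / "p", sizes, seed=6)
        man = load_manifest(tmp_path / "p" / "train")
        samples = load_split_samples(man)
        assert len(samples) == 3
        for s in samples:
            assert s.image.shape == (100, 100)
            assert s.patch_geom is not None
            # 16-bit quantization only
            assert s.image.min() >= 0 and s.image.max() <= 1

    def test_invalid_sizes_rejected(self, probe_model, tmp_path):
        with pytest.raises(ValueError):
            generate_dataset(probe_model, "pose", tmp_path, {"train": 0}, seed=0)
        with pytest.raises(ValueError):
            generate_dataset(probe_model, "nope", tmp_path, {"train": 1}, seed=0)
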