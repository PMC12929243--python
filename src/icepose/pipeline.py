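"""End-to-end orchestration: dataset generation -> detector training ->
pose training -> two-stage inference -> evaluation.

A single :class:`PipelineConfig` (YAML-serializable) drives the whole
experiment; every artifact directory is stamped with the global seed and a
hash of the config so runs are reproducible and auditable.  The bundled
``desk`` preset scales the study conditions down to sizes that complete on
a laptop CPU while exercising every stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml

from .augment import AugmentationConfig
from .detect import (
    DetectorConfig,
    ProbeDetector,
    crop_patch,
    detect_probe,
    evaluate_detection,
    train_detector,
)
from .evaluation import (
    compare_pixel_groups,
    detection_report,
    error_table,
    stratify_by_pixel_size,
    summarize_errors,
)
from .geometry import Pose5DoF, pose_abs_error
from .regressor import PoseRegressor, PoseRegressorConfig, predict_pose, train_pose_regressor
from .synth import (
    ProbeSpec,
    SceneConfig,
    build_probe_volume,
    generate_dataset,
    load_manifest,
    load_split_samples,
)

__all__ = ["PipelineConfig", "desk_config", "run_two_stage_inference", "run_full_experiment"]


@dataclass
class PipelineConfig:
    out_dir: str = "experiment"
    seed: int = 0
    detection_sizes: Dict[str, int] = field(
        default_factory=lambda: {"train": 8000, "val": 2000, "test": 1000}
    )
    pose_sizes: Dict[str, int] = field(
        default_factory=lambda: {"train": 8000, "val": 2000, "test": 1000}
    )
    probe: ProbeSpec = field(default_factory=ProbeSpec)
    scene: SceneConfig = field(default_factory=SceneConfig)
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    regressor: PoseRegressorConfig = field(default_factory=PoseRegressorConfig)
    detect_augment: Optional[AugmentationConfig] = field(
        default_factory=lambda: AugmentationConfig(probability=0.30)
    )
    pose_augment: Optional[AugmentationConfig] = field(
        default_factory=lambda: AugmentationConfig(probability=0.20, hflip=False)
    )
    include_tilt: bool = True
    make_plots: bool = False

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(_to_plain(self), sort_keys=True).encode()
        ).hexdigest()[:12]

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(_to_plain(self)))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return _from_plain(cls, yaml.safe_load(Path(path).read_text()))


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj


_NESTED = {
    "probe": ProbeSpec,
    "scene": SceneConfig,
    "detector": DetectorConfig,
    "regressor": PoseRegressorConfig,
    "detect_augment": AugmentationConfig,
    "pose_augment": AugmentationConfig,
}

_TUPLE_FIELDS = {
    "weights", "contrast_range", "scale_range", "gaussian_sigma_range",
    "poisson_scale_range", "stack_half", "marker_axial", "marker_azimuth",
    "shell_radial", "shell_axial",
    "pixel_size_range", "wire_depth", "wire_sigma_px",
}


def _from_plain(cls, d: dict):
    kwargs = {}
    for k, v in d.items():
        if k in _NESTED and isinstance(v, dict):
            kwargs[k] = _from_plain(_NESTED[k], v)
        elif k in _TUPLE_FIELDS and isinstance(v, list):
            kwargs[k] = tuple(v)
        else:
            kwargs[k] = v
    return cls(**kwargs)


def desk_config(out_dir: str = "experiment-desk", seed: int = 0) -> PipelineConfig:
    """Scaled-down preset exercising every stage in minutes on one CPU."""
    return PipelineConfig(
        out_dir=out_dir,
        seed=seed,
        detection_sizes={"train": 120, "val": 30, "test": 30},
        pose_sizes={"train": 300, "val": 60, "test": 60},
        detector=DetectorConfig(max_epochs=40, patience=20, batch_size=8),
        regressor=PoseRegressorConfig(epochs=25, lr=1e-3, batch_size=32),
        detect_augment=None,
        pose_augment=None,
    )


# ---------------------------------------------------------------------------
# inference


def run_two_stage_inference(
    detector: ProbeDetector,
    regressor: PoseRegressor,
    frames: Sequence[np.ndarray],
    pixel_sizes: Optional[Sequence[float]] = None,
) -> List[dict]:
    """Per-frame detect -> crop -> regress hand-off.

    Each record carries the detection (or an explicit failure — a frame
    with no confident detection never yields a fabricated pose), the pose
    in frame coordinates when available, and the wall time (informational
    only).  Unreadable frames produce error records; the loop continues.
    """
    records: List[dict] = []
    patch_size = regressor.config.input_size
    for i, frame in enumerate(frames):
        t0 = time.perf_counter()
        rec: dict = {"frame": i}
        try:
            frame = np.asarray(frame, dtype=np.float32)
            if frame.ndim != 2:
                raise ValueError(f"frame {i} is not a 2-D grayscale image")
            dets, midpoint = detect_probe(detector, frame, image_id=i)
            if midpoint is None:
                rec["status"] = "no_detection"
            else:
                patch, geom = crop_patch(frame, midpoint, size=patch_size)
                if pixel_sizes is not None:
                    geom = dataclasses.replace(geom, pixel_size=float(pixel_sizes[i]))
                pose = predict_pose(regressor, patch, geom)
                rec.update(
                    status="ok",
                    detection=dets[0].box.to_json_dict(),
                    midpoint=[float(midpoint[0]), float(midpoint[1])],
                    pose=pose.to_json_dict(),
                )
        except Exception as exc:  # per-frame failure never kills the run
            rec["status"] = "error"
            rec["error"] = str(exc)
        rec["wall_time_s"] = time.perf_counter() - t0
        records.append(rec)
    return records


# ---------------------------------------------------------------------------
# full experiment


def run_full_experiment(config: PipelineConfig) -> Path:
    """Generate -> train -> evaluate; returns the experiment directory.

    Stages write completion markers so a crashed run can be resumed without
    redoing finished stages.  Pose errors are computed only on frames whose
    detection succeeded; misses enter the detection report as FNs and never
    contaminate the pose statistics.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"seed": config.seed, "config_hash": config.config_hash()}
    config.to_yaml(out / "config.yaml")
    (out / "stamp.json").write_text(json.dumps(stamp))
    model = build_probe_volume(config.probe)

    def stage_done(name: str) -> bool:
        return (out / f".done-{name}").exists()

    def mark(name: str) -> None:
        (out / f".done-{name}").write_text("ok")

    # -- datasets ----------------------------------------------------------
    if not stage_done("datasets"):
        generate_dataset(model, "detection", out / "detection", config.detection_sizes,
                         seed=config.seed, scene_config=config.scene)
        generate_dataset(model, "pose", out / "pose", config.pose_sizes,
                         seed=config.seed + 1, scene_config=config.scene)
        mark("datasets")
    det_splits = {s: load_split_samples(load_manifest(out / "detection" / s))
                  for s in config.detection_sizes}
    pose_splits = {s: load_split_samples(load_manifest(out / "pose" / s))
                   for s in config.pose_sizes}

    # -- detector ----------------------------------------------------------
    det_path = out / "models" / "detector.npz"
    if not stage_done("detector"):
        detector, history = train_detector(
            det_splits["train"], det_splits["val"], config.detector,
            seed=config.seed, augment=config.detect_augment,
        )
        detector.save(det_path)
        (out / "models" / "detector_history.json").write_text(json.dumps(history))
        mark("detector")
    else:
        detector = ProbeDetector.load(det_path)

    # -- regressor ---------------------------------------------------------
    reg_path = out / "models" / "regressor.npz"
    if not stage_done("regressor"):
        regressor, history = train_pose_regressor(
            pose_splits["train"], pose_splits["val"], config.regressor,
            seed=config.seed, augment=config.pose_augment,
        )
        regressor.save(reg_path)
        (out / "models" / "regressor_history.json").write_text(json.dumps(history))
        mark("regressor")
    else:
        regressor = PoseRegressor.load(reg_path)

    # -- evaluation --------------------------------------------------------
    reports = out / "reports"
    reports.mkdir(exist_ok=True)

    det_metrics = {}
    for split in ("test",):
        samples = det_splits[split]
        dets = [detect_probe(detector, s.image, image_id=k)[0]
                for k, s in enumerate(samples)]
        metrics, outcomes = evaluate_detection(dets, [s.box for s in samples])
        det_metrics[f"synthetic-{split}"] = metrics
        (reports / f"detection_outcomes_{split}.json").write_text(json.dumps(outcomes))
    rep = detection_report(det_metrics)
    rep.to_csv(reports / "detection_report.csv", index=False)

    pose_test = pose_splits["test"]
    errors, pixel_sizes = [], []
    for s in pose_test:
        pred = predict_pose(regressor, s.image, s.patch_geom)
        errors.append(pose_abs_error(pred, s.pose, s.pixel_size))
        pixel_sizes.append(s.pixel_size)
    summaries = {"all": summarize_errors(errors, "all", include_tilt=config.include_tilt)}
    strata = stratify_by_pixel_size(pixel_sizes)
    for label, idx in strata.items():
        if idx.size:
            summaries[label] = summarize_errors([errors[i] for i in idx], label,
                                                include_tilt=config.include_tilt)
    table = error_table(summaries)
    table.to_csv(reports / "pose_errors.csv", index=False)

    sig = {}
    params = ["x", "y", "theta", "alpha"] + (["phi"] if config.include_tilt else [])
    labels = [l for l in strata if strata[l].size >= 3]
    for p in params:
        vals = {l: [getattr(errors[i], "e" + p) for i in strata[l]] for l in labels}
        for a in range(len(labels)):
            for b in range(a + 1, len(labels)):
                la, lb = labels[a], labels[b]
                pv, stars = compare_pixel_groups(vals[la], vals[lb])
                sig[f"{p}:{la} vs {lb}"] = {"p_value": pv, "stars": stars}
    (reports / "significance.json").write_text(json.dumps(sig, indent=1))

    if config.make_plots:
        from .evaluation import plot_error_violins

        plot_error_violins(
            {p: [getattr(e, "e" + p) for e in errors] for p in ("x", "y")},
            reports / "violin_position.png",
        )
        plot_error_violins(
            {p: [getattr(e, "e" + p) for e in errors]
             for p in ("theta", "alpha", "phi")},
            reports / "violin_rotation.png",
        )

    summary = {
        "detection": det_metrics,
        "pose_medians": {k: {p: s.median for p, s in v.items()}
                         for k, v in summaries.items()},
        **stamp,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1))
    return out
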