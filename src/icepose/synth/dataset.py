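"""Dataset generation: splits, manifests and the on-disk layout.

A dataset directory holds one subdirectory per split, each with ``images/``
(16-bit grayscale PNG) and ``labels/`` (for detection: one normalized
``class cx cy w h`` text file per image, for interoperability with common
detector tooling), plus a ``manifest.jsonl`` (one record per sample) and a
``manifest.csv`` mirror at the split root.

Default split sizes are the study conditions: 8,000 train / 2,000
validation / 1,000 test.  All randomness flows from one seeded generator
per split; per-sample base seeds are recorded in the manifest so any sample
can be regenerated in isolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from ..geometry import BoundingBox, PatchGeometry, Pose5DoF
from ..io_utils import load_png16, read_jsonl, save_png16, write_jsonl
from .probe import ProbeModel
from .scene import SceneConfig, SceneSample, make_detection_sample, make_pose_sample

__all__ = [
    "DatasetManifest",
    "DEFAULT_SPLIT_SIZES",
    "generate_dataset",
    "load_manifest",
    "load_split_samples",
]

DEFAULT_SPLIT_SIZES: Dict[str, int] = {"train": 8000, "val": 2000, "test": 1000}


@dataclass
class DatasetManifest:
    """One split: its name, directory and per-sample records."""

    split: str
    root: Path
    records: List[dict]

    def __len__(self) -> int:
        return len(self.records)

    @property
    def jsonl_path(self) -> Path:
        return self.root / "manifest.jsonl"

    def validate(self) -> None:
        for rec in self.records:
            p = self.root / rec["image"]
            if not p.exists():
                raise FileNotFoundError(f"manifest references missing file {p}")


def _sample_record(i: int, sample: SceneSample, image_rel: str, base_seed: int) -> dict:
    rec = {
        "index": i,
        "image": image_rel,
        "pixel_size_mm": float(sample.pixel_size),
        "pose": sample.pose.to_json_dict(),
        "seed": int(base_seed),
        "provenance": sample.provenance,
    }
    if sample.box is not None:
        rec["box"] = sample.box.to_json_dict()
    if sample.patch_geom is not None:
        rec["patch_size"] = sample.patch_geom.patch_size
    return rec


def _write_yolo_label(path: Path, box: BoundingBox, image_size: int) -> None:
    n = float(image_size)
    path.write_text(
        f"0 {box.cx / n:.6f} {box.cy / n:.6f} {box.w / n:.6f} {box.h / n:.6f}\n"
    )


def generate_dataset(
    model: ProbeModel,
    task: str,
    out_dir,
    sizes: Optional[Dict[str, int]] = None,
    seed: int = 0,
    scene_config: SceneConfig = SceneConfig(),
    midpoint_jitter_px: Optional[float] = None,
) -> Dict[str, DatasetManifest]:
    """Generate the train/val/test splits for ``task`` ('detection'|'pose').

    Fully deterministic per seed: each split derives its own child seed from
    ``seed`` and the split name, so regenerating with the same arguments
    reproduces every image and manifest bit-for-bit.
    """
    if task not in ("detection", "pose"):
        raise ValueError(f"unknown task {task!r}")
    sizes = dict(DEFAULT_SPLIT_SIZES if sizes is None else sizes)
    for split, n in sizes.items():
        if n < 1:
            raise ValueError(f"split {split!r} must have >= 1 sample, got {n}")
    out_dir = Path(out_dir)
    manifests: Dict[str, DatasetManifest] = {}
    for si, (split, n) in enumerate(sorted(sizes.items())):
        split_root = out_dir / split
        (split_root / "images").mkdir(parents=True, exist_ok=True)
        (split_root / "labels").mkdir(parents=True, exist_ok=True)
        split_seed = np.random.SeedSequence([seed, si]).generate_state(1)[0] % (2**31 - 1)
        records = []
        for i in range(n):
            base_seed = int(np.random.SeedSequence([int(split_seed), i]).generate_state(1)[0]
                            % (2**31 - 1))
            rng = np.random.default_rng(base_seed)
            if task == "detection":
                sample = make_detection_sample(model, rng, scene_config)
            else:
                sample = make_pose_sample(model, rng, scene_config,
                                          midpoint_jitter_px=midpoint_jitter_px)
            image_rel = f"images/{i:06d}.png"
            save_png16(split_root / image_rel, sample.image)
            if task == "detection" and sample.box is not None:
                _write_yolo_label(split_root / "labels" / f"{i:06d}.txt",
                                  sample.box, scene_config.image_size)
            records.append(_sample_record(i, sample, image_rel, base_seed))
        write_jsonl(split_root / "manifest.jsonl", records)
        _manifest_csv(records).to_csv(split_root / "manifest.csv", index=False)
        manifests[split] = DatasetManifest(split=split, root=split_root, records=records)
    return manifests


def _manifest_csv(records: List[dict]) -> pd.DataFrame:
    rows = []
    for rec in records:
        row = {
            "index": rec["index"],
            "image": rec["image"],
            "pixel_size_mm": rec["pixel_size_mm"],
            "seed": rec["seed"],
            **{k: v for k, v in rec["pose"].items()},
        }
        if "box" in rec:
            row.update({f"box_{k}": v for k, v in rec["box"].items()})
        rows.append(row)
    return pd.DataFrame(rows)


def load_manifest(split_root) -> DatasetManifest:
    split_root = Path(split_root)
    records = read_jsonl(split_root / "manifest.jsonl")
    return DatasetManifest(split=split_root.name, root=split_root, records=records)


def load_split_samples(manifest: DatasetManifest) -> List[SceneSample]:
    """Materialize a split's samples (images loaded from disk)."""
    out = []
    for rec in manifest.records:
        image = load_png16(manifest.root / rec["image"])
        pose = Pose5DoF.from_json_dict(rec["pose"])
        box = BoundingBox.from_json_dict(rec["box"]) if "box" in rec else None
        patch_geom = None
        if "patch_size" in rec:
            patch_geom = PatchGeometry(pixel_size=rec["pixel_size_mm"],
                                       origin=(0.0, 0.0), patch_size=rec["patch_size"])
        out.append(
            SceneSample(
                image=image,
                pixel_size=rec["pixel_size_mm"],
                pose=pose,
                box=box,
                provenance=rec.get("provenance", {}),
                patch_geom=patch_geom,
            )
        )
    return out
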