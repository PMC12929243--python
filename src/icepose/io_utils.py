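"""Image and manifest I/O: 16-bit grayscale PNG, JSON-lines, DICOM reading."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, List

import numpy as np
from PIL import Image

__all__ = [
    "save_png16",
    "load_png16",
    "load_grayscale_frame",
    "write_jsonl",
    "read_jsonl",
]


def save_png16(path, image: np.ndarray) -> None:
    """Write a [0, 1] float image as 16-bit grayscale PNG."""
    arr = np.clip(np.asarray(image, dtype=np.float64), 0.0, 1.0)
    Image.fromarray((arr * 65535.0 + 0.5).astype(np.uint16)).save(str(path))


def load_png16(path) -> np.ndarray:
    """Read a grayscale PNG (8- or 16-bit) back to float32 in [0, 1]."""
    img = Image.open(str(path))
    arr = np.asarray(img)
    if arr.ndim == 3:
        arr = arr[..., 0]
    scale = 65535.0 if arr.dtype == np.uint16 else 255.0
    return (arr.astype(np.float32) / scale).clip(0.0, 1.0)


def load_grayscale_frame(path) -> np.ndarray:
    """Read an inference input frame (PNG or DICOM) as float32 in [0, 1]."""
    p = Path(path)
    if p.suffix.lower() in (".dcm", ".dicom"):
        import pydicom

        ds = pydicom.dcmread(str(p))
        arr = ds.pixel_array.astype(np.float32)
        lo, hi = float(arr.min()), float(arr.max())
        return (arr - lo) / (hi - lo) if hi > lo else np.zeros_like(arr)
    return load_png16(p)


def write_jsonl(path, records: Iterable[dict]) -> None:
    with open(str(path), "w") as fh:
        for rec in records:
            fh.write(json.dumps(rec) + "\n")


def read_jsonl(path) -> List[dict]:
    out = []
    with open(str(path)) as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(json.loads(line))
    return out
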