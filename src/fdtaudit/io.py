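"""Image and manifest I/O helpers (8-bit grayscale PNG, CSV, JSON)."""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
from PIL import Image


def load_slice(path) -> np.ndarray:
    """Read a PNG/JPEG slice as a 2D float array in [0, 1]."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"), dtype=float)
    return arr / 255.0


def save_slice(img: np.ndarray, path) -> None:
    """Write a [0, 1] float grid as 8-bit grayscale PNG."""
    arr = np.clip(np.asarray(img, dtype=float), 0.0, 1.0)
    Image.fromarray(np.round(arr * 255.0).astype(np.uint8), mode="L").save(path)


def write_manifest(rows, path) -> None:
    """rows: iterable of (path, label)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["path", "label"])
        writer.writerows(rows)


def read_manifest(path) -> list:
    with open(path, newline="") as fh:
        return list(csv.DictReader(fh))


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
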