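"""Evaluation-time preprocessing and training-time augmentation.

Evaluation preprocessing is fully deterministic: bilinear resize to the
model input size (default 224x224, half-pixel-center sampling), grayscale
replicated across three channels, then per-channel normalization with
mean 0.5 and standard deviation 0.5 — a [0, 1] input maps onto [-1, 1].

Training augmentation applies, in this order: horizontal flip (p = 0.5),
rotation uniform in +-15 degrees (bilinear, zero fill), multiplicative
brightness jitter uniform in [0.8, 1.2], and contrast jitter in the same
range pivoting on the image mean (x <- mean + f*(x - mean)).  Vertical
flips are never applied: they break the superior-inferior orientation of
axial slices.  Output is clipped back to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = ["PreprocessedSlice", "preprocess_eval", "augment_train", "bilinear_resize"]

CHANNEL_MEAN = 0.5
CHANNEL_SD = 0.5


@dataclass(frozen=True)
class PreprocessedSlice:
    tensor: np.ndarray  # (3, H, W), values in [-1, 1] for [0, 1] inputs
    channel_mean: float = CHANNEL_MEAN
    channel_sd: float = CHANNEL_SD
    provenance: dict = field(default_factory=dict)


def _check(img) -> np.ndarray:
    arr = np.asarray(img, dtype=float)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError("expected a non-empty 2D intensity grid")
    return arr


def bilinear_resize(img: np.ndarray, out_shape: tuple) -> np.ndarray:
    """Bilinear resampling with the half-pixel-center convention.

    Output pixel ``i`` samples source coordinate ``(i + 0.5) * scale - 0.5``;
    coordinates are clamped at the borders (edge replication).
    """
    arr = _check(img)
    h, w = arr.shape
    oh, ow = out_shape
    ry = (np.arange(oh) + 0.5) * (h / oh) - 0.5
    rx = (np.arange(ow) + 0.5) * (w / ow) - 0.5
    yy, xx = np.meshgrid(np.clip(ry, 0, h - 1), np.clip(rx, 0, w - 1), indexing="ij")
    return ndimage.map_coordinates(arr, [yy, xx], order=1, mode="nearest")


def preprocess_eval(img: np.ndarray, size: int = 224, source_id: str = "") -> PreprocessedSlice:
    """Deterministic evaluation-path transform (no stochastic step)."""
    arr = _check(img)
    if arr.min() < -1e-9 or arr.max() > 1 + 1e-9:
        raise ValueError("intensities must lie in [0, 1]; rescale 8-bit input by /255")
    resized = arr if arr.shape == (size, size) else bilinear_resize(arr, (size, size))
    stacked = np.broadcast_to(resized, (3, size, size))
    tensor = (stacked - CHANNEL_MEAN) / CHANNEL_SD
    return PreprocessedSlice(
        tensor=np.ascontiguousarray(tensor),
        provenance={
            "source": source_id,
            "transforms": [f"bilinear_resize({size})", "replicate3", "normalize(0.5,0.5)"],
        },
    )


def augment_train(
    img: np.ndarray,
    seed: int,
    flip_p: float = 0.5,
    rot_deg: float = 15.0,
    jitter_frac: float = 0.2,
) -> np.ndarray:
    """Stochastic training transform; deterministic for a fixed seed."""
    arr = _check(img)
    rng = np.random.default_rng(seed)
    out = arr
    if rng.uniform() < flip_p:
        out = out[:, ::-1]
    if rot_deg > 0:
        angle = rng.uniform(-rot_deg, rot_deg)
        out = ndimage.rotate(out, angle, reshape=False, order=1, mode="constant", cval=0.0)
    if jitter_frac > 0:
        brightness = rng.uniform(1 - jitter_frac, 1 + jitter_frac)
        contrast = rng.uniform(1 - jitter_frac, 1 + jitter_frac)
        out = out * brightness
        m = out.mean()
        out = m + contrast * (out - m)
    return np.clip(out, 0.0, 1.0)
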