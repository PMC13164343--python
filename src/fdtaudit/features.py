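"""Model-independent symbolic features for slice-level verification.

Three real-valued surrogates of neuroradiologic findings are computed per
grayscale slice, purely from the pixel grid (no learned model is involved):

1. **Enhancement variance** — population variance of intensities inside the
   Otsu-segmented foreground mask.  Heterogeneous (mixed-intensity)
   enhancement of high-grade gliomas shows up as a large in-mask variance;
   a value above 0.1 on the [0, 1] intensity scale is treated as
   "heterogeneous enhancement present" by the default constraint set.
2. **Sellar band overlap** — fraction of mask pixels whose row falls in the
   central 20% band of the y-axis.  Pituitary tumors arise in the sella
   turcica, which sits in that band on standard axial slices.  The
   intensity-weighted centroid is reported alongside as auxiliary output.
3. **Border edge density** — Canny edge pixels (sigma = 1.0) inside the
   outer 10% border band, divided by the band's pixel count.  Dural
   contact of meningiomas produces edge activity near the slice border.

Variance is population (not sample) variance of [0, 1]-normalized
intensities, so its ceiling is 0.25 and the 0.1 threshold is meaningful.
Empty or degenerate masks yield 0.0 for every masked feature, with a flag
recorded so downstream traces can show the convention was applied.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from skimage import feature as _skfeature
from skimage.filters import threshold_otsu

__all__ = [
    "TumorMask",
    "SymbolicFeatures",
    "segment_otsu",
    "enhancement_variance",
    "sellar_band_overlap",
    "border_edge_density",
    "extract_all",
    "extract_manifest",
]

BAND_LO, BAND_HI = 0.4, 0.6  # central 20% of the y-axis
BORDER_MARGIN = 0.1  # outer 10% on each side
CANNY_SIGMA = 1.0
CANNY_LOW, CANNY_HIGH = 0.1, 0.2  # hysteresis thresholds on the [0, 1] scale


@dataclass(frozen=True)
class TumorMask:
    mask: np.ndarray  # boolean, same shape as source slice
    degenerate: bool = False

    @property
    def pixel_count(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class SymbolicFeatures:
    enhancement_variance: float
    sellar_band_overlap: float
    border_edge_density: float
    mask_area: int
    centroid: Optional[tuple] = None  # (row, col), intensity-weighted
    flags: tuple = ()

    def as_dict(self) -> dict:
        return {
            "enhancement_variance": self.enhancement_variance,
            "sellar_band_overlap": self.sellar_band_overlap,
            "border_edge_density": self.border_edge_density,
            "mask_area": self.mask_area,
        }


def _check_image(img: np.ndarray) -> np.ndarray:
    arr = np.asarray(img, dtype=float)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError("expected a non-empty 2D intensity grid")
    if arr.min() < -1e-9 or arr.max() > 1 + 1e-9:
        raise ValueError("intensities must lie in [0, 1]")
    return arr


def segment_otsu(img: np.ndarray) -> TumorMask:
    """Foreground mask from Otsu's threshold on a 256-bin histogram.

    Pixels strictly above the threshold are in the mask.  A constant image
    has a degenerate histogram: the mask is empty and flagged.
    """
    arr = _check_image(img)
    if np.ptp(arr) == 0:
        return TumorMask(np.zeros_like(arr, dtype=bool), degenerate=True)
    thr = threshold_otsu(arr, nbins=256)
    return TumorMask(arr > thr)


def enhancement_variance(img: np.ndarray, mask: TumorMask) -> float:
    arr = _check_image(img)
    if mask.mask.shape != arr.shape:
        raise ValueError("mask and image shapes differ")
    if mask.pixel_count == 0:
        return 0.0
    values = arr[mask.mask]
    return float(np.mean(values**2) - np.mean(values) ** 2)


def band_rows(height: int) -> tuple:
    """Row range [lo, hi) of the central 20% y-band (top = row 0)."""
    return int(BAND_LO * height), int(BAND_HI * height)


def sellar_band_overlap(img: np.ndarray, mask: TumorMask) -> tuple:
    """(overlap fraction, intensity-weighted centroid (row, col))."""
    arr = _check_image(img)
    total = float(arr.sum())
    if total > 0:
        rows, cols = np.indices(arr.shape)
        centroid = (
            float((rows * arr).sum() / total),
            float((cols * arr).sum() / total),
        )
    else:
        centroid = (arr.shape[0] / 2.0, arr.shape[1] / 2.0)
    if mask.pixel_count == 0:
        return 0.0, centroid
    lo, hi = band_rows(arr.shape[0])
    in_band = mask.mask[lo:hi, :].sum()
    return float(in_band / mask.pixel_count), centroid


def _border_band(shape: tuple) -> np.ndarray:
    h, w = shape
    mr, mc = int(BORDER_MARGIN * h), int(BORDER_MARGIN * w)
    band = np.ones(shape, dtype=bool)
    band[mr : h - mr, mc : w - mc] = False
    return band


def border_edge_density(img: np.ndarray) -> float:
    arr = _check_image(img)
    edges = _skfeature.canny(
        arr, sigma=CANNY_SIGMA, low_threshold=CANNY_LOW, high_threshold=CANNY_HIGH
    )
    band = _border_band(arr.shape)
    return float(edges[band].sum() / band.sum())


def extract_all(img: np.ndarray) -> SymbolicFeatures:
    """Compose the three extractors on one slice (deterministic)."""
    arr = _check_image(img)
    mask = segment_otsu(arr)
    flags = ("degenerate_mask",) if (mask.degenerate or mask.pixel_count == 0) else ()
    variance = enhancement_variance(arr, mask)
    overlap, centroid = sellar_band_overlap(arr, mask)
    density = border_edge_density(arr)
    return SymbolicFeatures(
        enhancement_variance=variance,
        sellar_band_overlap=overlap,
        border_edge_density=density,
        mask_area=mask.pixel_count,
        centroid=centroid,
        flags=flags,
    )


def extract_manifest(manifest_csv, out_csv) -> int:
    """Batch mode: read a manifest CSV (path[,label]) and write features.

    Returns the number of slices processed.
    """
    from .io import load_slice

    manifest_csv, out_csv = Path(manifest_csv), Path(out_csv)
    n = 0
    with open(manifest_csv, newline="") as fh, open(out_csv, "w", newline="") as out:
        reader = csv.DictReader(fh)
        writer = csv.writer(out)
        writer.writerow(
            ["slice_id", "variance", "overlap", "density", "mask_area", "flags"]
        )
        for row in reader:
            path = Path(row["path"])
            if not path.is_absolute():
                path = manifest_csv.parent / path
            f = extract_all(load_slice(path))
            writer.writerow(
                [
                    path.stem,
                    repr(f.enhancement_variance),
                    repr(f.sellar_band_overlap),
                    repr(f.border_edge_density),
                    f.mask_area,
                    ";".join(f.flags),
                ]
            )
            n += 1
    return n
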