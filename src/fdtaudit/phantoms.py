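"""Synthetic four-class slice phantoms with analytically known features.

Every downstream stage — preprocessing, feature extraction, constraint
verification, training — is exercised on phantoms that emulate axial
post-contrast T1-like slices: a dark background (~0.1), a bright skull
rim, and a class-specific bright structure:

* ``glioma`` — an off-center blob whose pixels alternate between two
  intensity levels, tuned so the in-blob population variance equals the
  requested target (heterogeneous enhancement).
* ``pituitary`` — a compact bright blob positioned so a requested
  fraction of its area falls inside the central 20% y-band (the sellar
  band on axial slices).
* ``meningioma`` — a peripheral blob plus bright "dural tail" bars in
  the border band, tuned so Canny border edge density approximates the
  requested target.
* ``no_tumor`` — background and rim only.

Ground truth is exact where the construction permits: variance and band
overlap are computed from the constructed bright-structure pixel multiset
itself, so extractor recovery error reflects only segmentation behavior.
Border edge density ground truth uses a drawn-boundary-length model of
Canny output (two edge lines per bar plus end caps) and is approximate
by nature; the stated recovery tolerance absorbs this.

The skull rim is included by default, mirroring full field-of-view
preprocessing (no skull stripping); ``rim=False`` gives the strict
configuration in which the Otsu mask equals the bright structure exactly
and the recovery guarantees hold.  Background levels and blob levels
(background 0.1, structures >= 0.5) guarantee a bimodal histogram so
Otsu's threshold lands in the background/structure gap; this bounds the
constructible in-blob variance at 0.05 (an equal mix of {0.553, 1.0}),
and larger targets raise a parameter error as unreachable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .constraints import CLASSES
from .features import SymbolicFeatures, band_rows
from . import io as _io

__all__ = [
    "PhantomSpec",
    "PhantomGroundTruth",
    "generate_phantom",
    "generate_cohort",
    "save_cohort",
    "MAX_TARGET_VARIANCE",
    "DEFAULT_TARGET_RANGES",
]

BACKGROUND = 0.1
RIM_VALUE = 0.95
RIM_RADIUS = 0.47  # fraction of image size
BLOB_FLOOR = 0.5  # structure intensities stay above this: keeps Otsu bimodal
MAX_TARGET_VARIANCE = 0.05  # equal mix {1 - 2*sqrt(V), 1.0} with floor 0.5

# Canny output model for a 3-px-thick bright bar of length L in the border
# band: two long edge lines plus end caps, ~ 2L + BAR_END edge pixels.
BAR_THICKNESS = 3
BAR_END_EDGES = 6

DEFAULT_TARGET_RANGES = {
    "glioma": {"target_variance": (0.02, 0.05)},
    "pituitary": {"target_band_overlap": (0.7, 1.0)},
    "meningioma": {"target_border_density": (0.06, 0.12)},
    "no_tumor": {},
}


class PhantomParameterError(ValueError):
    """A requested feature target is unreachable by the construction."""


@dataclass(frozen=True)
class PhantomSpec:
    class_label: str
    image_size: int = 224
    target_variance: float = 0.0
    target_band_overlap: float = 1.0
    target_border_density: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0
    rim: bool = True

    def __post_init__(self) -> None:
        if self.class_label not in CLASSES:
            raise PhantomParameterError(f"unknown class {self.class_label!r}")
        if self.image_size < 32:
            raise PhantomParameterError("image_size must be >= 32")
        if not 0.0 <= self.target_variance <= 0.25:
            raise PhantomParameterError("target_variance outside [0, 0.25]")
        if self.target_variance > MAX_TARGET_VARIANCE:
            raise PhantomParameterError(
                f"target_variance {self.target_variance} unreachable: the "
                f"construction keeps blob levels above {BLOB_FLOOR}, capping "
                f"variance at {MAX_TARGET_VARIANCE}"
            )
        for name in ("target_band_overlap", "target_border_density"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise PhantomParameterError(f"{name} outside [0, 1]")
        if self.noise_sd < 0:
            raise PhantomParameterError("noise_sd must be >= 0")


@dataclass(frozen=True)
class PhantomGroundTruth:
    true_features: SymbolicFeatures
    class_label: str
    spec: PhantomSpec

    def as_record(self, slice_id: str) -> dict:
        rec = {"slice_id": slice_id, "class_label": self.class_label}
        rec.update(self.true_features.as_dict())
        rec["params"] = asdict(self.spec)
        return rec


def _disk(size: int, center: tuple, radius: float) -> np.ndarray:
    rr, cc = np.indices((size, size))
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _rim_mask(size: int) -> np.ndarray:
    rr, cc = np.indices((size, size))
    c = (size - 1) / 2.0
    d = np.sqrt((rr - c) ** 2 + (cc - c) ** 2)
    r = RIM_RADIUS * size
    return np.abs(d - r) <= 0.75


def _truth(values: np.ndarray, rows: np.ndarray, size: int) -> "tuple[float, float]":
    """Exact variance and band overlap of the bright-structure pixel set."""
    if values.size == 0:
        return 0.0, 0.0
    var = float(np.mean(values**2) - np.mean(values) ** 2)
    lo, hi = band_rows(size)
    overlap = float(np.logical_and(rows >= lo, rows < hi).mean())
    return var, overlap


def _glioma(img: np.ndarray, spec: PhantomSpec):
    s = spec.image_size
    blob = _disk(s, (round(0.30 * s), round(0.62 * s)), 0.17 * s)
    rr, cc = np.nonzero(blob)
    parity = (rr + cc) % 2 == 0
    p = float(parity.mean())  # fraction assigned the high level
    if spec.target_variance > 0:
        gap = math.sqrt(spec.target_variance / (p * (1 - p)))
    else:
        gap = 0.0
    hi = 1.0
    lo = hi - gap
    if lo < BLOB_FLOOR:
        raise PhantomParameterError("variance target pushes blob level below floor")
    vals = np.where(parity, hi, lo)
    img[rr, cc] = vals
    return vals, rr


def _pituitary(img: np.ndarray, spec: PhantomSpec):
    s = spec.image_size
    radius = max(2.0, 0.08 * s)
    lo, hi = band_rows(s)
    best_cy, best_err = None, None
    for cy in range(int(radius) + 2, s - int(radius) - 2):
        rel = _disk(s, (cy, s // 2), radius)
        rows = np.nonzero(rel)[0]
        frac = float(np.logical_and(rows >= lo, rows < hi).mean())
        err = abs(frac - spec.target_band_overlap)
        if best_err is None or err < best_err - 1e-12:
            best_cy, best_err = cy, err
    blob = _disk(s, (best_cy, s // 2), radius)
    rr = np.nonzero(blob)[0]
    img[blob] = 0.9
    vals = np.full(rr.shape, 0.9)
    return vals, rr


def _meningioma(img: np.ndarray, spec: PhantomSpec):
    s = spec.image_size
    margin = int(0.1 * s)
    band_area = s * s - (s - 2 * margin) ** 2
    blob = _disk(s, (round(0.50 * s), round(0.76 * s)), 0.09 * s)
    img[blob] = 0.85
    target_edges = spec.target_border_density * band_area
    # bar slots: (row0, col0, horizontal?) anchored mid-band on each side
    r0 = max(2, margin // 2 - 1)
    slots = [
        (r0, None, True),  # top
        (s - r0 - BAR_THICKNESS, None, True),  # bottom
        (None, r0, False),  # left
        (None, s - r0 - BAR_THICKNESS, False),  # right
    ]
    max_half = int(0.36 * s)
    modeled_edges = 0.0
    remaining = target_edges
    for row0, col0, horiz in slots:
        if remaining < BAR_END_EDGES + 8:
            break
        want_len = min(2 * max_half, (remaining - BAR_END_EDGES) / 2.0)
        length = max(4, int(round(want_len)))
        mid = s // 2
        a, b = mid - length // 2, mid - length // 2 + length
        if horiz:
            img[row0 : row0 + BAR_THICKNESS, a:b] = 1.0
        else:
            img[a:b, col0 : col0 + BAR_THICKNESS] = 1.0
        e = 2 * length + BAR_END_EDGES
        modeled_edges += e
        remaining -= e
    density = modeled_edges / band_area
    bright = (img >= BLOB_FLOOR)
    rr, cc = np.nonzero(bright)
    return img[rr, cc].copy(), rr, density


def generate_phantom(spec: PhantomSpec):
    """Render one phantom; returns ``(image, PhantomGroundTruth)``.

    Deterministic given ``spec`` (noise is drawn from a generator seeded by
    ``spec.seed`` and applied to background pixels only, so structure
    intensities — and hence the analytic truth — are unaffected).
    """
    s = spec.image_size
    img = np.full((s, s), BACKGROUND)
    density_truth = 0.0
    if spec.class_label == "glioma":
        vals, rows = _glioma(img, spec)
    elif spec.class_label == "pituitary":
        vals, rows = _pituitary(img, spec)
    elif spec.class_label == "meningioma":
        vals, rows, density_truth = _meningioma(img, spec)
    else:  # no_tumor
        vals, rows = np.empty(0), np.empty(0, dtype=int)
    structure = img > BACKGROUND
    if spec.rim:
        img[_rim_mask(s)] = RIM_VALUE
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        noise = rng.normal(0.0, spec.noise_sd, size=img.shape)
        bg = ~structure & ~(_rim_mask(s) if spec.rim else np.zeros_like(structure))
        img[bg] = np.clip(img[bg] + noise[bg], 0.0, 0.35)
    img = np.clip(img, 0.0, 1.0)

    var, overlap = _truth(np.asarray(vals, dtype=float), rows, s)
    if spec.class_label == "glioma" and spec.target_variance > 0:
        # parity counts were folded into the level gap: truth is the target
        assert abs(var - spec.target_variance) < 1e-9
    truth = SymbolicFeatures(
        enhancement_variance=var,
        sellar_band_overlap=overlap,
        border_edge_density=density_truth,
        mask_area=int(len(rows)),
    )
    return img, PhantomGroundTruth(truth, spec.class_label, spec)


def _slice_seed(master_seed: int, index: int) -> int:
    return int(np.random.SeedSequence([master_seed, index]).generate_state(1)[0] % (2**31))


def generate_cohort(
    class_counts: Mapping[str, int],
    seed: int = 0,
    image_size: int = 64,
    noise_sd: float = 0.01,
    rim: bool = True,
    target_ranges: Optional[Mapping[str, Mapping[str, tuple]]] = None,
) -> list:
    """Generate a reproducible cohort; returns [(image, PhantomGroundTruth)].

    ``class_counts`` maps class label to a non-negative count.  Per-slice
    seeds derive from the master seed and slice index, and per-slice
    feature targets are drawn from ``target_ranges`` (default:
    :data:`DEFAULT_TARGET_RANGES`) by a cohort-level generator, so the
    same counts and seed always reproduce byte-identical images.
    """
    ranges = {**DEFAULT_TARGET_RANGES, **(target_ranges or {})}
    for label, n in class_counts.items():
        if label not in CLASSES:
            raise PhantomParameterError(f"unknown class {label!r}")
        if n < 0:
            raise PhantomParameterError("counts must be >= 0")
    draw_rng = np.random.default_rng(np.random.SeedSequence([seed, 0xFEA7]))
    cohort = []
    index = 0
    for label in CLASSES:
        for _ in range(int(class_counts.get(label, 0))):
            params = {}
            for pname, (lo, hi) in ranges.get(label, {}).items():
                params[pname] = float(draw_rng.uniform(lo, hi))
            spec = PhantomSpec(
                class_label=label,
                image_size=image_size,
                noise_sd=noise_sd,
                seed=_slice_seed(seed, index),
                rim=rim,
                **params,
            )
            cohort.append(generate_phantom(spec))
            index += 1
    return cohort


def save_cohort(cohort: Sequence, out_dir) -> dict:
    """Write PNGs, a ground-truth JSON sidecar, and a manifest CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records, manifest_rows = [], []
    for i, (img, truth) in enumerate(cohort):
        slice_id = f"phantom_{i:05d}"
        path = out_dir / f"{slice_id}.png"
        _io.save_slice(img, path)
        records.append(truth.as_record(slice_id))
        manifest_rows.append((path.name, truth.class_label))
    _io.write_json(records, out_dir / "ground_truth.json")
    _io.write_manifest(manifest_rows, out_dir / "manifest.csv")
    return {
        "n": len(cohort),
        "manifest": str(out_dir / "manifest.csv"),
        "ground_truth": str(out_dir / "ground_truth.json"),
    }
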