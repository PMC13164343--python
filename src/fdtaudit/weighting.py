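"""Inverse-frequency class weighting and the weighted cross-entropy loss.

With per-class counts :math:`n_c` in the current training partition, the
relative frequency is :math:`f_c = n_c / \\sum_k n_k`, the raw weight
:math:`w_c = 1/f_c`, and the normalized weight

.. math:: w_c^{norm} = \\frac{w_c}{\\tfrac{1}{C}\\sum_k w_k},
          \\qquad \\sum_c w_c^{norm} = C,

so the average weight is exactly 1 and the loss keeps its usual scale
while minority classes get proportionally stronger gradients.  The
per-sample loss is :math:`-w_y^{norm} \\ln p_y` (natural log); batch loss
is the mean over samples.  Weights are recomputed per training partition
— pass the counts of the split actually being optimized.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .constraints import CLASSES

__all__ = ["ClassWeights", "compute_weights", "weighted_cross_entropy"]

_EPS = 1e-12


@dataclass(frozen=True)
class ClassWeights:
    counts: tuple
    frequencies: tuple
    raw_weights: tuple
    normalized_weights: tuple

    @property
    def n_classes(self) -> int:
        return len(self.counts)

    def as_dict(self) -> dict:
        return {
            cls: {
                "count": c, "frequency": f, "raw_weight": w, "normalized_weight": wn,
            }
            for cls, c, f, w, wn in zip(
                CLASSES, self.counts, self.frequencies, self.raw_weights,
                self.normalized_weights,
            )
        }


def compute_weights(counts: Sequence[int]) -> ClassWeights:
    """Frequencies, raw inverse weights, and mean-1 normalized weights."""
    counts = tuple(int(c) for c in counts)
    if any(c <= 0 for c in counts):
        raise ValueError("every class count must be > 0 (weight undefined otherwise)")
    total = sum(counts)
    freqs = tuple(c / total for c in counts)
    raw = tuple(1.0 / f for f in freqs)
    mean_raw = sum(raw) / len(raw)
    norm = tuple(w / mean_raw for w in raw)
    return ClassWeights(counts, freqs, raw, norm)


def weighted_cross_entropy(softmax, true_label, weights: ClassWeights):
    """Per-sample or batch weighted cross-entropy with natural log.

    ``softmax`` is one probability vector or an (n, C) array;
    ``true_label`` a class index (or label string) or a vector of them.
    Probabilities are clamped at 1e-12 before the log.
    """
    p = np.atleast_2d(np.asarray(softmax, dtype=float))
    labels = np.atleast_1d(true_label)
    if labels.dtype.kind in "US":
        labels = np.array([CLASSES.index(l) for l in labels])
    labels = labels.astype(int)
    if p.shape[0] != labels.shape[0] or p.shape[1] != weights.n_classes:
        raise ValueError("softmax/label shape mismatch")
    w = np.asarray(weights.normalized_weights)
    py = p[np.arange(len(labels)), labels]
    if np.any(py < _EPS):
        import warnings

        warnings.warn("clamping zero probabilities at 1e-12 in cross-entropy")
        py = np.maximum(py, _EPS)
    losses = -w[labels] * np.log(py)
    return float(losses[0]) if np.isscalar(true_label) or losses.size == 1 else float(losses.mean())
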