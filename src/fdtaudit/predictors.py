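"""Stub predictors satisfying the audit loop's predictor contract.

The verifier only requires a callable ``PreprocessedSlice -> Prediction``
with a ``model_id``; these deterministic stand-ins let the verification
layer run end to end without a trained checkpoint, and let tests engineer
batches with known predicted classes.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

from .constraints import CLASSES
from .features import extract_all
from .verifier import Prediction

__all__ = ["FeaturePriorPredictor", "LabelLookupPredictor"]


def _one_hotish(label: str, confidence: float = 0.91) -> Prediction:
    rest = (1.0 - confidence) / (len(CLASSES) - 1)
    return Prediction(label, tuple(confidence if c == label else rest for c in CLASSES))


class FeaturePriorPredictor:
    """Rule-of-thumb classifier on the slice's own symbolic features.

    Mirrors the radiologic priors behind the constraint set (variance ->
    glioma, sellar overlap -> pituitary, border edges -> meningioma), so
    its predictions are mostly constraint-consistent by construction.
    """

    model_id = "feature-prior"
    input_size = 224

    def __call__(self, pre) -> Prediction:
        gray = pre.tensor[0] * pre.channel_sd + pre.channel_mean
        f = extract_all(np.clip(gray, 0.0, 1.0))
        if f.mask_area == 0:
            return _one_hotish("no_tumor")
        if f.border_edge_density > 0.05:
            return _one_hotish("meningioma")
        if f.sellar_band_overlap > 0.5:
            return _one_hotish("pituitary")
        if f.enhancement_variance > 0.01:
            return _one_hotish("glioma")
        return _one_hotish("no_tumor")


class LabelLookupPredictor:
    """Predicts a fixed class per slice id (for engineered audit batches)."""

    input_size = 224

    def __init__(self, labels: Mapping[str, str], model_id: str = "label-lookup"):
        self.labels = dict(labels)
        self.model_id = model_id

    def __call__(self, pre) -> Prediction:
        return _one_hotish(self.labels[pre.provenance["source"]])
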