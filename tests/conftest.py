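import numpy as np
import pytest

from fdtaudit.constraints import CLASSES, default_constraints
from fdtaudit.features import SymbolicFeatures
from fdtaudit.verifier import Prediction, build_trace


@pytest.fixture(scope="session")
def constraint_set():
    return default_constraints()


@pytest.fixture
def make_trace():
    """Factory building a minimal decision trace from feature values."""

    def _make(label, variance=0.0, overlap=0.0, density=0.0, slice_id="s0"):
        features = SymbolicFeatures(
            enhancement_variance=variance,
            sellar_band_overlap=overlap,
            border_edge_density=density,
            mask_area=100,
        )
        softmax = tuple(0.91 if c == label else 0.03 for c in CLASSES)
        return build_trace(slice_id, features, Prediction(label, softmax), "test-model")

    return _make


def random_trace(rng, make, boundary_thresholds=(0.1, 0.5, 0.05)):
    """One random trace; occasionally sits exactly at/around a threshold."""
    label = CLASSES[rng.integers(len(CLASSES))]
    c1, c2, c3 = boundary_thresholds
    choices = {
        "variance": [float(rng.uniform(0, 0.25)), c1, np.nextafter(c1, 0), np.nextafter(c1, 1)],
        "overlap": [float(rng.uniform(0, 1)), c2, np.nextafter(c2, 0), np.nextafter(c2, 1)],
        "density": [float(rng.uniform(0, 1)), c3, np.nextafter(c3, 0), np.nextafter(c3, 1)],
    }
    kwargs = {k: v[rng.integers(len(v))] for k, v in choices.items()}
    return make(label, **kwargs)
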