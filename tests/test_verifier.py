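"""Trace construction, dual-channel verification, artifacts, batch audit."""

import json

import numpy as np
import pytest

from fdtaudit.constraints import CLASSES, default_constraints
from fdtaudit.features import SymbolicFeatures
from fdtaudit.lra import Atom, Implies, BoolLit
from fdtaudit.verifier import (
    FDTArtifact,
    Prediction,
    build_artifact,
    build_trace,
    dual_channel_verify,
    encode_trace,
    exact_decimal,
    smt_check,
)
from conftest import random_trace

FROZEN_TS = "2001-01-01T00:00:00+00:00"


class TestPrediction:
    def test_valid_prediction(self):
        p = Prediction("glioma", (0.7, 0.1, 0.1, 0.1))
        assert p.confidence == 0.7

    def test_unnormalized_softmax_rejected(self):
        with pytest.raises(ValueError):
            Prediction("glioma", (0.3, 0.3, 0.3, 0.3))

    def test_tie_resolves_to_lowest_index(self):
        assert Prediction("glioma", (0.25, 0.25, 0.25, 0.25)).class_label == "glioma"
        with pytest.raises(ValueError):
            Prediction("meningioma", (0.25, 0.25, 0.25, 0.25))

    def test_argmax_mismatch_rejected(self):
        with pytest.raises(ValueError):
            Prediction("glioma", (0.1, 0.7, 0.1, 0.1))


class TestTraceStructure:
    def test_alternating_states_and_actions(self, make_trace):
        t = make_trace("glioma", variance=0.2)
        kinds = [k for k, _ in t.steps]
        assert kinds[0] == kinds[-1] == "state"
        assert all(a != b for a, b in zip(kinds, kinds[1:]))
        stages = [p["stage"] for _, p in t.steps]
        assert stages == ["raw", "extract_features", "featured", "predict", "decided"]

    def test_trace_exposes_features_and_prediction(self, make_trace):
        t = make_trace("pituitary", overlap=0.9)
        assert t.features.sellar_band_overlap == 0.9
        assert t.prediction.class_label == "pituitary"


class TestEncoding:
    def test_formula_set_contents(self, make_trace, constraint_set):
        fs = encode_trace(make_trace("glioma", variance=0.15), constraint_set)
        names = [n for n, _ in fs.assumptions]
        assert names == ["C1", "C2", "C3", "C4", "PRED"]
        text = fs.smtlib()
        assert "(set-logic QF_LRA)" in text
        assert "(=> is_glioma (> enhancement_variance" in text
        assert ":named C1" in text

    def test_feature_constants_rendered_as_exact_decimals(self, make_trace, constraint_set):
        fs = encode_trace(make_trace("glioma", variance=0.098), constraint_set)
        assert fs.feature_literals["enhancement_variance"] == exact_decimal(0.098)
        # the rendering is the exact binary value, not a rounded string
        assert fs.feature_literals["enhancement_variance"].startswith("0.09800000000000000")
        assert len(fs.feature_literals["enhancement_variance"]) > 20

    def test_encoding_is_deterministic(self, make_trace, constraint_set):
        t = make_trace("meningioma", density=0.123)
        assert encode_trace(t, constraint_set).smtlib() == encode_trace(t, constraint_set).smtlib()

    def test_empty_constraint_set_always_sat(self, make_trace):
        from fdtaudit.constraints import ConstraintSet

        fs = encode_trace(make_trace("glioma", variance=0.0), ConstraintSet((), version="v0"))
        assert smt_check(fs).status == "SAT"


class TestDualChannel:
    def test_borderline_glioma_unsat_with_core(self, make_trace, constraint_set):
        t = make_trace("glioma", variance=0.098, overlap=0.7, density=0.2)
        result, agreement = dual_channel_verify(t, constraint_set)
        assert result.status == "UNSAT"
        assert "C1" in result.violated_ids
        assert agreement is True
        assert result.per_constraint_truth["C1"] is False

    def test_verdict_flips_above_threshold(self, make_trace, constraint_set):
        t = make_trace("glioma", variance=0.101)
        result, agreement = dual_channel_verify(t, constraint_set)
        assert result.status == "SAT" and agreement is True

    def test_boundary_violation_in_both_channels(self, make_trace, constraint_set):
        t = make_trace("glioma", variance=0.1)  # strict '>' fails at the boundary
        result, agreement = dual_channel_verify(t, constraint_set)
        assert result.status == "UNSAT" and agreement is True
        assert result.per_constraint_truth["C1"] is False

    def test_corrupted_encoder_detected(self, make_trace, constraint_set):
        """Fault injection: an encoder that flips C1's comparator must trip
        the dual-channel agreement check."""

        def corrupted(trace, cs):
            fs = encode_trace(trace, cs)
            flipped = []
            for name, f in fs.assumptions:
                if name == "C1":
                    f = Implies(f.antecedent, Atom(f.consequent.var, "<", f.consequent.rhs))
                flipped.append((name, f))
            return type(fs)(
                feature_literals=fs.feature_literals,
                predicted_class=fs.predicted_class,
                background=fs.background,
                assumptions=tuple(flipped),
                constraint_version=fs.constraint_version,
            )

        # a trace the true rules accept: the flipped comparator must flip the
        # solver verdict while the direct channel still passes everything
        t = make_trace("glioma", variance=0.15, overlap=0.6, density=0.2)
        result, agreement = dual_channel_verify(t, constraint_set, encoder=corrupted)
        assert agreement is False

    def test_verdict_ignores_softmax_magnitudes(self, constraint_set):
        f = SymbolicFeatures(0.15, 0.7, 0.2, 50)
        t1 = build_trace("a", f, Prediction("glioma", (0.97, 0.01, 0.01, 0.01)), "m")
        t2 = build_trace("a", f, Prediction("glioma", (0.4, 0.2, 0.2, 0.2)), "m")
        assert dual_channel_verify(t1, constraint_set)[0].status == \
            dual_channel_verify(t2, constraint_set)[0].status

    def test_randomized_agreement(self, make_trace, constraint_set):
        rng = np.random.default_rng(123)
        for _ in range(100):
            t = random_trace(rng, make_trace)
            result, agreement = dual_channel_verify(t, constraint_set)
            assert agreement is True
            if result.status == "UNSAT":
                assert result.violated_ids
                for cid in result.violated_ids:
                    assert result.per_constraint_truth[cid] is False


class TestArtifacts:
    def _artifact(self, make_trace, constraint_set):
        t = make_trace("glioma", variance=0.098, overlap=0.7, density=0.2)
        fs = encode_trace(t, constraint_set)
        result, _ = dual_channel_verify(t, constraint_set)
        return build_artifact(t, fs, result, timestamp=FROZEN_TS)

    def test_round_trip_verification(self, make_trace, constraint_set):
        art = self._artifact(make_trace, constraint_set)
        assert art.verify()
        assert FDTArtifact.from_json(art.to_json()).verify()

    def test_any_single_byte_flip_detected(self, make_trace, constraint_set):
        art = self._artifact(make_trace, constraint_set)
        doc = art.to_json()
        rng = np.random.default_rng(0)
        sha_span = doc.find('"sha256"')
        for _ in range(25):
            pos = int(rng.integers(len(doc)))
            if sha_span <= pos < sha_span + 80:
                continue  # mutating the stored digest itself is detected trivially
            orig = doc[pos]
            repl = "x" if orig != "x" else "y"
            mutated = doc[:pos] + repl + doc[pos + 1 :]
            try:
                assert not FDTArtifact.from_json(mutated).verify()
            except (json.JSONDecodeError, KeyError, TypeError):
                pass  # mutation broke the JSON: detected even earlier

    def test_frozen_digest_regression(self, make_trace, constraint_set):
        art1 = self._artifact(make_trace, constraint_set)
        art2 = self._artifact(make_trace, constraint_set)
        assert art1.sha256 == art2.sha256
        assert len(art1.sha256) == 64 and int(art1.sha256, 16) >= 0

    def test_metadata_carried(self, make_trace, constraint_set):
        art = self._artifact(make_trace, constraint_set)
        meta = art.payload["metadata"]
        assert meta["slice_id"] == "s0"
        assert meta["model_id"] == "test-model"
        assert meta["constraint_version"] == "default-1"


class TestAuditBatch:
    def _manifest(self, n_violating, n_total, seed=0):
        """Pituitary phantoms; n_violating get an out-of-band blob."""
        from fdtaudit.phantoms import PhantomSpec, generate_phantom

        rows = []
        for i in range(n_total):
            overlap = 0.2 if i < n_violating else 0.95
            img, truth = generate_phantom(
                PhantomSpec("pituitary", image_size=64, target_band_overlap=overlap,
                            rim=False, seed=i)
            )
            rows.append({"image": img, "slice_id": f"p{i:03d}", "label": "pituitary"})
        return rows

    def _predictor(self):
        from fdtaudit.predictors import LabelLookupPredictor

        return LabelLookupPredictor(
            {f"p{i:03d}": "pituitary" for i in range(100)}, model_id="stub"
        )

    def test_all_sat_batch(self, constraint_set):
        report = __import__("fdtaudit.verifier", fromlist=["audit_batch"]).audit_batch(
            self._manifest(0, 10), self._predictor(), constraint_set
        )
        assert report["unsat_pct"] == 0.0
        assert report["dual_channel_agreement_pct"] == 100.0

    def test_engineered_violation_rate(self, constraint_set):
        from fdtaudit.verifier import audit_batch

        report = audit_batch(self._manifest(3, 100), self._predictor(), constraint_set)
        assert report["unsat_pct"] == pytest.approx(3.0)
        # partition identity: SAT + UNSAT-correct + UNSAT-incorrect = 100%
        total = (
            report["sat_pct"]
            + report["unsat_correct_label_pct"]
            + report["unsat_incorrect_label_pct"]
        )
        assert total == pytest.approx(100.0)

    def test_outputs_written(self, tmp_path, constraint_set):
        from fdtaudit.verifier import audit_batch

        audit_batch(
            self._manifest(1, 5), self._predictor(), constraint_set,
            out_dir=tmp_path, timestamp=FROZEN_TS,
        )
        report = json.loads((tmp_path / "audit_report.json").read_text())
        assert report["n_slices"] == 5
        arts = list((tmp_path / "artifacts").glob("*.fdt.json"))
        assert len(arts) == 5
        assert FDTArtifact.from_json(arts[0].read_text()).verify()

    def test_missing_images_skipped(self, tmp_path, constraint_set):
        from fdtaudit.verifier import audit_batch

        rows = [{"path": "does_not_exist.png", "label": "no_tumor"}]
        report = audit_batch(rows, self._predictor(), constraint_set, image_root=tmp_path)
        assert report["n_slices"] == 0
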