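"""Formal decision traces and their verification.

Every audited classification decision is recorded as a formal decision
trace — an alternating sequence of states and actions (raw slice,
feature-extraction outcome, prediction) — and then checked against the
neuroradiologic constraint set through two independent channels:

1. **SMT channel** — the trace is encoded into quantifier-free linear
   real arithmetic: one real constant per symbolic feature, one Boolean
   selector per class, and one *tracked* implication per constraint.  The
   conjunction is handed to the QF_LRA decision procedure, which returns
   SAT (with a model as certificate) or UNSAT (with an unsat core naming
   the violated constraints).
2. **Direct channel** — a plain Python Boolean evaluator applies each
   rule as a material implication on the same feature values.

Agreement between the channels certifies encoding fidelity; disagreement
(or an UNKNOWN verdict from a solver timeout) is flagged for manual
review.  Feature values are rendered as *exact* decimal literals of
their IEEE-754 value and both channels compare the same rationals, so
agreement can never hinge on binary-float representation.

The result is packaged as a tamper-evident artifact: trace, rendered
formulas, verdict, certificate, and metadata are canonically serialized
(sorted keys, exact-decimal floats, no insignificant whitespace) and
attested with a SHA-256 digest.  Any single-byte mutation of the
serialized record is detectable by recomputing the digest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from datetime import datetime, timezone
from decimal import Decimal
from fractions import Fraction
from pathlib import Path
from typing import Callable, Mapping, Optional, Sequence

import numpy as np

from .constraints import (
    CLASSES,
    FEATURE_NAMES,
    ConstraintSet,
    ConstraintSpec,
    evaluate_predicate,
)
from .features import SymbolicFeatures, extract_all
from .lra import And, Atom, BoolLit, ExactlyOne, Implies, LraSolver

logger = logging.getLogger(__name__)

__all__ = [
    "Prediction",
    "DecisionTrace",
    "FormulaSet",
    "VerificationResult",
    "FDTArtifact",
    "build_trace",
    "encode_trace",
    "smt_check",
    "dual_channel_verify",
    "build_artifact",
    "audit_batch",
    "exact_decimal",
]


def exact_decimal(x: float) -> str:
    """Exact decimal rendering of an IEEE-754 double (no rounding)."""
    return format(Decimal(float(x)), "f")


@dataclass(frozen=True)
class Prediction:
    class_label: str
    softmax: tuple  # probabilities in CLASSES order

    def __post_init__(self) -> None:
        sm = tuple(float(p) for p in self.softmax)
        object.__setattr__(self, "softmax", sm)
        if self.class_label not in CLASSES:
            raise ValueError(f"unknown class {self.class_label!r}")
        if len(sm) != len(CLASSES) or any(p < 0 for p in sm):
            raise ValueError("softmax must be 4 non-negative entries")
        if abs(sum(sm) - 1.0) > 1e-6:
            raise ValueError("softmax must sum to 1 within 1e-6")
        # ties resolve to the lowest class index
        arg = max(range(len(sm)), key=lambda i: (sm[i], -i))
        if CLASSES[arg] != self.class_label:
            raise ValueError("class_label inconsistent with softmax argmax")

    @property
    def confidence(self) -> float:
        return max(self.softmax)


@dataclass(frozen=True)
class DecisionTrace:
    """Alternating state/action record ending in a state (append-only)."""

    steps: tuple  # of ("state"|"action", dict)
    slice_id: str
    model_id: str

    def __post_init__(self) -> None:
        kinds = [k for k, _ in self.steps]
        if not kinds or kinds[0] != "state" or kinds[-1] != "state":
            raise ValueError("trace must start and end with a state")
        for a, b in zip(kinds, kinds[1:]):
            if a == b:
                raise ValueError("trace must alternate states and actions")

    @property
    def features(self) -> SymbolicFeatures:
        for kind, payload in self.steps:
            if kind == "state" and "features" in payload:
                return payload["features"]
        raise KeyError("trace carries no features state")

    @property
    def prediction(self) -> Prediction:
        for kind, payload in reversed(self.steps):
            if kind == "action" and "prediction" in payload:
                return payload["prediction"]
        raise KeyError("trace carries no prediction action")


def build_trace(
    slice_id: str,
    features: SymbolicFeatures,
    prediction: Prediction,
    model_id: str,
    preprocessing: Optional[Mapping] = None,
) -> DecisionTrace:
    """Assemble the canonical three-state trace for one decision."""
    steps = (
        ("state", {"stage": "raw", "slice_id": slice_id,
                   "preprocessing": dict(preprocessing or {})}),
        ("action", {"stage": "extract_features", "flags": list(features.flags)}),
        ("state", {"stage": "featured", "features": features}),
        ("action", {"stage": "predict", "prediction": prediction}),
        ("state", {"stage": "decided", "class_label": prediction.class_label}),
    )
    return DecisionTrace(steps=steps, slice_id=slice_id, model_id=model_id)


@dataclass(frozen=True)
class FormulaSet:
    """QF_LRA encoding of one trace against one constraint set."""

    feature_literals: Mapping[str, str]  # feature name -> exact decimal text
    predicted_class: str
    background: tuple  # untracked assertions (feature constants, prediction)
    assumptions: tuple  # (name, formula) tracked assertions
    theory: str = "QF_LRA"
    constraint_version: str = ""

    def smtlib(self) -> str:
        lines = [f"(set-logic {self.theory})"]
        for name in sorted(self.feature_literals):
            lines.append(f"(declare-const {name} Real)")
        for cls in CLASSES:
            lines.append(f"(declare-const is_{cls} Bool)")
        for f in self.background:
            lines.append(f"(assert {f.smtlib()})")
        for name, f in self.assumptions:
            lines.append(f"(assert (! {f.smtlib()} :named {name}))")
        lines.append("(check-sat)")
        lines.append("(get-unsat-core)")
        return "\n".join(lines)

    def conjunction(self) -> str:
        parts = [f.smtlib() for f in self.background]
        parts += [f.smtlib() for _, f in self.assumptions]
        return "(and " + " ".join(parts) + ")" if parts else "true"


def _constraint_formula(c: ConstraintSpec):
    if c.feature is None:
        return ExactlyOne(tuple(f"is_{cls}" for cls in CLASSES))
    atom = Atom(c.feature, c.comparator, Fraction(Decimal(exact_decimal(c.threshold))))
    if c.antecedent_class == "any":
        return atom
    return Implies(BoolLit(f"is_{c.antecedent_class}"), atom)


def encode_trace(trace: DecisionTrace, cs: ConstraintSet) -> FormulaSet:
    """Render the trace as background constants plus tracked rule assertions."""
    features = trace.features
    pred = trace.prediction
    literals = {}
    background = []
    for name in FEATURE_NAMES:
        value = getattr(features, name)
        text = exact_decimal(value)
        literals[name] = text
        background.append(Atom(name, "==", Fraction(Decimal(text))))
    background.append(BoolLit(f"is_{pred.class_label}"))
    assumptions = tuple((c.id, _constraint_formula(c)) for c in cs)
    return FormulaSet(
        feature_literals=literals,
        predicted_class=pred.class_label,
        background=tuple(background),
        assumptions=assumptions,
        constraint_version=cs.version,
    )


@dataclass
class VerificationResult:
    status: str  # "SAT" | "UNSAT" | "UNKNOWN"
    violated_ids: list = field(default_factory=list)
    per_constraint_truth: dict = field(default_factory=dict)
    certificate: str = ""
    solve_time: float = 0.0

    def as_dict(self) -> dict:
        return {
            "status": self.status,
            "violated_ids": list(self.violated_ids),
            "per_constraint_truth": dict(self.per_constraint_truth),
            "certificate": self.certificate,
            "solve_time": self.solve_time,
        }


def smt_check(fs: FormulaSet, timeout: float = 1.0) -> VerificationResult:
    """Run the solver channel on an encoded trace."""
    solver = LraSolver(timeout=timeout)
    outcome = solver.check(list(fs.background), list(fs.assumptions))
    if outcome.status == "sat":
        model_lines = [
            f"{var} = {val}" for var, val in sorted(outcome.model.items(), key=lambda kv: kv[0])
        ]
        return VerificationResult(
            "SAT", certificate="model:\n" + "\n".join(model_lines),
            solve_time=outcome.solve_time,
        )
    if outcome.status == "unsat":
        return VerificationResult(
            "UNSAT",
            violated_ids=list(outcome.core),
            certificate="unsat core: " + ", ".join(outcome.core),
            solve_time=outcome.solve_time,
        )
    return VerificationResult("UNKNOWN", certificate="solver timeout", solve_time=outcome.solve_time)


def dual_channel_verify(
    trace: DecisionTrace,
    cs: ConstraintSet,
    encoder: Callable = encode_trace,
    timeout: float = 1.0,
):
    """Verify through both channels; returns (VerificationResult, agreement).

    ``agreement`` is True when the solver verdict matches the direct
    Boolean evaluation (SAT iff every rule holds), False on mismatch, and
    None when the solver returned UNKNOWN.  Non-True agreement is logged
    and flagged for manual review.
    """
    result = smt_check(encoder(trace, cs), timeout=timeout)
    direct = {
        c.id: evaluate_predicate(c, trace.features, trace.prediction) for c in cs
    }
    result.per_constraint_truth = direct
    if result.status == "UNKNOWN":
        logger.warning("solver UNKNOWN on %s: flagged for manual review", trace.slice_id)
        return result, None
    agreement = (result.status == "SAT") == all(direct.values())
    if not agreement:
        logger.error(
            "dual-channel disagreement on %s (smt=%s, direct=%s): flagged for manual review",
            trace.slice_id, result.status, direct,
        )
    return result, agreement


# --- tamper-evident artifacts -------------------------------------------------


def _canonical(obj):
    """Convert to a JSON structure with exact-decimal floats."""
    if isinstance(obj, float):
        return exact_decimal(obj)
    if isinstance(obj, (np.floating,)):
        return exact_decimal(float(obj))
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, dict):
        return {str(k): _canonical(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_canonical(v) for v in obj]
    if isinstance(obj, SymbolicFeatures):
        return _canonical({**obj.as_dict(), "flags": list(obj.flags)})
    if isinstance(obj, Prediction):
        return _canonical({"class_label": obj.class_label, "softmax": list(obj.softmax)})
    if obj is None or isinstance(obj, (str, int, bool)):
        return obj
    raise TypeError(f"not canonically serializable: {type(obj)!r}")


def canonical_json(obj) -> str:
    return json.dumps(_canonical(obj), sort_keys=True, separators=(",", ":"), ensure_ascii=False)


@dataclass(frozen=True)
class FDTArtifact:
    payload: dict  # trace, formulas, result, metadata
    sha256: str

    def to_json(self) -> str:
        doc = dict(_canonical(self.payload))
        doc["sha256"] = self.sha256
        return json.dumps(doc, sort_keys=True, separators=(",", ":"), ensure_ascii=False)

    def verify(self) -> bool:
        return _digest(self.payload) == self.sha256

    @staticmethod
    def from_json(text: str) -> "FDTArtifact":
        doc = json.loads(text)
        digest = doc.pop("sha256")
        return FDTArtifact(payload=doc, sha256=digest)


def _digest(payload: dict) -> str:
    return hashlib.sha256(canonical_json(payload).encode("utf-8")).hexdigest()


def build_artifact(
    trace: DecisionTrace,
    fs: FormulaSet,
    result: VerificationResult,
    metadata: Optional[Mapping] = None,
    timestamp: Optional[str] = None,
) -> FDTArtifact:
    """Assemble and attest the complete record of one verified decision.

    ``timestamp`` defaults to the current UTC time; tests pass a frozen
    value so the digest is a stable regression fixture.  The timestamp is
    part of the hashed payload either way.
    """
    meta = {
        "timestamp": timestamp or datetime.now(timezone.utc).isoformat(),
        "model_id": trace.model_id,
        "slice_id": trace.slice_id,
        "constraint_version": fs.constraint_version,
    }
    meta.update(metadata or {})
    result_record = result.as_dict()
    result_record.pop("solve_time")  # wall-clock timing is operational, not evidential
    payload = {
        "trace": [
            {"kind": kind, **payload_} for kind, payload_ in trace.steps
        ],
        "formulas": {
            "per_assertion": {name: f.smtlib() for name, f in fs.assumptions},
            "background": [f.smtlib() for f in fs.background],
            "conjunction": fs.conjunction(),
            "smtlib": fs.smtlib(),
            "theory": fs.theory,
        },
        "result": result_record,
        "metadata": meta,
    }
    return FDTArtifact(payload=payload, sha256=_digest(payload))


def synthesize_traces(n: int, seed: int, cs: ConstraintSet) -> list:
    """Seeded batch of synthetic decision traces for verification exercises.

    Feature values are drawn uniformly over their ranges, but one draw in
    four lands deliberately at, just below, or just above a threshold of
    the constraint set, and predicted classes cycle so all four are
    always represented.  This spans exactly the cases where the two
    verification channels could plausibly diverge.
    """
    rng = np.random.default_rng(seed)
    thresholds = {}
    for c in cs:
        if c.feature is not None:
            thresholds.setdefault(c.feature, []).append(c.threshold)
    ranges = {
        "enhancement_variance": (0.0, 0.25),
        "sellar_band_overlap": (0.0, 1.0),
        "border_edge_density": (0.0, 1.0),
    }
    traces = []
    for i in range(n):
        label = CLASSES[i % len(CLASSES)]
        values = {}
        for name, (lo, hi) in ranges.items():
            if thresholds.get(name) and rng.uniform() < 0.25:
                t = float(rng.choice(thresholds[name]))
                values[name] = float(
                    rng.choice([t, np.nextafter(t, -np.inf), np.nextafter(t, np.inf)])
                )
            else:
                values[name] = float(rng.uniform(lo, hi))
        features = SymbolicFeatures(
            enhancement_variance=values["enhancement_variance"],
            sellar_band_overlap=values["sellar_band_overlap"],
            border_edge_density=values["border_edge_density"],
            mask_area=int(rng.integers(1, 500)),
        )
        conf = float(rng.uniform(0.3, 0.99))
        rest = (1.0 - conf) / (len(CLASSES) - 1)
        softmax = tuple(conf if c == label else rest for c in CLASSES)
        pred = Prediction(label, softmax)
        traces.append(build_trace(f"synthetic_{i:05d}", features, pred, "trace-synth"))
    return traces


# --- batch auditing -----------------------------------------------------------


def audit_batch(
    manifest: Sequence[Mapping],
    predictor,
    cs: ConstraintSet,
    image_root=None,
    out_dir=None,
    timestamp: Optional[str] = None,
) -> dict:
    """Audit a batch of slices end to end.

    ``manifest`` rows need a ``path`` (image file) or an ``image`` array,
    plus optionally a ground-truth ``label``.  Each slice is preprocessed,
    classified by ``predictor`` (a callable PreprocessedSlice -> Prediction
    with a ``model_id``), feature-extracted, verified through both
    channels, and packaged as an artifact.  Missing images are skipped
    with a log entry.

    Returns a report with percentage rates for the audit categories
    (SAT, UNSAT, UNSAT with correct/incorrect label, dual-channel
    agreement) and the per-slice artifacts.
    """
    from .io import load_slice
    from .preprocessing import preprocess_eval

    input_size = getattr(predictor, "input_size", 224)
    model_id = getattr(predictor, "model_id", "unknown")
    artifacts, rows = [], []
    n = n_sat = n_unsat = n_unsat_correct = n_unsat_wrong = n_agree = 0
    for i, row in enumerate(manifest):
        if "image" in row:
            img = np.asarray(row["image"], dtype=float)
            slice_id = str(row.get("slice_id", f"slice_{i:05d}"))
        else:
            path = Path(image_root or ".") / row["path"]
            if not path.exists():
                logger.warning("missing image %s: skipped", path)
                continue
            img = load_slice(path)
            slice_id = path.stem
        features = extract_all(img)
        pred = predictor(preprocess_eval(img, size=input_size, source_id=slice_id))
        trace = build_trace(slice_id, features, pred, model_id)
        fs = encode_trace(trace, cs)
        result, agreement = dual_channel_verify(trace, cs)
        artifacts.append(build_artifact(trace, fs, result, timestamp=timestamp))
        n += 1
        truth = row.get("label")
        if result.status == "SAT":
            n_sat += 1
        elif result.status == "UNSAT":
            n_unsat += 1
            if truth is not None:
                if pred.class_label == truth:
                    n_unsat_correct += 1
                else:
                    n_unsat_wrong += 1
        if agreement:
            n_agree += 1
        rows.append(
            {
                "slice_id": slice_id, "predicted": pred.class_label,
                "label": truth, "status": result.status,
                "violated": ";".join(result.violated_ids),
                "agreement": agreement,
            }
        )
    pct = lambda k: 100.0 * k / n if n else 0.0  # noqa: E731
    report = {
        "n_slices": n,
        "sat_pct": pct(n_sat),
        "unsat_pct": pct(n_unsat),
        "unsat_correct_label_pct": pct(n_unsat_correct),
        "unsat_incorrect_label_pct": pct(n_unsat_wrong),
        "dual_channel_agreement_pct": pct(n_agree),
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        (out_dir / "artifacts").mkdir(parents=True, exist_ok=True)
        for art in artifacts:
            sid = art.payload["metadata"]["slice_id"]
            (out_dir / "artifacts" / f"{sid}.fdt.json").write_text(art.to_json())
        Path(out_dir / "audit_report.json").write_text(json.dumps(report, indent=2))
        import csv as _csv

        with open(out_dir / "audit_summary.csv", "w", newline="") as fh:
            writer = _csv.DictWriter(fh, fieldnames=list(rows[0]) if rows else ["slice_id"])
            writer.writeheader()
            writer.writerows(rows)
    report["artifacts"] = artifacts
    report["rows"] = rows
    return report
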