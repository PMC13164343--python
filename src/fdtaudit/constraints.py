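"""Neuroradiologic consistency constraints over symbolic slice features.

Each rule is a guarded threshold test: *if* the classifier predicted a
given class, *then* a hand-crafted radiologic surrogate computed from the
raw slice must clear a threshold.  The default set encodes:

* C1 — glioma implies heterogeneous enhancement: the normalized intensity
  variance inside the Otsu-segmented region must exceed 0.1.
* C2 — pituitary tumor implies sellar proximity: the segmented mass must
  overlap the central 20% band of the y-axis by more than 0.5.
* C3 — meningioma implies a dural-contact proxy: Canny edge density in the
  slice-border band must exceed a configurable threshold (default 0.05;
  no canonical value exists, so it is a required configuration knob).
* C4 — a consistency invariant barring a glioma call without heterogeneous
  enhancement (the same predicate as C1, tracked separately so unsat cores
  can distinguish the two rules).
* PRED — structural invariant that exactly one class is predicted.

Rules are evaluated both directly (material implication in plain Python,
:func:`evaluate_predicate`) and through the SMT channel; the two paths are
deliberately independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional, Sequence

import yaml

CLASSES = ("glioma", "meningioma", "pituitary", "no_tumor")
FEATURE_NAMES = (
    "enhancement_variance",
    "sellar_band_overlap",
    "border_edge_density",
)

_COMPARATORS = (">", ">=", "<", "<=")


class ConfigError(ValueError):
    """A constraint configuration is missing or malformed."""


@dataclass(frozen=True)
class ConstraintSpec:
    """One guarded threshold rule.

    ``feature is None`` marks the structural one-hot prediction invariant,
    which has no feature predicate.
    """

    id: str
    antecedent_class: str  # one of CLASSES or "any"
    feature: Optional[str]
    comparator: str
    threshold: float
    description: str = ""

    def __post_init__(self) -> None:
        if self.antecedent_class != "any" and self.antecedent_class not in CLASSES:
            raise ConfigError(f"unknown class {self.antecedent_class!r}")
        if self.feature is not None:
            if self.feature not in FEATURE_NAMES:
                raise ConfigError(f"unknown feature {self.feature!r}")
            if self.comparator not in _COMPARATORS:
                raise ConfigError(f"unknown comparator {self.comparator!r}")
            if not (self.threshold == self.threshold and abs(self.threshold) < 1e30):
                raise ConfigError("threshold must be finite")


@dataclass(frozen=True)
class ConstraintSet:
    constraints: tuple
    version: str = "default-1"
    theory: str = "QF_LRA"

    def __post_init__(self) -> None:
        ids = [c.id for c in self.constraints]
        if len(ids) != len(set(ids)):
            raise ConfigError("constraint ids must be unique")

    def __iter__(self):
        return iter(self.constraints)

    def __len__(self) -> int:
        return len(self.constraints)

    def get(self, cid: str) -> ConstraintSpec:
        for c in self.constraints:
            if c.id == cid:
                return c
        raise KeyError(cid)

    def to_yaml(self) -> str:
        doc = {
            "version": self.version,
            "theory": self.theory,
            "constraints": [asdict(c) for c in self.constraints],
        }
        return yaml.safe_dump(doc, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ConstraintSet":
        doc = yaml.safe_load(text)
        if not isinstance(doc, dict) or "version" not in doc:
            raise ConfigError("constraint YAML must carry a version tag")
        specs = tuple(ConstraintSpec(**c) for c in doc.get("constraints", ()))
        return cls(specs, version=str(doc["version"]), theory=doc.get("theory", "QF_LRA"))


DEFAULT_THRESHOLDS = {
    "c1_variance": 0.1,
    "c2_overlap": 0.5,
    "c3_edge_density": 0.05,
}


def default_constraints(config: Optional[Mapping[str, float]] = None) -> ConstraintSet:
    """Build the default rule set, honouring threshold overrides.

    When ``config`` is given explicitly it must supply ``c3_edge_density``:
    that threshold has no canonical value and a configuration claiming to
    be complete without it is rejected.
    """
    if config is None:
        cfg = dict(DEFAULT_THRESHOLDS)
    else:
        cfg = {**{k: v for k, v in DEFAULT_THRESHOLDS.items() if k != "c3_edge_density"}, **config}
        if "c3_edge_density" not in cfg:
            raise ConfigError("config must provide c3_edge_density (no canonical value)")
    specs = (
        ConstraintSpec(
            "C1", "glioma", "enhancement_variance", ">", float(cfg["c1_variance"]),
            "glioma implies heterogeneous enhancement (in-mask intensity variance)",
        ),
        ConstraintSpec(
            "C2", "pituitary", "sellar_band_overlap", ">", float(cfg["c2_overlap"]),
            "pituitary implies sellar proximity (central y-band overlap)",
        ),
        ConstraintSpec(
            "C3", "meningioma", "border_edge_density", ">", float(cfg["c3_edge_density"]),
            "meningioma implies dural-contact proxy (border-band edge density)",
        ),
        ConstraintSpec(
            "C4", "glioma", "enhancement_variance", ">", float(cfg["c1_variance"]),
            "consistency invariant: no glioma call without heterogeneous enhancement",
        ),
        ConstraintSpec(
            "PRED", "any", None, ">", 0.0,
            "structural invariant: exactly one class is predicted",
        ),
    )
    return ConstraintSet(specs)


def evaluate_predicate(constraint: ConstraintSpec, features, prediction) -> bool:
    """Direct (non-SMT) evaluation of one rule as a material implication.

    True when the antecedent class differs from the prediction, or when the
    feature predicate holds.  This is the independent channel used to
    cross-check the solver; it shares no code with the SMT path.
    """
    if constraint.feature is None:
        return prediction.class_label in CLASSES  # one-hot is enforced at construction
    if constraint.antecedent_class != "any" and (
        prediction.class_label != constraint.antecedent_class
    ):
        return True
    value = getattr(features, constraint.feature, None)
    if value is None:
        raise KeyError(f"feature {constraint.feature!r} missing")
    value = float(value)
    t = constraint.threshold
    if constraint.comparator == ">":
        return value > t
    if constraint.comparator == ">=":
        return value >= t
    if constraint.comparator == "<":
        return value < t
    return value <= t
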