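"""Decision procedure for a guarded-threshold fragment of QF_LRA.

The verification layer encodes every audited decision as a conjunction of

* real-valued constants (``x = v``, the extracted symbolic features),
* Boolean class selectors with an exactly-one side condition, and
* tracked implications ``class_selector => (feature <op> threshold)``.

This module decides satisfiability of such formula sets exactly, using
rational (:class:`fractions.Fraction`) arithmetic throughout, and reports
an unsatisfiable core over the named (tracked) assertions.  The procedure
enumerates Boolean assignments (there are at most a handful of selectors)
and checks the induced conjunction of univariate linear atoms by interval
intersection, which is sound and complete for this fragment.  Cores are
minimised by deletion and are therefore minimal for conjunctive conflicts,
although minimality is not part of the contract.

Certificates: a satisfying assignment (model) for SAT, the named core for
UNSAT.  A wall-clock timeout yields UNKNOWN, which callers treat as an
environment fault to be flagged for manual review.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from fractions import Fraction
from itertools import product
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "Atom",
    "BoolLit",
    "And",
    "ExactlyOne",
    "Implies",
    "Formula",
    "LraSolver",
    "SolverOutcome",
]

_COMPARATORS = {">", ">=", "<", "<=", "=="}


@dataclass(frozen=True)
class Atom:
    """Univariate linear atom ``var <cmp> rhs`` over the reals."""

    var: str
    cmp: str
    rhs: Fraction

    def __post_init__(self) -> None:
        if self.cmp not in _COMPARATORS:
            raise ValueError(f"unknown comparator {self.cmp!r}")
        object.__setattr__(self, "rhs", Fraction(self.rhs))

    def holds(self, value: Fraction) -> bool:
        v = Fraction(value)
        if self.cmp == ">":
            return v > self.rhs
        if self.cmp == ">=":
            return v >= self.rhs
        if self.cmp == "<":
            return v < self.rhs
        if self.cmp == "<=":
            return v <= self.rhs
        return v == self.rhs

    def smtlib(self) -> str:
        op = {"==": "="}.get(self.cmp, self.cmp)
        rhs = _render_fraction(self.rhs)
        return f"({op} {self.var} {rhs})"


@dataclass(frozen=True)
class BoolLit:
    """A Boolean variable or its negation."""

    var: str
    negated: bool = False

    def holds(self, assignment: Mapping[str, bool]) -> bool:
        return assignment[self.var] != self.negated

    def smtlib(self) -> str:
        return f"(not {self.var})" if self.negated else self.var


@dataclass(frozen=True)
class And:
    parts: tuple

    def smtlib(self) -> str:
        if not self.parts:
            return "true"
        inner = " ".join(p.smtlib() for p in self.parts)
        return f"(and {inner})"


@dataclass(frozen=True)
class ExactlyOne:
    vars: tuple

    def smtlib(self) -> str:
        at_least = "(or " + " ".join(self.vars) + ")"
        pairs = [
            f"(not (and {a} {b}))"
            for i, a in enumerate(self.vars)
            for b in self.vars[i + 1 :]
        ]
        return "(and " + " ".join([at_least] + pairs) + ")"


@dataclass(frozen=True)
class Implies:
    antecedent: BoolLit
    consequent: object  # Atom | And of Atoms

    def smtlib(self) -> str:
        return f"(=> {self.antecedent.smtlib()} {self.consequent.smtlib()})"


Formula = object  # union of the node types above


def _render_fraction(q: Fraction) -> str:
    if q.denominator == 1:
        s = f"{q.numerator}.0"
    else:
        s = f"(/ {q.numerator}.0 {q.denominator}.0)"
    if q < 0:
        return f"(- {_render_fraction(-q)})" if q.denominator != 1 else s
    return s


def _bool_vars_of(formula: Formula) -> set:
    if isinstance(formula, BoolLit):
        return {formula.var}
    if isinstance(formula, And):
        out: set = set()
        for p in formula.parts:
            out |= _bool_vars_of(p)
        return out
    if isinstance(formula, ExactlyOne):
        return set(formula.vars)
    if isinstance(formula, Implies):
        return {formula.antecedent.var} | _bool_vars_of(formula.consequent)
    return set()


def _reduce(formula: Formula, assignment: Mapping[str, bool]):
    """Reduce under a Boolean assignment to (boolean_ok, required_atoms)."""
    if isinstance(formula, Atom):
        return True, [formula]
    if isinstance(formula, BoolLit):
        return formula.holds(assignment), []
    if isinstance(formula, And):
        atoms: list = []
        for p in formula.parts:
            ok, a = _reduce(p, assignment)
            if not ok:
                return False, []
            atoms.extend(a)
        return True, atoms
    if isinstance(formula, ExactlyOne):
        return sum(assignment[v] for v in formula.vars) == 1, []
    if isinstance(formula, Implies):
        if not formula.antecedent.holds(assignment):
            return True, []
        return _reduce(formula.consequent, assignment)
    raise TypeError(f"unsupported formula node {formula!r}")


class _Box:
    """Per-variable interval with exact rational, open/closed bounds."""

    def __init__(self) -> None:
        self.lo: Optional[Fraction] = None
        self.lo_strict = False
        self.hi: Optional[Fraction] = None
        self.hi_strict = False

    def add(self, atom: Atom) -> bool:
        if atom.cmp in (">", ">="):
            strict = atom.cmp == ">"
            if self.lo is None or atom.rhs > self.lo or (
                atom.rhs == self.lo and strict and not self.lo_strict
            ):
                self.lo, self.lo_strict = atom.rhs, strict
        elif atom.cmp in ("<", "<="):
            strict = atom.cmp == "<"
            if self.hi is None or atom.rhs < self.hi or (
                atom.rhs == self.hi and strict and not self.hi_strict
            ):
                self.hi, self.hi_strict = atom.rhs, strict
        else:  # equality: a point interval
            if (self.lo is None or atom.rhs >= self.lo) and not (
                self.lo is not None and atom.rhs == self.lo and self.lo_strict
            ):
                self.lo, self.lo_strict = atom.rhs, False
            else:
                return False
            if (self.hi is None or atom.rhs <= self.hi) and not (
                self.hi is not None and atom.rhs == self.hi and self.hi_strict
            ):
                self.hi, self.hi_strict = atom.rhs, False
            else:
                return False
        return self.feasible()

    def feasible(self) -> bool:
        if self.lo is None or self.hi is None:
            return True
        if self.lo < self.hi:
            return True
        if self.lo == self.hi:
            return not (self.lo_strict or self.hi_strict)
        return False

    def witness(self) -> Fraction:
        if self.lo is not None and self.hi is not None:
            if self.lo == self.hi:
                return self.lo
            return (self.lo + self.hi) / 2
        if self.lo is not None:
            return self.lo + 1 if self.lo_strict else self.lo
        if self.hi is not None:
            return self.hi - 1 if self.hi_strict else self.hi
        return Fraction(0)


def _theory_feasible(atoms: Iterable[Atom]):
    boxes: dict = {}
    for atom in atoms:
        box = boxes.setdefault(atom.var, _Box())
        if not box.add(atom):
            return False, {}
    return True, {v: b.witness() for v, b in boxes.items()}


@dataclass
class SolverOutcome:
    status: str  # "sat" | "unsat" | "unknown"
    core: list = field(default_factory=list)
    model: dict = field(default_factory=dict)
    solve_time: float = 0.0


class LraSolver:
    """Check a formula set with named-assumption tracking.

    Background assertions are not tracked and never appear in cores;
    assumptions are (name, formula) pairs, matching SMT-LIB
    ``(assert (! phi :named name))`` semantics.
    """

    def __init__(self, timeout: float = 1.0) -> None:
        self.timeout = timeout

    def check(
        self,
        background: Sequence[Formula],
        assumptions: Sequence[tuple],
    ) -> SolverOutcome:
        start = time.monotonic()
        bool_vars = sorted(
            set().union(
                *(_bool_vars_of(f) for f in background),
                *(_bool_vars_of(f) for _, f in assumptions),
                set(),
            )
        )
        best_core: Optional[list] = None
        for values in product((False, True), repeat=len(bool_vars)):
            if time.monotonic() - start > self.timeout:
                return SolverOutcome("unknown", solve_time=time.monotonic() - start)
            assignment = dict(zip(bool_vars, values))
            bg_atoms: list = []
            ok = True
            for f in background:
                f_ok, atoms = _reduce(f, assignment)
                if not f_ok:
                    ok = False
                    break
                bg_atoms.extend(atoms)
            if not ok:
                continue
            feasible, _ = _theory_feasible(bg_atoms)
            if not feasible:
                continue  # background itself inconsistent on this branch
            all_atoms = list(bg_atoms)
            failed_names: list = []
            for name, f in assumptions:
                f_ok, atoms = _reduce(f, assignment)
                if not f_ok:
                    failed_names.append(name)
                    continue
                all_atoms.extend(atoms)
            feasible, witness = _theory_feasible(all_atoms)
            if feasible and not failed_names:
                model = dict(assignment)
                model.update(witness)
                return SolverOutcome(
                    "sat", model=model, solve_time=time.monotonic() - start
                )
            core = self._core(assignment, bg_atoms, assumptions)
            if best_core is None or len(core) < len(best_core):
                best_core = core
        if best_core is None:
            # No Boolean branch satisfied even the background: the background
            # itself is inconsistent, which the encoder never produces.
            raise ValueError("background assertions are unsatisfiable")
        return SolverOutcome(
            "unsat", core=best_core, solve_time=time.monotonic() - start
        )

    @staticmethod
    def _core(assignment, bg_atoms, assumptions):
        """Core = every individually-violated named assumption.

        Identification, not minimality: an assumption enters the core when
        it conflicts with the background on its own (or its Boolean part
        fails), so duplicated rules are each named.  If no individual
        conflict exists (mutually conflicting assumptions), fall back to a
        deletion-based core.
        """
        violated = []
        for name, f in assumptions:
            f_ok, atoms = _reduce(f, assignment)
            if not f_ok:
                violated.append(name)
                continue
            feasible, _ = _theory_feasible(list(bg_atoms) + atoms)
            if not feasible:
                violated.append(name)
        if violated:
            remainder_atoms = list(bg_atoms)
            remainder_ok = True
            for name, f in assumptions:
                if name in violated:
                    continue
                f_ok, atoms = _reduce(f, assignment)
                remainder_ok = remainder_ok and f_ok
                remainder_atoms.extend(atoms)
            if remainder_ok and _theory_feasible(remainder_atoms)[0]:
                return violated
        # mutual conflict: shrink by deletion
        keep = list(assumptions)
        for name, _f in assumptions:
            trial = [(n, g) for n, g in keep if n != name]
            atoms = list(bg_atoms)
            sat = True
            for _n, g in trial:
                g_ok, a = _reduce(g, assignment)
                if not g_ok:
                    sat = False
                    break
                atoms.extend(a)
            if sat:
                sat, _ = _theory_feasible(atoms)
            if not sat:
                keep = trial  # still unsat without it: not needed
        return [n for n, _ in keep]
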