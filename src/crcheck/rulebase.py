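"""Declarative validation rules and their compilation to axioms.

Each ENCR-style validation rule is one of three scenarios:

* ``HARD_DISJOINT`` - an impossible combination; compiles to a
  DisjointClasses axiom (the offending conjunction is an empty class) and
  yields an ERROR.
* ``SOFT_RESTRICTION`` - an unlikely combination; compiles to a SubClassOf
  axiom with WARNING severity (the antecedent inherits a restriction which
  the validator checks against the asserted values).
* ``DEFINED_CODE`` - necessary-and-sufficient conditions for an assigned
  code; compiles to an EquivalentClass (defined class) axiom and registers
  a confirmation guard on the coded field. A guarded code that no defined
  class confirms is reported UNCONFIRMED.

The rule file is the single source of truth; the TBox is always derived
from it, so the rule base and the data model cannot drift apart.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import yaml

from .dl_engine import Axiom, ClassExpression, Interval, TBox
from .terminology import Terminology, expand_topography_range


class RuleError(ValueError):
    pass


SCENARIOS = {"HARD_DISJOINT", "SOFT_RESTRICTION", "DEFINED_CODE"}

#: concept kind used for confirmation classes registered per guarded field
_GUARD_KINDS = {
    "bod": "bod_code", "grade": "grade_code", "morphology": "morphology_code",
    "topography": "topography_code", "vital_status": "vital_status_code",
    "extent": "extent_code", "sex": "sex_code", "behaviour": "behaviour_code",
}

#: record attribute name -> record field (used by the validator)
ATTRIBUTES = ("sex", "topography", "morphology", "behaviour", "grade", "bod",
              "extent", "vital_status", "t", "n", "m", "age")

_T_CATEGORIES = frozenset(
    "TX T0 TIS TA T1 T1A T1B T2 T2A T2B T3 T3A T3B T4 T4A T4B".split())
_N_CATEGORIES = frozenset("NX N0 N1 N2 N3".split())
_M_CATEGORIES = frozenset("MX M0 M1".split())


def attribute_domains() -> dict:
    """Closed-world value domains for every record attribute.

    Topography and morphology cover all format-valid ICD-O-3 codes; the
    remaining domains mirror the shipped dictionary's code lists.
    """
    return {
        "sex": frozenset("1239"),
        "behaviour": frozenset("0123"),
        "grade": frozenset("123456789"),
        "bod": frozenset("01245679"),
        "extent": frozenset("1239"),
        "vital_status": frozenset("1239"),
        "topography": frozenset(f"C{i:03d}" for i in range(0, 810)),
        "morphology": frozenset(str(i) for i in range(8000, 9990)),
        "t": _T_CATEGORIES,
        "n": _N_CATEGORIES,
        "m": _M_CATEGORIES,
        "age": Interval(0, None),
    }


@dataclass(frozen=True)
class ValidationRule:
    id: str
    scenario: str
    subject: str = ""
    when: ClassExpression = ClassExpression()
    implies: ClassExpression | None = None
    defines: str | None = None
    definition: ClassExpression | None = None
    guard_field: str | None = None
    guard_codes: tuple[str, ...] = ()
    message: str = ""
    provenance: str = ""
    severity_note: str = ""


@dataclass(frozen=True)
class RuleSet:
    rules: tuple[ValidationRule, ...]
    version: str = ""

    def __post_init__(self):
        ids = [r.id for r in self.rules]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise RuleError(f"duplicate rule ids: {dupes}")

    def rule(self, rule_id: str) -> ValidationRule:
        for r in self.rules:
            if r.id == rule_id:
                return r
        raise KeyError(rule_id)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.rules]


# ---------------------------------------------------------------------------
# expression parsing

def _expand_codes(attr: str, values: Iterable, domain, rule_id: str) -> frozenset:
    out: set[str] = set()
    for v in values:
        v = str(v).strip()
        if attr == "topography" and ("-" in v or len(v) == 3):
            out.update(expand_topography_range(v))
        elif attr == "morphology" and "-" in v:
            lo, hi = v.split("-")
            out.update(str(x) for x in range(int(lo), int(hi) + 1))
        else:
            out.add(v.upper() if attr in {"t", "n", "m"} else v)
    bad = sorted(out - domain)
    if bad:
        raise RuleError(f"rule {rule_id!r}: codes {bad} outside the {attr} domain")
    return frozenset(out)


def parse_expression(node: Mapping, rule_id: str, domains: Mapping) -> ClassExpression:
    """YAML expression fragment -> ClassExpression (code ranges expanded)."""
    atoms = [str(a) for a in node.get("atoms", [])]
    in_sets: dict[str, frozenset] = {}
    not_in: dict[str, frozenset] = {}
    ranges: dict[str, Interval] = {}
    for attr, spec in node.items():
        if attr == "atoms":
            continue
        if attr not in domains:
            raise RuleError(f"rule {rule_id!r}: unknown field {attr!r}")
        dom = domains[attr]
        if isinstance(dom, Interval):
            if not isinstance(spec, Mapping) or not {"min", "max"} & set(spec):
                raise RuleError(f"rule {rule_id!r}: {attr} needs min/max bounds")
            ranges[attr] = Interval(spec.get("min"), spec.get("max"))
            continue
        if not isinstance(spec, Mapping):
            raise RuleError(f"rule {rule_id!r}: field {attr!r} needs in/not_in")
        if "in" in spec:
            in_sets[attr] = _expand_codes(attr, spec["in"], dom, rule_id)
        if "not_in" in spec:
            not_in[attr] = _expand_codes(attr, spec["not_in"], dom, rule_id)
        extra = set(spec) - {"in", "not_in"}
        if extra:
            raise RuleError(f"rule {rule_id!r}: unknown restriction {sorted(extra)}")
    return ClassExpression.build(atoms, in_sets, not_in, ranges)


def _expression_to_node(expr: ClassExpression) -> dict:
    node: dict = {}
    if expr.atoms:
        node["atoms"] = sorted(expr.atoms)
    for attr, s in expr.in_sets.items():
        node.setdefault(attr, {})["in"] = sorted(s)
    for attr, s in expr.not_in_sets.items():
        node.setdefault(attr, {})["not_in"] = sorted(s)
    for attr, iv in expr.ranges.items():
        node[attr] = {}
        if iv.lo is not None:
            node[attr]["min"] = iv.lo
        if iv.hi is not None:
            node[attr]["max"] = iv.hi
    return node


# ---------------------------------------------------------------------------
# loading

def load_rules(source: str | Path) -> RuleSet:
    """Parse the rule file; provenance and severity notes are preserved."""
    with open(source, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return RuleSet((), version="")
    domains = attribute_domains()
    rules: list[ValidationRule] = []
    for node in data.get("rules", []):
        rid = str(node.get("id", ""))
        if not rid:
            raise RuleError(f"rule entry without id: {node!r}")
        scenario = node.get("scenario")
        if scenario not in SCENARIOS:
            raise RuleError(f"rule {rid!r}: unknown scenario {scenario!r}")
        when = parse_expression(node.get("when", {}), rid, domains)
        implies = defines = definition = None
        guard_field, guard_codes = None, ()
        if scenario == "SOFT_RESTRICTION":
            if "implies" not in node:
                raise RuleError(f"rule {rid!r}: SOFT_RESTRICTION needs 'implies'")
            implies = parse_expression(node["implies"], rid, domains)
        elif scenario == "HARD_DISJOINT":
            if when.is_trivial:
                raise RuleError(f"rule {rid!r}: HARD_DISJOINT needs a 'when' conjunction")
        else:  # DEFINED_CODE
            defines = node.get("defines")
            if not defines or "definition" not in node:
                raise RuleError(f"rule {rid!r}: DEFINED_CODE needs defines/definition")
            definition = parse_expression(node["definition"], rid, domains)
            guard = node.get("guard", {})
            guard_field = guard.get("field")
            if guard_field is not None and guard_field not in domains:
                raise RuleError(f"rule {rid!r}: unknown guard field {guard_field!r}")
            guard_codes = tuple(str(c) for c in guard.get("codes", []))
        rules.append(ValidationRule(
            id=rid, scenario=scenario, subject=str(node.get("subject", "")),
            when=when, implies=implies, defines=defines, definition=definition,
            guard_field=guard_field, guard_codes=guard_codes,
            message=str(node.get("message", "")),
            provenance=str(node.get("provenance", "")),
            severity_note=str(node.get("severity_note", ""))))
    return RuleSet(tuple(rules), version=str(data.get("version", "")))


# ---------------------------------------------------------------------------
# compilation

def compile_rules(ruleset: RuleSet, terminology: Terminology) -> TBox:
    """One axiom per rule, ids preserved; defined classes are registered as
    confirmation concepts on their guarded field."""
    domains = attribute_domains()
    axioms: list[Axiom] = []
    for rule in ruleset.rules:
        for expr in (rule.when, rule.implies, rule.definition):
            if expr is None:
                continue
            for atom in expr.atoms:
                if not terminology.has_concept(atom):
                    raise RuleError(
                        f"rule {rule.id!r}: dangling concept reference {atom!r}")
        common = dict(scenario=rule.scenario, message=rule.message,
                      provenance=rule.provenance)
        if rule.scenario == "HARD_DISJOINT":
            axioms.append(Axiom(id=rule.id, form="disjoint",
                                members=(rule.when,), severity="ERROR", **common))
        elif rule.scenario == "SOFT_RESTRICTION":
            axioms.append(Axiom(id=rule.id, form="subclass", sub=rule.when,
                                sup=rule.implies, severity="WARNING", **common))
        else:
            kind = _GUARD_KINDS.get(rule.guard_field or "", "record_class")
            terminology.ensure_concept(rule.defines, kind=kind)
            axioms.append(Axiom(id=rule.id, form="equivalent",
                                defined=rule.defines, definition=rule.definition,
                                severity="ERROR",
                                guard_field=rule.guard_field,
                                guard_codes=rule.guard_codes, **common))
    return TBox(axioms, terminology, domains)


def decompile(tbox: TBox) -> RuleSet:
    """Inverse of compile_rules (loss-free up to rule ordering)."""
    rules = []
    for ax in tbox.axioms:
        if ax.form == "disjoint":
            rules.append(ValidationRule(
                id=ax.id, scenario="HARD_DISJOINT", when=ax.members[0],
                message=ax.message, provenance=ax.provenance))
        elif ax.form == "subclass":
            rules.append(ValidationRule(
                id=ax.id, scenario="SOFT_RESTRICTION", when=ax.sub,
                implies=ax.sup, message=ax.message, provenance=ax.provenance))
        else:
            rules.append(ValidationRule(
                id=ax.id, scenario="DEFINED_CODE", defines=ax.defined,
                definition=ax.definition, guard_field=ax.guard_field,
                guard_codes=ax.guard_codes, message=ax.message,
                provenance=ax.provenance))
    return RuleSet(tuple(rules))
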