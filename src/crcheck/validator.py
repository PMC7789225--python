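"""Single-record validation.

A parsed record is translated into a conjunctive class expression - one
singleton value restriction per populated coded field, a point interval for
age, plus the named classes the terminology resolves for it (morphology
code, topography code, morphology-behaviour, tumour type, TNM topography
grouping). The engine then maps outcomes to findings:

* hard inconsistency -> one ERROR per minimal explanation;
* an inherited soft restriction contradicted by an asserted value -> WARNING;
* a guarded code that no defined class confirms -> UNCONFIRMED;
* confirmed codes and terminological inferences (tumour type,
  morphology-behaviour group, stage group, completeness) are reported.

Calendar consistency (date ordering, age vs dates, survival duration) is a
separate check outside the terminological engine.
"""
from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from typing import Iterable

from .core_dictionary import CancerCaseRecord, Dictionary, PartialDate
from .dl_engine import (ClassExpression, Interval, TBox, classify,
                        is_inconsistent, minimal_explanations, most_specific,
                        subsumes)
from .findings import Finding, Severity, sort_findings
from .terminology import StageGroup, Terminology

#: record field backing each DL attribute
ATTRIBUTE_FIELDS = {
    "sex": "sex", "topography": "topography", "morphology": "morphology",
    "behaviour": "behaviour", "grade": "grade", "bod": "basis_of_diagnosis",
    "extent": "extent_of_disease", "vital_status": "vital_status",
    "t": "tnm_t", "n": "tnm_n", "m": "tnm_m",
}

COMPLETENESS_CLASS = "CaseTypeComplete"


@dataclass(frozen=True)
class ValidationReport:
    record_ref: tuple[str, str]
    findings: tuple[Finding, ...]
    record_status: str  # VALID | VALID_WITH_WARNINGS | INVALID
    confirmed_codes: tuple[tuple[str, str], ...] = ()  # field -> class id
    inferences: tuple[tuple[str, str], ...] = ()       # kind -> concept/stage

    def confirmed(self, field_name: str) -> str | None:
        return dict(self.confirmed_codes).get(field_name)

    def inference(self, kind: str) -> str | None:
        return dict(self.inferences).get(kind)

    @property
    def errors(self) -> list[Finding]:
        return [f for f in self.findings if f.severity == Severity.ERROR]

    @property
    def warnings(self) -> list[Finding]:
        return [f for f in self.findings if f.severity == Severity.WARNING]

    @property
    def unconfirmed(self) -> list[Finding]:
        return [f for f in self.findings if f.severity == Severity.UNCONFIRMED]


def record_to_expression(rec: CancerCaseRecord, term: Terminology) -> ClassExpression:
    """The record's class: singleton restrictions plus resolved memberships."""
    in_sets: dict[str, frozenset] = {}
    for attr, fname in ATTRIBUTE_FIELDS.items():
        value = getattr(rec, fname)
        if value is not None:
            in_sets[attr] = frozenset([str(value)])
    ranges = {}
    if rec.age_at_diagnosis is not None:
        ranges["age"] = Interval(rec.age_at_diagnosis, rec.age_at_diagnosis)
    atoms: set[str] = set()
    if rec.topography and term.has_concept(rec.topography):
        atoms.add(rec.topography)
    if rec.morphology and term.has_concept(rec.morphology):
        atoms.add(rec.morphology)
    if rec.morphology and rec.behaviour:
        mb = term.morph_behaviour(rec.morphology, rec.behaviour)
        if mb:
            atoms.add(mb)
        if rec.topography:
            tt = term.tumour_type(rec.topography, rec.morphology, rec.behaviour)
            if tt:
                atoms.add(tt)
    if rec.topography:
        grouping = term.tnm_grouping_for(rec.topography)
        if grouping:
            atoms.add(grouping)
    return ClassExpression.build(atoms, in_sets, ranges=ranges)


def _asserted_contradicts(expr: ClassExpression, restriction: ClassExpression,
                          tbox: TBox) -> list[str]:
    """Attributes whose asserted value set is disjoint from the restriction.

    Only asserted restrictions count - never values inferred through other
    rules - so that every warning is explainable from the input record.
    """
    out = []
    for attr in restriction.restricted_attrs:
        dom = tbox.domain(attr)
        want = restriction.allowed_for(attr, dom)
        have = expr.allowed_for(attr, dom)
        if attr not in expr.restricted_attrs:
            continue  # value not asserted: nothing to contradict
        if isinstance(have, Interval):
            if have.intersect(want).is_empty:
                out.append(attr)
        elif not (have & want):
            out.append(attr)
    return out


def _atom_condition_met(condition: ClassExpression, expr: ClassExpression,
                        tbox: TBox) -> bool:
    return subsumes(condition, expr, tbox)


def validate_record(rec: CancerCaseRecord, tbox: TBox, *,
                    dictionary: Dictionary | None = None,
                    escalate_unconfirmed: bool = False) -> ValidationReport:
    """Run the three validation scenarios on one parsed record."""
    term = tbox.terminology
    ref = (rec.patient_id, rec.tumour_id)
    expr = record_to_expression(rec, term)
    findings: list[Finding] = []

    inconsistent, _ = is_inconsistent(expr, tbox)
    if inconsistent:
        for explanation in minimal_explanations(expr, tbox):
            fields = _fields_of_axioms(explanation, tbox)
            msg = "; ".join(_axiom_message(a, tbox) for a in explanation) \
                or "record constraints are unsatisfiable"
            rule_id = explanation[0] if explanation else "unsatisfiable"
            findings.append(Finding(ref, Severity.ERROR, rule_id, fields, msg,
                                    tuple(explanation)))
        return _finish(ref, findings, (), (), escalate_unconfirmed)

    # scenario (ii): inherited soft restrictions vs asserted values
    for ax in tbox.soft_axioms:
        if not _atom_condition_met(ax.sub, expr, tbox):
            continue
        contradicted = _asserted_contradicts(expr, ax.sup, tbox)
        if contradicted:
            findings.append(Finding(
                ref, Severity.WARNING, ax.id,
                tuple(sorted(_fields_of_expr(ax.sub) | set(
                    ATTRIBUTE_FIELDS.get(a, a) for a in contradicted))),
                ax.message or f"soft restriction {ax.id} contradicted",
                (ax.id,)))

    # scenario (iii): defined-class confirmation of guarded codes
    confirmed: dict[str, str] = {}
    guards: dict[tuple[str, str], list] = {}
    for ax in tbox.equivalents:
        if not ax.guard_field:
            continue
        fname = ATTRIBUTE_FIELDS.get(ax.guard_field, ax.guard_field)
        value = getattr(rec, fname, None)
        if value is None or (ax.guard_codes and str(value) not in ax.guard_codes):
            continue
        guards.setdefault((ax.guard_field, str(value)), []).append(ax)
    for (gfield, value), axs in sorted(guards.items()):
        hit = None
        for ax in axs:
            if subsumes(ClassExpression.build(atoms=[ax.defined]), expr, tbox):
                hit = ax
                break
        fname = ATTRIBUTE_FIELDS.get(gfield, gfield)
        if hit is not None:
            confirmed[fname] = hit.defined
        else:
            candidates = tuple(ax.defined for ax in axs)
            findings.append(Finding(
                ref, Severity.UNCONFIRMED, axs[0].id, (fname,),
                f"no class subsumes the ascribed {fname} code {value!r}; "
                f"candidates tested: {', '.join(candidates)}",
                candidates))

    inferences = _inferences(rec, expr, tbox, dictionary)
    return _finish(ref, findings, tuple(sorted(confirmed.items())),
                   tuple(inferences), escalate_unconfirmed)


def _fields_of_expr(expr: ClassExpression) -> set[str]:
    return {ATTRIBUTE_FIELDS.get(a, a) for a in expr.restricted_attrs}


def _fields_of_axioms(axiom_ids: Iterable[str], tbox: TBox) -> tuple[str, ...]:
    fields: set[str] = set()
    by_id = {a.id: a for a in tbox.axioms}
    for ax_id in axiom_ids:
        ax = by_id.get(ax_id)
        if ax is None:
            continue
        for expr in ax.expressions():
            fields |= _fields_of_expr(expr)
    return tuple(sorted(fields))


def _axiom_message(ax_id: str, tbox: TBox) -> str:
    for a in tbox.axioms:
        if a.id == ax_id:
            return a.message or a.id
    return ax_id


def _inferences(rec: CancerCaseRecord, expr: ClassExpression, tbox: TBox,
                dictionary: Dictionary | None) -> list[tuple[str, str]]:
    term = tbox.terminology
    out: list[tuple[str, str]] = []
    if rec.morphology and rec.behaviour:
        mb = term.morph_behaviour(rec.morphology, rec.behaviour)
        if mb:
            out.append(("morph_behaviour", mb))
            groups = sorted(a for a in term.ancestors(mb)
                            if a != mb and term.concept(a).kind == "morph_behaviour_group")
            if groups:
                out.append(("morph_behaviour_group", groups[0]))
        if rec.topography:
            tt = term.tumour_type(rec.topography, rec.morphology, rec.behaviour)
            if tt:
                out.append(("tumour_type", tt))
    if rec.topography:
        grouping = term.tnm_grouping_for(rec.topography)
        if grouping:
            out.append(("tnm_topography_grouping", grouping))
            stage = term.stage_group(grouping, rec.tnm_t, rec.tnm_n, rec.tnm_m)
            if stage is not None:
                out.append(("stage_group", stage.roman()))
    # classification of the record's expression under the defined classes
    named = classify(expr, tbox)
    specific = most_specific(named, term)
    if specific:
        out.append(("classified_as", "|".join(specific)))
    if dictionary is not None and _is_complete(rec, dictionary):
        out.append((COMPLETENESS_CLASS.lower(), COMPLETENESS_CLASS))
    return out


def _is_complete(rec: CancerCaseRecord, dictionary: Dictionary) -> bool:
    """Mandatory-variable completeness, computed from the dictionary."""
    field_map = {
        "patient_id": rec.patient_id, "tumour_id": rec.tumour_id,
        "sex": rec.sex, "age": rec.age_at_diagnosis,
        "topography": rec.topography, "morphology": rec.morphology,
        "behaviour": rec.behaviour, "grade": rec.grade,
        "basis_of_diagnosis": rec.basis_of_diagnosis,
        "vital_status": rec.vital_status,
        "survival_duration": rec.survival_duration,
    }
    extras = dict(rec.extras)
    dates = {"birth": rec.birth_date, "incidence": rec.incidence_date,
             "registration": rec.registration_date,
             "last_vital_status": rec.last_vital_status_date}
    for name, mandatory in dictionary.logical_fields():
        if not mandatory:
            continue
        if name in dates:
            if not dates[name].complete:
                return False
        elif name in field_map:
            if field_map[name] is None or field_map[name] == "":
                return False
        elif not extras.get(name):
            return False
    return True


def _finish(ref, findings, confirmed, inferences, escalate) -> ValidationReport:
    findings = tuple(sort_findings(list(findings)))
    has_error = any(f.severity == Severity.ERROR for f in findings)
    has_unconfirmed = any(f.severity == Severity.UNCONFIRMED for f in findings)
    has_warning = any(f.severity == Severity.WARNING for f in findings)
    if has_error or (escalate and has_unconfirmed):
        status = "INVALID"
    elif has_warning or has_unconfirmed:
        status = "VALID_WITH_WARNINGS"
    else:
        status = "VALID"
    return ValidationReport(ref, findings, status, confirmed, inferences)


# ---------------------------------------------------------------------------
# calendar consistency

#: default tolerances; the age check allows the one-year ambiguity of
#: comparing completed years against possibly incomplete dates
AGE_TOLERANCE_YEARS = 1
SURVIVAL_TOLERANCE_DAYS = 31


def check_dates(rec: CancerCaseRecord, *,
                age_tolerance: int = AGE_TOLERANCE_YEARS,
                survival_tolerance: int = SURVIVAL_TOLERANCE_DAYS) -> list[Finding]:
    """Ordering, age-vs-dates and survival-duration consistency findings."""
    ref = (rec.patient_id, rec.tumour_id)
    out: list[Finding] = []

    def order(a: PartialDate, b: PartialDate, name_a: str, name_b: str, rule: str):
        if a.known and b.known and b.before(a) is True:
            out.append(Finding(ref, Severity.ERROR, rule, (name_a, name_b),
                               f"{name_a} is after {name_b}"))

    order(rec.birth_date, rec.incidence_date, "birth_date", "incidence_date",
          "date-order-birth-incidence")
    order(rec.incidence_date, rec.last_vital_status_date, "incidence_date",
          "last_vital_status_date", "date-order-incidence-vital")

    if (rec.age_at_diagnosis is not None and rec.birth_date.year is not None
            and rec.incidence_date.year is not None):
        year_diff = rec.incidence_date.year - rec.birth_date.year
        # completed years at diagnosis lie in [year_diff - 1, year_diff]
        if not (year_diff - 1 - age_tolerance <= rec.age_at_diagnosis
                <= year_diff + age_tolerance):
            out.append(Finding(ref, Severity.ERROR, "age-date-consistency",
                               ("age", "birth_date", "incidence_date"),
                               f"age {rec.age_at_diagnosis} inconsistent with "
                               f"birth year {rec.birth_date.year} and incidence "
                               f"year {rec.incidence_date.year}"))

    if (rec.survival_duration is not None and rec.incidence_date.complete
            and rec.last_vital_status_date.complete):
        d0 = datetime.date(rec.incidence_date.year, rec.incidence_date.month,
                           rec.incidence_date.day)
        d1 = datetime.date(rec.last_vital_status_date.year,
                           rec.last_vital_status_date.month,
                           rec.last_vital_status_date.day)
        days = (d1 - d0).days
        if abs(days - rec.survival_duration) > survival_tolerance:
            out.append(Finding(ref, Severity.ERROR, "survival-duration-check",
                               ("survival_duration", "incidence_date",
                                "last_vital_status_date"),
                               f"survival_duration {rec.survival_duration} d "
                               f"does not match the {days} d between incidence "
                               f"and last vital status"))
    return sort_findings(out)
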