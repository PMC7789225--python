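"""Single-record validation: the three scenarios, inferences, date checks."""
import pytest

import crcheck as cc
from crcheck.core_dictionary import PartialDate
from crcheck.dl_engine import TBox
from crcheck.findings import Severity
from crcheck.validator import (check_dates, record_to_expression,
                               validate_record)

from conftest import make_record


# -- hard-error worked example ----------------------------------------------

def test_in_situ_with_clinical_bod_is_a_hard_error(tbox):
    """BoD 1 + morphology 8720 + behaviour 2: exactly one ERROR citing the
    in-situ/basis-of-diagnosis disjointness."""
    rec = make_record(morphology="8720", behaviour="2", basis_of_diagnosis="1")
    report = validate_record(rec, tbox)
    assert report.record_status == "INVALID"
    assert len(report.findings) == 1
    f = report.findings[0]
    assert f.severity == Severity.ERROR
    assert f.explanation == ("R1",)


def test_corrected_behaviour_confirms_the_bod_code(tbox):
    rec = make_record(morphology="8720", behaviour="3", basis_of_diagnosis="1")
    report = validate_record(rec, tbox)
    assert report.record_status == "VALID"
    assert report.errors == []
    assert report.confirmed("basis_of_diagnosis") == "ENCRBoD_1"
    assert "ENCRBoD_1" in dict(report.inferences).get("classified_as", "")


# -- soft-error worked example ----------------------------------------------

def test_hepatoblastoma_at_age_ten_warns_but_is_not_an_error(tbox):
    rec = make_record(morphology="8970", behaviour="3", age_at_diagnosis=10)
    report = validate_record(rec, tbox)
    assert report.errors == []
    assert [f.rule_id for f in report.warnings] == ["R2"]
    assert dict(report.inferences)["morph_behaviour"] == "Hepatoblastoma"


def test_hepatoblastoma_age_sweep_bound_is_five(tbox):
    warning_free = [age for age in range(21)
                    if not validate_record(
                        make_record(morphology="8970", behaviour="3",
                                    age_at_diagnosis=age), tbox).warnings]
    assert max(warning_free) == 5
    assert warning_free == [0, 1, 2, 3, 4, 5]


def test_germ_cell_age_sweep_bound_is_seven(tbox):
    warning_free = [age for age in range(21)
                    if not validate_record(
                        make_record(morphology="9064", topography="C649",
                                    behaviour="3", age_at_diagnosis=age),
                        tbox).warnings]
    assert max(warning_free) == 7


def test_carcinoma_group_minimum_age_bound(tbox):
    """Carcinoma-NOS morphology-behaviour implies age > 5: ages up to 5
    warn, six onwards do not."""
    warn_ages = [age for age in range(21)
                 if validate_record(
                     make_record(morphology="8071", behaviour="3",
                                 age_at_diagnosis=age), tbox).warnings]
    assert warn_ages == [0, 1, 2, 3, 4, 5]


def test_unasserted_age_raises_no_soft_warning(tbox):
    """Soft restrictions only contradict asserted values."""
    rec = make_record(morphology="8970", behaviour="3")  # no age given
    assert validate_record(rec, tbox).warnings == []


# -- record expression -------------------------------------------------------

def test_record_expression_resolves_memberships(terminology, bladder_case):
    expr = record_to_expression(bladder_case, terminology)
    assert expr.in_sets["morphology"] == frozenset({"8071"})
    assert expr.in_sets["t"] == frozenset({"T3"})
    assert expr.ranges["age"].lo == expr.ranges["age"].hi == 53
    assert "SquamousCellCarcinomaKeratinising" in expr.atoms
    assert "TumourTypeUrinaryBladder" in expr.atoms
    assert "TNMEd6UrinaryBladder" in expr.atoms


def test_record_expression_omits_absent_fields(terminology):
    expr = record_to_expression(make_record(morphology="8000"), terminology)
    assert "topography" not in expr.in_sets
    assert "age" not in expr.ranges


# -- comprehensive-case battery ----------------------------------------------

def test_comprehensive_bladder_case_battery(tbox, dictionary, bladder_case):
    """The fully described case reproduces all six inferences plus an
    unconfirmed basis of diagnosis."""
    report = validate_record(bladder_case, tbox, dictionary=dictionary)
    inf = dict(report.inferences)
    assert inf["tumour_type"] == "TumourTypeUrinaryBladder"
    assert inf["morph_behaviour_group"] == "CarcinomaNOSGroupMorphBeh"
    assert report.confirmed("vital_status") == "ENCRVitalStatusAlive"
    assert report.confirmed("extent_of_disease") == "ENCRExtentOfDisease"
    assert inf["stage_group"] == "III"
    assert inf["casetypecomplete"] == "CaseTypeComplete"
    unconfirmed = report.unconfirmed
    assert len(unconfirmed) == 1
    assert unconfirmed[0].fields == ("basis_of_diagnosis",)
    assert "ENCRBoD_1" in unconfirmed[0].explanation
    assert report.errors == [] and report.warnings == []


def test_unconfirmed_escalation_flag(tbox, bladder_case):
    default = validate_record(bladder_case, tbox)
    escalated = validate_record(bladder_case, tbox, escalate_unconfirmed=True)
    assert default.record_status == "VALID_WITH_WARNINGS"
    assert escalated.record_status == "INVALID"


# -- properties ---------------------------------------------------------------

def test_validation_is_deterministic(tbox, dictionary, bladder_case):
    reports = [validate_record(bladder_case, tbox, dictionary=dictionary)
               for _ in range(3)]
    assert reports[0] == reports[1] == reports[2]


def test_scenario_separation(tbox, terminology):
    """Dropping the soft rules removes exactly the WARNING findings."""
    hard_only = TBox([a for a in tbox.axioms if a.severity != "WARNING"],
                     terminology, tbox.domains)
    records = [
        make_record(morphology="8970", behaviour="3", age_at_diagnosis=10),
        make_record(morphology="8720", behaviour="2", basis_of_diagnosis="1"),
        make_record(morphology="8071", behaviour="3", age_at_diagnosis=3,
                    basis_of_diagnosis="1"),
    ]
    for rec in records:
        full = validate_record(rec, tbox)
        reduced = validate_record(rec, hard_only)
        non_warn = [f for f in full.findings if f.severity != Severity.WARNING]
        assert list(reduced.findings) == non_warn


def test_valid_synthetic_records_validate_clean(tbox, dictionary):
    """Soundness: a record violating no axiom and matching a confirmation
    class for every guarded code is VALID."""
    for lab in cc.generate_valid(50, seed=5):
        report = validate_record(lab.record, tbox, dictionary=dictionary)
        assert report.record_status == "VALID", report.findings
        assert check_dates(lab.record) == []


# -- calendar checks ----------------------------------------------------------

def test_birth_after_incidence_is_an_error():
    rec = make_record(birth_date=PartialDate(1970, 1, 1),
                      incidence_date=PartialDate(1960, 5, 5))
    findings = check_dates(rec)
    assert [f.rule_id for f in findings] == ["date-order-birth-incidence"]
    assert findings[0].severity == Severity.ERROR


def test_consistent_age_and_dates_pass():
    rec = make_record(birth_date=PartialDate(1950, 3, 1),
                      incidence_date=PartialDate(2003, 6, 2),
                      age_at_diagnosis=53)
    assert check_dates(rec) == []


def test_inconsistent_age_is_flagged():
    rec = make_record(birth_date=PartialDate(1950, 1, 1),
                      incidence_date=PartialDate(2003, 6, 2),
                      age_at_diagnosis=40)
    assert [f.rule_id for f in check_dates(rec)] == ["age-date-consistency"]


def test_survival_duration_by_calendar_arithmetic():
    """2000-01-01 to 2001-01-01 is exactly 366 days (leap year)."""
    rec = make_record(incidence_date=PartialDate(2000, 1, 1),
                      last_vital_status_date=PartialDate(2001, 1, 1),
                      survival_duration=366)
    assert check_dates(rec) == []
    bad = make_record(incidence_date=PartialDate(2000, 1, 1),
                      last_vital_status_date=PartialDate(2001, 1, 1),
                      survival_duration=500)
    assert [f.rule_id for f in check_dates(bad)] == ["survival-duration-check"]


def test_unknown_date_parts_disable_undecidable_checks():
    rec = make_record(birth_date=PartialDate(1970, None, None),
                      incidence_date=PartialDate(1970, 6, 1))
    assert check_dates(rec) == []
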