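import pytest

import crcheck as cc
from crcheck.core_dictionary import CancerCaseRecord, PartialDate


@pytest.fixture(scope="session")
def dictionary():
    return cc.load_default_dictionary()


@pytest.fixture(scope="session")
def terminology():
    return cc.load_default_terminology()


@pytest.fixture(scope="session")
def ruleset():
    return cc.load_default_rules()


@pytest.fixture(scope="session")
def tbox(terminology, ruleset):
    return cc.compile_rules(ruleset, terminology)


def make_record(**kwargs) -> CancerCaseRecord:
    """Minimal record builder for validator-level tests."""
    base = dict(patient_id="P1", tumour_id="T1")
    base.update(kwargs)
    return CancerCaseRecord(**base)


@pytest.fixture()
def bladder_case() -> CancerCaseRecord:
    """The comprehensively described urinary-bladder case (male, 53)."""
    return CancerCaseRecord(
        patient_id="PX", tumour_id="TX1", sex="1",
        birth_date=PartialDate(1950, 3, 14),
        incidence_date=PartialDate(2003, 6, 2),
        registration_date=PartialDate(2003, 7, 1),
        last_vital_status_date=PartialDate(2004, 6, 2),
        age_at_diagnosis=53, topography="C679", morphology="8071",
        behaviour="3", grade="2", basis_of_diagnosis="1",
        extent_of_disease="1", tnm_t="T3", tnm_n="N0", tnm_m="M0",
        vital_status="1", survival_duration=366,
        extras=(("geo_code", "EU1"), ("icdo_edition", "3"),
                ("registry_id", "R1")))


def full_row(**overrides) -> dict:
    """A complete, format-valid data row (all mandatory columns filled)."""
    row = {
        "patient_id": "P1", "tumour_id": "T1", "registry_id": "R001",
        "geo_code": "EU001", "sex": "1", "age": "53",
        "birth_day": "14", "birth_month": "3", "birth_year": "1950",
        "incidence_day": "2", "incidence_month": "6", "incidence_year": "2003",
        "vital_status_day": "2", "vital_status_month": "6",
        "vital_status_year": "2004",
        "topography": "C67.9", "morphology": "8071", "behaviour": "3",
        "grade": "2", "basis_of_diagnosis": "1", "icdo_edition": "3",
        "vital_status": "1", "survival_duration": "366",
    }
    row.update(overrides)
    return row
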