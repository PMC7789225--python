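"""Seeded synthetic registry records with labelled, injected violations.

The generator emits structurally valid records - terminology-consistent
topography/morphology/behaviour combinations, ages inside every soft bound,
ordered dates, confirmable guarded codes - and a corruption step that
mutates records minimally so that exactly one named rule fires. Records are
structurally, not epidemiologically, representative: no incidence
distributions are modelled.

Every validation pathway is therefore testable round-trip without any real
registry data: corrupt + validate must recover exactly the injected
finding set.
"""
from __future__ import annotations

import csv
import random
from dataclasses import dataclass, replace
from pathlib import Path

from .core_dictionary import CancerCaseRecord, Dictionary, PartialDate, record_to_row
from .findings import Severity


class GeneratorError(ValueError):
    pass


@dataclass(frozen=True)
class CorruptionSpec:
    rule_id: str
    fraction: float
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.fraction <= 1.0:
            raise GeneratorError("fraction must be in [0, 1]")


@dataclass(frozen=True)
class LabelledRecord:
    record: CancerCaseRecord
    expected_findings: tuple[tuple[str, str], ...] = ()  # (severity, rule_id)


#: terminology-consistent case templates (site, histology, behaviour, basis
#: of diagnosis chosen so every guarded code is confirmable)
_TEMPLATES = [
    # topography, morphology, bod, extent, tnm (t, n, m) or None
    ("C443", "8720", "1", "1", None),            # skin melanoma, clinical BoD
    ("C220", "8170", "7", "2", None),            # hepatocellular carcinoma
    ("C679", "8120", "7", "1", ("T2", "N0", "M0")),  # bladder TCC, staged
    ("C349", "8140", "5", "2", None),            # lung adenocarcinoma
    ("C649", "8312", "7", "1", None),            # renal cell carcinoma
]

_DAYS_IN_MONTH = [31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31]


def _date(rng: random.Random, year: int) -> PartialDate:
    month = rng.randint(1, 12)
    day = rng.randint(1, _DAYS_IN_MONTH[month - 1])
    return PartialDate(year, month, day)


def _days_between(a: PartialDate, b: PartialDate) -> int:
    import datetime
    return (datetime.date(b.year, b.month, b.day)
            - datetime.date(a.year, a.month, a.day)).days


def generate_valid(n: int, seed: int) -> list[LabelledRecord]:
    """``n`` structurally valid records; deterministic in ``seed``."""
    if n < 0:
        raise GeneratorError("n must be >= 0")
    rng = random.Random(seed)
    out: list[LabelledRecord] = []
    for i in range(n):
        topo, morph, bod, extent, tnm = _TEMPLATES[rng.randrange(len(_TEMPLATES))]
        age = rng.randint(20, 85)
        inc_year = rng.randint(1995, 2015)
        incidence = _date(rng, inc_year)
        birth = _date(rng, inc_year - age)
        # completed years: birth day/month must not postdate incidence's
        if (birth.month, birth.day) > (incidence.month, incidence.day):
            birth = PartialDate(birth.year, incidence.month,
                                min(birth.day, _DAYS_IN_MONTH[incidence.month - 1]))
        survival = rng.randint(30, 3000)
        import datetime
        d_inc = datetime.date(incidence.year, incidence.month, incidence.day)
        d_lvs = d_inc + datetime.timedelta(days=survival)
        d_reg = d_inc + datetime.timedelta(days=rng.randint(7, 90))
        rec = CancerCaseRecord(
            patient_id=f"P{seed:04d}{i:06d}", tumour_id=f"T{seed:04d}{i:06d}",
            sex=rng.choice(["1", "2"]),
            birth_date=birth, incidence_date=incidence,
            registration_date=PartialDate(d_reg.year, d_reg.month, d_reg.day),
            last_vital_status_date=PartialDate(d_lvs.year, d_lvs.month, d_lvs.day),
            age_at_diagnosis=age, topography=topo, morphology=morph,
            behaviour="3", grade=rng.choice(["1", "2", "3"]),
            basis_of_diagnosis=bod, extent_of_disease=extent,
            tnm_t=tnm[0] if tnm else None, tnm_n=tnm[1] if tnm else None,
            tnm_m=tnm[2] if tnm else None,
            vital_status="1", survival_duration=survival,
            extras=(("geo_code", "EU001"), ("icdo_edition", "3"),
                    ("registry_id", "R001")),
        )
        out.append(LabelledRecord(rec, ()))
    return out


# ---------------------------------------------------------------------------
# corruption: minimal targeted mutations per shipped rule

def _drop_tnm(rec: CancerCaseRecord) -> CancerCaseRecord:
    return replace(rec, tnm_t=None, tnm_n=None, tnm_m=None)


def _set_age(rec: CancerCaseRecord, age: int) -> CancerCaseRecord:
    # keep the birth date consistent so only the targeted rule fires
    birth = PartialDate(rec.incidence_date.year - age, 1, 1)
    return replace(rec, age_at_diagnosis=age, birth_date=birth)


def _corrupt_r1(rec, rng):
    # in-situ behaviour with a basis of diagnosis outside {5, 7}
    return replace(rec, behaviour="2", basis_of_diagnosis="1",
                   morphology="8720"), (str(Severity.ERROR), "R1")


def _corrupt_r2(rec, rng):
    # hepatoblastoma above the unlikely-age bound
    rec = _set_age(_drop_tnm(rec), rng.randint(6, 60))
    return replace(rec, morphology="8970", behaviour="3",
                   topography="C220", basis_of_diagnosis="7"), \
        (str(Severity.WARNING), "R2")


def _corrupt_r3(rec, rng):
    # extragonadal germ-cell tumour above age 7
    rec = _set_age(_drop_tnm(rec), rng.randint(8, 60))
    return replace(rec, morphology="9064", topography="C649",
                   behaviour="3", basis_of_diagnosis="7"), \
        (str(Severity.WARNING), "R3")


def _corrupt_r4(rec, rng):
    # clinical BoD with a morphology outside the permitted list
    return replace(_drop_tnm(rec), basis_of_diagnosis="1", morphology="8170",
                   topography="C220", behaviour="3"), \
        (str(Severity.UNCONFIRMED), "R4")


def _corrupt_r5(rec, rng):
    # NK-cell grade with a non-NK morphology
    return replace(rec, grade="8"), (str(Severity.UNCONFIRMED), "R5")


def _corrupt_r6(rec, rng):
    # bile-duct morphology on a non-biliary site
    return replace(_drop_tnm(rec), morphology="8160", topography="C349",
                   behaviour="3", basis_of_diagnosis="7"), \
        (str(Severity.UNCONFIRMED), "R6")


def _corrupt_r7(rec, rng):
    # clinical-investigation BoD outside the 9380/C717 combination
    return replace(_drop_tnm(rec), basis_of_diagnosis="2", morphology="8170",
                   topography="C220", behaviour="3"), \
        (str(Severity.UNCONFIRMED), "R7")


def _corrupt_r8(rec, rng):
    # carcinoma-NOS group below its minimum age
    rec = _set_age(_drop_tnm(rec), rng.randint(0, 5))
    return replace(rec, morphology="8070", behaviour="3",
                   basis_of_diagnosis="7"), (str(Severity.WARNING), "R8")


def _corrupt_r9(rec, rng):
    # male sex on a female-specific site
    return replace(_drop_tnm(rec), sex="1", topography="C539",
                   morphology="8070", behaviour="3",
                   basis_of_diagnosis="7"), (str(Severity.WARNING), "R9")


def _corrupt_r11(rec, rng):
    # extent of disease recorded for a non-invasive behaviour
    return replace(_drop_tnm(rec), behaviour="1", basis_of_diagnosis="7",
                   extent_of_disease="1"), (str(Severity.UNCONFIRMED), "R11")


_MUTATORS = {
    "R1": _corrupt_r1, "R2": _corrupt_r2, "R3": _corrupt_r3,
    "R4": _corrupt_r4, "R5": _corrupt_r5, "R6": _corrupt_r6,
    "R7": _corrupt_r7, "R8": _corrupt_r8, "R9": _corrupt_r9,
    "R11": _corrupt_r11,
}

#: rules whose shipped guards admit no violating mutation
UNCORRUPTIBLE = frozenset({"R10"})

CORRUPTIBLE_RULES = tuple(sorted(_MUTATORS))


def corrupt(records: list[LabelledRecord], spec: CorruptionSpec) -> list[LabelledRecord]:
    """Mutate ``floor(fraction * n)`` records to violate exactly ``spec.rule_id``.

    The first ``k`` records (deterministic) are mutated; expected findings
    are updated with the injected (severity, rule_id) label.
    """
    if spec.rule_id in UNCORRUPTIBLE:
        raise GeneratorError(
            f"rule {spec.rule_id!r} cannot be violated by mutating a valid record")
    if spec.rule_id not in _MUTATORS:
        raise GeneratorError(f"no corruption recipe for rule {spec.rule_id!r}")
    rng = random.Random(spec.seed)
    k = int(spec.fraction * len(records))
    out: list[LabelledRecord] = []
    for i, lab in enumerate(records):
        if i < k:
            mutated, expected = _MUTATORS[spec.rule_id](lab.record, rng)
            out.append(LabelledRecord(mutated,
                                      lab.expected_findings + (expected,)))
        else:
            out.append(lab)
    return out


# ---------------------------------------------------------------------------
# fixture files

def write_fixture_files(records: list[LabelledRecord], data_path: str | Path,
                        truth_path: str | Path, dictionary: Dictionary,
                        delimiter: str = ",") -> None:
    """Delimited data file plus a ground-truth sidecar of expected findings."""
    columns = [v.name for v in dictionary.variables]
    with open(data_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=columns, delimiter=delimiter)
        writer.writeheader()
        for lab in records:
            writer.writerow(record_to_row(lab.record, dictionary))
    with open(truth_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(["patient_id", "tumour_id", "severity", "rule_id"])
        for lab in records:
            for severity, rule_id in lab.expected_findings:
                writer.writerow([lab.record.patient_id, lab.record.tumour_id,
                                 severity, rule_id])
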