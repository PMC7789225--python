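"""ENCR core variable dictionary and record parsing.

The harmonised European cancer-registry core data set is described by a
variable dictionary: 55 individual variables of which 23 are mandatory;
each of the four dates (birth, incidence, registration, last known vital
status) is split into day/month/year part variables sharing a date group,
so collapsing every date group to one logical field leaves 46 logical
variables (17 mandatory).

Parsing a delimited-text row against the dictionary yields either a fully
normalised :class:`CancerCaseRecord` or a list of FORMAT findings (missing
mandatory variables, typographic errors, out-of-domain codes) - never both.
Format trapping happens here, before any terminological reasoning.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import yaml

from .findings import Finding, Severity
from .terminology import normalise_tnm


class DictionaryError(ValueError):
    pass


VALUE_KINDS = {"code", "integer", "date_part", "identifier", "free_text"}

_TOPOGRAPHY_RE = re.compile(r"^C[0-9]{3}$")


@dataclass(frozen=True)
class VariableSpec:
    name: str
    mandatory: bool
    value_kind: str
    domain_ref: str | None = None
    date_group: str | None = None
    date_part: str | None = None  # day | month | year for date_part kind


@dataclass(frozen=True)
class CodeDomain:
    """Enumerated, patterned, or integer-range value domain."""

    name: str
    entries: tuple[tuple[str, str], ...] = ()   # (code, label)
    pattern: str | None = None
    int_range: tuple[int, int] | None = None

    def codes(self) -> frozenset:
        return frozenset(c for c, _ in self.entries)

    def contains(self, value: str) -> bool:
        if self.int_range is not None:
            if not value.isdigit():
                return False
            lo, hi = self.int_range
            return lo <= int(value) <= hi
        if self.pattern is not None:
            return re.fullmatch(self.pattern, value) is not None
        return value in self.codes()


@dataclass(frozen=True)
class PartialDate:
    """Calendar date whose parts may individually be unknown."""

    year: int | None = None
    month: int | None = None
    day: int | None = None

    @property
    def complete(self) -> bool:
        return None not in (self.year, self.month, self.day)

    @property
    def known(self) -> bool:
        return self.year is not None

    def before(self, other: "PartialDate") -> bool | None:
        """Strict ordering when decidable from the known parts, else None."""
        for a, b in ((self.year, other.year), (self.month, other.month),
                     (self.day, other.day)):
            if a is None or b is None:
                return None
            if a < b:
                return True
            if a > b:
                return False
        return False  # equal


@dataclass(frozen=True)
class CancerCaseRecord:
    """One tumour registration, normalised.

    Topography is dotless (C349); morphology is the 4-digit histology code;
    TNM categories are prefix-stripped (the raw clinical/pathological values
    stay in ``extras`` for reporting).
    """

    patient_id: str
    tumour_id: str
    sex: str | None = None
    birth_date: PartialDate = PartialDate()
    incidence_date: PartialDate = PartialDate()
    registration_date: PartialDate = PartialDate()
    last_vital_status_date: PartialDate = PartialDate()
    age_at_diagnosis: int | None = None
    topography: str | None = None
    morphology: str | None = None
    behaviour: str | None = None
    grade: str | None = None
    basis_of_diagnosis: str | None = None
    extent_of_disease: str | None = None
    tnm_t: str | None = None
    tnm_n: str | None = None
    tnm_m: str | None = None
    vital_status: str | None = None
    survival_duration: int | None = None
    extras: tuple[tuple[str, str], ...] = ()

    def extra(self, name: str) -> str | None:
        return dict(self.extras).get(name)


class Dictionary:
    """Immutable ENCR variable dictionary."""

    def __init__(self, variables: Iterable[VariableSpec],
                 domains: Mapping[str, CodeDomain], version: str = ""):
        self.variables: tuple[VariableSpec, ...] = tuple(variables)
        self.domains: dict[str, CodeDomain] = dict(domains)
        self.version = version
        names = [v.name for v in self.variables]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise DictionaryError(f"duplicate variable names: {dupes}")
        self.by_name = {v.name: v for v in self.variables}
        for v in self.variables:
            if v.value_kind not in VALUE_KINDS:
                raise DictionaryError(f"variable {v.name!r}: unknown kind {v.value_kind!r}")
            if v.value_kind == "code" and v.domain_ref and v.domain_ref not in self.domains:
                raise DictionaryError(f"variable {v.name!r}: unknown domain {v.domain_ref!r}")
        for g, parts in self.date_groups().items():
            kinds = [p.date_part for p in parts if p.value_kind == "date_part"]
            if sorted(k for k in kinds if k) != ["day", "month", "year"]:
                raise DictionaryError(
                    f"date group {g!r} must have exactly day/month/year parts")

    # -- counts ----------------------------------------------------------
    @property
    def n_variables(self) -> int:
        return len(self.variables)

    @property
    def n_mandatory(self) -> int:
        return sum(v.mandatory for v in self.variables)

    def date_groups(self) -> dict[str, list[VariableSpec]]:
        out: dict[str, list[VariableSpec]] = {}
        for v in self.variables:
            if v.date_group:
                out.setdefault(v.date_group, []).append(v)
        return out

    def logical_fields(self) -> list[tuple[str, bool]]:
        """Variables with each date group collapsed to one (name, mandatory)."""
        out: list[tuple[str, bool]] = []
        seen_groups: set[str] = set()
        for v in self.variables:
            if v.date_group:
                if v.date_group in seen_groups:
                    continue
                seen_groups.add(v.date_group)
                group = self.date_groups()[v.date_group]
                out.append((v.date_group, any(p.mandatory for p in group
                                              if p.value_kind == "date_part")))
            else:
                out.append((v.name, v.mandatory))
        return out

    @property
    def n_logical(self) -> int:
        return len(self.logical_fields())

    @property
    def n_logical_mandatory(self) -> int:
        return sum(m for _, m in self.logical_fields())

    @property
    def mandatory_names(self) -> list[str]:
        return [v.name for v in self.variables if v.mandatory]


def load_dictionary(source: str | Path) -> Dictionary:
    """Load the variable dictionary from its YAML description."""
    with open(source, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not data or "variables" not in data:
        raise DictionaryError(f"{source}: empty or missing 'variables' section")
    domains: dict[str, CodeDomain] = {}
    for name, spec in (data.get("domains") or {}).items():
        if isinstance(spec, dict) and "range" in spec:
            lo, hi = spec["range"]
            domains[name] = CodeDomain(name, int_range=(int(lo), int(hi)))
        elif isinstance(spec, dict) and "pattern" in spec:
            domains[name] = CodeDomain(name, pattern=spec["pattern"])
        elif isinstance(spec, dict):
            entries = tuple((str(c), str(l)) for c, l in spec.items())
            for code, label in entries:
                if not label:
                    raise DictionaryError(f"domain {name!r}: empty label for code {code!r}")
            domains[name] = CodeDomain(name, entries=entries)
        else:
            raise DictionaryError(f"domain {name!r}: unrecognised specification")
    variables = []
    for v in data["variables"]:
        try:
            variables.append(VariableSpec(
                name=v["name"], mandatory=bool(v.get("mandatory", False)),
                value_kind=v["kind"], domain_ref=v.get("domain"),
                date_group=v.get("date_group"), date_part=v.get("part")))
        except KeyError as exc:
            raise DictionaryError(f"variable entry {v!r}: missing field {exc}")
    return Dictionary(variables, domains, version=str(data.get("version", "")))


# ---------------------------------------------------------------------------
# record parsing

_MISSING = {"", "NA", "N/A", None}

#: registry sentinel conventions for unknown date parts
_UNKNOWN_DATE = {"", "9999", "99", "NA"}


def _fmt(patient: str, tumour: str, name: str, message: str) -> Finding:
    return Finding((patient, tumour), Severity.FORMAT, "format-check",
                   (name,), message)


def normalise_topography(value: str) -> str:
    return value.strip().upper().replace(".", "")


def parse_record(row: Mapping[str, str], dictionary: Dictionary):
    """Parse one data row; a record XOR a list of FORMAT findings.

    Missing optional variables parse as absent. Topography is accepted with
    or without the ICD-O print dot and stored dotless.
    """
    pid = str(row.get("patient_id") or "").strip()
    tid = str(row.get("tumour_id") or "").strip()
    findings: list[Finding] = []
    values: dict[str, str] = {}

    for name in row:
        if name not in dictionary.by_name:
            findings.append(_fmt(pid, tid, name, f"unknown variable {name!r}"))

    for var in dictionary.variables:
        raw = row.get(var.name)
        raw = None if raw is None else str(raw).strip()
        missing = raw in _MISSING or (var.value_kind == "date_part"
                                      and raw in _UNKNOWN_DATE)
        if missing:
            if var.mandatory and var.value_kind != "date_part":
                findings.append(_fmt(pid, tid, var.name,
                                     f"mandatory variable {var.name!r} is missing"))
            elif var.mandatory and var.value_kind == "date_part" and raw in {None, ""}:
                findings.append(_fmt(pid, tid, var.name,
                                     f"mandatory variable {var.name!r} is missing"))
            continue
        value = raw
        if var.name == "topography":
            value = normalise_topography(value)
            if not _TOPOGRAPHY_RE.fullmatch(value):
                findings.append(_fmt(pid, tid, var.name,
                                     f"topography {raw!r} does not match C-nnn"))
                continue
        if var.value_kind in {"integer", "date_part"}:
            if not re.fullmatch(r"[0-9]+", value):
                findings.append(_fmt(pid, tid, var.name,
                                     f"{var.name} value {raw!r} is not numeric"))
                continue
        if var.value_kind == "date_part":
            iv = int(value)
            limits = {"day": (1, 31), "month": (1, 12), "year": (1850, 2100)}
            lo, hi = limits[var.date_part]
            if not lo <= iv <= hi:
                findings.append(_fmt(pid, tid, var.name,
                                     f"{var.name} value {raw!r} out of range"))
                continue
        if var.value_kind == "integer" and int(value) < 0:
            findings.append(_fmt(pid, tid, var.name, f"{var.name} negative"))
            continue
        if var.value_kind == "code" and var.domain_ref:
            domain = dictionary.domains[var.domain_ref]
            check = value
            if var.name == "morphology" and not value.isdigit():
                findings.append(_fmt(pid, tid, var.name,
                                     f"morphology {raw!r} is not a 4-digit code"))
                continue
            if not domain.contains(check):
                findings.append(_fmt(pid, tid, var.name,
                                     f"{var.name} value {raw!r} not in domain "
                                     f"{var.domain_ref!r}"))
                continue
        values[var.name] = value

    if not pid:
        findings.append(_fmt(pid, tid, "patient_id", "patient_id is missing"))
    if not tid:
        findings.append(_fmt(pid, tid, "tumour_id", "tumour_id is missing"))
    if findings:
        return findings

    def date_of(group: str) -> PartialDate:
        parts = {}
        for var in dictionary.date_groups().get(group, []):
            if var.value_kind == "date_part" and var.name in values:
                parts[var.date_part] = int(values[var.name])
        return PartialDate(parts.get("year"), parts.get("month"), parts.get("day"))

    core = {"patient_id", "tumour_id", "sex", "age", "topography", "morphology",
            "behaviour", "grade", "basis_of_diagnosis", "extent_of_disease",
            "vital_status", "survival_duration", "tnm_t_clinical",
            "tnm_n_clinical", "tnm_m_clinical", "tnm_t_path", "tnm_n_path",
            "tnm_m_path"}
    extras = tuple(sorted((k, v) for k, v in values.items()
                          if k not in core and dictionary.by_name[k].date_group is None))

    def tnm(axis: str) -> str | None:
        # pathological category preferred for staging, clinical otherwise
        raw = values.get(f"tnm_{axis}_path") or values.get(f"tnm_{axis}_clinical")
        return normalise_tnm(raw, axis[0].upper() if axis[0] in "tnm" else axis)

    return CancerCaseRecord(
        patient_id=pid, tumour_id=tid, sex=values.get("sex"),
        birth_date=date_of("birth"), incidence_date=date_of("incidence"),
        registration_date=date_of("registration"),
        last_vital_status_date=date_of("last_vital_status"),
        age_at_diagnosis=int(values["age"]) if "age" in values else None,
        topography=values.get("topography"), morphology=values.get("morphology"),
        behaviour=values.get("behaviour"), grade=values.get("grade"),
        basis_of_diagnosis=values.get("basis_of_diagnosis"),
        extent_of_disease=values.get("extent_of_disease"),
        tnm_t=tnm("t"), tnm_n=tnm("n"), tnm_m=tnm("m"),
        vital_status=values.get("vital_status"),
        survival_duration=(int(values["survival_duration"])
                           if "survival_duration" in values else None),
        extras=extras,
    )


def record_to_row(rec: CancerCaseRecord, dictionary: Dictionary) -> dict[str, str]:
    """Serialise a record back to a row of strings (inverse of parse_record)."""
    row: dict[str, str] = {}

    def put(name: str, value) -> None:
        if value is not None and name in dictionary.by_name:
            row[name] = str(value)

    put("patient_id", rec.patient_id)
    put("tumour_id", rec.tumour_id)
    put("sex", rec.sex)
    put("age", rec.age_at_diagnosis)
    put("topography", rec.topography)
    put("morphology", rec.morphology)
    put("behaviour", rec.behaviour)
    put("grade", rec.grade)
    put("basis_of_diagnosis", rec.basis_of_diagnosis)
    put("extent_of_disease", rec.extent_of_disease)
    put("vital_status", rec.vital_status)
    put("survival_duration", rec.survival_duration)
    put("tnm_t_path", rec.tnm_t)
    put("tnm_n_path", rec.tnm_n)
    put("tnm_m_path", rec.tnm_m)
    dates = {"birth": rec.birth_date, "incidence": rec.incidence_date,
             "registration": rec.registration_date,
             "last_vital_status": rec.last_vital_status_date}
    for group, pd in dates.items():
        for var in dictionary.date_groups().get(group, []):
            if var.value_kind != "date_part":
                continue
            part = getattr(pd, var.date_part)
            if part is not None:
                row[var.name] = str(part)
    for k, v in rec.extras:
        put(k, v)
    return row
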