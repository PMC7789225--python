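"""Validation outcomes shared across the package.

A finding is one validation outcome attached to a record: a hard rule
violation (ERROR), a contradicted soft restriction (WARNING), a guarded code
that no defined class confirmed (UNCONFIRMED), or a pre-processing failure
(FORMAT).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum


class Severity(str, Enum):
    ERROR = "ERROR"
    WARNING = "WARNING"
    UNCONFIRMED = "UNCONFIRMED"
    FORMAT = "FORMAT"

    def __str__(self) -> str:  # keep log rendering flat
        return self.value


#: stable sort rank used when ordering findings in reports
_SEVERITY_RANK = {
    Severity.FORMAT: 0,
    Severity.ERROR: 1,
    Severity.WARNING: 2,
    Severity.UNCONFIRMED: 3,
}


@dataclass(frozen=True)
class Finding:
    """One validation outcome.

    ``rule_id`` names the violated/unconfirmed rule, or a ``date-check``
    token for calendar consistency checks. ``explanation`` carries the axiom
    ids supporting an ERROR; for UNCONFIRMED it lists the candidate
    confirmation classes that were tested and failed.
    """

    record_ref: tuple[str, str]  # (patient_id, tumour_id)
    severity: Severity
    rule_id: str
    fields: tuple[str, ...] = ()
    message: str = ""
    explanation: tuple[str, ...] = ()

    def sort_key(self) -> tuple:
        return (_SEVERITY_RANK[self.severity], self.rule_id, self.fields)


def sort_findings(findings: list[Finding]) -> list[Finding]:
    """Deterministic ordering: severity class, then rule id, then fields."""
    return sorted(findings, key=Finding.sort_key)
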