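"""Batch validation of delimited registry data files.

Rows are read in batches (bounded memory), pre-processed for format errors,
then validated terminologically; findings stream to a delimited error log
ordered by input row and rule id. Results are independent of the batch
size; a format-rejected record generates no semantic findings.
"""
from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .core_dictionary import Dictionary, load_dictionary, parse_record
from .dl_engine import TBox
from .findings import Finding, Severity
from .multiple_primary import PatientCaseSet, detect_multiple_primaries
from .validator import check_dates, validate_record


class BatchError(RuntimeError):
    pass


@dataclass
class BatchConfig:
    input_path: str | Path
    dictionary_path: str | Path | None = None
    rules_path: str | Path | None = None
    terminology_path: str | Path | None = None
    batch_size: int = 1000
    escalate_unconfirmed: bool = False
    error_log_path: str | Path | None = None
    report_path: str | Path | None = None
    delimiter: str | None = None  # auto-detected among ',' ';' when None
    check_multiple_primaries: bool = False
    seed: int | None = None

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class BatchSummary:
    records_read: int = 0
    records_valid: int = 0
    records_with_warnings: int = 0
    records_invalid: int = 0
    records_format_rejected: int = 0
    findings_by_rule: dict = field(default_factory=dict)

    def _count(self, finding: Finding) -> None:
        self.findings_by_rule[finding.rule_id] = \
            self.findings_by_rule.get(finding.rule_id, 0) + 1

    def consistent(self) -> bool:
        return self.records_read == (self.records_valid + self.records_with_warnings
                                     + self.records_invalid
                                     + self.records_format_rejected)

    def render(self) -> str:
        lines = [
            f"records read:            {self.records_read}",
            f"  valid:                 {self.records_valid}",
            f"  with warnings:         {self.records_with_warnings}",
            f"  invalid:               {self.records_invalid}",
            f"  format-rejected:       {self.records_format_rejected}",
            "findings by rule:",
        ]
        for rule, n in sorted(self.findings_by_rule.items()):
            lines.append(f"  {rule}: {n}")
        return "\n".join(lines) + "\n"


ERROR_LOG_COLUMNS = ["patient_id", "tumour_id", "severity", "rule_id",
                     "fields", "message"]


def _detect_delimiter(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return ";" if header.count(";") > header.count(",") else ","


def _log_row(f: Finding) -> list[str]:
    return [f.record_ref[0], f.record_ref[1], str(f.severity), f.rule_id,
            "|".join(f.fields), f.message]


def run_batch(cfg: BatchConfig, *, dictionary: Dictionary | None = None,
              tbox: TBox | None = None) -> BatchSummary:
    """Validate an input file batch-wise; returns the summary totals.

    Dictionary/rule base default to the shipped fixtures when neither paths
    nor objects are given.
    """
    from . import defaults  # local import: defaults builds on this module's deps

    path = Path(cfg.input_path)
    if not path.exists():
        raise BatchError(f"input file not found: {path}")
    if dictionary is None:
        dictionary = (defaults.load_default_dictionary()
                      if cfg.dictionary_path is None
                      else load_dictionary(cfg.dictionary_path))
    if tbox is None:
        tbox = defaults.build_tbox(rules_path=cfg.rules_path,
                                   terminology_path=cfg.terminology_path)

    sep = cfg.delimiter or _detect_delimiter(path)
    try:
        reader = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False,
                             chunksize=cfg.batch_size, encoding="utf-8")
    except pd.errors.EmptyDataError:
        raise BatchError(f"input file {path} has no header row")

    summary = BatchSummary()
    log_fh = None
    writer = None
    if cfg.error_log_path:
        log_fh = open(cfg.error_log_path, "w", newline="", encoding="utf-8")
        writer = csv.writer(log_fh, delimiter=";")
        writer.writerow(ERROR_LOG_COLUMNS)

    header_checked = False
    mp_cases: dict[str, list] = {}
    try:
        for chunk in reader:
            if not header_checked:
                missing = [n for n in dictionary.mandatory_names
                           if n not in chunk.columns]
                if missing:
                    raise BatchError(
                        f"input header is missing mandatory columns: {missing}")
                header_checked = True
            for _, row in chunk.iterrows():
                summary.records_read += 1
                outcome = parse_record(row.to_dict(), dictionary)
                if isinstance(outcome, list):  # FORMAT findings
                    summary.records_format_rejected += 1
                    for f in outcome:
                        summary._count(f)
                        if writer:
                            writer.writerow(_log_row(f))
                    continue
                rec = outcome
                findings = list(check_dates(rec))
                report = validate_record(
                    rec, tbox, dictionary=dictionary,
                    escalate_unconfirmed=cfg.escalate_unconfirmed)
                findings.extend(report.findings)
                for f in findings:
                    summary._count(f)
                    if writer:
                        writer.writerow(_log_row(f))
                has_error = any(f.severity == Severity.ERROR for f in findings)
                has_soft = any(f.severity in (Severity.WARNING,
                                              Severity.UNCONFIRMED)
                               for f in findings)
                if has_error or report.record_status == "INVALID":
                    summary.records_invalid += 1
                elif has_soft:
                    summary.records_with_warnings += 1
                else:
                    summary.records_valid += 1
                if cfg.check_multiple_primaries:
                    mp_cases.setdefault(rec.patient_id, []).append(rec)
        if not header_checked:  # empty file: still verify the header
            cols = pd.read_csv(path, sep=sep, dtype=str, nrows=0).columns
            missing = [n for n in dictionary.mandatory_names if n not in cols]
            if missing:
                raise BatchError(
                    f"input header is missing mandatory columns: {missing}")
        if cfg.check_multiple_primaries:
            gt = tbox.terminology.group_table
            for pid, cases in sorted(mp_cases.items()):
                if len(cases) < 2:
                    continue
                partition = detect_multiple_primaries(
                    PatientCaseSet(pid, tuple(cases)), gt)
                for f in partition.findings:
                    summary._count(f)
                    if writer:
                        writer.writerow(_log_row(f))
    finally:
        if log_fh:
            log_fh.close()

    if cfg.report_path:
        Path(cfg.report_path).write_text(summary.render(), encoding="utf-8")
    return summary
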