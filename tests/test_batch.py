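"""Batch file processing, error log and streaming equivalence."""
import csv

import pytest

import crcheck as cc
from crcheck.batch import BatchConfig, BatchError, run_batch
from crcheck.synthetic import write_fixture_files

from conftest import full_row


def write_csv(path, rows, columns=None, delimiter=","):
    columns = columns or sorted({k for r in rows for k in r})
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.DictWriter(fh, fieldnames=columns, delimiter=delimiter)
        w.writeheader()
        for r in rows:
            w.writerow(r)


@pytest.fixture()
def three_case_file(tmp_path):
    """The three worked cases: hard error, soft warning, unconfirmed code."""
    rows = [
        # in-situ behaviour with clinical BoD -> ERROR R1
        full_row(patient_id="P1", tumour_id="T1", morphology="8720",
                 behaviour="2", topography="C443"),
        # hepatoblastoma at age 10 -> WARNING R2
        full_row(patient_id="P2", tumour_id="T2", morphology="8970",
                 behaviour="3", topography="C220", basis_of_diagnosis="7",
                 age="10", birth_year="1993", birth_month="1", birth_day="1"),
        # comprehensive bladder case -> UNCONFIRMED basis of diagnosis
        full_row(patient_id="P3", tumour_id="T3", topography="C67.9",
                 morphology="8071", behaviour="3", basis_of_diagnosis="1",
                 tnm_t_path="T3", tnm_n_path="N0", tnm_m_path="M0",
                 extent_of_disease="1"),
    ]
    path = tmp_path / "cases.csv"
    write_csv(path, rows)
    return path


def test_three_worked_cases_summary(three_case_file, tmp_path):
    log = tmp_path / "err.csv"
    summary = run_batch(BatchConfig(three_case_file, error_log_path=log))
    assert summary.records_read == 3
    assert summary.records_invalid == 1
    assert summary.records_with_warnings == 2
    assert summary.records_valid == 0
    assert summary.findings_by_rule["R1"] == 1
    assert summary.findings_by_rule["R2"] == 1
    assert summary.consistent()
    logged = list(csv.DictReader(open(log), delimiter=";"))
    assert [r["rule_id"] for r in logged] == ["R1", "R2", "R4"]
    assert [r["severity"] for r in logged] == ["ERROR", "WARNING", "UNCONFIRMED"]


def test_empty_file_with_valid_header_gives_zero_summary(tmp_path, dictionary):
    path = tmp_path / "empty.csv"
    write_csv(path, [], columns=[v.name for v in dictionary.variables])
    summary = run_batch(BatchConfig(path))
    assert summary.records_read == 0
    assert summary.findings_by_rule == {}
    assert summary.consistent()


def test_missing_mandatory_columns_abort_naming_them(tmp_path):
    path = tmp_path / "bad.csv"
    write_csv(path, [{"patient_id": "P1", "tumour_id": "T1"}])
    with pytest.raises(BatchError, match="morphology"):
        run_batch(BatchConfig(path))


def test_missing_input_file_aborts():
    with pytest.raises(BatchError, match="not found"):
        run_batch(BatchConfig("does/not/exist.csv"))


def test_semicolon_delimiter_is_autodetected(tmp_path):
    path = tmp_path / "semi.csv"
    write_csv(path, [full_row()], delimiter=";")
    summary = run_batch(BatchConfig(path))
    assert summary.records_read == 1


def test_format_rejected_records_generate_no_semantic_findings(tmp_path):
    # in-situ + clinical BoD would be an R1 error, but the morphology typo
    # stops the record at the pre-processing stage
    path = tmp_path / "typo.csv"
    write_csv(path, [full_row(morphology="80X0", behaviour="2")])
    summary = run_batch(BatchConfig(path))
    assert summary.records_format_rejected == 1
    assert "R1" not in summary.findings_by_rule
    assert set(summary.findings_by_rule) == {"format-check"}


def test_results_independent_of_batch_size(tmp_path, dictionary):
    records = cc.corrupt(cc.generate_valid(60, seed=4),
                         cc.CorruptionSpec("R2", 0.25, seed=4))
    data = tmp_path / "data.csv"
    write_fixture_files(records, data, tmp_path / "truth.csv", dictionary)
    summaries = [run_batch(BatchConfig(data, batch_size=bs))
                 for bs in (1, 7, 1000)]
    for s in summaries[1:]:
        assert s.records_read == summaries[0].records_read
        assert s.records_valid == summaries[0].records_valid
        assert s.records_with_warnings == summaries[0].records_with_warnings
        assert s.records_invalid == summaries[0].records_invalid
        assert s.findings_by_rule == summaries[0].findings_by_rule


def test_injected_violation_counts_match_ground_truth(tmp_path, dictionary):
    """Seeded corruption of 5% R1 violations: the batch summary recovers
    exactly the injected count."""
    n, fraction = 400, 0.05
    records = cc.corrupt(cc.generate_valid(n, seed=11),
                         cc.CorruptionSpec("R1", fraction, seed=11))
    injected = sum(1 for r in records if r.expected_findings)
    data = tmp_path / "data.csv"
    write_fixture_files(records, data, tmp_path / "truth.csv", dictionary)
    summary = run_batch(BatchConfig(data))
    assert injected == int(n * fraction)
    assert summary.findings_by_rule.get("R1", 0) == injected
    assert summary.records_invalid == injected
    assert summary.records_valid == n - injected


def test_multiple_primary_pass_flags_duplicates(tmp_path):
    rows = [
        full_row(patient_id="PY", tumour_id="Y1", topography="C339",
                 morphology="8550", basis_of_diagnosis="7"),
        full_row(patient_id="PY", tumour_id="Y2", topography="C349",
                 morphology="8140", basis_of_diagnosis="7"),
        full_row(patient_id="PY", tumour_id="Y3", topography="C189",
                 morphology="8936", basis_of_diagnosis="7"),
    ]
    path = tmp_path / "mp.csv"
    write_csv(path, rows)
    summary = run_batch(BatchConfig(path, check_multiple_primaries=True))
    assert summary.findings_by_rule.get("mp-duplicate-suspect") == 1
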