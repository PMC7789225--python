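"""Grouping-based multiple-primary detection."""
import itertools
import random

import pytest

from crcheck.findings import Severity
from crcheck.multiple_primary import (PatientCaseSet, detect_multiple_primaries)
from crcheck.terminology import GroupTable

from conftest import make_record


def case(tumour_id, topo, morph, patient="PY"):
    return make_record(patient_id=patient, tumour_id=tumour_id,
                       topography=topo, morphology=morph, behaviour="3")


@pytest.fixture(scope="module")
def group_table():
    import crcheck
    return crcheck.load_default_terminology().group_table


def test_worked_three_case_example(group_table):
    """C33/8550 and C34/8140 share both site and histology groups (one
    primary); C18/8936 is independent."""
    pcs = PatientCaseSet("PY", (case("Y1", "C33", "8550"),
                                case("Y2", "C34", "8140"),
                                case("Y3", "C18", "8936")))
    partition = detect_multiple_primaries(pcs, group_table)
    assert partition.groups == (("Y1", "Y2"), ("Y3",))
    duplicates = [f for f in partition.findings
                  if f.severity == Severity.WARNING]
    assert len(duplicates) == 1
    assert duplicates[0].record_ref == ("PY", "Y1+Y2")


def test_shipped_group_assignments(group_table):
    assert group_table.topography_group("C33") == group_table.topography_group("C34")
    assert group_table.morphology_group("8550") == group_table.morphology_group("8140")
    assert group_table.topography_group("C18") != group_table.topography_group("C33")
    assert group_table.morphology_group("8936") != group_table.morphology_group("8550")
    # four-character codes resolve through their site prefix
    assert group_table.topography_group("C349") == group_table.topography_group("C33")


def test_single_case_is_one_group_without_findings(group_table):
    pcs = PatientCaseSet("PY", (case("Y1", "C33", "8550"),))
    partition = detect_multiple_primaries(pcs, group_table)
    assert partition.groups == (("Y1",),)
    assert partition.findings == ()


def test_unknown_codes_form_singletons_with_unconfirmed_finding(group_table):
    pcs = PatientCaseSet("PY", (case("Y1", "C33", "8550"),
                                case("Y2", "C33", "9992")))  # unmapped histology
    partition = detect_multiple_primaries(pcs, group_table)
    assert partition.groups == (("Y1",), ("Y2",))
    unconfirmed = [f for f in partition.findings
                   if f.severity == Severity.UNCONFIRMED]
    assert len(unconfirmed) == 1 and unconfirmed[0].record_ref == ("PY", "Y2")


def test_partition_invariant_under_reordering(group_table):
    cases = (case("Y1", "C33", "8550"), case("Y2", "C34", "8140"),
             case("Y3", "C18", "8936"), case("Y4", "C181", "8140"))
    expected = detect_multiple_primaries(PatientCaseSet("PY", cases),
                                         group_table).groups
    for perm in itertools.permutations(cases):
        got = detect_multiple_primaries(PatientCaseSet("PY", perm),
                                        group_table).groups
        assert got == expected


def naive_partition(cases, gt):
    """Oracle: transitive closure of pairwise same-group merges."""
    ids = sorted(c.tumour_id for c in cases)
    by_id = {c.tumour_id: c for c in cases}

    def key(cid):
        c = by_id[cid]
        tg = gt.topography_group(c.topography or "")
        mg = gt.morphology_group(c.morphology or "")
        return None if tg is None or mg is None else (tg, mg)

    groups = [{i} for i in ids]
    changed = True
    while changed:
        changed = False
        for a, b in itertools.combinations(range(len(groups)), 2):
            if any(key(x) is not None and key(x) == key(y)
                   for x in groups[a] for y in groups[b]):
                groups[a] |= groups[b]
                del groups[b]
                changed = True
                break
    return tuple(sorted(tuple(sorted(g)) for g in groups))


def test_random_case_sets_match_transitive_closure_oracle(group_table):
    rng = random.Random(99)
    topos = ["C33", "C34", "C18", "C20", "C64", "C679", "C44", "C999"]
    morphs = ["8550", "8140", "8936", "8720", "8070", "9992"]
    for _ in range(150):
        n = rng.randint(1, 6)
        cases = tuple(case(f"Y{i}", rng.choice(topos), rng.choice(morphs))
                      for i in range(n))
        partition = detect_multiple_primaries(PatientCaseSet("PY", cases),
                                              group_table)
        assert tuple(sorted(partition.groups)) == naive_partition(cases,
                                                                  group_table)


def test_same_group_relation_is_an_equivalence(group_table):
    """Groups partition the case set: disjoint, exhaustive, order-free."""
    cases = tuple(case(f"Y{i}", t, m) for i, (t, m) in enumerate(
        [("C33", "8550"), ("C34", "8140"), ("C33", "8140"), ("C18", "8140")]))
    partition = detect_multiple_primaries(PatientCaseSet("PY", cases),
                                          group_table)
    flat = [cid for g in partition.groups for cid in g]
    assert sorted(flat) == sorted(c.tumour_id for c in cases)
    assert len(flat) == len(set(flat))


def test_patient_case_set_invariants():
    with pytest.raises(ValueError):
        PatientCaseSet("PY", ())
    with pytest.raises(ValueError):
        PatientCaseSet("PY", (case("Y1", "C33", "8550", patient="OTHER"),))
    with pytest.raises(ValueError):
        PatientCaseSet("PY", (case("Y1", "C33", "8550"),
                              case("Y1", "C34", "8140")))
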