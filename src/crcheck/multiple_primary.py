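"""Multiple-primary tumour detection.

All registered cases of one patient are partitioned into independent
primaries: two cases belong to the same primary when their topography codes
fall in the same site group AND their morphology codes fall in the same
histology group (the grouping tables shipped with the terminology). Groups
with more than one case are flagged as suspected duplicates - undetected
multiple registrations of a single cancer skew incidence statistics.

Only the grouping-based mechanism is implemented; the full international
multiple-primary rules (timing windows, behaviour transitions, laterality)
are a registry-policy layer this check deliberately leaves out. Behaviour
is carried but not used for merging.
"""
from __future__ import annotations

from dataclasses import dataclass

from .core_dictionary import CancerCaseRecord
from .findings import Finding, Severity, sort_findings
from .terminology import GroupTable


@dataclass(frozen=True)
class PatientCaseSet:
    patient_id: str
    cases: tuple[CancerCaseRecord, ...]

    def __post_init__(self):
        if not self.cases:
            raise ValueError("a patient case set needs at least one case")
        for c in self.cases:
            if c.patient_id != self.patient_id:
                raise ValueError(f"case {c.tumour_id!r} belongs to another patient")
        ids = [c.tumour_id for c in self.cases]
        if len(ids) != len(set(ids)):
            raise ValueError("tumour ids must be unique within a patient")


@dataclass(frozen=True)
class PrimaryPartition:
    groups: tuple[tuple[str, ...], ...]  # each inner tuple = one primary
    findings: tuple[Finding, ...]


class _UnionFind:
    def __init__(self, items):
        self.parent = {i: i for i in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def detect_multiple_primaries(pcs: PatientCaseSet, gt: GroupTable) -> PrimaryPartition:
    """Partition a patient's cases into independent primaries.

    Cases whose topography or morphology is absent from the group tables
    cannot be assessed: each forms its own group and carries an UNCONFIRMED
    finding. The partition is invariant under case ordering.
    """
    ids = sorted(c.tumour_id for c in pcs.cases)
    by_id = {c.tumour_id: c for c in pcs.cases}
    keys: dict[str, tuple[str, str] | None] = {}
    findings: list[Finding] = []
    for cid in ids:
        c = by_id[cid]
        tg = gt.topography_group(c.topography or "")
        mg = gt.morphology_group(c.morphology or "")
        if tg is None or mg is None:
            keys[cid] = None
            missing = [n for n, g in (("topography", tg), ("morphology", mg))
                       if g is None]
            findings.append(Finding(
                (pcs.patient_id, cid), Severity.UNCONFIRMED, "mp-group-check",
                tuple(missing),
                f"case {cid}: {'/'.join(missing)} not covered by the "
                f"multiple-primary group tables; treated as independent"))
        else:
            keys[cid] = (tg, mg)

    uf = _UnionFind(ids)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            if keys[a] is not None and keys[a] == keys[b]:
                uf.union(a, b)

    grouped: dict[str, list[str]] = {}
    for cid in ids:
        grouped.setdefault(uf.find(cid), []).append(cid)
    groups = tuple(tuple(sorted(v)) for _, v in sorted(grouped.items()))

    for members in groups:
        if len(members) > 1:
            tg, mg = keys[members[0]]
            findings.append(Finding(
                (pcs.patient_id, "+".join(members)), Severity.WARNING,
                "mp-duplicate-suspect", ("topography", "morphology"),
                f"cases {', '.join(members)} share topography group {tg} and "
                f"morphology group {mg}: suspected single primary registered "
                f"{len(members)} times"))
    return PrimaryPartition(groups, tuple(sort_findings(findings)))
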