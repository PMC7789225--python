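"""Concept taxonomy for cancer-registry coding.

Holds ICD-O-3 topography and morphology concepts and their groupings, the
morphology-behaviour pairing classes, tumour types (topography grouping x
morphology-behaviour, modelled on the SEER histology/behaviour
categorisation), TNM ed.6 topography groupings with their stage-group
tables, and the site/histology group maps used by the multiple-primary
check. Everything is a named class with parent links; the parent graph is a
DAG and ancestor queries are transitive.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import yaml


class TerminologyError(ValueError):
    pass


#: allowed concept kinds
CONCEPT_KINDS = {
    "topography_code", "topography_group", "topography_grouping",
    "morphology_code", "morphology_family", "morph_behaviour",
    "morph_behaviour_group", "tumour_type", "tnm_topography_grouping",
    "stage_group", "bod_code", "behaviour_code", "grade_code", "sex_code",
    "extent_code", "vital_status_code", "record_class",
}

_ROMAN = {0: "0", 1: "I", 2: "II", 3: "III", 4: "IV"}


@dataclass(frozen=True)
class ConceptClass:
    id: str
    label: str
    kind: str
    parents: frozenset = frozenset()


@dataclass(frozen=True)
class StageGroup:
    """TNM stage group 0-IV, with an optional sub-stage suffix (a, is, A...)."""

    value: int
    sub: str | None = None

    def roman(self) -> str:
        return _ROMAN[self.value] + (self.sub or "")

    def __str__(self) -> str:
        return self.roman()


@dataclass(frozen=True)
class _StageRow:
    t: frozenset | None  # None = any
    n: frozenset | None
    m: frozenset | None
    stage: StageGroup

    def matches(self, t: str, n: str, m: str) -> bool:
        return ((self.t is None or t in self.t)
                and (self.n is None or n in self.n)
                and (self.m is None or m in self.m))


@dataclass
class _TnmGrouping:
    id: str
    label: str
    members: frozenset  # topography codes (4-char)
    t_categories: tuple[str, ...]
    n_categories: tuple[str, ...]
    m_categories: tuple[str, ...]
    rows: tuple[_StageRow, ...]


def normalise_tnm(code: str | None, axis: str) -> str | None:
    """Strip clinical/pathological prefixes; 'pT3' -> 'T3', '3' -> 'T3'."""
    if code is None or code == "":
        return None
    c = code.strip()
    if c[:1] in "cpy":
        c = c[1:]
    c = c.upper()
    if not c.startswith(axis.upper()):
        c = axis.upper() + c
    return c


class GroupTable:
    """Site and histology group maps for the multiple-primary check.

    Topography groups are keyed by three-character site prefix (``C34``);
    morphology groups are expanded from code ranges to explicit codes.
    """

    def __init__(self, topography_groups: Mapping[str, str],
                 morphology_groups: Mapping[str, str]):
        self._topo = dict(topography_groups)    # prefix or full code -> group
        self._morph = dict(morphology_groups)   # 4-digit code -> group

    def topography_group(self, code: str) -> str | None:
        if code in self._topo:
            return self._topo[code]
        return self._topo.get(code[:3])

    def morphology_group(self, code: str) -> str | None:
        return self._morph.get(str(code))


def _expand_morph_ranges(ranges: Iterable[str]) -> list[str]:
    out = []
    for r in ranges:
        r = str(r)
        if "-" in r:
            lo, hi = r.split("-")
            out.extend(str(v) for v in range(int(lo), int(hi) + 1))
        else:
            out.append(r)
    return out


def expand_topography_range(spec: str) -> list[str]:
    """``C00-C55`` or ``C73-C750`` or ``C101`` to explicit 4-char codes.

    Three-character endpoints cover all their sub-sites (C34 = C340..C349).
    """
    spec = spec.strip().upper()
    if "-" not in spec:
        if len(spec) == 3:
            return [f"{spec}{d}" for d in range(10)]
        return [spec]
    lo_s, hi_s = spec.split("-")
    lo = int(lo_s[1:]) * 10 if len(lo_s) == 3 else int(lo_s[1:])
    hi = int(hi_s[1:]) * 10 + 9 if len(hi_s) == 3 else int(hi_s[1:])
    return [f"C{v:03d}" for v in range(lo, hi + 1)]


class Terminology:
    """Queryable concept store with ancestor closure."""

    def __init__(self) -> None:
        self._concepts: dict[str, ConceptClass] = {}
        self._ancestors: dict[str, frozenset] = {}
        self._morph_behaviour: dict[tuple[str, str], str] = {}
        self._tumour_types: list[tuple[str, str, str]] = []  # (topo_group, mb, type id)
        self._topo_group_members: dict[str, frozenset] = {}
        self._tnm: dict[str, _TnmGrouping] = {}
        self.group_table = GroupTable({}, {})

    # -- construction ----------------------------------------------------
    def add_concept(self, id: str, label: str = "", kind: str = "record_class",
                    parents: Iterable[str] = ()) -> None:
        if kind not in CONCEPT_KINDS:
            raise TerminologyError(f"unknown concept kind {kind!r} for {id!r}")
        merged = frozenset(parents)
        if id in self._concepts:
            merged |= self._concepts[id].parents
        self._concepts[id] = ConceptClass(id, label or id, kind, merged)
        self._ancestors.clear()

    def ensure_concept(self, id: str, kind: str = "record_class",
                       parents: Iterable[str] = ()) -> None:
        if id not in self._concepts:
            self.add_concept(id, kind=kind, parents=parents)

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}

        def visit(node: str, path: list[str]) -> None:
            mark = state.get(node, 0)
            if mark == 1:
                cycle = path[path.index(node):] + [node]
                raise TerminologyError(f"cyclic parent links: {' -> '.join(cycle)}")
            if mark == 2:
                return
            state[node] = 1
            for p in self._concepts.get(node, ConceptClass(node, node, "record_class")).parents:
                visit(p, path + [node])
            state[node] = 2

        for cid in self._concepts:
            visit(cid, [])

    # -- queries ---------------------------------------------------------
    def has_concept(self, id: str) -> bool:
        return id in self._concepts

    def concept(self, id: str) -> ConceptClass:
        return self._concepts[id]

    @property
    def concept_ids(self) -> list[str]:
        return sorted(self._concepts)

    def ancestors(self, id: str) -> frozenset:
        """Ancestor-or-self closure; unknown ids have no ancestors."""
        if id in self._ancestors:
            return self._ancestors[id]
        if id not in self._concepts:
            return frozenset()
        seen: set[str] = set()
        stack = [id]
        while stack:
            node = stack.pop()
            if node in seen:
                continue
            seen.add(node)
            if node in self._concepts:
                stack.extend(self._concepts[node].parents)
        result = frozenset(seen)
        self._ancestors[id] = result
        return result

    def morph_behaviour(self, morphology: str, behaviour: str) -> str | None:
        """The unique morphology-behaviour class for a code pair, if classified."""
        return self._morph_behaviour.get((str(morphology), str(behaviour)))

    def topography_groups_of(self, topography: str) -> list[str]:
        out = [g for g, members in self._topo_group_members.items()
               if topography in members]
        return sorted(out)

    def tumour_type(self, topography: str, morphology: str, behaviour: str) -> str | None:
        mb = self.morph_behaviour(morphology, behaviour)
        if mb is None:
            return None
        mb_anc = self.ancestors(mb)
        groups = set(self.topography_groups_of(topography))
        hits = sorted({t for (tg, mbref, t) in self._tumour_types
                       if tg in groups and mbref in mb_anc})
        return hits[0] if hits else None

    def tnm_grouping_for(self, topography: str) -> str | None:
        hits = sorted(g.id for g in self._tnm.values() if topography in g.members)
        return hits[0] if hits else None

    def tnm_grouping_members(self, grouping_id: str) -> frozenset:
        return self._tnm[grouping_id].members

    def tnm_categories(self, grouping_id: str) -> tuple[tuple[str, ...], tuple[str, ...], tuple[str, ...]]:
        g = self._tnm[grouping_id]
        return g.t_categories, g.n_categories, g.m_categories

    @property
    def tnm_grouping_ids(self) -> list[str]:
        return sorted(self._tnm)

    def iter_valid_combinations(self, grouping_id: str):
        """All stageable (T, N, M) combinations of a grouping.

        In-situ / non-invasive categories (Tis, Ta) pair only with N0 M0 -
        an in-situ lesion has by definition neither nodal involvement nor
        metastases.
        """
        g = self._tnm[grouping_id]
        for t in g.t_categories:
            for n in g.n_categories:
                for m in g.m_categories:
                    if t in ("TIS", "TA") and (n != "N0" or m != "M0"):
                        continue
                    yield t, n, m

    def stage_group(self, grouping_id: str, t: str | None, n: str | None,
                    m: str | None) -> StageGroup | None:
        """Stage-group lookup; ``None`` means unstageable (absent combination).

        Clinical/pathological prefixes are stripped. Rows are evaluated in
        shipped table order; the first matching row wins.
        """
        if grouping_id not in self._tnm:
            raise TerminologyError(f"unknown TNM grouping {grouping_id!r}")
        t = normalise_tnm(t, "T")
        n = normalise_tnm(n, "N")
        m = normalise_tnm(m, "M")
        if t is None or n is None or m is None:
            return None
        g = self._tnm[grouping_id]
        if t not in g.t_categories or n not in g.n_categories or m not in g.m_categories:
            return None
        for row in g.rows:
            if row.matches(t, n, m):
                return row.stage
        return None


# ---------------------------------------------------------------------------
# fixture loading

def _as_code(v) -> str:
    return str(v)


def load_terminology(sources: Iterable[str | Path] | str | Path) -> Terminology:
    """Build a Terminology from one or more YAML fixture files.

    Each file may carry any subset of the sections (topography_groups,
    morphology_families, morph_behaviour_groups, morph_behaviours,
    tumour_types, tnm_groupings, mp_topography_groups,
    mp_morphology_groups, concepts); sections from several files merge.
    """
    if isinstance(sources, (str, Path)):
        p = Path(sources)
        sources = sorted(p.glob("*.yaml")) if p.is_dir() else [p]
    data: dict = {}
    for src in sources:
        with open(src, "r", encoding="utf-8") as fh:
            part = yaml.safe_load(fh) or {}
        if not isinstance(part, dict):
            raise TerminologyError(f"{src}: fixture file must be a mapping")
        for key, value in part.items():
            if isinstance(value, list):
                data.setdefault(key, []).extend(value)
            elif isinstance(value, dict):
                data.setdefault(key, {}).update(value)
            else:
                data[key] = value
    return build_terminology(data)


def build_terminology(data: Mapping) -> Terminology:
    term = Terminology()

    for entry in data.get("concepts", []):
        term.add_concept(entry["id"], entry.get("label", ""),
                         entry.get("kind", "record_class"),
                         [str(p) for p in entry.get("parents", [])])

    for grp in data.get("topography_groups", []):
        gid = grp["id"]
        term.add_concept(gid, grp.get("label", ""), "topography_group")
        members = []
        for m in grp.get("members", []):
            for code in expand_topography_range(_as_code(m)):
                members.append(code)
                term.ensure_concept(code, "topography_code")
                term.add_concept(code, code, "topography_code", [gid])
        term._topo_group_members[gid] = frozenset(members)

    for fam in data.get("morphology_families", []):
        fid = _as_code(fam["id"])
        term.add_concept(fid, fam.get("label", ""), "morphology_family")
        for code in fam.get("codes", []):
            code = _as_code(code)
            term.ensure_concept(code, "morphology_code")
            term.add_concept(code, code, "morphology_code", [fid])

    for grp in data.get("morph_behaviour_groups", []):
        term.add_concept(grp["id"], grp.get("label", ""), "morph_behaviour_group")

    for mb in data.get("morph_behaviours", []):
        mbid = mb["id"]
        parents = [mb["parent"]] if mb.get("parent") else []
        term.add_concept(mbid, mb.get("label", ""), "morph_behaviour", parents)
        key = (_as_code(mb["morphology"]), _as_code(mb["behaviour"]))
        if key in term._morph_behaviour:
            raise TerminologyError(f"duplicate morph-behaviour pair {key}")
        term._morph_behaviour[key] = mbid

    for tt in data.get("tumour_types", []):
        tid = tt["id"]
        term.add_concept(tid, tt.get("label", ""), "tumour_type")
        term._tumour_types.append((tt["topography_group"], tt["morph_behaviour"], tid))

    for grp in data.get("tnm_groupings", []):
        gid = grp["id"]
        term.add_concept(gid, grp.get("label", ""), "tnm_topography_grouping")
        members = frozenset(code for m in grp.get("members", [])
                            for code in expand_topography_range(_as_code(m)))
        rows = []
        for row in grp.get("stages", []):
            def cats(v):
                if v is None or v == "ANY":
                    return None
                vals = v if isinstance(v, list) else [v]
                return frozenset(str(x).upper() for x in vals)
            stage = StageGroup(int(row["stage"]), row.get("sub"))
            rows.append(_StageRow(cats(row.get("t", "ANY")), cats(row.get("n", "ANY")),
                                  cats(row.get("m", "ANY")), stage))
            sg_id = f"{gid}Stage{stage.roman()}"
            term.ensure_concept(sg_id, "stage_group", [gid])
        term._tnm[gid] = _TnmGrouping(
            gid, grp.get("label", ""), members,
            tuple(str(x).upper() for x in grp.get("t_categories", [])),
            tuple(str(x).upper() for x in grp.get("n_categories", [])),
            tuple(str(x).upper() for x in grp.get("m_categories", [])),
            tuple(rows))

    topo_map: dict[str, str] = {}
    for gid, prefixes in data.get("mp_topography_groups", {}).items():
        term.ensure_concept(gid, "topography_grouping")
        for p in prefixes:
            topo_map[_as_code(p).upper()] = gid
    morph_map: dict[str, str] = {}
    for gid, ranges in data.get("mp_morphology_groups", {}).items():
        term.ensure_concept(gid, "morph_behaviour_group")
        for code in _expand_morph_ranges(ranges):
            morph_map[code] = gid
    term.group_table = GroupTable(topo_map, morph_map)

    term._check_acyclic()
    return term
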