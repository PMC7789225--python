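"""Restricted description-logic core.

The validation scenarios only ever need a small fragment of OWL DL:
conjunctions of named classes (atoms), enumerated value restrictions on
record attributes (``in``/``not-in`` code sets), and integer intervals
(age). Axioms are SubClassOf, DisjointClasses and EquivalentClass (defined
classes) over such expressions. This module decides structural subsumption,
disjointness-based consistency and classification for that fragment, with
finite attribute domains read closed-world, and produces minimal axiom-level
explanations for inconsistencies.

The decision procedure is a structural closure with case-splitting: the
constraint state of an expression is closed under the hard axioms of the
TBox; whenever an axiom antecedent *partially* overlaps the state's allowed
value set for some attribute, the state is split along that boundary so that
at every leaf each axiom either definitely applies or definitely does not.
Over finite domains this is equivalent to exhaustive model enumeration while
staying cheap on realistic record expressions (singleton value sets never
split).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING, Iterable, Mapping, Union

if TYPE_CHECKING:  # pragma: no cover
    from .terminology import Terminology


class UnknownConceptError(KeyError):
    """An expression or axiom references a concept id absent from the terminology."""


class UnknownAttributeError(KeyError):
    """An expression restricts an attribute with no declared domain."""


# ---------------------------------------------------------------------------
# intervals

@dataclass(frozen=True)
class Interval:
    """Closed integer interval; ``None`` means unbounded at that end."""

    lo: int | None = None
    hi: int | None = None

    @property
    def is_empty(self) -> bool:
        return self.lo is not None and self.hi is not None and self.lo > self.hi

    def intersect(self, other: "Interval") -> "Interval":
        lo = self.lo if other.lo is None else (other.lo if self.lo is None else max(self.lo, other.lo))
        hi = self.hi if other.hi is None else (other.hi if self.hi is None else min(self.hi, other.hi))
        return Interval(lo, hi)

    def issubset(self, other: "Interval") -> bool:
        if self.is_empty:
            return True
        if other.lo is not None and (self.lo is None or self.lo < other.lo):
            return False
        if other.hi is not None and (self.hi is None or self.hi > other.hi):
            return False
        return True

    def difference(self, other: "Interval") -> list["Interval"]:
        """Parts of self not covered by other (0, 1 or 2 intervals)."""
        if self.is_empty:
            return []
        out: list[Interval] = []
        if other.lo is not None:
            left = Interval(self.lo, other.lo - 1)
            if not left.is_empty and (self.hi is None or other.lo - 1 <= self.hi):
                lo, hi = left.lo, min(h for h in (left.hi, self.hi) if h is not None)
                cand = Interval(lo, hi)
                if not cand.is_empty:
                    out.append(cand)
        if other.hi is not None:
            lo = other.hi + 1 if self.lo is None else max(self.lo, other.hi + 1)
            right = Interval(lo, self.hi)
            if not right.is_empty:
                out.append(right)
        return out

    def contains(self, value: int) -> bool:
        return (self.lo is None or value >= self.lo) and (self.hi is None or value <= self.hi)

    def __str__(self) -> str:
        lo = "-inf" if self.lo is None else str(self.lo)
        hi = "+inf" if self.hi is None else str(self.hi)
        return f"[{lo}, {hi}]"


AllowedValues = Union[frozenset, Interval]


# ---------------------------------------------------------------------------
# class expressions

def _freeze_map(m: Mapping[str, Iterable[str]] | None) -> dict[str, frozenset]:
    return {k: frozenset(v) for k, v in (m or {}).items()}


@dataclass(frozen=True)
class ClassExpression:
    """Conjunction of atoms and attribute restrictions (the record's "class")."""

    atoms: frozenset = frozenset()
    in_sets: Mapping[str, frozenset] = field(default_factory=dict)
    not_in_sets: Mapping[str, frozenset] = field(default_factory=dict)
    ranges: Mapping[str, Interval] = field(default_factory=dict)

    @staticmethod
    def build(atoms: Iterable[str] = (), in_sets=None, not_in_sets=None,
              ranges: Mapping[str, Interval] | None = None) -> "ClassExpression":
        return ClassExpression(
            atoms=frozenset(atoms),
            in_sets=_freeze_map(in_sets),
            not_in_sets=_freeze_map(not_in_sets),
            ranges=dict(ranges or {}),
        )

    @property
    def restricted_attrs(self) -> set[str]:
        return set(self.in_sets) | set(self.not_in_sets) | set(self.ranges)

    @property
    def is_trivial(self) -> bool:
        return not self.atoms and not self.restricted_attrs

    def conjoin(self, other: "ClassExpression") -> "ClassExpression":
        in_sets = dict(self.in_sets)
        for k, v in other.in_sets.items():
            in_sets[k] = in_sets[k] & v if k in in_sets else v
        not_in = dict(self.not_in_sets)
        for k, v in other.not_in_sets.items():
            not_in[k] = not_in[k] | v if k in not_in else v
        ranges = dict(self.ranges)
        for k, v in other.ranges.items():
            ranges[k] = ranges[k].intersect(v) if k in ranges else v
        return ClassExpression(self.atoms | other.atoms, in_sets, not_in, ranges)

    def allowed_for(self, attr: str, domain: AllowedValues) -> AllowedValues:
        """Effective value set for ``attr`` under this expression's restrictions."""
        if isinstance(domain, Interval):
            if attr in self.in_sets or attr in self.not_in_sets:
                raise UnknownAttributeError(
                    f"attribute {attr!r} is integer-valued; use ranges, not code sets")
            return domain.intersect(self.ranges.get(attr, domain))
        s = domain
        if attr in self.in_sets:
            s = s & self.in_sets[attr]
        if attr in self.not_in_sets:
            s = s - self.not_in_sets[attr]
        if attr in self.ranges:
            raise UnknownAttributeError(
                f"attribute {attr!r} is code-valued; use in/not-in sets, not ranges")
        return s


TOP = ClassExpression()


# ---------------------------------------------------------------------------
# axioms and TBox

@dataclass(frozen=True)
class Axiom:
    """One terminological axiom.

    form: "subclass" (sub ⊑ sup), "disjoint" (members pairwise disjoint; a
    single member means the member is unsatisfiable, i.e. disjoint with ⊤),
    or "equivalent" (defined ≡ definition).
    severity "WARNING" marks a soft restriction: it never participates in the
    consistency closure and is only reported as a contradiction by the
    validator.
    """

    id: str
    form: str
    sub: ClassExpression | None = None
    sup: ClassExpression | None = None
    members: tuple[ClassExpression, ...] = ()
    defined: str | None = None
    definition: ClassExpression | None = None
    severity: str = "ERROR"
    scenario: str | None = None
    guard_field: str | None = None
    guard_codes: tuple[str, ...] = ()
    message: str = ""
    provenance: str = ""

    def expressions(self) -> list[ClassExpression]:
        out = [e for e in (self.sub, self.sup, self.definition) if e is not None]
        out.extend(self.members)
        if self.defined is not None:
            out.append(ClassExpression.build(atoms=[self.defined]))
        return out


class TBox:
    """Compiled axiom base over a terminology plus attribute domains."""

    def __init__(self, axioms: Iterable[Axiom], terminology: "Terminology",
                 domains: Mapping[str, AllowedValues]):
        self.axioms: list[Axiom] = list(axioms)
        ids = [a.id for a in self.axioms]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate axiom ids: {dupes}")
        self.terminology = terminology
        self.domains: dict[str, AllowedValues] = dict(domains)
        self._check_references()

    def _check_references(self) -> None:
        for ax in self.axioms:
            for expr in ax.expressions():
                for atom in expr.atoms:
                    if not self.terminology.has_concept(atom):
                        raise UnknownConceptError(
                            f"axiom {ax.id!r} references unknown concept {atom!r}")
                for attr in expr.restricted_attrs:
                    if attr not in self.domains:
                        raise UnknownAttributeError(
                            f"axiom {ax.id!r} restricts unknown attribute {attr!r}")

    def domain(self, attr: str) -> AllowedValues:
        try:
            return self.domains[attr]
        except KeyError:
            raise UnknownAttributeError(f"no declared domain for attribute {attr!r}")

    @property
    def hard_axioms(self) -> list[Axiom]:
        return [a for a in self.axioms if a.severity != "WARNING"]

    @property
    def soft_axioms(self) -> list[Axiom]:
        return [a for a in self.axioms if a.severity == "WARNING" and a.form == "subclass"]

    @property
    def equivalents(self) -> list[Axiom]:
        return [a for a in self.axioms if a.form == "equivalent"]

    def without(self, axiom_ids: set[str]) -> "TBox":
        return TBox([a for a in self.axioms if a.id not in axiom_ids],
                    self.terminology, self.domains)


# ---------------------------------------------------------------------------
# the decision procedure

@dataclass
class _State:
    atoms: set
    allowed: dict  # attr -> frozenset | Interval (absent key = full domain)
    fired: set

    def clone(self) -> "_State":
        return _State(set(self.atoms), dict(self.allowed), set(self.fired))


@dataclass
class _Leaf:
    atoms: frozenset
    allowed: dict
    fired: frozenset
    clash: tuple[str, ...]  # axiom ids responsible for the clash; () = alive
    syntactic_clash: bool = False

    @property
    def alive(self) -> bool:
        return not self.clash and not self.syntactic_clash


def _sub_like(axioms: Iterable[Axiom]) -> list[tuple[str, ClassExpression, ClassExpression]]:
    """Expand subclass and equivalence axioms into directed implications."""
    out = []
    for ax in axioms:
        if ax.form == "subclass":
            out.append((ax.id, ax.sub, ax.sup))
        elif ax.form == "equivalent":
            atom_expr = ClassExpression.build(atoms=[ax.defined])
            out.append((ax.id, ax.definition, atom_expr))
            out.append((ax.id, atom_expr, ax.definition))
    return out


class _Engine:
    def __init__(self, tbox: TBox):
        self.tbox = tbox
        self.term = tbox.terminology
        self.implications = _sub_like(tbox.hard_axioms)
        self.disjoints = [a for a in tbox.hard_axioms if a.form == "disjoint"]

    # -- helpers ---------------------------------------------------------
    def _closure_atoms(self, atoms: Iterable[str]) -> set:
        out: set = set()
        for a in atoms:
            if not self.term.has_concept(a):
                raise UnknownConceptError(f"unknown concept {a!r}")
            out |= self.term.ancestors(a)
        return out

    def _allowed(self, state: _State, attr: str) -> AllowedValues:
        return state.allowed.get(attr) if attr in state.allowed else self.tbox.domain(attr)

    def _apply(self, state: _State, expr: ClassExpression) -> None:
        state.atoms |= self._closure_atoms(expr.atoms)
        for attr in expr.restricted_attrs:
            dom = self.tbox.domain(attr)
            cur = self._allowed(state, attr)
            new = expr.allowed_for(attr, dom)
            if isinstance(cur, Interval):
                state.allowed[attr] = cur.intersect(new)
            else:
                state.allowed[attr] = cur & new

    def _antecedent_status(self, state: _State, expr: ClassExpression):
        """FIRE / BLOCK / (PARTIAL, attr, antecedent-allowed)."""
        if not expr.atoms <= state.atoms:
            return ("BLOCK",)
        for attr in sorted(expr.restricted_attrs):
            dom = self.tbox.domain(attr)
            want = expr.allowed_for(attr, dom)
            cur = self._allowed(state, attr)
            if isinstance(cur, Interval):
                if cur.issubset(want):
                    continue
                if cur.intersect(want).is_empty:
                    return ("BLOCK",)
                return ("PARTIAL", attr, want)
            if cur <= want:
                continue
            if not (cur & want):
                return ("BLOCK",)
            return ("PARTIAL", attr, want)
        return ("FIRE",)

    def _state_empty(self, state: _State) -> bool:
        for v in state.allowed.values():
            if isinstance(v, Interval):
                if v.is_empty:
                    return True
            elif not v:
                return True
        return False

    # -- exploration -----------------------------------------------------
    def leaves(self, expr: ClassExpression) -> list[_Leaf]:
        root = _State(set(), {}, set())
        try:
            self._apply(root, expr)
        except UnknownConceptError:
            raise
        out: list[_Leaf] = []
        self._explore(root, out, depth=0)
        return out

    def _explore(self, state: _State, out: list[_Leaf], depth: int) -> None:
        if depth > 64:  # safety net; realistic rule bases stay tiny
            raise RecursionError("case-split depth exceeded")
        # close under implications
        changed = True
        while changed:
            changed = False
            if self._state_empty(state):
                fired = frozenset(i for i in state.fired if isinstance(i, str))
                out.append(_Leaf(frozenset(state.atoms), dict(state.allowed),
                                 fired, tuple(sorted(fired)),
                                 syntactic_clash=True))
                return
            for key, (ax_id, sub, sup) in enumerate(self.implications):
                if ("applied", key) in state.fired:
                    continue
                status = self._antecedent_status(state, sub)
                if status[0] == "FIRE":
                    state.fired.add(("applied", key))
                    state.fired.add(ax_id)
                    self._apply(state, sup)
                    changed = True
        if self._state_empty(state):
            out.append(_Leaf(frozenset(state.atoms), dict(state.allowed),
                             frozenset(i for i in state.fired if isinstance(i, str)),
                             tuple(sorted(i for i in state.fired if isinstance(i, str))),
                             syntactic_clash=True))
            return
        # find a split point among implication antecedents and disjoint members
        split = self._find_split(state)
        if split is not None:
            attr, want = split
            cur = self._allowed(state, attr)
            branches: list[AllowedValues] = []
            if isinstance(cur, Interval):
                inter = cur.intersect(want)
                if not inter.is_empty:
                    branches.append(inter)
                branches.extend(cur.difference(want))
            else:
                if cur & want:
                    branches.append(cur & want)
                if cur - want:
                    branches.append(cur - want)
            for b in branches:
                child = state.clone()
                child.allowed[attr] = b
                self._explore(child, out, depth + 1)
            return
        # leaf: evaluate disjointness clashes
        clash = self._clash(state)
        fired = frozenset(i for i in state.fired if isinstance(i, str))
        out.append(_Leaf(frozenset(state.atoms), dict(state.allowed), fired,
                         clash))

    def _find_split(self, state: _State):
        for _, sub, _ in self.implications:
            status = self._antecedent_status(state, sub)
            if status[0] == "PARTIAL":
                return status[1], status[2]
        for ax in self.disjoints:
            for member in ax.members:
                status = self._antecedent_status(state, member)
                if status[0] == "PARTIAL":
                    return status[1], status[2]
        return None

    def _clash(self, state: _State) -> tuple[str, ...]:
        for ax in self.disjoints:
            holding = 0
            for member in ax.members:
                if self._antecedent_status(state, member)[0] == "FIRE":
                    holding += 1
            if (len(ax.members) == 1 and holding == 1) or holding >= 2:
                fired = sorted(i for i in state.fired if isinstance(i, str))
                return tuple(dict.fromkeys(fired + [ax.id]))
        return ()

    # -- queries ---------------------------------------------------------
    def satisfies(self, leaf: _Leaf, general: ClassExpression) -> bool:
        if not self._closure_check(leaf, general.atoms):
            return False
        for attr in general.restricted_attrs:
            dom = self.tbox.domain(attr)
            want = general.allowed_for(attr, dom)
            cur = leaf.allowed.get(attr) if attr in leaf.allowed else dom
            if isinstance(cur, Interval):
                if not cur.issubset(want):
                    return False
            elif not cur <= want:
                return False
        return True

    def _closure_check(self, leaf: _Leaf, atoms: frozenset) -> bool:
        for a in atoms:
            if not self.term.has_concept(a):
                raise UnknownConceptError(f"unknown concept {a!r}")
            if a not in leaf.atoms:
                return False
        return True


# ---------------------------------------------------------------------------
# public operations

def subsumes(general: ClassExpression, specific: ClassExpression, tbox: TBox) -> bool:
    """True iff every model of ``specific`` (closed-world, finite domains,
    under the TBox's hard axioms) satisfies ``general``."""
    eng = _Engine(tbox)
    leaves = eng.leaves(specific)
    alive = [l for l in leaves if l.alive]
    return all(eng.satisfies(l, general) for l in alive)


def is_inconsistent(expr: ClassExpression, tbox: TBox) -> tuple[bool, list[str]]:
    """Hard-inconsistency check with one minimal supporting axiom set.

    Returns ``(True, axiom_ids)`` when the expression, closed under the hard
    SubClassOf/EquivalentClass axioms, hits a DisjointClasses axiom or is
    syntactically unsatisfiable; the cited set is minimal (removing any cited
    axiom restores consistency). ``(False, [])`` otherwise.
    """
    eng = _Engine(tbox)
    leaves = eng.leaves(expr)
    if any(l.alive for l in leaves):
        return False, []
    cited: set[str] = set()
    for l in leaves:
        cited |= set(l.clash) | set(l.fired)
    return True, _minimise(expr, tbox, cited)


def _still_inconsistent(expr: ClassExpression, tbox: TBox) -> bool:
    eng = _Engine(tbox)
    return not any(l.alive for l in eng.leaves(expr))


def _minimise(expr: ClassExpression, tbox: TBox, cited: set[str]) -> list[str]:
    keep = set(cited)
    for ax_id in sorted(cited):
        trial = keep - {ax_id}
        reduced = tbox.without(set(a.id for a in tbox.axioms) - trial)
        if _still_inconsistent(expr, reduced):
            keep = trial
    return sorted(keep)


def minimal_explanations(expr: ClassExpression, tbox: TBox, limit: int = 16) -> list[list[str]]:
    """All minimal axiom sets supporting the inconsistency (hitting-set tree).

    Empty list when the expression is consistent. A syntactically
    unsatisfiable expression yields one empty explanation.
    """
    inconsistent, first = is_inconsistent(expr, tbox)
    if not inconsistent:
        return []
    found: list[list[str]] = [first]
    frontier: list[set[str]] = [{ax} for ax in first]
    seen_removals: set[frozenset] = set()
    while frontier and len(found) < limit:
        removal = frontier.pop(0)
        key = frozenset(removal)
        if key in seen_removals:
            continue
        seen_removals.add(key)
        reduced = tbox.without(removal)
        inc, expl = is_inconsistent(expr, reduced)
        if not inc:
            continue
        if expl not in found:
            found.append(expl)
        for ax in expl:
            frontier.append(removal | {ax})
    return found


def classify(expr: ClassExpression, tbox: TBox) -> frozenset:
    """Named subsumers of a consistent expression.

    All defined classes whose definitions subsume the expression, the
    terminology ancestors of those classes, and the ancestors of the
    expression's asserted atoms.
    """
    eng = _Engine(tbox)
    result: set = set()
    for atom in expr.atoms:
        result |= eng._closure_atoms([atom])
    for ax in tbox.equivalents:
        if subsumes(ClassExpression.build(atoms=[ax.defined]), expr, tbox):
            result |= eng._closure_atoms([ax.defined])
    return frozenset(result)


def most_specific(concept_ids: Iterable[str], terminology: "Terminology") -> list[str]:
    """Drop every concept that is a strict ancestor of another in the set."""
    ids = set(concept_ids)
    out = []
    for c in ids:
        if any(c != other and c in terminology.ancestors(other) for other in ids):
            continue
        out.append(c)
    return sorted(out)
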