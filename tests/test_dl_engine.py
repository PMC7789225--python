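"""Description-logic core: structural subsumption, consistency,
classification and explanations, cross-checked against exhaustive
finite-model enumeration on small random axiom bases."""
import itertools
import random

import pytest

from crcheck.dl_engine import (Axiom, ClassExpression, Interval, TBox,
                               UnknownConceptError, classify, is_inconsistent,
                               minimal_explanations, subsumes)
from crcheck.terminology import Terminology

CE = ClassExpression.build


# ---------------------------------------------------------------------------
# small hand-built world

def tiny_terminology(n_atoms=5, edges=()):
    term = Terminology()
    for i in range(n_atoms):
        term.add_concept(f"A{i}", kind="record_class")
    for child, parent in edges:
        term.add_concept(f"A{child}", kind="record_class", parents=[f"A{parent}"])
    return term


def tiny_tbox(axioms=(), n_atoms=5, edges=(), domains=None):
    term = tiny_terminology(n_atoms, edges)
    dom = {"x": frozenset("abc"), "y": frozenset("pqr"), "age": Interval(0, 4)}
    if domains:
        dom.update(domains)
    return TBox(axioms, term, dom)


def test_subsumption_of_enumerated_sets():
    tbox = tiny_tbox(domains={"morphology": frozenset(
        str(c) for c in range(8000, 9990))})
    general = CE(in_sets={"morphology": {"8000", "8720", "9140", "9590", "9800"}})
    specific = CE(in_sets={"morphology": {"8720"}})
    assert subsumes(general, specific, tbox)
    assert not subsumes(specific, general, tbox)


def test_subsumption_is_reflexive():
    tbox = tiny_tbox()
    exprs = [CE(), CE(atoms=["A0"]), CE(in_sets={"x": {"a"}}),
             CE(atoms=["A1"], in_sets={"x": {"a", "b"}}, not_in_sets={"y": {"p"}},
                ranges={"age": Interval(1, 3)})]
    for e in exprs:
        assert subsumes(e, e, tbox)


def test_subsumption_is_transitive_on_samples():
    tbox = tiny_tbox(edges=[(1, 0), (2, 1)])
    rng = random.Random(11)
    exprs = [_random_expr(rng, 3) for _ in range(24)]
    for a, b, c in itertools.islice(itertools.permutations(exprs, 3), 600):
        if subsumes(a, b, tbox) and subsumes(b, c, tbox):
            assert subsumes(a, c, tbox)


def test_unknown_concept_is_an_error():
    tbox = tiny_tbox()
    with pytest.raises(UnknownConceptError, match="Nope"):
        subsumes(CE(atoms=["Nope"]), CE(), tbox)


def test_inconsistency_via_single_member_disjoint():
    """An in-situ record with a non-histology basis of diagnosis is an
    empty class; correcting the behaviour restores consistency."""
    r1 = Axiom(id="R1", form="disjoint", members=(
        CE(in_sets={"x": {"a"}}, not_in_sets={"y": {"p", "q"}}),))
    tbox = tiny_tbox([r1])
    bad = CE(in_sets={"x": {"a"}, "y": {"r"}})
    inconsistent, explanation = is_inconsistent(bad, tbox)
    assert inconsistent and explanation == ["R1"]
    good = CE(in_sets={"x": {"a"}, "y": {"p"}})
    assert is_inconsistent(good, tbox) == (False, [])


def test_empty_expression_is_consistent():
    tbox = tiny_tbox()
    assert is_inconsistent(CE(), tbox) == (False, [])


def test_syntactically_unsatisfiable_expression():
    tbox = tiny_tbox()
    expr = CE(in_sets={"x": {"a"}}, not_in_sets={"x": {"a", "b", "c"}})
    inconsistent, explanation = is_inconsistent(expr, tbox)
    assert inconsistent and explanation == []


def test_classification_with_defined_class():
    ax = Axiom(id="D1", form="equivalent", defined="A0",
               definition=CE(in_sets={"x": {"a", "b"}}))
    tbox = tiny_tbox([ax])
    assert "A0" in classify(CE(in_sets={"x": {"a"}}), tbox)
    assert "A0" not in classify(CE(in_sets={"x": {"a", "c"}}), tbox)
    assert classify(CE(in_sets={"y": {"p"}}), tbox) == frozenset()


def test_classification_is_monotone_in_defined_classes():
    """Adding an EquivalentClass axiom never removes previous subsumers."""
    ax1 = Axiom(id="D1", form="equivalent", defined="A0",
                definition=CE(in_sets={"x": {"a", "b"}}))
    ax2 = Axiom(id="D2", form="equivalent", defined="A1",
                definition=CE(in_sets={"x": {"a"}}))
    expr = CE(in_sets={"x": {"a"}})
    before = classify(expr, tiny_tbox([ax1]))
    after = classify(expr, tiny_tbox([ax1, ax2]))
    assert before <= after


def test_explanations_are_minimal():
    """Within the cited axiom set, removing any axiom removes the clash."""
    sub = Axiom(id="S1", form="subclass", sub=CE(in_sets={"x": {"a"}}),
                sup=CE(atoms=["A1"]))
    dis = Axiom(id="D1", form="disjoint",
                members=(CE(atoms=["A1"]), CE(atoms=["A2"])))
    other = Axiom(id="S9", form="subclass", sub=CE(in_sets={"y": {"p"}}),
                  sup=CE(atoms=["A3"]))
    tbox = tiny_tbox([sub, dis, other])
    expr = CE(atoms=["A2"], in_sets={"x": {"a"}})
    for explanation in minimal_explanations(expr, tbox):
        assert set(explanation) == {"S1", "D1"}
        for dropped in explanation:
            remaining = {a.id for a in tbox.axioms} - (
                {a.id for a in tbox.axioms} - set(explanation)) - {dropped}
            reduced = TBox([a for a in tbox.axioms if a.id in remaining],
                           tbox.terminology, tbox.domains)
            assert not is_inconsistent(expr, reduced)[0]


# ---------------------------------------------------------------------------
# exhaustive finite-model oracle

def _random_expr(rng, n_atoms, allow_atoms=True):
    atoms = []
    if allow_atoms and rng.random() < 0.5:
        atoms = rng.sample([f"A{i}" for i in range(n_atoms)],
                           rng.randint(1, min(2, n_atoms)))
    in_sets, not_in, ranges = {}, {}, {}
    for attr, dom in (("x", "abc"), ("y", "pqr")):
        roll = rng.random()
        if roll < 0.35:
            in_sets[attr] = frozenset(rng.sample(dom, rng.randint(1, len(dom))))
        elif roll < 0.55:
            not_in[attr] = frozenset(rng.sample(dom, rng.randint(1, 2)))
    if rng.random() < 0.4:
        lo = rng.randint(0, 4)
        ranges["age"] = Interval(lo, rng.randint(lo, 4))
    return CE(atoms, in_sets, not_in, ranges)


def _random_tbox(rng, n_atoms=5):
    edges = [(i, rng.randrange(i)) for i in range(1, n_atoms)
             if rng.random() < 0.5]
    axioms = []
    for k in range(rng.randint(1, 3)):
        axioms.append(Axiom(id=f"S{k}", form="subclass",
                            sub=_random_expr(rng, n_atoms),
                            sup=_random_expr(rng, n_atoms)))
    if rng.random() < 0.6:
        members = tuple(_random_expr(rng, n_atoms)
                        for _ in range(rng.randint(1, 2)))
        axioms.append(Axiom(id="DJ", form="disjoint", members=members))
    if rng.random() < 0.5:
        axioms.append(Axiom(id="EQ", form="equivalent",
                            defined=f"A{rng.randrange(n_atoms)}",
                            definition=_random_expr(rng, n_atoms,
                                                    allow_atoms=False)))
    return tiny_tbox(axioms, n_atoms=n_atoms, edges=edges)


def _models(tbox):
    """All (atom-set, assignment) pairs satisfying every hard axiom."""
    term = tbox.terminology
    atoms = [c for c in term.concept_ids]
    domains = {"x": sorted(tbox.domains["x"]), "y": sorted(tbox.domains["y"]),
               "age": list(range(tbox.domains["age"].lo,
                                 tbox.domains["age"].hi + 1))}

    def sat(expr, held, asgn):
        if not expr.atoms <= held:
            return False
        for attr, allowed in expr.in_sets.items():
            if asgn[attr] not in allowed:
                return False
        for attr, excluded in expr.not_in_sets.items():
            if asgn[attr] in excluded:
                return False
        for attr, iv in expr.ranges.items():
            if not iv.contains(asgn[attr]):
                return False
        return True

    for bits in itertools.product([0, 1], repeat=len(atoms)):
        held = frozenset(a for a, b in zip(atoms, bits) if b)
        if any(not term.ancestors(a) <= held for a in held):
            continue  # must be closed under the hierarchy
        for x in domains["x"]:
            for y in domains["y"]:
                for age in domains["age"]:
                    asgn = {"x": x, "y": y, "age": age}
                    ok = True
                    for ax in tbox.hard_axioms:
                        if ax.form == "subclass":
                            if sat(ax.sub, held, asgn) and not sat(ax.sup, held, asgn):
                                ok = False
                        elif ax.form == "disjoint":
                            n_hit = sum(sat(m, held, asgn) for m in ax.members)
                            if (len(ax.members) == 1 and n_hit) or n_hit >= 2:
                                ok = False
                        else:
                            if sat(ax.definition, held, asgn) != (ax.defined in held):
                                ok = False
                        if not ok:
                            break
                    if ok:
                        yield held, asgn, sat


def oracle_inconsistent(expr, tbox):
    return not any(sat(expr, held, asgn) for held, asgn, sat in _models(tbox))


def oracle_subsumes(general, specific, tbox):
    for held, asgn, sat in _models(tbox):
        if sat(specific, held, asgn) and not sat(general, held, asgn):
            return False
    return True


def test_engine_agrees_with_model_enumeration():
    """600 random axiom bases: structural subsumption and inconsistency
    equal brute-force enumeration over all closed-world interpretations."""
    rng = random.Random(2024)
    checked = 0
    for _ in range(600):
        tbox = _random_tbox(rng)
        e1 = _random_expr(rng, 5)
        e2 = _random_expr(rng, 5)
        assert is_inconsistent(e1, tbox)[0] == oracle_inconsistent(e1, tbox)
        assert subsumes(e1, e2, tbox) == oracle_subsumes(e1, e2, tbox)
        assert subsumes(e2, e1, tbox) == oracle_subsumes(e2, e1, tbox)
        checked += 1
    assert checked == 600
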