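"""OWL 2 functional-style syntax export and re-import.

Every concept gets a declaration with a stable IRI derived from its id;
every compiled rule becomes one annotated axiom (rule id, severity,
scenario and guard metadata as axiom annotations), so the exported document
can be re-imported and re-compiled into an equivalent axiom base. Hard
empty-class rules are exported as DisjointClasses over the offending
intersection and owl:Thing.

Only the fragment this engine emits is parsed back; the importer is not a
general OWL parser.
"""
from __future__ import annotations

import re
from pathlib import Path

from .dl_engine import Axiom, ClassExpression, Interval, TBox
from .rulebase import attribute_domains
from .terminology import Terminology

IRI_BASE = "https://crcheck.example.org/onto#"

_DATA_PROPERTIES = ("sex", "topography", "morphology", "behaviour", "grade",
                    "bod", "extent", "vital_status", "t", "n", "m", "age")


def _name(concept_id: str) -> str:
    # IRIs must not carry spaces; concept ids are tokens already
    return ":" + re.sub(r"[^A-Za-z0-9_.-]", "_", concept_id)


def _literal_set(values) -> str:
    return "DataOneOf(" + " ".join(f'"{v}"' for v in sorted(values)) + ")"


def _expr_to_owl(expr: ClassExpression) -> str:
    parts: list[str] = []
    for atom in sorted(expr.atoms):
        parts.append(_name(atom))
    for attr in sorted(expr.in_sets):
        parts.append(f"DataSomeValuesFrom(:{attr} {_literal_set(expr.in_sets[attr])})")
    for attr in sorted(expr.not_in_sets):
        parts.append(f"DataSomeValuesFrom(:{attr} "
                     f"DataComplementOf({_literal_set(expr.not_in_sets[attr])}))")
    for attr in sorted(expr.ranges):
        iv = expr.ranges[attr]
        facets = []
        if iv.lo is not None:
            facets.append(f'xsd:minInclusive "{iv.lo}"^^xsd:integer')
        if iv.hi is not None:
            facets.append(f'xsd:maxInclusive "{iv.hi}"^^xsd:integer')
        parts.append(f"DataSomeValuesFrom(:{attr} "
                     f"DatatypeRestriction(xsd:integer {' '.join(facets)}))")
    if not parts:
        return "owl:Thing"
    if len(parts) == 1:
        return parts[0]
    return "ObjectIntersectionOf(" + " ".join(parts) + ")"


def _annotations(ax: Axiom) -> str:
    items = [f'Annotation(:ruleId "{ax.id}")',
             f'Annotation(:severity "{ax.severity}")']
    if ax.scenario:
        items.append(f'Annotation(:scenario "{ax.scenario}")')
    if ax.guard_field:
        items.append(f'Annotation(:guardField "{ax.guard_field}")')
    if ax.guard_codes:
        items.append(f'Annotation(:guardCodes "{"|".join(ax.guard_codes)}")')
    return " ".join(items)


def export_owl(term: Terminology, tbox: TBox, path: str | Path) -> int:
    """Write the terminology and compiled rules; returns the rule-axiom count."""
    lines = [
        f"Prefix(:=<{IRI_BASE}>)",
        "Prefix(owl:=<http://www.w3.org/2002/07/owl#>)",
        "Prefix(xsd:=<http://www.w3.org/2001/XMLSchema#>)",
        f"Ontology(<{IRI_BASE.rstrip('#')}>",
    ]
    for cid in term.concept_ids:
        lines.append(f"Declaration(Class({_name(cid)}))")
    for prop in _DATA_PROPERTIES:
        lines.append(f"Declaration(DataProperty(:{prop}))")
    for cid in term.concept_ids:
        for parent in sorted(term.concept(cid).parents):
            lines.append(f"SubClassOf({_name(cid)} {_name(parent)})")
    count = 0
    for ax in tbox.axioms:
        ann = _annotations(ax)
        if ax.form == "disjoint":
            members = " ".join(_expr_to_owl(m) for m in ax.members)
            if len(ax.members) == 1:  # empty-class rule: disjoint with Thing
                members += " owl:Thing"
            lines.append(f"DisjointClasses({ann} {members})")
        elif ax.form == "subclass":
            lines.append(f"SubClassOf({ann} {_expr_to_owl(ax.sub)} "
                         f"{_expr_to_owl(ax.sup)})")
        else:
            lines.append(f"EquivalentClasses({ann} {_name(ax.defined)} "
                         f"{_expr_to_owl(ax.definition)})")
        count += 1
    lines.append(")")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
    return count


# ---------------------------------------------------------------------------
# re-import of the emitted fragment

_TOKEN_RE = re.compile(r"""
    (?P<func>[A-Za-z][A-Za-z0-9]*)\( |
    (?P<close>\)) |
    (?P<literal>"[^"]*"(\^\^xsd:integer)?) |
    (?P<iri><[^>]*>) |
    (?P<symbol>[A-Za-z0-9_:.\-]+)
""", re.VERBOSE)


def _tokenize(text: str):
    for m in _TOKEN_RE.finditer(text):
        kind = m.lastgroup or ("literal" if m.group("literal") else "symbol")
        for k in ("func", "close", "literal", "iri", "symbol"):
            if m.group(k):
                yield k, m.group(k)
                break


class _Parser:
    def __init__(self, text: str):
        self.tokens = list(_tokenize(text))
        self.pos = 0

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else (None, None)

    def next(self):
        tok = self.peek()
        self.pos += 1
        return tok

    def parse_node(self):
        kind, value = self.next()
        if kind == "func":
            children = []
            while self.peek()[0] != "close":
                children.append(self.parse_node())
            self.next()  # consume close
            return (value, children)
        return (kind, value)


def _strip_name(symbol: str) -> str:
    return symbol[1:] if symbol.startswith(":") else symbol


def _literal_value(tok: str) -> str:
    return tok.split('"')[1]


def _node_to_expr(node) -> ClassExpression:
    kind, payload = node
    if kind == "symbol":
        if payload == "owl:Thing":
            return ClassExpression()
        return ClassExpression.build(atoms=[_strip_name(payload)])
    if kind == "ObjectIntersectionOf":
        expr = ClassExpression()
        for child in payload:
            expr = expr.conjoin(_node_to_expr(child))
        return expr
    if kind == "DataSomeValuesFrom":
        prop_node, range_node = payload
        attr = _strip_name(prop_node[1])
        rkind, rpayload = range_node
        if rkind == "DataOneOf":
            values = frozenset(_literal_value(c[1]) for c in rpayload)
            return ClassExpression.build(in_sets={attr: values})
        if rkind == "DataComplementOf":
            inner = rpayload[0]
            values = frozenset(_literal_value(c[1]) for c in inner[1])
            return ClassExpression.build(not_in_sets={attr: values})
        if rkind == "DatatypeRestriction":
            lo = hi = None
            children = rpayload
            i = 1  # skip xsd:integer symbol
            while i + 1 < len(children) + 1 and i < len(children):
                facet = children[i][1]
                value = int(_literal_value(children[i + 1][1]))
                if facet.endswith("minInclusive"):
                    lo = value
                elif facet.endswith("maxInclusive"):
                    hi = value
                i += 2
            return ClassExpression.build(ranges={attr: Interval(lo, hi)})
    raise ValueError(f"unsupported class expression node: {kind}")


def import_owl(path: str | Path, terminology: Terminology) -> TBox:
    """Rebuild the axiom base from an exported document.

    Concept declarations and hierarchy edges are assumed to live in the
    supplied terminology; rule axioms are identified by their ruleId
    annotation.
    """
    parser = _Parser(Path(path).read_text(encoding="utf-8"))
    axioms: list[Axiom] = []
    while parser.peek()[0] is not None:
        node = parser.parse_node()
        kind, payload = node
        if kind != "Ontology":
            continue
        for child in payload:
            ckind, cpayload = child
            if ckind not in {"SubClassOf", "DisjointClasses", "EquivalentClasses"}:
                continue
            meta = {}
            body = []
            for sub in cpayload:
                if sub[0] == "Annotation":
                    key = _strip_name(sub[1][0][1])
                    meta[key] = _literal_value(sub[1][1][1])
                else:
                    body.append(sub)
            if "ruleId" not in meta:
                continue  # terminology hierarchy edge
            guard_codes = tuple(meta.get("guardCodes", "").split("|")) \
                if meta.get("guardCodes") else ()
            common = dict(id=meta["ruleId"], severity=meta.get("severity", "ERROR"),
                          scenario=meta.get("scenario"),
                          guard_field=meta.get("guardField"),
                          guard_codes=guard_codes)
            if ckind == "DisjointClasses":
                members = [b for b in body
                           if not (b[0] == "symbol" and b[1] == "owl:Thing")]
                axioms.append(Axiom(form="disjoint",
                                    members=tuple(_node_to_expr(m) for m in members),
                                    **common))
            elif ckind == "SubClassOf":
                axioms.append(Axiom(form="subclass", sub=_node_to_expr(body[0]),
                                    sup=_node_to_expr(body[1]), **common))
            else:
                defined = _strip_name(body[0][1])
                axioms.append(Axiom(form="equivalent", defined=defined,
                                    definition=_node_to_expr(body[1]), **common))
    return TBox(axioms, terminology, attribute_domains())
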