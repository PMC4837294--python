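"""Knowledge-level drug expressions, code resolution and SPARQL emission.

A clinical question rarely starts from drug codes.  It starts from
expressions like "drugs classified as renin angiotensin inhibitors",
"drugs causing leukopenia at a frequency of 30% or higher" or "atypical
antipsychotics with a 5HT2C or H1 inhibitory effect".  This module resolves
such expressions against the materialized drug knowledge graph into the
set of local drug codes that actually appear in RXE-2 of the medication
orders, and emits the equivalent SPARQL 1.1 text in two forms:

* the federation form, where the knowledge subpattern is wrapped in a
  ``SERVICE`` clause targeting the knowledge endpoint while the clinical
  triple patterns stay outside it;
* the conventional form, where the resolved codes are enumerated literally
  in a ``FILTER ... IN`` expression.

Over the same merged data the two forms return identical rows; they differ
only in where code resolution happens.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import Iterable, Optional, Sequence, Union

from rdflib import Graph, Literal, RDF, RDFS, URIRef
from rdflib.plugins.sparql import prepareQuery

from .linked_drug_data import DRUG, DrugKnowledgeGraph, class_uri
from .rdf_conversion import DEFAULT_BASE, vocab_namespace

__all__ = [
    "ByClass",
    "ByAde",
    "ByClassAndTarget",
    "DrugExpression",
    "CodeSet",
    "TemplateError",
    "resolve",
    "emit_sparql",
    "enumerate_filter_sparql",
    "knowledge_pattern",
    "merge_graphs",
    "run_select",
    "CLINICAL_TEMPLATES",
]


class TemplateError(KeyError):
    """Unknown clinical query template."""


@dataclass(frozen=True)
class ByClass:
    """Drugs classified under a classification-scheme class (and below)."""

    scheme: str
    cls: str
    by_label: bool = True


@dataclass(frozen=True)
class ByAde:
    """Drugs whose side-effect record matches any of the preferred terms at
    or above a frequency threshold (fraction of [0, 1])."""

    terms: tuple[str, ...]
    min_frequency: float
    freq_bound: str = "upper"  # which SIDER-style bound the threshold tests

    def __init__(self, terms: Union[str, Sequence[str]], min_frequency: float, freq_bound: str = "upper"):
        if isinstance(terms, str):
            terms = (terms,)
        object.__setattr__(self, "terms", tuple(t.strip().casefold() for t in terms))
        if not (0.0 <= min_frequency <= 1.0):
            raise ValueError("min_frequency must be a fraction in [0, 1]")
        if freq_bound not in ("upper", "lower"):
            raise ValueError("freq_bound must be 'upper' or 'lower'")
        object.__setattr__(self, "min_frequency", float(min_frequency))
        object.__setattr__(self, "freq_bound", freq_bound)


@dataclass(frozen=True)
class ByClassAndTarget:
    """Class resolution narrowed to compounds hitting any of the targets."""

    scheme: str
    cls: str
    targets: frozenset[str]
    by_label: bool = True

    def __init__(self, scheme: str, cls: str, targets: Iterable[str], by_label: bool = True):
        object.__setattr__(self, "scheme", scheme)
        object.__setattr__(self, "cls", cls)
        object.__setattr__(self, "targets", frozenset(targets))
        object.__setattr__(self, "by_label", by_label)


DrugExpression = Union[ByClass, ByAde, ByClassAndTarget]


@dataclass
class CodeSet:
    """Resolved local drug codes with their resolution path per code."""

    codes: frozenset[str]
    provenance: dict[str, list[tuple[str, ...]]] = dc_field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.codes)

    def __iter__(self):
        return iter(sorted(self.codes))

    def __contains__(self, code: str) -> bool:
        return code in self.codes


def _find_classes(kg: DrugKnowledgeGraph, scheme: str, cls: str, by_label: bool) -> set[URIRef]:
    g = kg.graph
    if not by_label:
        c = class_uri(cls)
        return {c} if (c, DRUG.scheme, None) in g else set()
    want = cls.strip().casefold()
    out: set[URIRef] = set()
    for s in g.subjects(DRUG.scheme, Literal(scheme)):
        for label in g.objects(s, RDFS.label):
            if str(label).strip().casefold() == want:
                out.add(s)  # type: ignore[arg-type]
    return out


def _compounds_of_class(kg: DrugKnowledgeGraph, cls: URIRef) -> set[URIRef]:
    g = kg.graph
    compounds = set(g.subjects(RDF.type, DRUG.Compound))
    return {s for s in g.subjects(RDF.type, cls) if s in compounds}


def _codes_of_compound(kg: DrugKnowledgeGraph, compound: URIRef) -> set[str]:
    g = kg.graph
    out: set[str] = set()
    for code_res in g.subjects(DRUG.mapsTo, compound):
        for v in g.objects(code_res, DRUG.codeValue):
            out.add(str(v))
    return out


def resolve(expr: DrugExpression, kg: DrugKnowledgeGraph) -> CodeSet:
    """Resolve a drug expression to the set of local codes.

    Requires a materialized graph: subclass transitivity and instance
    propagation are assumed to be explicit, so "all drugs under class C"
    is exactly "all compounds typed C".  An unknown class or term yields an
    empty CodeSet with a warning, mirroring SPARQL no-match semantics.
    """
    if not kg.materialized:
        raise ValueError("knowledge graph must be materialized before resolution")
    g = kg.graph
    chains: list[tuple[str, URIRef]] = []  # (head-of-chain description, compound)

    if isinstance(expr, (ByClass, ByClassAndTarget)):
        classes = _find_classes(kg, expr.scheme, expr.cls, expr.by_label)
        if not classes:
            warnings.warn(f"unknown class {expr.cls!r} in scheme {expr.scheme!r}; empty code set")
            return CodeSet(frozenset())
        compounds: set[URIRef] = set()
        for c in sorted(classes, key=str):
            for k in _compounds_of_class(kg, c):
                compounds.add(k)
                chains.append((str(c), k))
        if isinstance(expr, ByClassAndTarget):
            keep = {
                k for k in compounds
                if {str(t) for t in g.objects(k, DRUG.target)} & expr.targets
            }
            compounds = keep
            chains = [(head, k) for head, k in chains if k in keep]
    elif isinstance(expr, ByAde):
        bound_pred = DRUG.freqUpper if expr.freq_bound == "upper" else DRUG.freqLower
        compounds = set()
        for rec in sorted(g.subjects(RDF.type, DRUG.SideEffectRecord), key=str):
            terms = {str(t).strip().casefold() for t in g.objects(rec, DRUG.adeTerm)}
            if not (terms & set(expr.terms)):
                continue
            freqs = [float(v) for v in g.objects(rec, bound_pred)]
            if not freqs or max(freqs) < expr.min_frequency:
                continue
            for about in g.objects(rec, DRUG.about):
                if (about, RDF.type, DRUG.Compound) in g:
                    compounds.add(about)  # type: ignore[arg-type]
                    chains.append((str(rec), about))  # type: ignore[arg-type]
                else:
                    for k in _compounds_of_class(kg, about):  # type: ignore[arg-type]
                        compounds.add(k)
                        chains.append((f"{rec}|{about}", k))
        if not compounds:
            warnings.warn(f"no side-effect record matches terms {expr.terms}; empty code set")
            return CodeSet(frozenset())
    else:  # pragma: no cover - exhaustive over the union
        raise TypeError(f"unsupported expression {type(expr).__name__}")

    codes: set[str] = set()
    provenance: dict[str, list[tuple[str, ...]]] = {}
    for head, k in chains:
        for code in _codes_of_compound(kg, k):
            codes.add(code)
            provenance.setdefault(code, []).append((head, str(k), code))
    return CodeSet(frozenset(codes), provenance)


# --------------------------------------------------------------------------
# SPARQL emission


_PREFIXES = """\
PREFIX rdf: <http://www.w3.org/1999/02/22-rdf-syntax-ns#>
PREFIX rdfs: <http://www.w3.org/2000/01/rdf-schema#>
PREFIX xsd: <http://www.w3.org/2001/XMLSchema#>
PREFIX v: <{vocab}>
PREFIX d: <{drug_vocab}>
"""


def _sparql_str(s: str) -> str:
    return '"' + s.replace("\\", "\\\\").replace('"', '\\"') + '"'


def knowledge_pattern(expr: DrugExpression) -> str:
    """The knowledge-graph subpattern binding ``?code`` for an expression."""
    if isinstance(expr, ByClass) or isinstance(expr, ByClassAndTarget):
        if expr.by_label:
            head = (
                f"?class d:scheme {_sparql_str(expr.scheme)} ;\n"
                f"           rdfs:label ?clabel .\n"
                f"    FILTER(LCASE(STR(?clabel)) = LCASE({_sparql_str(expr.cls)}))"
            )
        else:
            head = f"VALUES ?class {{ <{class_uri(expr.cls)}> }}"
        lines = [
            head,
            "?compound a ?class, d:Compound .",
        ]
        if isinstance(expr, ByClassAndTarget):
            targets = ", ".join(_sparql_str(t) for t in sorted(expr.targets))
            lines += [
                "?compound d:target ?target .",
                f"FILTER(STR(?target) IN ({targets}))",
            ]
        lines += [
            "?codeRes d:mapsTo ?compound ;",
            "         d:codeValue ?code .",
        ]
        return "\n    ".join(lines)
    if isinstance(expr, ByAde):
        terms = ", ".join(_sparql_str(t) for t in expr.terms)
        bound = "d:freqUpper" if expr.freq_bound == "upper" else "d:freqLower"
        return "\n    ".join(
            [
                "?rec a d:SideEffectRecord ;",
                "     d:adeTerm ?term ;",
                f"     {bound} ?freq ;",
                "     d:about ?about .",
                f"FILTER(LCASE(STR(?term)) IN ({terms}))",
                f"FILTER(?freq >= {expr.min_frequency})",
                "{ ?compound a ?about . ?about d:scheme ?aboutScheme . }",
                "UNION",
                "{ BIND(?about AS ?compound) . ?about a d:Compound . }",
                "?compound a d:Compound .",
                "?codeRes d:mapsTo ?compound ;",
                "         d:codeValue ?code .",
            ]
        )
    raise TypeError(f"unsupported expression {type(expr).__name__}")


_ORDER_PATTERN = """\
?msg a v:RDE_O11 ;
       v:PATIENT ?pt .
  ?pt v:PID ?pid .
  ?pid v:PID.3 ?pidf .
  ?pidf v:CX.1 ?patient_id .
  ?msg v:ORDER ?order .
  ?order v:RXE ?rxe .
  ?rxe v:RXE.2 ?rxe2 .
  ?rxe2 v:CE.1 ?ocode .
  ?order v:TQ1 ?tq .
  ?tq v:TQ1.7 ?tq7 .
  ?tq7 v:TS.1 ?odate .
  ?tq v:TQ1.6 ?tq6 .
  ?tq6 v:CQ.1 ?days ."""

_LAB_PATTERN = """\
?lmsg{sfx} a v:OUL_R22 ;
       v:PATIENT ?lpt{sfx} .
  ?lpt{sfx} v:PID ?lpid{sfx} .
  ?lpid{sfx} v:PID.3 ?lpidf{sfx} .
  ?lpidf{sfx} v:CX.1 ?patient_id .
  ?lmsg{sfx} v:RESULT ?res{sfx} .
  ?res{sfx} v:OBX ?obx{sfx} .
  ?obx{sfx} v:OBX.3 ?obx3{sfx} .
  ?obx3{sfx} v:CE.1 ?tcode{sfx} .
  ?obx{sfx} v:OBX.5 ?obx5{sfx} .
  ?obx5{sfx} v:NM.1 ?value{sfx} .
  ?obx{sfx} v:OBX.14 ?obx14{sfx} .
  ?obx14{sfx} v:TS.1 ?tdate{sfx} ."""


def _comparator(op: str) -> str:
    try:
        return {"le": "<=", "ge": ">=", "lt": "<", "gt": ">"}[op]
    except KeyError:
        raise ValueError(f"unknown comparator {op!r}") from None


def _predicate_filter(predicates: Sequence, sfx: str = "") -> str:
    """Disjunction over event predicates (objects with test_code,
    comparator, threshold attributes)."""
    clauses = [
        f"(STR(?tcode{sfx}) = {_sparql_str(p.test_code)} && "
        f"?value{sfx} {_comparator(p.comparator)} {p.threshold})"
        for p in predicates
    ]
    return "FILTER(" + " || ".join(clauses) + ")"


def _knowledge_block(expr: Optional[DrugExpression], endpoint: Optional[str], codes: Optional[CodeSet]) -> str:
    if expr is not None:
        pattern = knowledge_pattern(expr)
        if endpoint:
            return f"SERVICE <{endpoint}> {{\n    {pattern}\n  }}\n  FILTER(STR(?ocode) = STR(?code))"
        return f"{pattern}\n  FILTER(STR(?ocode) = STR(?code))"
    assert codes is not None
    if not codes.codes:
        raise ValueError("cannot enumerate an empty code set in a FILTER")
    listed = ", ".join(_sparql_str(c) for c in sorted(codes.codes))
    return f"FILTER(STR(?ocode) IN ({listed}))"


def _template_all_orders(knowledge: str, **_: object) -> str:
    return (
        "SELECT DISTINCT ?patient_id ?order ?ocode ?odate\n"
        "WHERE {\n"
        f"  {knowledge}\n"
        f"  {_ORDER_PATTERN}\n"
        "}\n"
        "ORDER BY ?patient_id ?odate ?order"
    )


def _template_during_each_period(knowledge: str, predicates: Sequence = (), **_: object) -> str:
    if not predicates:
        raise ValueError("during_each_period requires at least one event predicate")
    return (
        "SELECT DISTINCT ?patient_id ?order ?obx\n"
        "WHERE {\n"
        f"  {knowledge}\n"
        f"  {_ORDER_PATTERN}\n"
        f"  {_LAB_PATTERN.format(sfx='')}\n"
        f"  {_predicate_filter(predicates)}\n"
        "  FILTER(?tdate >= ?odate && ?tdate <= ?odate + "
        'STRDT(CONCAT("P", STR(xsd:integer(?days) - 1), "D"), xsd:dayTimeDuration))\n'
        "}\n"
        "ORDER BY ?patient_id ?order ?obx"
    )


def _template_between_initial_final(
    knowledge: str,
    predicates: Sequence = (),
    window_days: int = 0,
    **_: object,
) -> str:
    if not predicates:
        raise ValueError("between_initial_final requires at least one event predicate")
    exclusion = ""
    if window_days:
        exclusion = (
            "  FILTER NOT EXISTS {\n"
            f"    {_LAB_PATTERN.format(sfx='X')}\n"
            f"    {_predicate_filter(predicates, sfx='X')}\n"
            f'    FILTER(?tdateX >= ?first - "P{int(window_days)}D"^^xsd:dayTimeDuration '
            "&& ?tdateX < ?first)\n"
            "  }\n"
        )
    return (
        "SELECT DISTINCT ?patient_id ?obx ?first ?last\n"
        "WHERE {\n"
        "  {\n"
        "    SELECT ?patient_id (MIN(?odate) AS ?first) (MAX(?odate) AS ?last)\n"
        "    WHERE {\n"
        f"      {knowledge}\n"
        f"      {_ORDER_PATTERN}\n"
        "    }\n"
        "    GROUP BY ?patient_id\n"
        "  }\n"
        f"  {_LAB_PATTERN.format(sfx='')}\n"
        f"  {_predicate_filter(predicates)}\n"
        "  FILTER(?tdate >= ?first && ?tdate <= ?last)\n"
        f"{exclusion}"
        "}\n"
        "ORDER BY ?patient_id ?obx"
    )


CLINICAL_TEMPLATES = {
    "all_orders": _template_all_orders,
    "during_each_period": _template_during_each_period,
    "between_initial_final": _template_between_initial_final,
}


def _assemble(
    knowledge: str,
    clinical_pattern: str,
    clinical_base: str,
    **params: object,
) -> str:
    try:
        template = CLINICAL_TEMPLATES[clinical_pattern]
    except KeyError:
        raise TemplateError(f"unknown clinical template {clinical_pattern!r}") from None
    body = template(knowledge, **params)
    prefixes = _PREFIXES.format(vocab=vocab_namespace(clinical_base), drug_vocab=str(DRUG))
    return prefixes + body + "\n"


def emit_sparql(
    expr: DrugExpression,
    endpoint: Optional[str],
    clinical_pattern: str,
    clinical_base: str = DEFAULT_BASE,
    **params: object,
) -> str:
    """Emit the federation-form SPARQL for an expression.

    With ``endpoint`` set, the knowledge subpattern is wrapped in a
    ``SERVICE <endpoint>`` clause; with ``endpoint=None`` the same
    subpattern is inlined, which evaluates identically over a merged graph
    that contains the knowledge triples (the form used for local
    execution, since no remote endpoint is dereferenced in-process).
    Templates: ``all_orders``, ``during_each_period`` (needs
    ``predicates``), ``between_initial_final`` (needs ``predicates`` and
    optional ``window_days``).
    """
    return _assemble(_knowledge_block(expr, endpoint, None), clinical_pattern, clinical_base, **params)


def enumerate_filter_sparql(
    codes: CodeSet,
    clinical_pattern: str,
    clinical_base: str = DEFAULT_BASE,
    **params: object,
) -> str:
    """Emit the conventional form enumerating resolved codes in a FILTER."""
    return _assemble(_knowledge_block(None, None, codes), clinical_pattern, clinical_base, **params)


def validate_sparql(query: str) -> bool:
    """Syntax-check a query with rdflib's SPARQL parser."""
    prepareQuery(query)
    return True


def merge_graphs(*graphs: Union[Graph, DrugKnowledgeGraph]) -> Graph:
    """Union several graphs into one in-memory graph."""
    merged = Graph()
    for g in graphs:
        if isinstance(g, DrugKnowledgeGraph):
            g = g.graph
        for t in g:
            merged.add(t)
    return merged


def run_select(query: str, graph: Graph) -> list[tuple]:
    """Execute a SELECT and return sorted result rows as string tuples."""
    rows = []
    for binding in graph.query(query):
        rows.append(tuple("" if v is None else str(v) for v in binding))
    return sorted(rows)
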