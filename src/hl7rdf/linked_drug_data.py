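"""Cross-linked drug knowledge: classifications, compounds, side effects,
local codes, and RDFS subclass materialization.

The knowledge side of the ADE queries mirrors the shape of the public drug
resources a hospital would link: two classification hierarchies (an
ATC-like anatomical/chemical scheme and a USP-like therapeutic scheme,
both expressed with ``rdfs:subClassOf``), a compound resource carrying
molecular targets (KEGG-like), side-effect records with MedDRA-style
preferred terms and lower/upper frequency bounds (SIDER-like), and the
local drug terminology whose codes appear in RXE-2 of the medication
orders (MEDIS-DRUG-like).

Sources are tidy CSV/TSV tables rather than the native dumps of the real
databases: the linked structure, not dump parsing, is what the queries
need.  Compound-to-class membership is asserted with ``rdf:type`` so that
the two RDFS rules used here — subclass transitivity and instance
propagation to superclasses — make every compound reachable from every
ancestor class once the closure is materialized in advance.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional, Union

import pandas as pd
from rdflib import Graph, Literal, Namespace, RDF, RDFS, URIRef
from rdflib.namespace import XSD
from urllib.parse import quote

__all__ = [
    "DRUG",
    "KB",
    "LoadError",
    "ValidationError",
    "CycleError",
    "DrugKnowledgeGraph",
    "load_sources",
    "materialize_subclass_closure",
    "validate_links",
    "LinkReport",
]

KB = Namespace("http://drugdata.example.org/kb/")
DRUG = Namespace("http://drugdata.example.org/vocab#")


class LoadError(ValueError):
    """Referential integrity violation while loading source tables."""


class ValidationError(ValueError):
    """A row violates a value constraint (e.g. frequency outside [0, 1])."""


class CycleError(ValueError):
    """subClassOf edges contain a cycle."""

    def __init__(self, cycle: list[URIRef]):
        self.cycle = cycle
        super().__init__("subClassOf cycle: " + " -> ".join(str(c) for c in cycle))


def class_uri(class_id: str) -> URIRef:
    return KB["class/" + quote(str(class_id), safe="._-~:")]


def compound_uri(compound_id: str) -> URIRef:
    return KB["compound/" + quote(str(compound_id), safe="._-~:")]


def code_uri(code: str) -> URIRef:
    return KB["code/" + quote(str(code), safe="._-~:")]


@dataclass
class LinkReport:
    """Report-only integrity findings over a loaded knowledge graph."""

    dangling: list[str] = dc_field(default_factory=list)
    unlinked_compounds: list[str] = dc_field(default_factory=list)
    codes_without_compound: list[str] = dc_field(default_factory=list)

    @property
    def clean(self) -> bool:
        return not (self.dangling or self.unlinked_compounds or self.codes_without_compound)

    def __len__(self) -> int:
        return len(self.dangling) + len(self.unlinked_compounds) + len(self.codes_without_compound)


@dataclass
class DrugKnowledgeGraph:
    """An rdflib graph of the linked drug data plus a materialization flag."""

    graph: Graph
    materialized: bool = False

    def __len__(self) -> int:
        return len(self.graph)

    def classes(self) -> set[URIRef]:
        return {s for s in self.graph.subjects(DRUG.scheme, None)}  # type: ignore[misc]

    def compounds(self) -> set[URIRef]:
        return set(self.graph.subjects(RDF.type, DRUG.Compound))  # type: ignore[arg-type]


def _read_table(path_or_frame: Union[str, Path, pd.DataFrame]) -> pd.DataFrame:
    if isinstance(path_or_frame, pd.DataFrame):
        return path_or_frame
    path = Path(path_or_frame)
    sep = "\t" if path.suffix in (".tsv", ".tab") else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def load_sources(
    class_table: Union[str, Path, pd.DataFrame],
    compound_table: Union[str, Path, pd.DataFrame],
    sideeffect_table: Union[str, Path, pd.DataFrame],
    code_table: Union[str, Path, pd.DataFrame],
    link_table: Optional[Union[str, Path, pd.DataFrame]] = None,
) -> DrugKnowledgeGraph:
    """Build the knowledge graph from tidy tables.

    Expected columns::

        classes:     id, label, scheme, parent        (parent empty at roots)
        compounds:   id, label, targets               (targets ';'-separated)
        sideeffects: link_id, ade_term, freq_lower, freq_upper
        codes:       code, label, compound_id
        links:       compound_id, class_id            (class membership)

    Dangling references raise :class:`LoadError` naming the offending row;
    frequencies outside ``[0, 1]`` (or lower > upper) raise
    :class:`ValidationError`.
    """
    classes = _read_table(class_table)
    compounds = _read_table(compound_table)
    sideeffects = _read_table(sideeffect_table)
    codes = _read_table(code_table)
    links = _read_table(link_table) if link_table is not None else pd.DataFrame(
        columns=["compound_id", "class_id"]
    )

    g = Graph()
    class_ids = set(classes["id"])
    compound_ids = set(compounds["id"])

    for i, row in classes.iterrows():
        c = class_uri(row["id"])
        g.add((c, RDFS.label, Literal(row["label"])))
        g.add((c, DRUG.scheme, Literal(row["scheme"])))
        parent = row.get("parent", "")
        if parent:
            if parent not in class_ids:
                raise LoadError(f"classes row {i}: dangling parent {parent!r}")
            g.add((c, RDFS.subClassOf, class_uri(parent)))

    for i, row in compounds.iterrows():
        k = compound_uri(row["id"])
        g.add((k, RDF.type, DRUG.Compound))
        g.add((k, RDFS.label, Literal(row["label"])))
        for target in filter(None, str(row.get("targets", "")).split(";")):
            g.add((k, DRUG.target, Literal(target.strip())))

    for i, row in links.iterrows():
        if row["compound_id"] not in compound_ids:
            raise LoadError(f"links row {i}: dangling compound {row['compound_id']!r}")
        if row["class_id"] not in class_ids:
            raise LoadError(f"links row {i}: dangling class {row['class_id']!r}")
        g.add((compound_uri(row["compound_id"]), RDF.type, class_uri(row["class_id"])))

    for i, row in sideeffects.iterrows():
        link_id = row["link_id"]
        if link_id in class_ids:
            about = class_uri(link_id)
        elif link_id in compound_ids:
            about = compound_uri(link_id)
        else:
            raise LoadError(f"sideeffects row {i}: dangling link_id {link_id!r}")
        lo, hi = float(row["freq_lower"]), float(row["freq_upper"])
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValidationError(
                f"sideeffects row {i}: frequency bounds [{lo}, {hi}] outside 0 <= lower <= upper <= 1"
            )
        rec = KB[f"sideeffect/{i}"]
        g.add((rec, RDF.type, DRUG.SideEffectRecord))
        g.add((rec, DRUG.about, about))
        g.add((rec, DRUG.adeTerm, Literal(row["ade_term"])))
        g.add((rec, DRUG.freqLower, Literal(f"{lo}", datatype=XSD.decimal)))
        g.add((rec, DRUG.freqUpper, Literal(f"{hi}", datatype=XSD.decimal)))

    seen_codes: set[str] = set()
    for i, row in codes.iterrows():
        if row["code"] in seen_codes:
            raise LoadError(f"codes row {i}: duplicate code {row['code']!r}")
        seen_codes.add(row["code"])
        if row["compound_id"] not in compound_ids:
            raise LoadError(f"codes row {i}: dangling compound {row['compound_id']!r}")
        cd = code_uri(row["code"])
        g.add((cd, RDF.type, DRUG.LocalCode))
        g.add((cd, DRUG.codeValue, Literal(row["code"])))
        g.add((cd, RDFS.label, Literal(row["label"])))
        g.add((cd, DRUG.mapsTo, compound_uri(row["compound_id"])))

    return DrugKnowledgeGraph(graph=g)


def _subclass_edges(g: Graph) -> dict[URIRef, set[URIRef]]:
    adj: dict[URIRef, set[URIRef]] = {}
    for s, o in g.subject_objects(RDFS.subClassOf):
        adj.setdefault(s, set()).add(o)  # type: ignore[arg-type]
    return adj


def _find_cycle(adj: dict[URIRef, set[URIRef]]) -> Optional[list[URIRef]]:
    WHITE, GREY, BLACK = 0, 1, 2
    color: dict[URIRef, int] = {}
    stack_path: list[URIRef] = []

    def dfs(u: URIRef) -> Optional[list[URIRef]]:
        color[u] = GREY
        stack_path.append(u)
        for v in sorted(adj.get(u, ()), key=str):
            c = color.get(v, WHITE)
            if c == GREY:
                return stack_path[stack_path.index(v):] + [v]
            if c == WHITE:
                found = dfs(v)
                if found:
                    return found
        stack_path.pop()
        color[u] = BLACK
        return None

    for node in sorted(adj, key=str):
        if color.get(node, WHITE) == WHITE:
            found = dfs(node)
            if found:
                return found
    return None


def transitive_ancestors(adj: dict[URIRef, set[URIRef]]) -> dict[URIRef, set[URIRef]]:
    """All strict ancestors per node over the (acyclic) subclass relation."""
    memo: dict[URIRef, set[URIRef]] = {}

    def up(u: URIRef) -> set[URIRef]:
        if u in memo:
            return memo[u]
        memo[u] = set()  # placeholder; graph is acyclic so no re-entry
        anc: set[URIRef] = set()
        for p in adj.get(u, ()):
            anc.add(p)
            anc |= up(p)
        memo[u] = anc
        return anc

    for node in list(adj):
        up(node)
    return memo


def materialize_subclass_closure(kg: DrugKnowledgeGraph) -> DrugKnowledgeGraph:
    """Materialize the two RDFS rules the queries rely on.

    Adds ``(A, subClassOf, C)`` for every subclass path A -> ... -> C
    (transitivity; reflexive triples are never asserted) and propagates
    every instance's ``rdf:type`` to all superclasses of its classes.
    Idempotent; raises :class:`CycleError` listing a cycle if one exists.
    """
    g = kg.graph
    adj = _subclass_edges(g)
    cycle = _find_cycle(adj)
    if cycle:
        raise CycleError(cycle)
    anc = transitive_ancestors(adj)
    for node, ancestors in anc.items():
        for a in ancestors:
            g.add((node, RDFS.subClassOf, a))
    hierarchy_nodes = set(adj) | {a for s in adj.values() for a in s}
    for inst, cls in list(g.subject_objects(RDF.type)):
        if cls in hierarchy_nodes:
            for a in anc.get(cls, ()):  # type: ignore[arg-type]
                g.add((inst, RDF.type, a))
    kg.materialized = True
    return kg


def validate_links(kg: DrugKnowledgeGraph) -> LinkReport:
    """Report dangling links, unlinked compounds and orphan codes."""
    g = kg.graph
    report = LinkReport()
    classes = kg.classes()
    compounds = kg.compounds()
    for cmp_ in sorted(compounds, key=str):
        classed = any(o in classes for o in g.objects(cmp_, RDF.type))
        coded = any(True for _ in g.subjects(DRUG.mapsTo, cmp_))
        if not classed and not coded:
            report.unlinked_compounds.append(str(cmp_))
    for code in sorted(g.subjects(RDF.type, DRUG.LocalCode), key=str):
        targets = list(g.objects(code, DRUG.mapsTo))
        if not targets:
            report.codes_without_compound.append(str(code))
        for t in targets:
            if t not in compounds:
                report.dangling.append(f"{code} mapsTo missing compound {t}")
    for rec in sorted(g.subjects(RDF.type, DRUG.SideEffectRecord), key=str):
        for about in g.objects(rec, DRUG.about):
            if about not in classes and about not in compounds:
                report.dangling.append(f"{rec} about missing entity {about}")
    return report
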