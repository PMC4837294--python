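"""Element-tree to RDF conversion with path-based URI minting.

Every element of the XML-encoded message becomes an RDF resource whose URI
is the concatenation of the message file's SS-MIX2 storage path (already
unique within a corpus) and the path of the element inside the message.
Steps for repeatable elements carry an ``_n`` occurrence suffix
(``ORDER_2``) so that repeated segment groups never collide.  Traversing
the tree yields one triple per parent-child edge, one literal triple per
leaf, and (optionally) one ``rdf:type`` triple per resource, typed by a
class named after the element.

Literal datatypes follow the advance mapping: numeric content to
``xsd:decimal``, dates to ``xsd:date``, timestamps to ``xsd:dateTime`` and
everything else to ``xsd:string``.  HL7 DT/TS lexical forms
(``YYYYMMDD[HHMM[SS]]``) are normalized to ISO 8601 at conversion time;
unparseable values raise rather than silently demoting to string.

Because the amount of RDF produced from a full message is dominated by
segments irrelevant to clinical research (MSH above all), conversion is
driven by an include list of segments and optional field indices.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Iterator, Mapping, Optional, Sequence, Union
from urllib.parse import quote

import yaml
from rdflib import Graph, Literal, Namespace, RDF, URIRef
from rdflib.namespace import XSD

from .hl7_model import HL7Message, MessageStructure, default_registry, iter_messages
from .xml_encoding import ElementNode, FieldTypeMap, default_field_types, encode_message

__all__ = [
    "ConversionConfig",
    "ConversionError",
    "NamingError",
    "DEFAULT_BASE",
    "DEFAULT_DATATYPE_RULES",
    "vocab_namespace",
    "build_uri",
    "map_datatype",
    "convert_tree",
    "convert_message",
    "convert_directory",
    "serialize_graph",
    "write_graph",
    "count_law",
]

DEFAULT_BASE = "http://hospital.example.org/ssmix2"

# Leaf-tag (or base-token) -> xsd datatype. Full component tags take
# precedence over base tokens, so the numeric first component of a CQ
# quantity maps to decimal while other CQ components stay strings.
DEFAULT_DATATYPE_RULES: dict[str, URIRef] = {
    "NM": XSD.decimal,
    "DT": XSD.date,
    "TS": XSD.dateTime,
    "CQ.1": XSD.decimal,
}


class ConversionError(ValueError):
    """Literal content does not parse under its declared HL7 datatype."""


class NamingError(ValueError):
    """An element path cannot be rendered as a legal URI."""


@dataclass
class ConversionConfig:
    """What to convert and where the URIs live.

    ``include`` maps segment id to a list of field indices (None = all
    fields of that segment).  Segments not listed produce no triples at
    all — the default keeps the clinically relevant subset of the
    medication-order/lab-result profile and drops MSH entirely.
    """

    base_namespace: str = DEFAULT_BASE
    include: Optional[dict[str, Optional[list[int]]]] = None
    emit_type_triples: bool = True
    datatype_rules: dict[str, URIRef] = dc_field(default_factory=lambda: dict(DEFAULT_DATATYPE_RULES))

    def __post_init__(self) -> None:
        if self.include is not None and not self.include:
            raise ValueError("include list must be non-empty (omit it to convert everything)")

    def includes_segment(self, segment_id: str) -> bool:
        return self.include is None or segment_id in self.include

    def includes_field(self, segment_id: str, field_index: int) -> bool:
        if self.include is None:
            return True
        fields = self.include.get(segment_id)
        return fields is None or field_index in fields

    @classmethod
    def clinical_default(cls, base_namespace: str = DEFAULT_BASE) -> "ConversionConfig":
        """Patient id, order (code/dose/timing) and numeric-result fields."""
        return cls(
            base_namespace=base_namespace,
            include={
                "PID": [3, 7, 8],
                "ORC": [1, 2],
                "RXE": [2, 3, 5],
                "TQ1": [6, 7, 8],
                "OBR": [1, 3, 4, 7],
                "OBX": [2, 3, 5, 6, 14],
            },
        )

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "ConversionConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        rules = dict(DEFAULT_DATATYPE_RULES)
        for tok, name in (data.get("datatype_rules") or {}).items():
            rules[tok] = XSD[name]
        return cls(
            base_namespace=data.get("base_namespace", DEFAULT_BASE),
            include=data.get("include"),
            emit_type_triples=bool(data.get("emit_type_triples", True)),
            datatype_rules=rules,
        )


def vocab_namespace(base: str) -> Namespace:
    """Predicate/class namespace, kept apart from instance URIs."""
    return Namespace(base.rstrip("/") + "/vocab#")


_URI_OK = re.compile(r"^[A-Za-z][A-Za-z0-9+.-]*://\S+$")
_STEP_SAFE = "._-~"


def _render_step(name: str, occurrence: int, repeatable: bool) -> str:
    step = f"{name}_{occurrence}" if repeatable else name
    encoded = quote(step, safe=_STEP_SAFE)
    if not encoded:
        raise NamingError(f"empty path step from element {name!r}")
    return encoded


def build_uri(
    base: str,
    storage_path: str,
    element_path: Sequence[tuple],
) -> URIRef:
    """Mint the URI of an element from its storage path and element path.

    ``element_path`` is a sequence of ``(name, occurrence)`` or
    ``(name, occurrence, repeatable)`` steps.  Steps of repeatable elements
    are suffixed ``name_occurrence`` so that a group occurring twice yields
    two distinct URIs; non-repeatable steps carry the bare name.  All path
    segments are percent-encoded.
    """
    parts = [quote(p, safe=_STEP_SAFE) for p in Path(storage_path).parts if p not in ("/", "")]
    for step in element_path:
        name, occ = step[0], step[1]
        repeatable = step[2] if len(step) > 2 else False
        if occ < 1:
            raise NamingError(f"occurrence must be >= 1 (element {name!r})")
        parts.append(_render_step(name, occ, repeatable))
    uri = base.rstrip("/") + "/" + "/".join(parts)
    if not _URI_OK.match(uri):
        raise NamingError(f"cannot form a legal absolute URI from {uri!r}")
    return URIRef(uri)


_TS_RE = re.compile(r"^(\d{4})(\d{2})(\d{2})(?:(\d{2})(\d{2})?(\d{2})?)?$")
_DT_RE = re.compile(r"^(\d{4})(\d{2})(\d{2})$")


def _normalize_ts(text: str) -> str:
    m = _TS_RE.match(text.strip())
    if not m:
        raise ValueError(f"not an HL7 timestamp: {text!r}")
    y, mo, d, hh, mi, ss = m.groups()
    return f"{y}-{mo}-{d}T{hh or '00'}:{mi or '00'}:{ss or '00'}"


def _normalize_dt(text: str) -> str:
    m = _DT_RE.match(text.strip())
    if not m:
        raise ValueError(f"not an HL7 date: {text!r}")
    y, mo, d = m.groups()
    return f"{y}-{mo}-{d}"


def map_datatype(
    hl7_type: str,
    text: str,
    rules: Optional[Mapping[str, URIRef]] = None,
    element_path: str = "",
) -> Literal:
    """Map an HL7-typed text value to a typed RDF literal.

    ``hl7_type`` may be a full component tag (``TS.1``, ``CQ.1``) or a bare
    token (``TS``); full tags take precedence in the rules.  Values that do
    not parse under a numeric/temporal rule raise :class:`ConversionError`
    carrying the element path — they are never demoted to plain strings.
    """
    rules = rules if rules is not None else DEFAULT_DATATYPE_RULES
    base = hl7_type.split(".", 1)[0]
    dtype = rules.get(hl7_type, rules.get(base, XSD.string))
    try:
        if dtype == XSD.decimal:
            float(text)  # lexical check; Literal keeps the exact lexical form
            return Literal(text.strip(), datatype=XSD.decimal)
        if dtype == XSD.date:
            return Literal(_normalize_dt(text), datatype=XSD.date)
        if dtype == XSD.dateTime:
            return Literal(_normalize_ts(text), datatype=XSD.dateTime)
    except ValueError as exc:
        where = f" at {element_path}" if element_path else ""
        raise ConversionError(f"cannot map {text!r} as {hl7_type}{where}: {exc}") from exc
    return Literal(text, datatype=XSD.string)


def convert_tree(
    root: ElementNode,
    storage_path: str,
    config: Optional[ConversionConfig] = None,
    graph: Optional[Graph] = None,
) -> Graph:
    """Convert one message's element tree into an RDF graph.

    For every internal node N with child C, emits
    ``(uri(N), vocab:C.name, uri(C))``; for every leaf, a typed-literal
    triple; and, when ``emit_type_triples`` is on, ``rdf:type`` for every
    resource node, typed by ``vocab:name``.  Nodes under segments/fields
    outside the include list produce nothing.
    """
    config = config or ConversionConfig()
    vocab = vocab_namespace(config.base_namespace)
    g = graph if graph is not None else Graph(identifier=URIRef(
        build_uri(config.base_namespace, storage_path, [])))

    def visit(node: ElementNode, path: tuple, uri: URIRef) -> None:
        if config.emit_type_triples:
            g.add((uri, RDF.type, vocab[quote(node.name, safe=_STEP_SAFE)]))
        for child in node.children:
            # Segment ids are 3-character tokens; group names (PATIENT,
            # ORDER, RESULT) and the root message type are longer.
            if not child.is_leaf and "." in child.name:
                seg, idx = child.name.rsplit(".", 1)
                if not config.includes_field(seg, int(idx)):
                    continue
            elif len(child.name) == 3 and "." not in child.name:
                if not config.includes_segment(child.name):
                    continue
            pred = vocab[quote(child.name, safe=_STEP_SAFE)]
            if child.is_leaf:
                lit = map_datatype(
                    child.name,
                    child.text or "",
                    config.datatype_rules,
                    element_path="/".join(n for n, _, _ in path) + "/" + child.name,
                )
                g.add((uri, pred, lit))
            else:
                cpath = path + ((child.name, child.occurrence, child.repeatable),)
                curi = build_uri(config.base_namespace, storage_path, cpath)
                g.add((uri, pred, curi))
                visit(child, cpath, curi)

    rpath = ((root.name, root.occurrence, root.repeatable),)
    ruri = build_uri(config.base_namespace, storage_path, rpath)
    visit(root, rpath, ruri)
    return g


def convert_message(
    msg: HL7Message,
    config: Optional[ConversionConfig] = None,
    registry: Optional[Mapping[str, MessageStructure]] = None,
    types: Optional[FieldTypeMap] = None,
) -> Graph:
    """Parse-tree -> element tree -> RDF for one message."""
    registry = registry or default_registry()
    types = types or default_field_types()
    tree = encode_message(msg, registry[msg.message_type], types)
    return convert_tree(tree, msg.storage_path, config)


def convert_directory(
    root: Union[str, Path],
    config: Optional[ConversionConfig] = None,
    registry: Optional[Mapping[str, MessageStructure]] = None,
    types: Optional[FieldTypeMap] = None,
) -> Iterator[tuple[HL7Message, Graph]]:
    """Convert every message of an SS-MIX2-style tree, in sorted path order."""
    registry = registry or default_registry()
    for msg in iter_messages(root, registry=registry):
        yield msg, convert_message(msg, config=config, registry=registry, types=types)


def serialize_graph(g: Graph, format: str = "ntriples") -> str:
    """Serialize; N-Triples output is line-sorted for byte determinism."""
    if format in ("ntriples", "nt", "nt11"):
        text = g.serialize(format="nt")
        lines = sorted(ln for ln in text.splitlines() if ln.strip())
        return "\n".join(lines) + ("\n" if lines else "")
    if format in ("turtle", "ttl"):
        return g.serialize(format="turtle")
    raise ValueError(f"unsupported serialization format {format!r}")


def write_graph(g: Graph, path: Union[str, Path], format: str = "ntriples") -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(serialize_graph(g, format), encoding="utf-8")
    return path


def count_law(root: ElementNode) -> tuple[int, int, int]:
    """(resources, leaves, expected triple count) for an unfiltered tree.

    With type triples on, an unfiltered conversion emits exactly
    ``(r - 1) + l + r`` triples: one edge per non-root resource, one
    literal per leaf, one type per resource.
    """
    r = l = 0

    def walk(n: ElementNode) -> None:
        nonlocal r, l
        if n.is_leaf:
            l += 1
        else:
            r += 1
            for c in n.children:
                walk(c)

    walk(root)
    return r, l, (r - 1) + l + r
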