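"""Hierarchical (XML-encoding style) element trees for HL7 v2.5 messages.

The ER7 form of a message does not spell out segment groups or field
metadata; the HL7 XML encoding does.  :func:`encode_message` rebuilds that
hierarchy: the root element is the message type (``RDE_O11``), group
elements (``PATIENT``, ``ORDER``, ``RESULT``) wrap their member segments
according to the message-structure grammar, each populated field becomes an
element named ``SEG.i``, and every component is wrapped in a datatype
element (``CE.1``, ``TS.1``, ``NM.1`` ...) so that downstream RDF
conversion can read the component's HL7 datatype straight off the element
name.

Datatype assignment comes from a :class:`FieldTypeMap`.  OBX-5 has no fixed
type in HL7 (it "varies" with OBX-2), which the map expresses with the
sentinel token ``VARIES`` resolved against the segment at encoding time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Mapping, Optional, Union

import yaml
from lxml import etree

from .hl7_model import HL7Message, MessageStructure, Segment, StructureNode

__all__ = [
    "ElementNode",
    "FieldType",
    "FieldTypeMap",
    "StructureError",
    "default_field_types",
    "load_field_types",
    "encode_message",
    "serialize_xml",
    "parse_xml",
]

_PRIMITIVE_TYPES = frozenset({"ST", "NM", "SI", "ID", "IS", "DT", "TM", "TS", "TX", "FT", "GTS"})


class StructureError(ValueError):
    """Segment sequence cannot be derived from the message grammar."""


@dataclass
class ElementNode:
    """A node of the hierarchical element tree.

    Leaves carry ``text``; internal nodes carry ``children`` (exclusive or).
    ``occurrence`` is the 1-based ordinal among same-named siblings and
    ``repeatable`` records whether the grammar allows this element to repeat
    (groups and segments) or the field actually repeated (``~``).
    ``repeatable`` is bookkeeping for URI minting and does not participate
    in equality.
    """

    name: str
    children: list["ElementNode"] = dc_field(default_factory=list)
    text: Optional[str] = None
    occurrence: int = 1
    repeatable: bool = dc_field(default=False, compare=False)

    def __post_init__(self) -> None:
        if (self.text is not None) and self.children:
            raise ValueError(f"element {self.name} has both text and children")

    @property
    def is_leaf(self) -> bool:
        return self.text is not None

    def find(self, name: str) -> Optional["ElementNode"]:
        for c in self.children:
            if c.name == name:
                return c
        return None

    def find_all(self, name: str) -> list["ElementNode"]:
        return [c for c in self.children if c.name == name]

    def iter_segments(self) -> list["ElementNode"]:
        """Segment-level nodes in document order (for grammar-soundness checks)."""
        out: list[ElementNode] = []

        def walk(n: ElementNode) -> None:
            for c in n.children:
                if "." in c.name or c.is_leaf:
                    continue
                if any("." in g.name or g.is_leaf for g in c.children) or not c.children:
                    out.append(c)
                else:
                    walk(c)

        walk(self)
        return out


@dataclass(frozen=True)
class FieldType:
    """HL7 datatype token of one (segment, field).

    Composite tokens (CE, CX, CQ ...) name every component element
    ``TOKEN.j``; the literal datatype of a specific component (e.g. the
    numeric CQ.1) is decided by the conversion layer's datatype rules,
    which are keyed by the full component tag.
    """

    token: str


class FieldTypeMap:
    """Map (segment_id, field_index) -> FieldType, with a string fallback."""

    def __init__(self, entries: Mapping[tuple[str, int], FieldType], default_token: str = "ST"):
        self._entries = dict(entries)
        self._default = FieldType(default_token)

    def field_type(self, segment_id: str, field_index: int, segment: Optional[Segment] = None) -> FieldType:
        ft = self._entries.get((segment_id, field_index), self._default)
        if ft.token == "VARIES":
            # Resolve against the declaring field (OBX-2 names OBX-5's type).
            tok = None
            if segment is not None:
                tok = segment.value(2, 1)
            return FieldType(tok if tok in _PRIMITIVE_TYPES else "ST")
        return ft

    def items(self):
        return self._entries.items()


def default_field_types() -> FieldTypeMap:
    """Datatypes for the fields of the supported RDE_O11/OUL_R22 profile."""
    e: dict[tuple[str, int], FieldType] = {
        ("MSH", 3): FieldType("HD"),
        ("MSH", 5): FieldType("HD"),
        ("MSH", 7): FieldType("TS"),
        ("MSH", 9): FieldType("MSG"),
        ("MSH", 10): FieldType("ST"),
        ("MSH", 11): FieldType("PT"),
        ("MSH", 12): FieldType("VID"),
        ("PID", 3): FieldType("CX"),
        ("PID", 7): FieldType("TS"),
        ("PID", 8): FieldType("IS"),
        ("ORC", 1): FieldType("ID"),
        ("ORC", 2): FieldType("EI"),
        ("ORC", 9): FieldType("TS"),
        ("RXE", 1): FieldType("TQ"),
        ("RXE", 2): FieldType("CE"),
        ("RXE", 3): FieldType("NM"),
        ("RXE", 5): FieldType("CE"),
        ("TQ1", 1): FieldType("SI"),
        ("TQ1", 6): FieldType("CQ"),
        ("TQ1", 7): FieldType("TS"),
        ("TQ1", 8): FieldType("TS"),
        ("OBR", 1): FieldType("SI"),
        ("OBR", 3): FieldType("EI"),
        ("OBR", 4): FieldType("CE"),
        ("OBR", 7): FieldType("TS"),
        ("OBX", 1): FieldType("SI"),
        ("OBX", 2): FieldType("ID"),
        ("OBX", 3): FieldType("CE"),
        ("OBX", 5): FieldType("VARIES"),
        ("OBX", 6): FieldType("CE"),
        ("OBX", 11): FieldType("ID"),
        ("OBX", 14): FieldType("TS"),
    }
    return FieldTypeMap(e)


def load_field_types(path: Union[str, Path]) -> FieldTypeMap:
    """Load a FieldTypeMap from a YAML/JSON mapping of ``SEG.i: TOKEN``."""
    text = Path(path).read_text(encoding="utf-8")
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    entries: dict[tuple[str, int], FieldType] = {}
    for key, val in data.items():
        seg, idx = key.rsplit(".", 1)
        entries[(seg, int(idx))] = FieldType(val)
    return FieldTypeMap(entries)


def _component_text(comp: list[str]) -> str:
    return "&".join(comp)


def _encode_segment(seg: Segment, types: FieldTypeMap) -> ElementNode:
    node = ElementNode(name=seg.segment_id)
    for i, f in enumerate(seg.fields, start=1):
        ft = types.field_type(seg.segment_id, i, seg)
        reps = [rep for rep in f if any(any(s for s in comp) for comp in rep)]
        repeatable = len(reps) > 1
        for occ, rep in enumerate(reps, start=1):
            fnode = ElementNode(name=f"{seg.segment_id}.{i}", occurrence=occ, repeatable=repeatable)
            for j, comp in enumerate(rep, start=1):
                text = _component_text(comp)
                if text == "":
                    continue
                fnode.children.append(ElementNode(name=f"{ft.token}.{j}", text=text))
            if fnode.children:
                node.children.append(fnode)
    return node


def _match(
    gnode: StructureNode,
    segments: list[Segment],
    pos: int,
    types: FieldTypeMap,
) -> tuple[list[ElementNode], int]:
    """Greedy left-to-right derivation of ``segments[pos:]`` from ``gnode``."""
    produced: list[ElementNode] = []
    while True:
        if gnode.is_segment:
            if pos >= len(segments) or segments[pos].segment_id != gnode.name:
                if not produced:
                    found = segments[pos].segment_id if pos < len(segments) else "<end>"
                    raise StructureError(
                        f"expected segment {gnode.name} at position {pos}, found {found}"
                    )
                return produced, pos
            seg_node = _encode_segment(segments[pos], types)
            seg_node.repeatable = gnode.repeat
            produced.append(seg_node)
            pos += 1
        else:
            first = gnode.first_segment()
            if pos >= len(segments) or segments[pos].segment_id != first:
                if not produced:
                    found = segments[pos].segment_id if pos < len(segments) else "<end>"
                    raise StructureError(
                        f"expected group {gnode.name} (starting {first}) at position {pos}, found {found}"
                    )
                return produced, pos
            group = ElementNode(name=gnode.name, repeatable=gnode.repeat)
            for child in gnode.children:
                nodes, pos = _match(child, segments, pos, types)
                group.children.extend(nodes)
            produced.append(group)
        if not gnode.repeat:
            return produced, pos
        nxt = gnode.name if gnode.is_segment else gnode.first_segment()
        if pos >= len(segments) or segments[pos].segment_id != nxt:
            return produced, pos


def _number_occurrences(node: ElementNode) -> None:
    counts: dict[str, int] = {}
    for c in node.children:
        counts[c.name] = counts.get(c.name, 0) + 1
        c.occurrence = counts[c.name]
        if not c.is_leaf and "." not in c.name:
            _number_occurrences(c)


def encode_message(
    msg: HL7Message,
    structure: MessageStructure,
    types: Optional[FieldTypeMap] = None,
) -> ElementNode:
    """Encode a parsed message as its hierarchical element tree.

    Raises :class:`StructureError` when the segment sequence cannot be
    derived from the grammar (greedy left-to-right matching, no
    backtracking).
    """
    if msg.message_type != structure.message_type:
        raise StructureError(
            f"message type {msg.message_type} does not match structure {structure.message_type}"
        )
    types = types or default_field_types()
    root = ElementNode(name=structure.message_type)
    pos = 0
    for child in structure.root.children:
        nodes, pos = _match(child, msg.segments, pos, types)
        root.children.extend(nodes)
    if pos != len(msg.segments):
        raise StructureError(
            f"trailing segment {msg.segments[pos].segment_id} at position {pos} "
            "not derivable from grammar"
        )
    _number_occurrences(root)
    return root


def _to_etree(node: ElementNode) -> etree._Element:
    el = etree.Element(node.name)
    if node.is_leaf:
        el.text = node.text
    for c in node.children:
        el.append(_to_etree(c))
    return el


def serialize_xml(root: ElementNode) -> str:
    """Deterministic XML text for an element tree (same tree, same bytes)."""
    el = _to_etree(root)
    return etree.tostring(el, encoding="unicode", pretty_print=True)


def _from_etree(el: etree._Element) -> ElementNode:
    children = [_from_etree(c) for c in el]
    if children:
        node = ElementNode(name=el.tag, children=children)
    else:
        node = ElementNode(name=el.tag, text=el.text or "")
    return node


def parse_xml(text: str) -> ElementNode:
    """Inverse of :func:`serialize_xml`; occurrences are renumbered, the
    grammar-repeatability flag is not recoverable from XML."""
    parser = etree.XMLParser(remove_blank_text=True)
    root = _from_etree(etree.fromstring(text.encode("utf-8"), parser=parser))
    if not root.children and root.text == "":
        root = ElementNode(name=root.name)
        root.text = None
    _renumber(root)
    return root


def _renumber(node: ElementNode) -> None:
    counts: dict[str, int] = {}
    for c in node.children:
        counts[c.name] = counts.get(c.name, 0) + 1
        c.occurrence = counts[c.name]
        _renumber(c)
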