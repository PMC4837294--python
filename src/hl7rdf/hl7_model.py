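"""Parsing of ER7-encoded HL7 v2.5 messages into a structured message model.

ER7 ("vertical bar") encoding is line oriented: each line is a segment, a
segment is split into fields by the field separator (``|``), a field into
repetitions (``~``), a repetition into components (``^``), and a component
into subcomponents (``&``).  The five delimiter characters are declared by
the message itself in MSH-1 and MSH-2, so a parsed message can be
re-serialized with the exact delimiters it arrived with.

Only the message structures needed for medication orders (RDE^O11) and
laboratory results (OUL^R22) ship in the default registry; further
structures can be registered from a YAML/JSON grammar file without code
changes.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import yaml

__all__ = [
    "Component",
    "Repetition",
    "Field",
    "Delimiters",
    "Segment",
    "HL7Message",
    "StructureNode",
    "MessageStructure",
    "ParseError",
    "UnsupportedMessageTypeError",
    "default_registry",
    "load_registry",
    "parse_er7",
    "parse_er7_file",
    "serialize_er7",
    "get_value",
    "iter_messages",
]

# A component is a list of subcomponent strings, a repetition a list of
# components, and a field a list of repetitions.
Component = list[str]
Repetition = list[Component]
Field = list[Repetition]

_SEGMENT_ID_RE = re.compile(r"^[A-Z][A-Z0-9]{2}$")


class ParseError(ValueError):
    """Raised when an ER7 message cannot be parsed."""


class UnsupportedMessageTypeError(ParseError):
    """Raised when MSH-9 names a message type absent from the registry."""


@dataclass(frozen=True)
class Delimiters:
    """The five ER7 delimiter characters (MSH-1 and MSH-2)."""

    field: str = "|"
    component: str = "^"
    repetition: str = "~"
    escape: str = "\\"
    subcomponent: str = "&"

    @property
    def encoding_characters(self) -> str:
        return self.component + self.repetition + self.escape + self.subcomponent


DEFAULT_DELIMITERS = Delimiters()


@dataclass
class Segment:
    """One message line: a 3-character id plus 1-based fields.

    ``fields[0]`` is HL7 field 1.  For MSH, field 1 is the field separator
    itself and field 2 the raw encoding characters, per the standard.
    """

    segment_id: str
    fields: list[Field] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not _SEGMENT_ID_RE.match(self.segment_id):
            raise ParseError(f"invalid segment id {self.segment_id!r}")

    def field_(self, index: int) -> Optional[Field]:
        """Return HL7 field ``index`` (1-based) or None when absent."""
        if index < 1:
            raise IndexError("HL7 field indices are 1-based")
        if index > len(self.fields):
            return None
        return self.fields[index - 1]

    def value(
        self,
        field_index: int,
        component_index: int = 1,
        subcomponent_index: int = 1,
        repetition: int = 1,
    ) -> Optional[str]:
        f = self.field_(field_index)
        if f is None:
            return None
        if repetition > len(f):
            return None
        rep = f[repetition - 1]
        if component_index > len(rep):
            return None
        comp = rep[component_index - 1]
        if subcomponent_index > len(comp):
            return None
        return comp[subcomponent_index - 1]


@dataclass
class HL7Message:
    """A parsed ER7 message with its SS-MIX2 storage location."""

    message_type: str
    segments: list[Segment]
    storage_path: str = ""
    delimiters: Delimiters = DEFAULT_DELIMITERS

    def __post_init__(self) -> None:
        if not self.segments or self.segments[0].segment_id != "MSH":
            raise ParseError("first segment must be MSH")
        if self.storage_path and len(Path(self.storage_path).parts) != 4:
            raise ParseError(
                "storage_path must have exactly 4 components "
                "(patientID/date/dataType/file), got "
                f"{self.storage_path!r}"
            )

    def segment(self, segment_id: str) -> Optional[Segment]:
        for seg in self.segments:
            if seg.segment_id == segment_id:
                return seg
        return None


@dataclass(frozen=True)
class StructureNode:
    """A node of a message-structure grammar: a segment or a segment group."""

    name: str
    children: tuple["StructureNode", ...] = ()
    repeat: bool = False

    @property
    def is_segment(self) -> bool:
        return not self.children

    def first_segment(self) -> str:
        node = self
        while node.children:
            node = node.children[0]
        return node.name


@dataclass(frozen=True)
class MessageStructure:
    """Grammar for one message type (tree of groups and segment ids)."""

    message_type: str
    root: StructureNode


def _grammar_node(item: Union[str, Mapping]) -> StructureNode:
    if isinstance(item, str):
        return StructureNode(name=item)
    if "segment" in item:
        return StructureNode(name=item["segment"], repeat=bool(item.get("repeat", False)))
    name = item["group"]
    children = tuple(_grammar_node(c) for c in item["children"])
    return StructureNode(name=name, children=children, repeat=bool(item.get("repeat", False)))


def structure_from_dict(message_type: str, items: Sequence) -> MessageStructure:
    root = StructureNode(name=message_type, children=tuple(_grammar_node(i) for i in items))
    return MessageStructure(message_type=message_type, root=root)


def default_registry() -> dict[str, MessageStructure]:
    """Grammars for RDE_O11 (medication order) and OUL_R22 (lab result).

    RDE_O11: MSH, PATIENT{PID}, ORDER*{ORC, RXE, TQ1*}
    OUL_R22: MSH, PATIENT{PID}, RESULT*{OBR, OBX*}
    """
    rde = structure_from_dict(
        "RDE_O11",
        [
            "MSH",
            {"group": "PATIENT", "children": ["PID"]},
            {
                "group": "ORDER",
                "repeat": True,
                "children": ["ORC", "RXE", {"segment": "TQ1", "repeat": True}],
            },
        ],
    )
    oul = structure_from_dict(
        "OUL_R22",
        [
            "MSH",
            {"group": "PATIENT", "children": ["PID"]},
            {
                "group": "RESULT",
                "repeat": True,
                "children": ["OBR", {"segment": "OBX", "repeat": True}],
            },
        ],
    )
    return {"RDE_O11": rde, "OUL_R22": oul}


def load_registry(path: Union[str, Path]) -> dict[str, MessageStructure]:
    """Load additional message structures from a YAML or JSON grammar file.

    The file maps message type to a list of grammar items, e.g.::

        RDE_O11:
          - MSH
          - group: PATIENT
            children: [PID]
          - group: ORDER
            repeat: true
            children: [ORC, RXE, {segment: TQ1, repeat: true}]
    """
    text = Path(path).read_text(encoding="utf-8")
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    return {mt: structure_from_dict(mt, items) for mt, items in data.items()}


def _unescape(text: str, d: Delimiters) -> str:
    """Decode the five basic HL7 escape sequences; pass others through."""
    if d.escape not in text:
        return text
    table = {
        "F": d.field,
        "S": d.component,
        "T": d.subcomponent,
        "R": d.repetition,
        "E": d.escape,
    }
    out: list[str] = []
    i = 0
    e = d.escape
    while i < len(text):
        ch = text[i]
        if ch == e:
            j = text.find(e, i + 1)
            if j == i + 2 and text[i + 1] in table:
                out.append(table[text[i + 1]])
                i = j + 1
                continue
            # unknown or unterminated escape: verbatim
        out.append(ch)
        i += 1
    return "".join(out)


def _escape(text: str, d: Delimiters) -> str:
    out = text.replace(d.escape, d.escape + "E" + d.escape)
    for ch, code in ((d.field, "F"), (d.component, "S"), (d.subcomponent, "T"), (d.repetition, "R")):
        out = out.replace(ch, d.escape + code + d.escape)
    return out


def _split_field(raw: str, d: Delimiters) -> Field:
    reps: Field = []
    for rep in raw.split(d.repetition):
        comps: Repetition = []
        for comp in rep.split(d.component):
            comps.append([_unescape(s, d) for s in comp.split(d.subcomponent)])
        reps.append(comps)
    return reps


def _parse_msh(line: str) -> tuple[Segment, Delimiters]:
    if len(line) < 9 or not line.startswith("MSH"):
        raise ParseError("line 1: malformed MSH segment (must begin 'MSH' + delimiters)")
    fs = line[3]
    rest = line[4:]
    enc_end = rest.find(fs)
    enc = rest if enc_end == -1 else rest[:enc_end]
    if len(enc) < 4:
        raise ParseError("line 1: malformed MSH-2 (need 4 encoding characters)")
    d = Delimiters(field=fs, component=enc[0], repetition=enc[1], escape=enc[2], subcomponent=enc[3])
    # MSH-1 is the field separator, MSH-2 the encoding characters verbatim.
    fields: list[Field] = [[[[fs]]], [[[enc]]]]
    if enc_end != -1:
        for raw in rest[enc_end + 1 :].split(fs):
            fields.append(_split_field(raw, d))
    return Segment("MSH", fields), d


def _message_type_token(msh: Segment) -> str:
    code = msh.value(9, 1) or ""
    event = msh.value(9, 2) or ""
    structure = msh.value(9, 3) or ""
    if structure:
        return structure
    if code and event:
        return f"{code}_{event}"
    raise ParseError("line 1: MSH-9 does not identify a message type")


def parse_er7(
    text: str,
    registry: Optional[Mapping[str, MessageStructure]] = None,
    storage_path: str = "",
) -> HL7Message:
    """Parse an ER7 message string into an :class:`HL7Message`.

    Delimiters are read from MSH-1/MSH-2.  When a ``registry`` is supplied,
    a message type absent from it raises
    :class:`UnsupportedMessageTypeError`.
    """
    if not text or not text.strip():
        raise ParseError("empty message")
    lines = [ln for ln in re.split(r"\r\n|\r|\n", text) if ln]
    if not lines[0].startswith("MSH"):
        raise ParseError("line 1: message must begin with MSH")
    msh, d = _parse_msh(lines[0])
    segments = [msh]
    for ln in lines[1:]:
        parts = ln.split(d.field)
        segments.append(Segment(parts[0], [_split_field(raw, d) for raw in parts[1:]]))
    mtype = _message_type_token(msh)
    if registry is not None and mtype not in registry:
        raise UnsupportedMessageTypeError(f"message type {mtype!r} not in registry")
    return HL7Message(message_type=mtype, segments=segments, storage_path=storage_path, delimiters=d)


def parse_er7_file(
    path: Union[str, Path],
    root: Optional[Union[str, Path]] = None,
    registry: Optional[Mapping[str, MessageStructure]] = None,
) -> HL7Message:
    """Parse one ER7 file; ``storage_path`` is the path relative to ``root``."""
    path = Path(path)
    rel = str(path.relative_to(root)) if root is not None else ""
    rel = rel.replace("\\", "/")
    return parse_er7(path.read_text(encoding="utf-8"), registry=registry, storage_path=rel)


def iter_messages(
    root: Union[str, Path],
    registry: Optional[Mapping[str, MessageStructure]] = None,
) -> Iterable[HL7Message]:
    """Walk an SS-MIX2-style tree (patient/date/dataType/file), sorted."""
    root = Path(root)
    for path in sorted(p for p in root.rglob("*") if p.is_file()):
        if len(path.relative_to(root).parts) != 4:
            continue
        yield parse_er7_file(path, root=root, registry=registry)


def _serialize_field(f: Field, d: Delimiters, raw: bool = False) -> str:
    if raw:
        return f[0][0][0]
    return d.repetition.join(
        d.component.join(d.subcomponent.join(_escape(s, d) for s in comp) for comp in rep)
        for rep in f
    )


def serialize_er7(msg: HL7Message, newline: str = "\r") -> str:
    """Re-serialize a message; trailing empty fields are dropped per segment."""
    d = msg.delimiters
    lines = []
    for seg in msg.segments:
        if seg.segment_id == "MSH":
            rendered = [_serialize_field(f, d, raw=i < 2) for i, f in enumerate(seg.fields)]
            # MSH-1 is the separator itself: it is the delimiter after "MSH"
            body = rendered[1:]
            while body and body[-1] == "":
                body.pop()
            lines.append("MSH" + d.field + d.field.join(body))
        else:
            rendered = [_serialize_field(f, d) for f in seg.fields]
            while rendered and rendered[-1] == "":
                rendered.pop()
            lines.append(d.field.join([seg.segment_id] + rendered))
    return newline.join(lines) + newline


def get_value(
    msg: HL7Message,
    segment_id: str,
    field_index: int,
    component_index: int = 1,
    subcomponent_index: int = 1,
) -> Optional[str]:
    """First matching segment's value, or None when segment/field is absent.

    Total over valid messages: out-of-range indices return None rather than
    raising.  An empty string is a present-but-empty value; None means the
    element lies beyond the last delimiter or the segment does not occur.
    """
    if field_index < 1 or component_index < 1 or subcomponent_index < 1:
        raise IndexError("HL7 indices are 1-based")
    seg = msg.segment(segment_id)
    if seg is None:
        return None
    return seg.value(field_index, component_index, subcomponent_index)


def with_storage_path(msg: HL7Message, storage_path: str) -> HL7Message:
    return replace(msg, storage_path=storage_path)
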