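"""URI minting, datatype mapping, tree-to-RDF conversion, serialization."""

from __future__ import annotations

import pytest
from rdflib import Graph, Literal, URIRef
from rdflib.namespace import RDF, XSD

from hl7rdf import hl7_model as hm
from hl7rdf import rdf_conversion as rc
from hl7rdf import xml_encoding as xe

REG = hm.default_registry()
BASE = "http://ex.org/s"
V = BASE + "/vocab#"

RDE = (
    "MSH|^~\\&|HIS|HOSP|SSMIX|HOSP|201305280900||RDE^O11^RDE_O11|M1|P|2.5\r"
    "PID|||0123456789\r"
    "ORC|NW|O1\r"
    "RXE||D001^DrugA^MEDIS|2||TAB^tablet^LOCAL\r"
    "TQ1|1|||||7^d|201305280900|201306030900\r"
)
STORAGE = "0123456789/20130528/OMP-01/M1.txt"


def _tree(text: str = RDE):
    msg = hm.parse_er7(text, registry=REG, storage_path=STORAGE)
    return xe.encode_message(msg, REG[msg.message_type])


class TestBuildUri:
    def test_repeated_group_occurrences_distinct(self):
        u1 = rc.build_uri(BASE, STORAGE, [("RDE_O11", 1), ("ORDER", 1, True)])
        u2 = rc.build_uri(BASE, STORAGE, [("RDE_O11", 1), ("ORDER", 2, True)])
        assert u1 != u2
        assert str(u1).endswith("/ORDER_1") and str(u2).endswith("/ORDER_2")

    def test_non_repeatable_step_has_no_suffix(self):
        u = rc.build_uri(BASE, STORAGE, [("RDE_O11", 1), ("PATIENT", 1)])
        assert str(u).endswith("/RDE_O11/PATIENT")

    def test_distinct_storage_paths_distinct_uris(self):
        steps = [("RDE_O11", 1), ("PATIENT", 1)]
        assert rc.build_uri(BASE, "a/b/c/d.txt", steps) != rc.build_uri(BASE, "a/b/c/e.txt", steps)

    def test_illegal_characters_percent_encoded(self):
        u = rc.build_uri(BASE, "p 1/20130528/OMP-01/m.txt", [("RDE_O11", 1)])
        assert " " not in str(u) and "%20" in str(u)

    def test_occurrence_below_one_rejected(self):
        with pytest.raises(rc.NamingError):
            rc.build_uri(BASE, STORAGE, [("ORDER", 0, True)])

    def test_no_collisions_across_fixture_corpus(self):
        """Exhaustive collision scan: the URI set size equals the summed
        per-message resource counts."""
        minted: set[str] = set()
        total = 0
        for n in range(1, 4):
            storage = f"000000000{n}/20130528/OMP-01/M{n}.txt"
            msg = hm.parse_er7(RDE.replace("M1", f"M{n}"), registry=REG, storage_path=storage)
            tree = xe.encode_message(msg, REG[msg.message_type])
            g = rc.convert_tree(tree, storage, rc.ConversionConfig(base_namespace=BASE))
            uris = {t for triple in g for t in (triple[0], triple[2]) if isinstance(t, URIRef)
                    and not str(t).startswith(V)}
            r, _, _ = rc.count_law(tree)
            assert len(uris) == r
            total += r
            minted |= {str(u) for u in uris}
        assert len(minted) == total


class TestMapDatatype:
    @pytest.mark.parametrize(
        "hl7_type,text,expected",
        [
            ("TS", "201305281030", Literal("2013-05-28T10:30:00", datatype=XSD.dateTime)),
            ("TS.1", "20130528103045", Literal("2013-05-28T10:30:45", datatype=XSD.dateTime)),
            ("TS", "20130528", Literal("2013-05-28T00:00:00", datatype=XSD.dateTime)),
            ("DT", "20130528", Literal("2013-05-28", datatype=XSD.date)),
            ("NM", "3.5", Literal("3.5", datatype=XSD.decimal)),
            ("CQ.1", "7", Literal("7", datatype=XSD.decimal)),
            ("CE", "D001", Literal("D001", datatype=XSD.string)),
            ("CE.1", "D001", Literal("D001", datatype=XSD.string)),
            ("ST", "free text", Literal("free text", datatype=XSD.string)),
        ],
    )
    def test_advance_mapping(self, hl7_type, text, expected):
        assert rc.map_datatype(hl7_type, text) == expected

    @pytest.mark.parametrize(
        "hl7_type,text", [("NM", "POSITIVE"), ("TS", "2013"), ("DT", "28-05-2013")]
    )
    def test_unparseable_content_fails_loud(self, hl7_type, text):
        with pytest.raises(rc.ConversionError, match="PID.7"):
            rc.map_datatype(hl7_type, text, element_path="PID/PID.7")


class TestConvertTree:
    def test_count_law_unfiltered(self):
        tree = _tree()
        g = rc.convert_tree(tree, STORAGE, rc.ConversionConfig(base_namespace=BASE))
        r, l, expected = rc.count_law(tree)
        assert len(g) == expected == (r - 1) + l + r

    def test_no_type_triples_halves_resource_overhead(self):
        tree = _tree()
        g = rc.convert_tree(
            tree, STORAGE, rc.ConversionConfig(base_namespace=BASE, emit_type_triples=False)
        )
        r, l, _ = rc.count_law(tree)
        assert len(g) == (r - 1) + l

    def test_msh_exclusion_removes_all_msh_paths(self):
        g = rc.convert_tree(_tree(), STORAGE, rc.ConversionConfig.clinical_default(BASE))
        assert not [t for t in g if "/MSH" in str(t[0]) or "/MSH" in str(t[2])]

    def test_filtering_is_monotone(self):
        tree = _tree()
        full = rc.convert_tree(tree, STORAGE, rc.ConversionConfig(base_namespace=BASE))
        filtered = rc.convert_tree(tree, STORAGE, rc.ConversionConfig.clinical_default(BASE))
        assert set(filtered) <= set(full)

    def test_resource_subgraph_is_a_tree(self):
        g = rc.convert_tree(_tree(), STORAGE, rc.ConversionConfig(base_namespace=BASE))
        incoming: dict = {}
        nodes = set()
        for s, p, o in g:
            if p == RDF.type or not isinstance(o, URIRef):
                continue
            nodes |= {s, o}
            incoming[o] = incoming.get(o, 0) + 1
        roots = [n for n in nodes if n not in incoming]
        assert len(roots) == 1
        assert all(c == 1 for c in incoming.values())

    def test_datatype_errors_propagate_with_path(self):
        bad = RDE.replace("TQ1|1|||||7^d|201305280900|", "TQ1|1|||||7^d|garbage|")
        with pytest.raises(rc.ConversionError, match="TQ1.7"):
            rc.convert_tree(_tree(bad), STORAGE, rc.ConversionConfig(base_namespace=BASE))

    def test_fixture_message_equals_hand_built_triples(self):
        """The full triple set of the clinically filtered fixture message,
        enumerated by hand from the URI naming and mapping rules."""
        g = rc.convert_tree(_tree(), STORAGE, rc.ConversionConfig.clinical_default(BASE))
        p = f"{BASE}/{STORAGE}/RDE_O11"

        def u(suffix: str = "") -> URIRef:
            return URIRef(p + suffix)

        def v(name: str) -> URIRef:
            return URIRef(V + name)

        def s(x: str) -> Literal:
            return Literal(x, datatype=XSD.string)

        resources = {
            "": "RDE_O11",
            "/PATIENT": "PATIENT",
            "/PATIENT/PID": "PID",
            "/PATIENT/PID/PID.3": "PID.3",
            "/ORDER_1": "ORDER",
            "/ORDER_1/ORC": "ORC",
            "/ORDER_1/ORC/ORC.1": "ORC.1",
            "/ORDER_1/ORC/ORC.2": "ORC.2",
            "/ORDER_1/RXE": "RXE",
            "/ORDER_1/RXE/RXE.2": "RXE.2",
            "/ORDER_1/RXE/RXE.3": "RXE.3",
            "/ORDER_1/RXE/RXE.5": "RXE.5",
            "/ORDER_1/TQ1_1": "TQ1",
            "/ORDER_1/TQ1_1/TQ1.6": "TQ1.6",
            "/ORDER_1/TQ1_1/TQ1.7": "TQ1.7",
            "/ORDER_1/TQ1_1/TQ1.8": "TQ1.8",
        }
        expected = {(u(suffix), RDF.type, v(name)) for suffix, name in resources.items()}
        edges = [
            ("", "PATIENT", "/PATIENT"),
            ("/PATIENT", "PID", "/PATIENT/PID"),
            ("/PATIENT/PID", "PID.3", "/PATIENT/PID/PID.3"),
            ("", "ORDER", "/ORDER_1"),
            ("/ORDER_1", "ORC", "/ORDER_1/ORC"),
            ("/ORDER_1/ORC", "ORC.1", "/ORDER_1/ORC/ORC.1"),
            ("/ORDER_1/ORC", "ORC.2", "/ORDER_1/ORC/ORC.2"),
            ("/ORDER_1", "RXE", "/ORDER_1/RXE"),
            ("/ORDER_1/RXE", "RXE.2", "/ORDER_1/RXE/RXE.2"),
            ("/ORDER_1/RXE", "RXE.3", "/ORDER_1/RXE/RXE.3"),
            ("/ORDER_1/RXE", "RXE.5", "/ORDER_1/RXE/RXE.5"),
            ("/ORDER_1", "TQ1", "/ORDER_1/TQ1_1"),
            ("/ORDER_1/TQ1_1", "TQ1.6", "/ORDER_1/TQ1_1/TQ1.6"),
            ("/ORDER_1/TQ1_1", "TQ1.7", "/ORDER_1/TQ1_1/TQ1.7"),
            ("/ORDER_1/TQ1_1", "TQ1.8", "/ORDER_1/TQ1_1/TQ1.8"),
        ]
        expected |= {(u(a), v(name), u(b)) for a, name, b in edges}
        expected |= {
            (u("/PATIENT/PID/PID.3"), v("CX.1"), s("0123456789")),
            (u("/ORDER_1/ORC/ORC.1"), v("ID.1"), s("NW")),
            (u("/ORDER_1/ORC/ORC.2"), v("EI.1"), s("O1")),
            (u("/ORDER_1/RXE/RXE.2"), v("CE.1"), s("D001")),
            (u("/ORDER_1/RXE/RXE.2"), v("CE.2"), s("DrugA")),
            (u("/ORDER_1/RXE/RXE.2"), v("CE.3"), s("MEDIS")),
            (u("/ORDER_1/RXE/RXE.3"), v("NM.1"), Literal("2", datatype=XSD.decimal)),
            (u("/ORDER_1/RXE/RXE.5"), v("CE.1"), s("TAB")),
            (u("/ORDER_1/RXE/RXE.5"), v("CE.2"), s("tablet")),
            (u("/ORDER_1/RXE/RXE.5"), v("CE.3"), s("LOCAL")),
            (u("/ORDER_1/TQ1_1/TQ1.6"), v("CQ.1"), Literal("7", datatype=XSD.decimal)),
            (u("/ORDER_1/TQ1_1/TQ1.6"), v("CQ.2"), s("d")),
            (u("/ORDER_1/TQ1_1/TQ1.7"), v("TS.1"), Literal("2013-05-28T09:00:00", datatype=XSD.dateTime)),
            (u("/ORDER_1/TQ1_1/TQ1.8"), v("TS.1"), Literal("2013-06-03T09:00:00", datatype=XSD.dateTime)),
        }
        assert set(g) == expected


class TestSerialization:
    def test_empty_graph_empty_ntriples(self):
        assert rc.serialize_graph(Graph(), "ntriples") == ""

    def test_single_literal_triple_line_format(self):
        g = Graph()
        g.add((URIRef("http://ex.org/a"), URIRef("http://ex.org/p"), Literal("x", datatype=XSD.string)))
        text = rc.serialize_graph(g, "ntriples")
        assert text.count("\n") == 1 and text.rstrip("\n").endswith(" .")

    def test_round_trip_via_independent_parser(self):
        g = rc.convert_tree(_tree(), STORAGE, rc.ConversionConfig(base_namespace=BASE))
        g2 = Graph()
        g2.parse(data=rc.serialize_graph(g, "ntriples"), format="nt")
        assert set(g2) == set(g)
        # turtle canonicalizes numeric lexical forms; compare at value level
        g3 = Graph()
        g3.parse(data=rc.serialize_graph(g, "turtle"), format="turtle")

        def values(graph):
            return {(s, p, o.toPython() if isinstance(o, Literal) else o) for s, p, o in graph}

        assert values(g3) == values(g)

    def test_ntriples_bytes_deterministic(self):
        a = rc.serialize_graph(rc.convert_tree(_tree(), STORAGE, rc.ConversionConfig(base_namespace=BASE)))
        b = rc.serialize_graph(rc.convert_tree(_tree(), STORAGE, rc.ConversionConfig(base_namespace=BASE)))
        assert a == b

    def test_unknown_format_rejected(self):
        with pytest.raises(ValueError):
            rc.serialize_graph(Graph(), "rdfxml")


def test_config_include_must_be_nonempty_if_given():
    with pytest.raises(ValueError):
        rc.ConversionConfig(include={})


def test_config_from_yaml(tmp_path):
    p = tmp_path / "conv.yaml"
    p.write_text(
        "base_namespace: http://ex.org/s\ninclude:\n  PID: [3]\n  RXE:\n", encoding="utf-8"
    )
    cfg = rc.ConversionConfig.from_yaml(p)
    assert cfg.includes_field("PID", 3) and not cfg.includes_field("PID", 7)
    assert cfg.includes_field("RXE", 99)  # null = all fields
    assert not cfg.includes_segment("MSH")
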