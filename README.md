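# hl7rdf

Knowledge-level querying over RDF-ized HL7 v2.5 clinical messages.

Hospital information systems exchange medication orders and laboratory
results as HL7 v2.5 messages (pipe-delimited "ER7" text), and stores such
as Japan's SS-MIX2 archive them as plain files under
`patientID/date/dataType/` directories.  Those messages carry the raw
material for pharmacovigilance — which drugs were given, which laboratory
values moved — but none of the *knowledge* needed to ask a question like
*"find every case where a drug that causes leukopenia was prescribed and
the leukocyte count fell to 3000 or less during the medication period."*
Answering it normally means hand-curating a list of drug codes and a
temporal filter for every query.

`hl7rdf` is for clinical-informatics engineers and researchers who want to
ask such questions directly.  It:

1. **converts HL7 v2.5 messages to RDF** — each message is first encoded
   as its hierarchical XML-style element tree (segment groups such as
   `PATIENT`/`ORDER` made explicit, every component wrapped in its HL7
   datatype tag), then each element becomes an RDF resource whose URI is
   the storage path of the message file joined with the element path.
   Repeatable elements carry an `_n` occurrence suffix (`ORDER_2`), so
   URIs are unique across a whole corpus by construction.  Numeric content
   maps to `xsd:decimal`, dates to `xsd:date`, timestamps to
   `xsd:dateTime`, everything else to `xsd:string`;
2. **builds linked drug knowledge** — ATC-like and USP-like classification
   hierarchies (`rdfs:subClassOf`), compounds with molecular targets,
   SIDER-style side-effect records with frequency bounds, and the local
   code terminology used in RXE-2 of the orders, cross-linked and with
   RDFS subclass/instance inference materialized in advance;
3. **expands knowledge-level drug expressions** — "drugs classified as
   renin angiotensin inhibitors", "drugs causing leukopenia at ≥ 30%
   frequency", "atypical antipsychotics hitting the 5HT2C or H1 receptor"
   — into the concrete local code sets, and emits the equivalent SPARQL
   1.1 text both as a federated query (`SERVICE` clause around the
   knowledge subpattern) and as the conventional enumerated
   `FILTER ... IN` form;
4. **evaluates four temporal patterns** linking orders to candidate
   adverse events: (1) all orders, (2) events inside each medication
   period `[order date, order date + days − 1]`, (3) events between a
   patient's initial and final order dates, (4) exclusion of cases with a
   qualifying event in the window immediately before the initial order.

A seeded synthetic-data module generates SS-MIX2-style corpora with
planted, exactly recoverable cases plus one-unit-off decoys, so the whole
pipeline is testable without any hospital data.

## Worked example

```python
from hl7rdf import hl7_model as hm, rdf_conversion as rc

text = (
    "MSH|^~\\&|HIS|HOSP|SSMIX|HOSP|201305280900||RDE^O11^RDE_O11|M001|P|2.5\r"
    "PID|||0123456789\r"
    "ORC|NW|ORD1\r"
    "RXE||D001^DrugA^MEDIS|2||TAB^tablet^LOCAL\r"
    "TQ1|1|||||7^d|201305280900|201306030900\r"
)
msg = hm.parse_er7(text, registry=hm.default_registry(),
                   storage_path="0123456789/20130528/OMP-01/M001.txt")
graph = rc.convert_message(msg, rc.ConversionConfig.clinical_default())
print(f"{len(graph)} triples")
```

prints `45 triples`, among them (N-Triples, shortened):

```
<.../M001.txt/RDE_O11/ORDER_1/RXE/RXE.2> <.../vocab#CE.1> "D001"^^xsd:string .
<.../M001.txt/RDE_O11/ORDER_1/TQ1_1/TQ1.7> <.../vocab#TS.1> "2013-05-28T09:00:00"^^xsd:dateTime .
```

The drug code `D001` sits at the end of the path
`RDE_O11 → ORDER_1 → RXE → RXE.2 → CE.1`, exactly mirroring the message
structure; the order timestamp has been normalized from the HL7 lexical
form `201305280900` to ISO 8601.

The same flow from the shell, on synthetic data end to end:

```sh
hl7rdf synth corpus --seed 1 --out ssmix2/     # 391 messages, planted cases
hl7rdf synth kg --out kg/                      # toy linked drug tables
hl7rdf convert --root ssmix2 --out rdf/        # one .nt per message + corpus.nt
hl7rdf expand --kg kg --expr q1.yaml --out codes.csv --sparql q1.rq
hl7rdf query run --kg kg --corpus rdf/corpus.nt --spec q1.yaml --out matches.csv
```

where `q1.yaml` is

```yaml
expression:
  kind: by_class
  scheme: ATC
  class: renin angiotensin inhibitors
pattern: '1'
```

`codes.csv` then lists the four resolved local codes
(`MED001`…`MED004`, each with its class → compound → code resolution
chain), `q1.rq` holds the federated SPARQL with its `SERVICE` clause, and
`matches.csv` contains exactly the 50 planted medication orders.

## Layout

| module | role |
| --- | --- |
| `hl7rdf.hl7_model` | ER7 parsing, message/segment model, structure registry |
| `hl7rdf.xml_encoding` | hierarchical element tree, field datatype map |
| `hl7rdf.rdf_conversion` | URI minting, datatype mapping, tree → RDF, serialization |
| `hl7rdf.linked_drug_data` | knowledge-graph loading, RDFS closure, link validation |
| `hl7rdf.query_expansion` | expression resolution, SPARQL emission (both forms) |
| `hl7rdf.temporal_patterns` | event projection, patterns 1–4, composite queries |
| `hl7rdf.synthetic_data` | seeded corpus/knowledge generators with ground truth |

See `docs/methods.md` for the conversion and query model in detail, the
conventions chosen where HL7 or the use case leaves room, and known
limitations.
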