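# Methods

This note documents the conversion and query model implemented by
`hl7rdf`, the conventions adopted where the HL7 standard or the use case
leaves room, and what the synthetic test data does and does not establish.

## From ER7 to an element tree

An ER7 message is parsed into segments, fields, repetitions, components
and subcomponents using the five delimiter characters the message itself
declares in MSH-1/MSH-2 (default `|^~\&`).  The five basic escape
sequences `\F\ \S\ \T\ \R\ \E\` are decoded to the corresponding
delimiter characters; all other escape sequences pass through verbatim,
since decoding the full HL7 escape repertoire (hex escapes, charset
switches) buys nothing for code- and number-valued fields.  Field access
is 1-based per HL7 convention, and *absent* (beyond the last delimiter)
is distinguished from *empty* (between delimiters) at access time;
serialization drops trailing empty fields, so round-tripping is exact up
to that canonicalization.

The flat segment list is then matched against a message-structure grammar
— a tree of segment groups with repeat flags — to recover the hierarchy
that the HL7 XML encoding makes explicit.  Two structures ship by
default:

    RDE_O11 (medication order):  MSH, PATIENT{PID}, ORDER*{ORC, RXE, TQ1*}
    OUL_R22 (laboratory result): MSH, PATIENT{PID}, RESULT*{OBR, OBX*}

Matching is greedy left-to-right without backtracking, which is
unambiguous for these structures because each group is identified by its
leading segment.  Additional structures can be registered from a YAML
grammar file without code changes.  A segment sequence not derivable from
the grammar is an error naming the offending segment, not a silent skip.

Every populated field becomes an element `SEG.i`; every non-empty
component becomes a leaf named by the field's HL7 datatype
(`CE.1`, `TS.1`, `NM.1` …).  Primitive fields get the same one-component
treatment for uniformity.  OBX-5 has no static type; its datatype is read
from OBX-2 at encoding time (`NM` → numeric leaf, anything else →
string leaf).  Datatypes come from a field-type map covering the two
profiles; unmapped fields fall back to string, which is the conservative
choice for content the queries never touch.

## URI naming

The URI of every element is

    base / storage-path / element-path

where the storage path (`patientID/date/dataType/file`) is already unique
within an SS-MIX2-style store, and the element path lists the element
names from the message root down.  Steps for elements that may repeat —
groups and segments flagged repeatable in the grammar, and fields that
actually repeated — carry an `_n` occurrence suffix (`ORDER_1`,
`ORDER_2`); occurrence numbering is contiguous from 1 per parent and
name.  The suffix uses `_` rather than XPath-style brackets because
brackets are illegal in URIs unencoded.  All path segments are
percent-encoded; a step that cannot be rendered raises a naming error.
Under this scheme URI minting is injective over (storage path, element
path), which the tests verify by exhaustive collision scans rather than
by comparing against any particular expected spelling.

Predicates and classes live in a separate vocabulary namespace
(`base + "/vocab#" + element name`), so `vocab#RXE.2` is reusable across
messages while instance URIs remain per-element.

## Conversion to RDF

Traversal of the element tree emits, for an unfiltered message,

* one triple per parent→child edge between resources,
* one typed-literal triple per leaf, and
* (by default) one `rdf:type` triple per resource, typed by the
  vocabulary class of its element name,

for an exact total of `(r − 1) + l + r` triples given `r` resources and
`l` leaves.  This count law is the primary conversion oracle in the test
suite.  Type triples are on by default because they make element-name
classes directly queryable (`?msg a v:RDE_O11`); switching them off
drops exactly `r` triples.  Blank nodes are never emitted — every node is
addressable by construction.

Literal mapping is decided in advance per HL7 datatype: `NM` (and the
numeric quantity component `CQ.1`) → `xsd:decimal`, `DT` → `xsd:date`,
`TS` → `xsd:dateTime`, all else → `xsd:string`.  HL7 lexical forms
`YYYYMMDD[HH[MM[SS]]]` are normalized to ISO 8601 with missing time
components zero-filled (day resolution for dates, second resolution for
timestamps).  Content that does not parse under its declared type raises
a conversion error carrying the element path; values are never silently
demoted to strings, because a corrupted timestamp that survives as a
string would silently fall out of every temporal filter.

Because most of a message is irrelevant to clinical queries (MSH above
all), conversion is driven by an include list of segments and optional
field indices.  The shipped clinical default keeps patient id (PID-3),
order identity (ORC-1/2), drug code, dose and unit (RXE-2/3/5), timing
(TQ1-6/7/8) and the numeric-result fields (OBR-1/3/4/7,
OBX-2/3/5/6/14).  Filtering only removes triples; the count law applies
to unfiltered conversion.

N-Triples output is line-sorted, so identical input yields byte-identical
files; Turtle is offered for readability (note Turtle canonicalizes
decimal lexical forms, e.g. `2` → `2.0`, which is value-preserving).

## Linked drug knowledge

The knowledge side mirrors the linked structure of the public drug
resources a hospital would connect to its terminology: classification
hierarchies (ATC-like anatomical/chemical and USP-like therapeutic
schemes) expressed with `rdfs:subClassOf`; compounds carrying molecular
target annotations; side-effect records with a preferred term and
lower/upper frequency bounds in `[0, 1]`; and the local drug terminology
whose codes appear in RXE-2.  Sources are tidy CSV/TSV tables — the
linked structure is the point, not parsers for each database's native
dump, whose formats and licenses vary.

Compound-to-class membership is asserted as `rdf:type`.  Exactly two RDFS
rules are materialized in advance: subclass transitivity and propagation
of instance types to superclasses.  After materialization, "all drugs
under class C" is literally "all subjects typed C", which keeps both the
resolver and the SPARQL templates one-hop.  Reflexive `C ⊑ C` triples are
not asserted (no query needs them and closure sizes stay interpretable,
e.g. a chain of *n* classes closes to exactly *n(n−1)/2* subclass
triples).  Cycles in the subclass relation are a hard error listing the
cycle.  Side-effect records may attach to a class (the usual case,
matching chemical-substance-subgroup-level linking) or directly to a
compound; both are resolved.

## Query expansion

Three expression variants resolve to local code sets:

* **by class** — codes of all compounds typed to the named class (label
  match is case-folded and trimmed; id match is exact);
* **by adverse event** — codes of compounds whose side-effect record
  matches any of the given preferred terms with frequency ≥ threshold.
  Term matching is exact on normalized preferred terms, no fuzzy or
  synonym matching, since the records are coded terminology.  The
  threshold tests the **upper** frequency bound by default — a drug whose
  reported frequency range *can reach* the threshold qualifies — with the
  lower bound available as an option;
* **by class and target** — class resolution intersected with compounds
  whose target set meets the requested targets (union/OR semantics over
  targets).

An unknown class or term yields an empty code set with a warning rather
than an error, mirroring SPARQL no-match semantics.  Resolution demands a
materialized graph and refuses to run otherwise.

Each expression also renders as a SPARQL 1.1 subpattern.  The federation
form wraps that subpattern in a `SERVICE <endpoint>` clause with the
clinical triple patterns outside it; the conventional form enumerates the
resolved codes in `FILTER(STR(?ocode) IN (...))`.  Local execution uses
the same query with the knowledge subpattern inlined (`endpoint=None`),
which is semantically identical over a merged graph containing the
knowledge triples; the SERVICE text itself is emitted and
parser-validated but not dereferenced in-process, so no test depends on a
network.  The code join between the clinical and knowledge patterns is
written `FILTER(STR(?ocode) = STR(?code))` rather than a shared variable
so that plain and `xsd:string`-typed literals compare by value.  All
templates use `SELECT DISTINCT` with stable variable names, making the
two forms comparable row-for-row.

## Temporal patterns

Events are projected from the converted RDF: one medication order per
ORDER group with a populated RXE (patient, code, dose, order date from
TQ1-7, prescribed days from TQ1-6), one laboratory result per numeric OBX
(test code, value, date from OBX-14).  Non-numeric OBX values are skipped
with a warning; a missing patient id or date is an error naming the
message URI.  All records keep the URI of the RDF resource they came
from, so query answers point back into the corpus.

Interval conventions, chosen once and pinned by boundary decoys in the
test data:

* **Pattern 2** uses the closed period `[order date, order date + days −
  1]` — the order day counts as day 1 of the prescription.
* **Pattern 3** spans `[initial order date, final order date]`, closed; a
  single order gives a one-day period.  The period deliberately ends at
  the final order *date*, not the end of its prescription; a flag extends
  it by the final order's duration for drugs with long tails.
* **Pattern 4** excludes the whole patient case (not just the offending
  event) when a qualifying event falls in `[initial − window, initial −
  1]` — strictly before the initial date, so an event on the initial day
  itself never excludes.  `window = 0` is the identity.  The exclusion
  window is before-only; extending it past the initial date is possible
  via the same predicate machinery but is not the default reading of
  "immediately before".
* Multiple orders on the initial date are all "initial"; min/max over
  dates is well defined regardless of ties.

The impaired-glucose-tolerance style criterion of the third composite
query is a disjunction of per-test numeric predicates (e.g. serum glucose
≥ 200 mg/dL or HbA1c ≥ 6.5%) supplied by the query spec; no clinical
threshold is hard-coded beyond the shipped example specs.

Composite query specs (expression + pattern chain + predicates + window)
are YAML-serializable and run as resolve → project → pattern chain with
deterministic output ordering.

## Synthetic data: what it covers and what it does not

The generator emulates the *logical* shape of an SS-MIX2 medication/lab
corpus: the four-level directory layout, RDE_O11 and OUL_R22 profiles
(including messages with repeated ORDER groups and multi-OBX results),
zero-padded 10-digit patient ids, and a fixed drug catalog whose
side-effect frequency bounds straddle the 30% threshold at
0.29/0.30/0.31.  Planted cases are generated per pattern — K1 plain
orders, K2 in-period events, K3 between-period events, K4 pre-initial
exclusions (each K4 case is a K3-shaped case that must disappear) — with
defaults K1=50, K2=20, K3=10, K4=5 and at least three decoys per case,
each decoy sitting exactly one unit outside a boundary: labs one day
outside windows, values one unit past thresholds, drug codes from a class
whose frequency bound misses the threshold by 0.01.  Ground truth is
recorded while planting, never computed by the pipeline under test.  The
same seed reproduces a byte-identical tree (integer RNG only, no
float-ordering dependence).

The generator makes no attempt at epidemiological realism: no prevalence
structure, dosing curves, missingness, free-text noise, or realistic
terminology sizes.  Passing the planted-recovery tests therefore shows
that the pipeline implements its stated conventions exactly — not that
those conventions capture real prescription behaviour, nor that real
HL7 traffic (vendor Z-segments, encoding quirks, irregular timing fields)
would convert without configuration work.

## Test problem sizes

The suite verifies the conversion count law and byte determinism on a
~110-message corpus, URI injectivity on a ~1200-message corpus, closure
correctness against an independent transitive-closure implementation on
200 random DAGs of up to 100 nodes, expansion correctness against
table-level path enumeration on 100 random toy knowledge bases,
dual-form SPARQL equivalence on the planted fixture corpus, temporal
patterns against exhaustive (order, lab)-pair scans over 10⁴ events, and
exact planted-case recovery at the default scenario size.  These sizes
were chosen to exercise every boundary while keeping the whole suite
fast enough to run on every change.

## Known limitations

* Only the RDE_O11 and OUL_R22 profiles ship; other message types need a
  grammar and field-type entries (by design, via config).
* No validation against official HL7 v2.xml XSD schemas, no MLLP
  transport, no batch framing, no Z-segments.
* The SPARQL engine is in-memory (rdflib); corpus-scale federation over
  HTTP endpoints and triple-store deployment are out of scope, as is
  query-plan tuning.
* Field repetitions (`~`) are parsed and encoded, but no real-world
  corpus with repeating fields has been exercised against this code.
* The knowledge tables are toy-scale stand-ins with the real resources'
  *structure*; no licensed database content is included or parsed.
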