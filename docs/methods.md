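# Methods

## The data model

`triplify` treats a tabular biodiversity dataset as a set of implicit class
instances. Its working vocabulary is a bundled, pinned snapshot of the
Darwin Core term list from the six-core-class era of the standard
(`src/triplify/data/dwc_terms.tsv`), interpreted as follows:

* the six DwC categories are RDFS **classes**: `dwc:Occurrence`,
  `dwc:Event`, `dcterms:Location`, `dwc:GeologicalContext`,
  `dwc:Identification`, `dwc:Taxon`. Seven Dublin Core classes useful for
  biocollections data are registered alongside them (`dcterms:Location`,
  `dcterms:Agent`, `dcterms:Image`, `dcterms:MovingImage`,
  `dcterms:PhysicalObject`, `dcterms:Sound`, `dcterms:Text`).
  `dwc:MaterialSample` post-dates the pinned snapshot and is not included.
* each core class has exactly one **ID term** (`occurrenceID` … `taxonID`)
  denoting the identifiers usable for its instances — a bijection the
  loader enforces.
* every other term is a **literal property** whose domain is the class it
  is organized in. Record-level terms have no single-class domain; seven of
  them (`dcterms:type`, `dwc:institutionID`, `dwc:collectionID`,
  `dwc:institutionCode`, `dwc:collectionCode`, `dwc:ownerInstitutionCode`,
  `dwc:basisOfRecord`) most often describe the occurrence record in
  practice and are therefore given the domain `dwc:Occurrence`. The
  remaining domainless record-level terms (e.g. `dcterms:language`,
  `dwc:datasetName`) stay in the vocabulary but are excluded from automatic
  mapping; they can be mapped explicitly, and then attach to whatever
  entity the user chose.

The snapshot is a static table: no network fetch ever happens at run time,
so conversions are reproducible against a fixed vocabulary version. Users
can substitute their own snapshot (same TSV layout, or an RDFS/Turtle file
using `rdfs:Class` / `rdf:Property` / `rdfs:domain`).

Column resolution is exact for full term URIs (URIs are case-sensitive by
standard) and case-insensitive for bare local names, since real CSV headers
vary in case. A bare name that exists under two prefixes is an ambiguity
error listing the candidates rather than a silent pick.

## The relationship ontology

Four properties connect class instances:

| property          | meaning                               | symmetric | transitive |
|-------------------|---------------------------------------|-----------|------------|
| `ro:derives_from` | physical derivation                   | no        | yes        |
| `bsc:depends_on`  | existential dependence                | no        | no         |
| `bsc:alias_of`    | two identifiers, one thing            | yes       | yes        |
| `bsc:related_to`  | non-dependent association             | yes       | no         |

The flags are published as `owl:SymmetricProperty` / `owl:TransitiveProperty`
typings in a prelude included in every output graph (suppressible with
`--no-prelude`), so downstream reasoners see the semantics. `closure()`
materializes the entailments for validation and testing; emitted output
never materializes them — a symmetric relation is written as a single
directed triple in the configured direction, avoiding doubled triple
counts. Note that the full fixpoint of a symmetric-and-transitive property
over a chain also contains the reflexive triples (`a alias_of a`), which the
closure correctly produces.

Instances are auto-connected along a configurable class-to-class edge set
(`src/triplify/data/class_graph.json`). The default is:

* Occurrence `related_to` Taxon
* Identification `depends_on` Occurrence
* Identification `related_to` Taxon
* Occurrence `depends_on` Event
* Event `related_to` Location
* Event `related_to` GeologicalContext

The first two pairings are fixed by the documented meaning of the
properties (a specimen is related to a taxon; an identification depends on
a specimen); the rest follow standard Darwin Core usage (an occurrence is
recorded at an event; events are situated in a locality / geological
context; an identification asserts a taxon). The edge set is a plain JSON
file precisely so users can replace it. `derives_from` and `alias_of` never
appear in the default graph — derivation chains and identifier aliasing are
special cases that must be requested through explicit mapping entries.

When a dataset has no Event columns, Location and GeologicalContext edges
are rerouted to the hub class (the core row type, normally Occurrence), so
locality columns on an event-less table still connect; the alternative —
dropping place information on such tables — seemed clearly worse.

## Normalization

For each detected class, source rows are projected onto that class's
columns. A projection that is entirely empty produces no instance
(whitespace-only cells count as absent throughout, preventing vacuous
literals). Duplicate instances collapse under a per-class key:

* the explicit identifier, when the class has an ID-term column — database
  semantics: same key, same instance;
* the full tuple of literal values otherwise — the only possible key.

A repeated explicit identifier carrying *different* literal values is a
data-quality problem, not a structural one: it is reported as a warning and
first-seen values win, so dirty real-world archives still convert;
`--strict` promotes such warnings to errors. Rows whose explicit ID cell is
empty but whose literal cells are not are skipped for that class, with a
warning.

Classes with no identifier column get local integer IDs 1..n in
first-appearance order — deterministic given the input row order. Every
source row contributes one tuple to a link table recording which instance
of each class it instantiated; relationship emission walks this table, so
four rows sharing one locality yield four `Event related_to Location`
candidate pairs that collapse to the distinct ones.

DwC-A extensions are normalized independently and then joined to the core's
hub instances through the archive's `coreid` column before relation
emission; orphan coreids warn.

## Identifiers

Non-global instance IRIs are
`base_uri + percent_encode(table "." id_column "_" value)`, where the
percent-encoding (RFC 3986, no safe characters) covers everything illegal
in an IRI path segment, and the table name is the normalized per-class
table (`occurrence`, `taxon`, …). The scheme guarantees distinct IRIs for
distinct (table, column, value) triplets and nothing beyond dataset-level
uniqueness; the default base `http://example.org/id/` is deliberately
non-resolvable and should be overridden with `--base-uri` for real
publication. Columns flagged as globally unique are used verbatim and must
parse as absolute IRIs; a non-IRI value there is an error naming the value,
since silently encoding a "GUID" would defeat its purpose.

Literals are plain (untyped, no language tag): source cells are untyped
text, and guessing datatypes for, say, `decimalLatitude` would bake
interpretation into a format conversion. Typed-literal emission is a
straightforward extension point in `emit.py`.

## Serialization

N-Triples output is sorted line-wise, so two runs over the same input are
byte-identical and diffs are meaningful. Turtle carries `@prefix`
declarations for every namespace in use and is graph-equal to the
N-Triples output by construction (both serialize the same `rdflib` graph).
DOT output draws one node per distinct subject/object (IRIs in prefixed
short form, literals as boxes) and one labeled edge per triple; node ids
are assigned in sorted order, so DOT output is deterministic too.

## The synthetic archive generator

`triplify.fixtures.generate_dwca` writes conformant occurrence-core
archives (meta.xml + CSV, fixed zip timestamps, stored compression — same
spec and seed, byte-identical archive) with controllable structure: which
of the six classes have columns, which have explicit ID columns, a
per-class duplication fraction (instances are drawn from a pool of
`max(1, n·(1−dup))` distinct value tuples, each used at least once), and a
per-class missing fraction (an exact count `round(missing·n)` of rows left
empty for that class; the hub Occurrence is always present). Values come
from small fixed pools of plausible names, localities and dates, made
distinct with an index suffix when the pool is exhausted.

Because assignments are constructed, the generator knows the ground truth
exactly and writes it to a manifest: per-class deduplicated instance
counts, distinct related-pair counts per class edge, the number of
non-empty literal cells surviving deduplication (= literal triples a
correct conversion emits), and the occurrence IRIs that end up related to a
taxon (= the answer set of the standard SPARQL query). Tests and the
acceptance script compare pipeline output against these manifests over a
grid of sizes (n ∈ {0, 1, 25, 500}) and duplication fractions ({0, 0.5}).

What the generator does **not** model: content realism (taxonomic
consistency, coordinate plausibility), ragged or mis-encoded files, EML
metadata, or multi-extension archives. Passing the grid therefore
demonstrates structural correctness of detection, normalization,
deduplication, identifier construction and emission — not robustness to
arbitrarily dirty real-world archives, which is what the warning/strict
machinery is for.

## Scope and limitations

* Input formats: DwC-A zips, CSV/TSV text, `.xlsx` and `.ods` workbooks
  (first sheet by default). Live relational-database connections are out of
  scope, but the reader registry accepts plugins without modifying existing
  code. The ODS reader is a minimal content.xml parser adequate for flat
  data sheets.
* No OWL reasoning engine; `closure` is a test utility.
* No RDF/XML or JSON-LD output; no EML parsing; no streaming of
  multi-gigabyte archives (desk-scale batch conversion is the target).
* The mapping file is a versioned JSON schema of the four configuration
  steps (joins, entities, attributes, relations) with a dataset
  fingerprint; applying a mapping to a structurally different dataset warns
  instead of failing silently. Domain-mismatched attribute mappings warn
  rather than error, since users may map freely.
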