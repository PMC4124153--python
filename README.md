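# triplify

Convert tabular biodiversity data — Darwin Core Archives, CSV files, and
spreadsheets — into RDF, so that occurrence records, collecting events,
localities, taxa and identifications become uniquely identified, explicitly
linked class instances that can be loaded into a triple store and queried
with SPARQL.

Most biocollections data travels as "flat" tables: one row mixes the
occurrence, where and when it was collected, and what taxon it was
determined to be. `triplify` undoes that flattening. It resolves each column
to a Darwin Core term, splits the columns into per-class instance tables
(the six core classes: `dwc:Occurrence`, `dwc:Event`, `dcterms:Location`,
`dwc:GeologicalContext`, `dwc:Identification`, `dwc:Taxon`), removes
duplicate instances, constructs an IRI for every instance, and emits RDF:

* one `rdf:type` triple per instance,
* one plain-literal triple per non-empty mapped cell
  (e.g. `?taxon dwc:scientificName "Taricha torosa"`),
* relationship triples connecting instances with a small four-property
  ontology: `bsc:related_to` (symmetric), `bsc:depends_on`,
  `bsc:alias_of` (symmetric, transitive) and `ro:derives_from` (transitive),
  each declared with its OWL semantics in an output prelude.

For instances without globally unique identifiers, IRIs are built
deterministically as

```
base_uri + percent_encode(table_name + "." + id_column + "_" + value)
```

for example `http://example.org/id/occurrence.occurrenceID_MVZ%3AHerp%3A256`.
Classes with no identifier column at all get local integer IDs assigned
during normalization. These IRIs are unique within one version of one
dataset — minting global identifiers is out of scope.

Output formats: N-Triples (sorted, byte-reproducible), Turtle, and Graphviz
DOT for visualization.

## Worked example

Given `example.csv`:

```csv
occurrenceID,scientificName,family,locality,country,eventDate
MVZ:Herp:256,Taricha torosa,Salamandridae,Sagehen Creek,United States,1998-04-12
MVZ:Herp:257,Taricha torosa,Salamandridae,Sagehen Creek,United States,1998-04-12
MVZ:Herp:301,Rana draytonii,Ranidae,Pine Crest,United States,2003-07-30
```

run:

```
triplify example.csv -o example.nt --write-mapping example-mapping.json
```

which prints (to standard error):

```
example.csv: mapping written to example-mapping.json
example.csv: 35 triples -> example.nt
```

Four classes were detected from the headers (Occurrence, Taxon, Event,
Location). The three rows collapse to 3 occurrence instances, 2 taxa,
2 events and 2 localities — the two *Taricha torosa* rows share one taxon,
one event and one locality instance. `example.nt` contains lines such as:

```
<http://example.org/id/occurrence.occurrenceID_MVZ%3AHerp%3A256> <http://www.w3.org/1999/02/22-rdf-syntax-ns#type> <http://rs.tdwg.org/dwc/terms/Occurrence> .
<http://example.org/id/taxon.localID_1> <http://rs.tdwg.org/dwc/terms/scientificName> "Taricha torosa" .
<http://example.org/id/occurrence.occurrenceID_MVZ%3AHerp%3A256> <http://biscicol.org/terms/biscicol.owl#related_to> <http://example.org/id/taxon.localID_1> .
```

The exported `example-mapping.json` captures the four configuration steps
(joins, entities, attributes, relations); it can be hand-edited — for
instance to add a `ro:derives_from` relation — and reused in batch runs:

```
triplify example.csv -m example-mapping.json -o example.ttl -s turtle
```

Once loaded into any RDF store, instance-level questions become one-line
SPARQL queries, e.g. *which occurrences carry taxonomic information?*

```sparql
PREFIX bsc: <http://biscicol.org/terms/biscicol.owl#>
PREFIX dwc: <http://rs.tdwg.org/dwc/terms/>
SELECT ?occurrence
WHERE { ?occurrence bsc:related_to ?taxon .
        ?occurrence a dwc:Occurrence .
        ?taxon a dwc:Taxon }
```

Darwin Core Archives need no configuration at all: `triplify occ.zip -o occ.nt`
reads `meta.xml`, maps every declared term, and completes all four steps
automatically.

## Library use

```python
from triplify import convert, serialize_ntriples

result = convert("occ.zip")                 # auto mode
print(result.report["instance_counts"])     # per-class instances
print(serialize_ntriples(result.graph))
```

See `docs/methods.md` for the data model, the identifier scheme, the
relationship ontology and its default class graph, and the design decisions
behind them.

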