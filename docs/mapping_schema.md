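# Mapping file schema (version 1)

A mapping file is JSON with these top-level keys:

```json
{
  "version": 1,
  "base_uri": "http://example.org/id/",
  "fingerprint": {"<table>": ["<header>", "..."]},
  "joins": [
    {"left_table": "...", "left_column": "...",
     "right_table": "...", "right_column": "..."}
  ],
  "entities": [
    {"table": "...", "id_column": "...",
     "class_uri": "http://rs.tdwg.org/dwc/terms/Occurrence",
     "id_is_global": false}
  ],
  "attributes": [
    {"table": "...", "id_column": "...", "column": "...",
     "property_uri": "http://rs.tdwg.org/dwc/terms/scientificName"}
  ],
  "relations": [
    {"subject_table": "...", "subject_id_column": "...",
     "property_uri": "http://biscicol.org/terms/biscicol.owl#related_to",
     "object_table": "...", "object_id_column": "..."}
  ]
}
```

Semantics:

* **entities** — one per class instance population. An entity is addressed
  elsewhere by its `(table, id_column)` pair. `id_is_global: true` means the
  column holds absolute IRIs used verbatim; otherwise IRIs are constructed
  from `base_uri`, table, column and value.
* **attributes** — one per literal column; `property_uri` should be a
  vocabulary literal property (domain mismatches validate with a warning).
* **relations** — `property_uri` must be one of the four relationship
  properties (`ro:derives_from`, `bsc:depends_on`, `bsc:alias_of`,
  `bsc:related_to`); anything else fails to load. Subject/object entities
  on different tables are paired through the normalization link table when
  one is available, otherwise through a join path from `joins`.
* **fingerprint** — table names and headers of the dataset the mapping was
  generated for; a structural mismatch at load time produces a warning.

Unknown keys are rejected (`extra="forbid"`), so typos fail loudly with a
JSON path to the offending element.
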