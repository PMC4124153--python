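"""The four configuration steps, as a serializable mapping file.

Converting arbitrary tables to RDF takes four pieces of information:

1. **joins** — which key columns join multiple tables together;
2. **entities** — which column identifies instances of which class, and
   whether those identifiers are globally unique;
3. **attributes** — which literal columns map to which vocabulary property;
4. **relations** — how class instances connect to one another using the four
   relationship properties.

A :class:`MappingConfig` captures all four, serializes to a versioned JSON
file, and can be built fully automatically for class-detectable data with
:func:`build_auto_mapping`.  Mapping files can be generated once, hand-edited
(e.g. to add a ``ro:derives_from`` relation), and reused for batch runs.
"""

from __future__ import annotations

import json
from pathlib import Path

from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import relations as rel
from .errors import AutoMappingError, MappingError
from .normalize import NormalizedDataset
from .tabular import SourceTable
from .vocabulary import TermKind, Vocabulary

SCHEMA_VERSION = 1


class Join(BaseModel):
    model_config = ConfigDict(extra="forbid")
    left_table: str
    left_column: str
    right_table: str
    right_column: str


class EntityMapping(BaseModel):
    model_config = ConfigDict(extra="forbid")
    table: str
    id_column: str
    class_uri: str
    id_is_global: bool = False

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.table, self.id_column, self.class_uri)


class AttributeMapping(BaseModel):
    model_config = ConfigDict(extra="forbid")
    table: str
    id_column: str
    column: str
    property_uri: str


class RelationMapping(BaseModel):
    model_config = ConfigDict(extra="forbid")
    subject_table: str
    subject_id_column: str
    property_uri: str
    object_table: str
    object_id_column: str


class MappingConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    version: int = SCHEMA_VERSION
    base_uri: str = "http://example.org/id/"
    fingerprint: dict[str, list[str]] = Field(default_factory=dict)
    joins: list[Join] = Field(default_factory=list)
    entities: list[EntityMapping] = Field(default_factory=list)
    attributes: list[AttributeMapping] = Field(default_factory=list)
    relations: list[RelationMapping] = Field(default_factory=list)

    def entity_for(self, table: str, id_column: str) -> EntityMapping | None:
        for e in self.entities:
            if e.table == table and e.id_column == id_column:
                return e
        return None


def build_auto_mapping(normalized: NormalizedDataset, vocab: Vocabulary,
                       graph: rel.ClassGraph,
                       base_uri: str = "http://example.org/id/") -> MappingConfig:
    """Complete all four configuration steps from a normalized dataset.

    One entity per present class, one attribute per assigned literal column,
    and one relation per configured class-graph edge whose two classes are
    both present.  When the Event class is absent, edges that would pass
    through it (Location, GeologicalContext) are rerouted to the hub class so
    that place columns on an event-less occurrence table still connect.
    """
    if not normalized.tables:
        raise AutoMappingError(
            "no vocabulary classes detected; supply a mapping file instead"
        )
    config = MappingConfig(base_uri=base_uri)
    tables = normalized.source_tables()
    config.fingerprint = {name: t.headers for name, t in sorted(tables.items())}

    by_class: dict[str, EntityMapping] = {}
    for cls in sorted(normalized.tables):
        it = normalized.tables[cls]
        entity = EntityMapping(
            table=it.table_name, id_column=it.id_column,
            class_uri=cls, id_is_global=False,
        )
        by_class[cls] = entity
        config.entities.append(entity)
        for col in it.literal_columns:
            if col.term_uri:
                config.attributes.append(
                    AttributeMapping(table=it.table_name, id_column=it.id_column,
                                     column=col.header, property_uri=col.term_uri)
                )

    event = "http://rs.tdwg.org/dwc/terms/Event"
    edges: list[rel.ClassEdge] = []
    for edge in graph.edges:
        subject, obj = edge.subject_class, edge.object_class
        if event not in by_class and normalized.hub_class is not None:
            # reroute around a missing Event hub
            if subject == event and obj in by_class:
                subject = normalized.hub_class
            elif obj == event and subject in by_class:
                obj = normalized.hub_class
        if subject in by_class and obj in by_class and subject != obj:
            candidate = rel.ClassEdge(subject, edge.property, obj)
            if candidate not in edges:
                edges.append(candidate)
    for edge in edges:
        s, o = by_class[edge.subject_class], by_class[edge.object_class]
        config.relations.append(
            RelationMapping(
                subject_table=s.table, subject_id_column=s.id_column,
                property_uri=edge.property,
                object_table=o.table, object_id_column=o.id_column,
            )
        )
    return config


def validate_mapping(config: MappingConfig,
                     tables: dict[str, SourceTable],
                     vocab: Vocabulary | None = None) -> dict:
    """Check every mapping reference against the dataset and vocabulary.

    Returns ``{"errors": [...], "warnings": [...], "valid": bool}``; domain
    mismatches and domainless record-level terms are warnings only (users may
    map freely), broken references and non-relation properties are errors.
    """
    errors: list[str] = []
    warnings_: list[str] = []

    def check_column(table: str, column: str, what: str) -> None:
        if table not in tables:
            errors.append(f"{what}: table {table!r} not found in dataset")
        elif column not in tables[table].headers:
            errors.append(f"{what}: column {column!r} not found in table {table!r}")

    seen_joins = set()
    for j in config.joins:
        check_column(j.left_table, j.left_column, "join")
        check_column(j.right_table, j.right_column, "join")
        key = frozenset([(j.left_table, j.left_column), (j.right_table, j.right_column)])
        if key in seen_joins:
            errors.append(f"duplicate join {j}")
        seen_joins.add(key)

    seen_entities = set()
    for e in config.entities:
        check_column(e.table, e.id_column, f"entity {e.class_uri}")
        if vocab is not None and not vocab.is_class(e.class_uri):
            errors.append(f"entity class {e.class_uri!r} is not a registered class")
        if e.key in seen_entities:
            errors.append(f"duplicate entity {e.key}")
        seen_entities.add(e.key)

    for a in config.attributes:
        check_column(a.table, a.column, f"attribute {a.property_uri}")
        entity = config.entity_for(a.table, a.id_column)
        if entity is None:
            errors.append(
                f"attribute {a.property_uri}: no entity ({a.table}, {a.id_column})"
            )
        if vocab is not None:
            term = vocab.terms.get(a.property_uri)
            if term is None:
                warnings_.append(f"attribute property {a.property_uri!r} not in vocabulary")
            elif term.kind not in (TermKind.LITERAL_PROPERTY, TermKind.ID_TERM):
                errors.append(
                    f"attribute property {a.property_uri!r} is a {term.kind.value}, "
                    "not a literal property"
                )
            elif term.domain_class is None:
                warnings_.append(
                    f"attribute property {a.property_uri!r} has no single-class domain"
                )
            elif entity is not None and term.domain_class != entity.class_uri:
                warnings_.append(
                    f"attribute {a.property_uri!r} has domain {term.domain_class!r} "
                    f"but is mapped onto class {entity.class_uri!r}"
                )

    for r in config.relations:
        if r.property_uri not in rel.RELATION_PROPERTIES:
            errors.append(
                f"relation property {r.property_uri!r} is not one of the four "
                "relationship properties"
            )
        subject = config.entity_for(r.subject_table, r.subject_id_column)
        obj = config.entity_for(r.object_table, r.object_id_column)
        if subject is None:
            errors.append(f"relation: no entity ({r.subject_table}, {r.subject_id_column})")
        if obj is None:
            errors.append(f"relation: no entity ({r.object_table}, {r.object_id_column})")
        if subject is not None and obj is not None:
            if subject.table != obj.table and not _joined(
                subject.table, obj.table, config.joins
            ):
                warnings_.append(
                    f"relation {r.property_uri}: tables {subject.table!r} and "
                    f"{obj.table!r} share no join path; link-table co-occurrence "
                    "will be used if available"
                )

    return {"errors": errors, "warnings": warnings_, "valid": not errors}


def _joined(a: str, b: str, joins: list[Join]) -> bool:
    adj: dict[str, set[str]] = {}
    for j in joins:
        adj.setdefault(j.left_table, set()).add(j.right_table)
        adj.setdefault(j.right_table, set()).add(j.left_table)
    stack, seen = [a], {a}
    while stack:
        t = stack.pop()
        if t == b:
            return True
        for n in adj.get(t, ()):
            if n not in seen:
                seen.add(n)
                stack.append(n)
    return False


def save_mapping(config: MappingConfig, path: str | Path) -> None:
    """Write the mapping as canonical JSON (sorted keys, stable bytes)."""
    Path(path).write_text(dumps_mapping(config), encoding="utf-8")


def dumps_mapping(config: MappingConfig) -> str:
    return json.dumps(config.model_dump(), indent=2, sort_keys=True) + "\n"


def load_mapping(path: str | Path) -> MappingConfig:
    """Load and schema-validate a mapping file."""
    try:
        raw = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise MappingError(f"{path}: not valid JSON: {exc}") from exc
    try:
        config = MappingConfig.model_validate(raw)
    except ValidationError as exc:
        locations = "; ".join(
            "/".join(str(p) for p in err["loc"]) + ": " + err["msg"]
            for err in exc.errors()
        )
        raise MappingError(f"{path}: invalid mapping file at {locations}") from exc
    if config.version != SCHEMA_VERSION:
        raise MappingError(
            f"{path}: unsupported mapping schema version {config.version}"
        )
    for r in config.relations:
        if r.property_uri not in rel.RELATION_PROPERTIES:
            raise MappingError(
                f"{path}: relations/{config.relations.index(r)}/property_uri: "
                f"unknown relation property {r.property_uri!r}"
            )
    return config
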