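"""Instance IRI construction, triple emission and serialization.

Identifier construction follows the table/column/value concatenation scheme:
when a column does not hold globally unique identifiers, the instance IRI is

    base_uri + percent_encode(table_name + "." + id_column + "_" + value)

which guarantees distinct IRIs for distinct (table, column, value) triplets
— unique within one version of one dataset, nothing more.  Columns flagged
as globally unique are used verbatim and must already be absolute IRIs.

Emission produces, per entity instance, one ``rdf:type`` triple; per mapped
literal column and non-empty cell, one plain-literal triple; and per related
instance pair, one relationship triple in the configured direction (symmetry
is declared in OWL, not materialized).  An ontology prelude typing the four
relationship properties is included by default.

Serializations: N-Triples (lines sorted for reproducible diffs), Turtle
(prefix declarations for every namespace in use), and Graphviz DOT (one node
per distinct subject/object, literals drawn as boxes, one labeled edge per
triple).
"""

from __future__ import annotations

import urllib.parse
from dataclasses import dataclass

from rdflib import Graph, Literal, URIRef
from rdflib.namespace import OWL, RDF

from . import relations as rel
from .errors import EmissionError, IdentifierError, MappingError
from .mapping import MappingConfig, validate_mapping
from .namespaces import PREFIXES
from .tabular import SourceTable


@dataclass(frozen=True)
class InstanceIRI:
    iri: str
    table: str
    id_column: str
    local_value: str
    is_global: bool = False


def _is_absolute_iri(value: str) -> bool:
    parts = urllib.parse.urlsplit(value)
    return bool(parts.scheme) and " " not in value and (
        bool(parts.netloc) or bool(parts.path) or bool(parts.fragment) or bool(parts.query)
    )


def make_instance_iri(entity, local_value: str,
                      base_uri: str | None = None) -> InstanceIRI:
    """Build the IRI for one instance of an entity mapping.

    ``entity`` needs ``table``, ``id_column`` and ``id_is_global`` attributes
    (an :class:`~triplify.mapping.EntityMapping`).  ``base_uri`` defaults to
    the documented ``http://example.org/id/`` prefix.
    """
    if not local_value or not local_value.strip():
        raise IdentifierError(
            f"{entity.table}.{entity.id_column}: empty identifier value"
        )
    local_value = local_value.strip()
    if getattr(entity, "id_is_global", False):
        if not _is_absolute_iri(local_value):
            raise IdentifierError(
                f"{entity.table}.{entity.id_column}: value {local_value!r} flagged "
                "globally unique but is not an absolute IRI"
            )
        return InstanceIRI(local_value, entity.table, entity.id_column,
                           local_value, is_global=True)
    base = base_uri if base_uri is not None else "http://example.org/id/"
    composed = f"{entity.table}.{entity.id_column}_{local_value}"
    return InstanceIRI(base + urllib.parse.quote(composed, safe=""),
                       entity.table, entity.id_column, local_value)


class TripleGraph:
    """A set of RDF triples plus the namespace table, backed by rdflib."""

    def __init__(self, base_uri: str = "http://example.org/id/"):
        self.graph = Graph()
        self.base_uri = base_uri
        for prefix, uri in PREFIXES.items():
            self.graph.bind(prefix, uri, replace=True)

    def add(self, subject: str, predicate: str, obj) -> None:
        o = obj if isinstance(obj, (URIRef, Literal)) else URIRef(obj)
        self.graph.add((URIRef(subject), URIRef(predicate), o))

    def __len__(self) -> int:
        return len(self.graph)

    def __contains__(self, triple) -> bool:
        s, p, o = triple
        o = o if isinstance(o, (URIRef, Literal)) else (
            Literal(o[1]) if isinstance(o, tuple) else URIRef(o)
        )
        return (URIRef(s), URIRef(p), o) in self.graph

    def triples(self):
        return set(self.graph)


def ontology_prelude(graph: TripleGraph) -> None:
    """Type the four relationship properties, with their OWL semantics."""
    for p in sorted(rel.RELATION_PROPERTIES):
        prop = rel.RELATION_PROPERTIES[p]
        graph.add(p, str(RDF.type), str(OWL.ObjectProperty))
        if prop.symmetric:
            graph.add(p, str(RDF.type), str(OWL.SymmetricProperty))
        if prop.transitive:
            graph.add(p, str(RDF.type), str(OWL.TransitiveProperty))


def emit(tables: dict[str, SourceTable], config: MappingConfig,
         links: list[dict[str, str]] | None = None,
         vocab=None, *, prelude: bool = True) -> TripleGraph:
    """Emit the RDF graph a mapping specifies over a set of tables.

    ``links`` carries per-source-row co-occurrence tuples (table name ->
    identifier value) from normalization; relations between entities on
    different tables are routed through it when present, through the
    mapping's joins otherwise, and by row pairing when both entities share a
    table.
    """
    report = validate_mapping(config, tables, vocab)
    if not report["valid"]:
        raise MappingError(
            "mapping does not validate: " + "; ".join(report["errors"])
        )
    g = TripleGraph(config.base_uri)
    if prelude:
        ontology_prelude(g)

    iri_cache: dict[tuple[str, str, str], str] = {}

    def iri_for(entity, value: str) -> str:
        key = (entity.table, entity.id_column, value)
        if key not in iri_cache:
            iri_cache[key] = make_instance_iri(entity, value, config.base_uri).iri
        return iri_cache[key]

    # rdf:type triples, one per entity instance
    for entity in config.entities:
        table = tables[entity.table]
        idx = table.column_index(entity.id_column)
        for row in table.rows:
            value = row[idx].strip()
            if value:
                g.add(iri_for(entity, value), str(RDF.type), entity.class_uri)

    # literal triples, one per non-empty mapped cell
    for attr in config.attributes:
        entity = config.entity_for(attr.table, attr.id_column)
        table = tables[attr.table]
        id_idx = table.column_index(attr.id_column)
        col_idx = table.column_index(attr.column)
        for row in table.rows:
            id_value, cell = row[id_idx].strip(), row[col_idx].strip()
            if id_value and cell:
                g.add(iri_for(entity, id_value), attr.property_uri, Literal(cell))

    # relationship triples
    for relation in config.relations:
        subject = config.entity_for(relation.subject_table, relation.subject_id_column)
        obj = config.entity_for(relation.object_table, relation.object_id_column)
        for s_val, o_val in _instance_pairs(relation, subject, obj, tables,
                                            config, links):
            g.add(iri_for(subject, s_val), relation.property_uri,
                  URIRef(iri_for(obj, o_val)))
    return g


def _instance_pairs(relation, subject, obj, tables, config, links):
    """Yield (subject id value, object id value) pairs for one relation."""
    if subject.table == obj.table:
        table = tables[subject.table]
        s_idx = table.column_index(subject.id_column)
        o_idx = table.column_index(obj.id_column)
        for row in table.rows:
            s_val, o_val = row[s_idx].strip(), row[o_idx].strip()
            if s_val and o_val:
                yield s_val, o_val
        return
    if links is not None:
        emitted = set()
        for link in links:
            s_val = link.get(subject.table)
            o_val = link.get(obj.table)
            if s_val and o_val and (s_val, o_val) not in emitted:
                emitted.add((s_val, o_val))
                yield s_val, o_val
        return
    yield from _join_pairs(relation, subject, obj, tables, config)


def _join_pairs(relation, subject, obj, tables, config):
    path = _join_path(subject.table, obj.table, config.joins)
    if path is None:
        raise EmissionError(
            f"relation {relation.property_uri}: no join path between "
            f"{subject.table!r} and {obj.table!r} and no link table available"
        )
    # rows of the subject table, progressively joined along the path
    current = [
        {subject.table: row} for row in tables[subject.table].rows
    ]
    for join, left, right in path:
        try:
            l_idx = tables[left].column_index(
                join.left_column if join.left_table == left else join.right_column
            )
            r_idx = tables[right].column_index(
                join.right_column if join.right_table == right else join.left_column
            )
        except Exception as exc:
            raise EmissionError(f"join column missing: {exc}") from exc
        by_key: dict[str, list] = {}
        for row in tables[right].rows:
            key = row[r_idx].strip()
            if key:
                by_key.setdefault(key, []).append(row)
        nxt = []
        for bound in current:
            key = bound[left][l_idx].strip()
            for row in by_key.get(key, ()):
                merged = dict(bound)
                merged[right] = row
                nxt.append(merged)
        current = nxt
    s_idx = tables[subject.table].column_index(subject.id_column)
    o_idx = tables[obj.table].column_index(obj.id_column)
    emitted = set()
    for bound in current:
        s_val = bound[subject.table][s_idx].strip()
        o_val = bound[obj.table][o_idx].strip()
        if s_val and o_val and (s_val, o_val) not in emitted:
            emitted.add((s_val, o_val))
            yield s_val, o_val


def _join_path(a: str, b: str, joins):
    """BFS over joins; returns [(join, from_table, to_table), ...] or None."""
    adj: dict[str, list] = {}
    for j in joins:
        adj.setdefault(j.left_table, []).append((j, j.left_table, j.right_table))
        adj.setdefault(j.right_table, []).append((j, j.right_table, j.left_table))
    frontier = [(a, [])]
    seen = {a}
    while frontier:
        table, path = frontier.pop(0)
        if table == b:
            return path
        for j, frm, to in adj.get(table, ()):
            if to not in seen:
                seen.add(to)
                frontier.append((to, path + [(j, frm, to)]))
    return None


# -- serialization ---------------------------------------------------------

def serialize_ntriples(graph: TripleGraph) -> str:
    """Canonical N-Triples: one triple per line, lines sorted, UTF-8."""
    lines = sorted(
        f"{s.n3()} {p.n3()} {o.n3()} ." for s, p, o in graph.graph
    )
    return "\n".join(lines) + ("\n" if lines else "")


def serialize_turtle(graph: TripleGraph) -> str:
    """Turtle with prefix declarations; graph-equal to the N-Triples form."""
    return graph.graph.serialize(format="turtle")


def _qname(graph: TripleGraph, uri: URIRef) -> str:
    try:
        prefix, _, local = graph.graph.compute_qname(uri, generate=False)
        return f"{prefix}:{local}"
    except Exception:
        return str(uri)


def _dot_escape(label: str) -> str:
    return label.replace("\\", "\\\\").replace('"', '\\"').replace("\n", "\\n")


def serialize_dot(graph: TripleGraph) -> str:
    """Graphviz DOT digraph: nodes for distinct subjects/objects, labeled
    edges for triples, literal nodes drawn as boxes."""
    nodes: dict[object, tuple[str, bool]] = {}

    def node_key(term):
        if isinstance(term, Literal):
            return ("literal", str(term))
        return ("iri", str(term))

    triples = sorted(graph.graph, key=lambda t: (str(t[0]), str(t[1]), str(t[2])))
    for s, p, o in triples:
        nodes.setdefault(node_key(s), (_qname(graph, s), False))
        if isinstance(o, Literal):
            nodes.setdefault(node_key(o), (str(o), True))
        else:
            nodes.setdefault(node_key(o), (_qname(graph, o), False))

    lines = ["digraph triples {"]
    ids = {}
    for n, key in enumerate(sorted(nodes)):
        label, is_literal = nodes[key]
        ids[key] = f"n{n}"
        shape = "box" if is_literal else "ellipse"
        lines.append(f'  n{n} [label="{_dot_escape(label)}" shape={shape}];')
    for s, p, o in triples:
        lines.append(
            f'  {ids[node_key(s)]} -> {ids[node_key(o)]} '
            f'[label="{_dot_escape(_qname(graph, p))}"];'
        )
    lines.append("}")
    return "\n".join(lines) + "\n"


SERIALIZERS = {
    "ntriples": serialize_ntriples,
    "turtle": serialize_turtle,
    "dot": serialize_dot,
}
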