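"""The four-property relationship ontology connecting class instances.

Instances of the core classes are linked with exactly four high-level
properties:

===============  =========  ==========
property         symmetric  transitive
===============  =========  ==========
ro:derives_from  no         yes
bsc:depends_on   no         no
bsc:alias_of     yes        yes
bsc:related_to   yes        no
===============  =========  ==========

``derives_from`` expresses physical derivation (a tissue sample from a
specimen), ``depends_on`` existential dependence (an identification on a
specimen), ``alias_of`` identity between two identifiers, and ``related_to``
a non-dependent association (a specimen and a taxon).  The symmetric and
transitive flags are published as ``owl:SymmetricProperty`` /
``owl:TransitiveProperty`` typings in the output prelude so that consumers
can reason over them; :func:`closure` materializes the entailed triples and
is used for validation only, never for output.

A :class:`ClassGraph` holds the class-to-class edges used to auto-connect
instances.  The bundled default connects Occurrence↔Taxon and
Identification↔Taxon with ``related_to``, Identification→Occurrence and
Occurrence→Event with ``depends_on``, and Event↔Location /
Event↔GeologicalContext with ``related_to``.  Neither ``derives_from`` nor
``alias_of`` appears in the default graph; both are applied only through
explicit mapping entries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .errors import OntologyConfigError, UnknownPropertyError
from .namespaces import BSC, RO

DERIVES_FROM = str(RO.derives_from)
DEPENDS_ON = str(BSC.depends_on)
ALIAS_OF = str(BSC.alias_of)
RELATED_TO = str(BSC.related_to)


@dataclass(frozen=True)
class RelationProperty:
    uri: str
    symmetric: bool
    transitive: bool


RELATION_PROPERTIES: dict[str, RelationProperty] = {
    DERIVES_FROM: RelationProperty(DERIVES_FROM, symmetric=False, transitive=True),
    DEPENDS_ON: RelationProperty(DEPENDS_ON, symmetric=False, transitive=False),
    ALIAS_OF: RelationProperty(ALIAS_OF, symmetric=True, transitive=True),
    RELATED_TO: RelationProperty(RELATED_TO, symmetric=True, transitive=False),
}


def property_semantics(uri: str) -> tuple[bool, bool]:
    """Return ``(symmetric, transitive)`` for one of the four properties."""
    try:
        p = RELATION_PROPERTIES[uri]
    except KeyError:
        raise UnknownPropertyError(
            f"{uri!r} is not a relationship property; expected one of: "
            + ", ".join(sorted(RELATION_PROPERTIES))
        ) from None
    return p.symmetric, p.transitive


@dataclass(frozen=True)
class ClassEdge:
    subject_class: str
    property: str
    object_class: str


@dataclass
class ClassGraph:
    edges: tuple[ClassEdge, ...] = field(default_factory=tuple)

    def __post_init__(self):
        seen = set()
        for e in self.edges:
            if e.property not in RELATION_PROPERTIES:
                raise UnknownPropertyError(
                    f"class-graph edge uses unknown property {e.property!r}"
                )
            if e in seen:
                raise OntologyConfigError(f"duplicate class-graph edge {e}")
            seen.add(e)


def load_class_graph(path: str | Path | None = None) -> ClassGraph:
    """Load the class-to-class edge set from JSON (bundled default if None)."""
    if path is None:
        text = resources.files("triplify").joinpath("data/class_graph.json").read_text(
            encoding="utf-8"
        )
    else:
        text = Path(path).read_text(encoding="utf-8")
    try:
        raw = json.loads(text)
        edges = tuple(
            ClassEdge(e["subject_class"], e["property"], e["object_class"])
            for e in raw
        )
    except (json.JSONDecodeError, KeyError, TypeError) as exc:
        raise OntologyConfigError(f"malformed class-graph file: {exc}") from exc
    return ClassGraph(edges)


def default_edge(class_a: str, class_b: str, graph: ClassGraph) -> ClassEdge | None:
    """The unique configured edge connecting a pair of classes, if any.

    The pair is matched in both orders; the returned edge keeps its
    configured direction (for symmetric properties a single directed triple
    is emitted — symmetry lives in the OWL declaration, not in duplicated
    triples).
    """
    matches = [
        e
        for e in graph.edges
        if {e.subject_class, e.object_class} == {class_a, class_b}
        and class_a != class_b
    ]
    if not matches:
        return None
    if len(set(matches)) > 1:
        raise OntologyConfigError(
            f"more than one configured edge between {class_a!r} and {class_b!r}"
        )
    return matches[0]


Triple = tuple[str, str, str]


def closure(triples: set[Triple]) -> set[Triple]:
    """Least superset closed under the symmetry/transitivity of each property.

    A validation and testing utility — emitted output never materializes
    entailments.  Idempotent by construction (fixpoint iteration).
    """
    for _, p, _ in triples:
        property_semantics(p)
    result = set(triples)
    changed = True
    while changed:
        changed = False
        for s, p, o in list(result):
            sym, trans = property_semantics(p)
            if sym and (o, p, s) not in result:
                result.add((o, p, s))
                changed = True
            if trans:
                for s2, p2, o2 in list(result):
                    if p2 == p and s2 == o and (s, p, o2) not in result:
                        result.add((s, p, o2))
                        changed = True
    return result
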