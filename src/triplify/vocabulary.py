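"""The working RDF vocabulary: Darwin Core classes, ID terms and properties.

The vocabulary is loaded from a bundled tab-separated snapshot of the Darwin
Core term list (``data/dwc_terms.tsv``).  Each row carries the full term URI,
its kind, an optional domain class, and a record-level flag.  The snapshot
follows the term list of the six-core-class era of the standard: the six core
classes are Occurrence, Event, Location, GeologicalContext, Identification
and Taxon, each with a single dedicated ID term (``occurrenceID`` …
``taxonID``).  Seven Dublin Core classes useful for biocollections data are
included as well.  Properties carry the class they are organized in as their
domain; record-level terms either apply to the record as a whole (no domain)
or, for seven of them, are treated as describing the Occurrence.

Users may supply a replacement snapshot in the same tabular format, or an
RDFS/Turtle file using ``rdfs:domain`` statements.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path

from .errors import AmbiguousTermError, VocabularyError
from .namespaces import PREFIXES

SIX_CORE_CLASSES = (
    "http://rs.tdwg.org/dwc/terms/Occurrence",
    "http://rs.tdwg.org/dwc/terms/Event",
    "http://purl.org/dc/terms/Location",
    "http://rs.tdwg.org/dwc/terms/GeologicalContext",
    "http://rs.tdwg.org/dwc/terms/Identification",
    "http://rs.tdwg.org/dwc/terms/Taxon",
)

DUBLIN_CORE_CLASSES = (
    "http://purl.org/dc/terms/Location",
    "http://purl.org/dc/terms/Agent",
    "http://purl.org/dc/terms/Image",
    "http://purl.org/dc/terms/MovingImage",
    "http://purl.org/dc/terms/PhysicalObject",
    "http://purl.org/dc/terms/Sound",
    "http://purl.org/dc/terms/Text",
)


class TermKind(str, Enum):
    CLASS = "CLASS"
    ID_TERM = "ID_TERM"
    LITERAL_PROPERTY = "LITERAL_PROPERTY"
    RELATION_PROPERTY = "RELATION_PROPERTY"


def split_uri(uri: str) -> tuple[str, str]:
    """Split a term URI into (prefix, local name) using the known prefixes.

    Longest-match wins so that ``dwcattributes`` terms are not claimed by
    ``dwc``.  Raises :class:`VocabularyError` for URIs outside every prefix.
    """
    best = None
    for prefix, base in PREFIXES.items():
        if uri.startswith(base) and (best is None or len(base) > len(PREFIXES[best])):
            best = prefix
    if best is None:
        raise VocabularyError(f"URI {uri!r} does not start with any known prefix")
    return best, uri[len(PREFIXES[best]):]


@dataclass(frozen=True)
class VocabTerm:
    uri: str
    local_name: str
    prefix: str
    kind: TermKind
    domain_class: str | None = None
    record_level: bool = False
    label: str = ""


@dataclass
class Vocabulary:
    """An indexed registry of vocabulary terms.

    Attributes
    ----------
    terms : dict
        All registered terms keyed by URI.
    core_classes : tuple
        The six core class URIs in canonical order.
    id_term_of : dict
        Core class URI -> its ID term URI (a bijection).
    """

    terms: dict[str, VocabTerm] = field(default_factory=dict)
    core_classes: tuple[str, ...] = SIX_CORE_CLASSES
    id_term_of: dict[str, str] = field(default_factory=dict)
    _by_local: dict[str, list[str]] = field(default_factory=dict, repr=False)

    def add(self, term: VocabTerm) -> None:
        if term.uri in self.terms:
            raise VocabularyError(f"duplicate term URI {term.uri!r}")
        self.terms[term.uri] = term
        self._by_local.setdefault(term.local_name.lower(), []).append(term.uri)

    # -- lookups ----------------------------------------------------------

    def term_for_column(self, column_uri_or_name: str) -> VocabTerm | None:
        """Resolve a column header to a vocabulary term.

        Full URIs are matched exactly (URIs are case-sensitive); bare names
        match registered local names case-insensitively.  Returns ``None``
        for unknown names; raises :class:`AmbiguousTermError` when a bare
        name exists under more than one prefix.
        """
        name = column_uri_or_name.strip()
        if not name:
            return None
        if "://" in name:
            return self.terms.get(name)
        uris = self._by_local.get(name.lower(), [])
        if not uris:
            return None
        if len(uris) > 1:
            raise AmbiguousTermError(name, uris)
        return self.terms[uris[0]]

    def class_of_term(self, term_uri: str) -> str | None:
        """The class a term belongs to: itself for classes, its domain
        otherwise; ``None`` for record-level terms without a single-class
        domain."""
        try:
            term = self.terms[term_uri]
        except KeyError:
            raise VocabularyError(f"term URI {term_uri!r} is not registered") from None
        if term.kind is TermKind.CLASS:
            return term.uri
        return term.domain_class

    # -- derived views ----------------------------------------------------

    def classes(self) -> list[VocabTerm]:
        return [t for t in self.terms.values() if t.kind is TermKind.CLASS]

    def dublin_core_classes(self) -> list[VocabTerm]:
        return [
            t for t in self.classes() if t.uri in DUBLIN_CORE_CLASSES
        ]

    def record_level_terms(self) -> list[VocabTerm]:
        return [t for t in self.terms.values() if t.record_level]

    def properties_of(self, class_uri: str) -> list[VocabTerm]:
        return [
            t
            for t in self.terms.values()
            if t.kind is TermKind.LITERAL_PROPERTY and t.domain_class == class_uri
        ]

    def is_class(self, uri: str) -> bool:
        t = self.terms.get(uri)
        return t is not None and t.kind is TermKind.CLASS

    # -- validation -------------------------------------------------------

    def _check(self) -> None:
        for uri, term in self.terms.items():
            if term.domain_class is not None and not self.is_class(term.domain_class):
                raise VocabularyError(
                    f"term {uri!r} has unregistered domain class {term.domain_class!r}"
                )
        for cls in self.core_classes:
            if not self.is_class(cls):
                raise VocabularyError(f"core class {cls!r} missing from snapshot")
        id_terms = [t for t in self.terms.values() if t.kind is TermKind.ID_TERM]
        self.id_term_of = {}
        for t in id_terms:
            if t.domain_class is None:
                raise VocabularyError(f"ID term {t.uri!r} lacks a domain class")
            if t.domain_class in self.id_term_of:
                raise VocabularyError(
                    f"class {t.domain_class!r} has more than one ID term"
                )
            self.id_term_of[t.domain_class] = t.uri
        missing = [c for c in self.core_classes if c not in self.id_term_of]
        if missing:
            raise VocabularyError(f"core classes without an ID term: {missing}")


def _parse_row(row: dict[str, str], lineno: int) -> VocabTerm:
    try:
        uri = row["uri"].strip()
        kind = TermKind(row["kind"].strip())
        domain = row.get("domain", "").strip() or None
        record_level = row.get("record_level", "0").strip() == "1"
        label = row.get("label", "").strip()
    except (KeyError, ValueError, AttributeError) as exc:
        raise VocabularyError(f"malformed snapshot row {lineno}: {row!r}") from exc
    if not uri:
        raise VocabularyError(f"malformed snapshot row {lineno}: empty URI")
    prefix, local = split_uri(uri)
    return VocabTerm(
        uri=uri,
        local_name=local,
        prefix=prefix,
        kind=kind,
        domain_class=domain,
        record_level=record_level,
        label=label,
    )


def _load_rdfs(path: Path) -> Vocabulary:
    # Accept an RDFS/Turtle vocabulary file as an alternative to the TSV:
    # rdf:type rdfs:Class rows become classes, rdf:Property rows with an
    # rdfs:domain become properties of that class.
    from rdflib import Graph
    from rdflib.namespace import RDF, RDFS

    g = Graph()
    g.parse(str(path))
    vocab = Vocabulary()
    for s in g.subjects(RDF.type, RDFS.Class):
        prefix, local = split_uri(str(s))
        vocab.add(VocabTerm(str(s), local, prefix, TermKind.CLASS))
    id_locals = {
        "occurrenceID", "eventID", "locationID", "geologicalContextID",
        "identificationID", "taxonID",
    }
    for s in g.subjects(RDF.type, RDF.Property):
        prefix, local = split_uri(str(s))
        domain = g.value(s, RDFS.domain)
        kind = TermKind.ID_TERM if local in id_locals else TermKind.LITERAL_PROPERTY
        vocab.add(
            VocabTerm(str(s), local, prefix, kind,
                      domain_class=str(domain) if domain else None)
        )
    vocab._check()
    return vocab


def load_vocabulary(snapshot_path: str | Path | None = None) -> Vocabulary:
    """Load the vocabulary from the bundled snapshot or a user override.

    ``snapshot_path`` may point to a TSV in the documented column layout or
    to an RDFS/Turtle file (``.ttl``/``.rdf``/``.xml`` extensions).
    """
    if snapshot_path is None:
        ref = resources.files("triplify").joinpath("data/dwc_terms.tsv")
        text = ref.read_text(encoding="utf-8")
    else:
        snapshot_path = Path(snapshot_path)
        if snapshot_path.suffix.lower() in {".ttl", ".rdf", ".xml", ".nt"}:
            return _load_rdfs(snapshot_path)
        text = snapshot_path.read_text(encoding="utf-8")

    vocab = Vocabulary()
    reader = csv.DictReader(text.splitlines(), delimiter="\t")
    for lineno, row in enumerate(reader, start=2):
        vocab.add(_parse_row(row, lineno))
    vocab._check()
    return vocab


# Thin functional wrappers mirroring the method surface.

def term_for_column(vocab: Vocabulary, column_uri_or_name: str) -> VocabTerm | None:
    return vocab.term_for_column(column_uri_or_name)


def class_of_term(vocab: Vocabulary, term_uri: str) -> str | None:
    return vocab.class_of_term(term_uri)
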