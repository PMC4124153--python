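"""Instance IRIs, triple emission, and the three serializations."""

import pytest
from rdflib import Graph, Literal, URIRef

from triplify import (
    build_auto_mapping,
    emit,
    make_instance_iri,
    normalize_table,
    serialize_dot,
    serialize_ntriples,
    serialize_turtle,
)
from triplify.emit import TripleGraph, ontology_prelude
from triplify.errors import IdentifierError
from triplify.mapping import EntityMapping, MappingConfig, Join, RelationMapping
from triplify.relations import ALIAS_OF, RELATED_TO
from triplify.tabular import Column, SourceTable

DWC = "http://rs.tdwg.org/dwc/terms/"
BSC = "http://biscicol.org/terms/biscicol.owl#"
RDF_TYPE = "http://www.w3.org/1999/02/22-rdf-syntax-ns#type"
BASE = "http://example.org/id/"


def entity(table="occurrence", id_column="occurrenceID", global_=False):
    return EntityMapping(table=table, id_column=id_column,
                         class_uri=DWC + "Occurrence", id_is_global=global_)


class TestInstanceIri:
    def test_concatenation_with_percent_encoding(self):
        iri = make_instance_iri(entity(), "MVZ:Herp:256", BASE)
        assert iri.iri == BASE + "occurrence.occurrenceID_MVZ%3AHerp%3A256"

    def test_decodes_back_to_the_concatenation(self):
        import urllib.parse

        iri = make_instance_iri(entity(), "MVZ Herp/256", BASE)
        decoded = urllib.parse.unquote(iri.iri[len(BASE):])
        assert decoded == "occurrence.occurrenceID_MVZ Herp/256"

    def test_global_identifier_used_verbatim(self):
        guid = "http://arctos.database.museum/guid/MVZ:Herp:256"
        iri = make_instance_iri(entity(global_=True), guid, BASE)
        assert iri.iri == guid

    def test_global_non_iri_value_is_an_error(self):
        with pytest.raises(IdentifierError, match="not a uri"):
            make_instance_iri(entity(global_=True), "not a uri", BASE)

    def test_empty_value_is_an_error(self):
        with pytest.raises(IdentifierError, match="empty"):
            make_instance_iri(entity(), "  ", BASE)

    def test_distinct_triplets_yield_distinct_iris(self):
        seen = set()
        for table in ("occurrence", "taxon"):
            for col in ("occurrenceID", "localID"):
                for value in ("1", "2", "a_b", "a.b", "a:b"):
                    e = EntityMapping(table=table, id_column=col,
                                      class_uri=DWC + "Occurrence")
                    seen.add(make_instance_iri(e, value, BASE).iri)
        assert len(seen) == 2 * 2 * 5


@pytest.fixture
def one_row_graph(vocab, class_graph):
    t = SourceTable("occ", [Column("occurrenceID"), Column("scientificName")],
                    [("OCC1", "Quercus alba")])
    ds = normalize_table(t, vocab)
    config = build_auto_mapping(ds, vocab, class_graph, BASE)
    return emit(ds.source_tables(), config, ds.link_table(), vocab), config


class TestEmit:
    def test_one_row_expected_graph(self, one_row_graph):
        g, _ = one_row_graph
        occ = BASE + "occurrence.occurrenceID_OCC1"
        taxon = BASE + "taxon.localID_1"
        assert (occ, RDF_TYPE, DWC + "Occurrence") in g
        assert (taxon, RDF_TYPE, DWC + "Taxon") in g
        assert (URIRef(taxon), URIRef(DWC + "scientificName"),
                Literal("Quercus alba")) in g.graph
        assert (occ, BSC + "related_to", taxon) in g

    def test_symmetric_relation_not_materialized_both_ways(self, one_row_graph):
        g, _ = one_row_graph
        occ = BASE + "occurrence.occurrenceID_OCC1"
        taxon = BASE + "taxon.localID_1"
        assert (taxon, BSC + "related_to", occ) not in g

    def test_empty_dataset_emits_prelude_only(self, vocab, class_graph):
        t = SourceTable("occ", [Column("occurrenceID"), Column("scientificName")], [])
        ds = normalize_table(t, vocab)
        config = build_auto_mapping(ds, vocab, class_graph, BASE)
        g = emit(ds.source_tables(), config, ds.link_table(), vocab)
        prelude = TripleGraph(BASE)
        ontology_prelude(prelude)
        assert g.triples() == prelude.triples()

    def test_empty_cell_emits_no_literal_triple(self, vocab, class_graph):
        t = SourceTable("occ",
                        [Column("occurrenceID"), Column("scientificName"),
                         Column("catalogNumber")],
                        [("OCC1", "", "C7")])
        ds = normalize_table(t, vocab)
        config = build_auto_mapping(ds, vocab, class_graph, BASE)
        g = emit(ds.source_tables(), config, ds.link_table(), vocab)
        literals = [o for _, _, o in g.graph if isinstance(o, Literal)]
        assert literals == [Literal("C7")]

    def test_prelude_declares_owl_semantics(self, one_row_graph):
        g, _ = one_row_graph
        owl = "http://www.w3.org/2002/07/owl#"
        assert (ALIAS_OF, RDF_TYPE, owl + "SymmetricProperty") in g
        assert (ALIAS_OF, RDF_TYPE, owl + "TransitiveProperty") in g
        assert (BSC + "depends_on", RDF_TYPE, owl + "ObjectProperty") in g

    def test_join_routed_relation_on_raw_tables(self, vocab):
        occ = SourceTable("occ", [Column("oid"), Column("eid")],
                          [("O1", "E1"), ("O2", "E1"), ("O3", "")])
        ev = SourceTable("ev", [Column("eid2")], [("E1",), ("E2",)])
        config = MappingConfig(
            base_uri=BASE,
            joins=[Join(left_table="occ", left_column="eid",
                        right_table="ev", right_column="eid2")],
            entities=[
                EntityMapping(table="occ", id_column="oid",
                              class_uri=DWC + "Occurrence"),
                EntityMapping(table="ev", id_column="eid2",
                              class_uri=DWC + "Event"),
            ],
            relations=[RelationMapping(
                subject_table="occ", subject_id_column="oid",
                property_uri=BSC + "depends_on",
                object_table="ev", object_id_column="eid2")],
        )
        g = emit({"occ": occ, "ev": ev}, config, None, vocab, prelude=False)
        rel_triples = {(str(s), str(o)) for s, p, o in g.graph
                       if str(p) == BSC + "depends_on"}
        assert rel_triples == {
            (BASE + "occ.oid_O1", BASE + "ev.eid2_E1"),
            (BASE + "occ.oid_O2", BASE + "ev.eid2_E1"),
        }


class TestSerialization:
    def test_ntriples_lines_are_sorted_and_terminated(self, one_row_graph):
        g, _ = one_row_graph
        text = serialize_ntriples(g)
        lines = text.splitlines()
        assert lines == sorted(lines)
        assert all(line.endswith(" .") for line in lines)
        assert len(lines) == len(g)

    def test_ntriples_round_trip(self, one_row_graph):
        g, _ = one_row_graph
        parsed = Graph()
        parsed.parse(data=serialize_ntriples(g), format="nt")
        assert set(parsed) == g.triples()

    def test_turtle_round_trip_and_prefixes(self, one_row_graph):
        g, _ = one_row_graph
        text = serialize_turtle(g)
        assert "@prefix dwc: <http://rs.tdwg.org/dwc/terms/> ." in text
        parsed = Graph()
        parsed.parse(data=text, format="turtle")
        assert set(parsed) == g.triples()

    def test_repeated_serialization_is_byte_identical(self, vocab, class_graph):
        t = SourceTable("occ", [Column("occurrenceID"), Column("scientificName")],
                        [("OCC1", "Quercus alba"), ("OCC2", "Acer rubrum")])
        outputs = set()
        for _ in range(2):
            ds = normalize_table(t, vocab)
            config = build_auto_mapping(ds, vocab, class_graph, BASE)
            g = emit(ds.source_tables(), config, ds.link_table(), vocab)
            outputs.add(serialize_ntriples(g))
            outputs.add(serialize_turtle(g))
        assert len(outputs) == 2  # one .nt text, one .ttl text

    def test_empty_graph_serializations(self):
        g = TripleGraph(BASE)
        assert serialize_ntriples(g) == ""
        assert serialize_dot(g) == "digraph triples {\n}\n"
        parsed = Graph()
        parsed.parse(data=serialize_turtle(g), format="turtle")
        assert len(parsed) == 0


class TestDot:
    def test_edge_per_triple_node_per_distinct_term(self, one_row_graph):
        g, _ = one_row_graph
        text = serialize_dot(g)
        edge_lines = [l for l in text.splitlines() if "->" in l]
        node_lines = [l for l in text.splitlines()
                      if "[label=" in l and "->" not in l]
        assert len(edge_lines) == len(g)
        distinct_terms = {s for s, _, _ in g.graph} | {o for _, _, o in g.graph}
        assert len(node_lines) == len(
            {("literal", str(t)) if isinstance(t, Literal) else ("iri", str(t))
             for t in distinct_terms}
        )

    def test_relation_edge_labeled_with_prefixed_predicate(self, one_row_graph):
        g, _ = one_row_graph
        text = serialize_dot(g)
        assert 'label="bsc:related_to"' in text

    def test_literals_use_box_shape(self, one_row_graph):
        g, _ = one_row_graph
        lines = [l for l in serialize_dot(g).splitlines()
                 if 'label="Quercus alba"' in l]
        assert len(lines) == 1 and "shape=box" in lines[0]
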