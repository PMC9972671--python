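"""RDF mapping: IRI minting, triple emission, serialization round-trips."""

import pytest
from rdflib import Graph, Literal, URIRef
from rdflib.namespace import RDF

from salon.errors import SalonError, SchemaViolationError, UnsupportedFormatError
from salon.fixtures import FixtureSpec, generate, with_columns
from salon.model import Alignment
from salon.rdf import (
    FORMATS,
    SALON,
    SALON_NAMESPACE,
    IriPolicy,
    from_rdf,
    mint_iri,
    serialize,
    to_rdf,
    to_sparql_update,
)
from salon.schema import builtin_schema

POLICY = IriPolicy()


class TestMintIri:
    def test_published_instance_pattern(self):
        assert mint_iri(POLICY, "BB11001", "1aab_") == URIRef(
            SALON_NAMESPACE + "BB11001_1aab_"
        )

    def test_sanitizer(self):
        assert str(mint_iri(POLICY, "A B", "x/y")).endswith("#A_B_x_y")

    def test_deterministic(self):
        assert mint_iri(POLICY, "a", "b") == mint_iri(POLICY, "a", "b")

    def test_empty_inputs_rejected(self):
        with pytest.raises(SalonError):
            mint_iri(POLICY, "", "x")


class TestToRdf:
    def test_forward_and_inverse_sequence_triples(self, small_alignment):
        g = to_rdf(small_alignment).graph
        assert len(list(g.subject_objects(SALON["hasSequence"]))) == 2
        assert len(list(g.subject_objects(SALON["isSequenceOf"]))) == 2

    def test_accession_literal(self, small_alignment):
        g = to_rdf(small_alignment).graph
        seq = URIRef(SALON_NAMESPACE + "BB11001_1aab_")
        assert (seq, SALON["accessionNumber"], Literal("P69905")) in g

    def test_subclass_typing(self, small_alignment):
        g = to_rdf(small_alignment).graph
        seq = URIRef(SALON_NAMESPACE + "BB11001_1aab_")
        assert (seq, RDF.type, SALON["ProteinAlignmentSequence"]) in g

    def test_empty_alignment_rejected_before_emission(self):
        with pytest.raises(SchemaViolationError):
            to_rdf(Alignment("empty", ()))

    def test_every_predicate_is_registered(self, seeded_alignment):
        reg = builtin_schema()
        g = to_rdf(seeded_alignment).graph
        for _, p, _ in g:
            if p == RDF.type:
                continue
            name = str(p)[len(SALON_NAMESPACE):]
            reg.lookup(name)  # raises KeyError if unregistered

    def test_forward_inverse_counts_match(self, seeded_alignment):
        g = to_rdf(seeded_alignment).graph
        for fwd, inv in builtin_schema().inverse_pairs():
            assert len(list(g.subject_objects(SALON[fwd]))) == len(
                list(g.subject_objects(SALON[inv]))
            )


class TestSerialization:
    @pytest.mark.parametrize("fmt", sorted(FORMATS))
    def test_round_trip_triple_set_equality(self, small_alignment, fmt):
        g = to_rdf(small_alignment)
        text = serialize(g, fmt)
        g2 = Graph()
        g2.parse(data=text, format=FORMATS[fmt])
        assert set(g2) == g.triples()

    @pytest.mark.parametrize("fmt", sorted(FORMATS))
    def test_empty_graph_serializes(self, fmt):
        from salon.rdf import TripleGraph

        text = serialize(TripleGraph(), fmt)
        g = Graph()
        g.parse(data=text, format=FORMATS[fmt])
        assert len(g) == 0

    def test_unknown_format(self, small_alignment):
        with pytest.raises(UnsupportedFormatError, match="turtle"):
            serialize(to_rdf(small_alignment), "csv")

    def test_sparql_update_export(self, small_alignment):
        update = to_sparql_update(to_rdf(small_alignment))
        assert update.startswith("INSERT DATA {")
        assert "BB11001_1aab_" in update


class TestFromRdf:
    @pytest.mark.parametrize("fmt", sorted(FORMATS))
    def test_model_round_trip(self, fmt):
        aln = with_columns(generate(FixtureSpec(seed=3, n_sequences=3, n_columns=12)))
        text = serialize(to_rdf(aln), fmt)
        assert from_rdf(text, fmt) == aln

    def test_missing_rdf_type_reported(self, small_alignment):
        g = to_rdf(small_alignment).graph
        seq = URIRef(SALON_NAMESPACE + "BB11001_1aab_")
        g.remove((seq, RDF.type, SALON["ProteinAlignmentSequence"]))
        text = g.serialize(format="turtle")
        violations = []
        from_rdf(text, "turtle", violations=violations)
        assert any("no rdf:type" in v for v in violations)
        with pytest.raises(SchemaViolationError):
            from_rdf(text, "turtle")

    def test_inverse_only_graph_equivalent(self, small_alignment):
        full = to_rdf(small_alignment).graph
        reg = builtin_schema()
        inverse_only = Graph()
        forwards = {fwd for fwd, _ in reg.inverse_pairs()}
        for s, p, o in full:
            name = str(p)[len(SALON_NAMESPACE):] if str(p).startswith(SALON_NAMESPACE) else None
            if name in forwards:
                inv = reg.object_properties[name].inverse_of
                inverse_only.add((o, SALON[inv], s))
            else:
                inverse_only.add((s, p, o))
        a1 = from_rdf(full.serialize(format="turtle"), "turtle")
        a2 = from_rdf(inverse_only.serialize(format="turtle"), "turtle")
        assert a1 == a2

    def test_no_alignment_node(self):
        with pytest.raises(SchemaViolationError, match="no salon:Alignment"):
            from_rdf("", "turtle")
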