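"""Enrichment queries, offline client behaviour, description-line dialects."""

import random

import pytest
from rdflib import URIRef

from salon.enrichment import (
    StaticEndpointClient,
    build_accession_query,
    build_pdb_query,
    enrich,
)
from salon.errors import SalonError
from salon.fasta import parse_fasta
from salon.headers import ncbi_header, record_from_fields, uniprot_header
from salon.model import ProteinRecord
from salon.rdf import SALON, SALON_NAMESPACE, to_rdf


class TestQueryBuilders:
    def test_accession_query_contains_service_block(self):
        q = build_accession_query("1D2N")
        assert "SERVICE <https://sparql.uniprot.org/sparql>" in q
        assert '"1D2N"' in q
        assert q.lstrip().startswith("PREFIX")

    def test_pdb_query_selects_seven_header_fields(self):
        q = build_pdb_query("1AAB")
        for var in (
            "?db",
            "?unique_identifier",
            "?entry_name",
            "?protein_name",
            "?organism_name",
            "?gene_name",
            "?protein_existence",
        ):
            assert var in q

    def test_deterministic(self):
        assert build_accession_query("P69905") == build_accession_query("P69905")
        assert build_pdb_query("1AAB") == build_pdb_query("1AAB")

    def test_injection_guard(self):
        q = build_accession_query('x" } DROP ALL #')
        assert '\\"' in q
        assert 'x" }' not in q

    def test_empty_inputs(self):
        with pytest.raises(SalonError):
            build_accession_query("")
        with pytest.raises(SalonError):
            build_pdb_query("")


ROW_P69905 = {
    "accession": "P69905",
    "entry_name": "HBA_HUMAN",
    "protein_name": "Hemoglobin subunit alpha",
    "organism_name": "Homo sapiens",
    "gene_name": "HBA1",
    "protein_existence": "1",
    "db": "sp",
}


class TestEnrich:
    def test_adds_protein_link_without_mutating_alignment(self, small_alignment):
        before = to_rdf(small_alignment).triples()
        client = StaticEndpointClient({"P69905": [ROW_P69905]})
        outcome = enrich(small_alignment, client)
        assert len(outcome.results) == 1
        rec = outcome.results[0].protein
        assert rec.accession_number == "P69905"
        assert rec.gene_name == "HBA1"
        g = outcome.graph.graph
        links = list(g.subject_objects(SALON["hasAssociationWithProtein"]))
        assert len(links) == 1
        assert links[0][0] == URIRef(SALON_NAMESPACE + "BB11001")
        # enrichment only adds: the original alignment triples are intact
        assert before <= outcome.graph.triples()

    def test_ambiguous_matches_surfaced_and_ranked(self, small_alignment):
        rows = [
            {**ROW_P69905, "accession": "Q11111", "protein_existence": "3"},
            {**ROW_P69905, "accession": "P69905", "protein_existence": "1"},
            {**ROW_P69905, "accession": "A00001", "protein_existence": "2"},
        ]
        outcome = enrich(small_alignment, StaticEndpointClient({"P69905": rows}))
        result = outcome.results[0]
        assert result.is_ambiguous
        # strongest evidence (lowest PE code) wins
        assert result.protein.accession_number == "P69905"
        assert {r.accession_number for r in result.ambiguous_matches} == {"Q11111", "A00001"}

    def test_failing_client_isolated_per_accession(self, small_alignment):
        class ExplodingClient:
            def execute(self, query_text):
                raise ConnectionError("endpoint down")

        before = to_rdf(small_alignment).triples()
        outcome = enrich(small_alignment, ExplodingClient())
        assert outcome.results == []
        assert list(outcome.failures) == ["P69905"]
        assert outcome.graph.triples() == before

    def test_no_rows_is_a_reported_failure(self, small_alignment):
        outcome = enrich(small_alignment, StaticEndpointClient({}))
        assert outcome.failures == {"P69905": "no rows returned"}


def _random_record(rng):
    maybe = lambda v: v if rng.random() < 0.7 else None
    return ProteinRecord(
        accession_number="P" + "".join(rng.choices("0123456789", k=5)),
        entry_name=maybe("NAME" + str(rng.randint(0, 99)) + "_HUMAN"),
        protein_name=maybe("Protein " + rng.choice("ABCDEFG")),
        organism_name=maybe(rng.choice(["Homo sapiens", "Mus musculus"])),
        gene_name=maybe("GEN" + str(rng.randint(0, 9))),
        protein_existence=rng.randint(1, 5) if rng.random() < 0.7 else None,
        db_tag=rng.choice(["sp", "tr"]),
    )


class TestHeaderDialects:
    def test_uniprot_header_field_order(self):
        rec = ProteinRecord(
            accession_number="P69905",
            entry_name="HBA_HUMAN",
            protein_name="Hemoglobin subunit alpha",
            organism_name="Homo sapiens",
            gene_name="HBA1",
            protein_existence=1,
            db_tag="sp",
        )
        assert uniprot_header(rec) == (
            ">sp|P69905|HBA_HUMAN Hemoglobin subunit alpha OS=Homo sapiens GN=HBA1 PE=1"
        )

    def test_absent_fields_omit_tags(self):
        rec = ProteinRecord(accession_number="P1", entry_name="E_X")
        header = uniprot_header(rec)
        assert "GN=" not in header and "OS=" not in header and "PE=" not in header

    def test_ncbi_header_bracket(self):
        rec = ProteinRecord(
            accession_number="NP_000549.1",
            protein_name="hemoglobin subunit alpha",
            organism_name="Homo sapiens",
        )
        assert ncbi_header(rec).endswith("[Homo sapiens]")
        rec2 = ProteinRecord(accession_number="NP_1", protein_name="x")
        assert "[" not in ncbi_header(rec2)

    @pytest.mark.parametrize("dialect", ["uniprotkb", "ncbi"])
    def test_generate_parse_identity_randomized(self, dialect):
        """Header generation then dialect parsing recovers every populated
        field, over 150 random protein records."""
        rng = random.Random(2024)
        for _ in range(150):
            rec = _random_record(rng)
            header = uniprot_header(rec) if dialect == "uniprotkb" else ncbi_header(rec)
            (parsed,) = parse_fasta(header + "\nMKWV\n", dialect=dialect)
            back = record_from_fields(parsed.parsed_fields)
            assert back.accession_number == rec.accession_number
            if dialect == "uniprotkb":
                assert back.entry_name == rec.entry_name
                assert back.protein_name == rec.protein_name
                assert back.organism_name == rec.organism_name
                assert back.gene_name == rec.gene_name
                assert back.protein_existence == rec.protein_existence
                assert back.db_tag == rec.db_tag
            else:
                assert back.organism_name == rec.organism_name
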