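"""Semantic enrichment of aligned protein sequences from UniProtKB.

For every distinct accession number in an alignment, a federated SPARQL
query (a ``SELECT`` wrapping a ``SERVICE`` block aimed at the UniProt
endpoint) retrieves the protein's name, source organism, gene and NCBI
identifier.  Returned rows become :class:`ProteinRecord` objects and are
linked into the local graph with ``hasAssociationWithProtein`` triples, so
the information is persisted on arrival and later queries never depend on
the remote endpoint again.

Remote access goes exclusively through an injected client object exposing
``execute(query_text) -> rows``; tests use canned fixtures
(:class:`StaticEndpointClient`) and an optional stdlib-urllib live client is
provided for interactive use.  Endpoint failures degrade gracefully: the
alignment stays untouched and failures are reported per accession.

When a single PDB identifier maps to several UniProtKB entries (frequent
for highly conserved proteins in closely related species), all candidates
are surfaced for expert review; the default selection prefers the strongest
protein-existence evidence (lowest PE code), then the lexicographically
first accession.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Protocol, Sequence

from .errors import SalonError
from .model import Alignment, ProteinRecord
from .rdf import SALON, IriPolicy, TripleGraph, mint_iri, to_rdf
from rdflib import Literal, URIRef
from rdflib.namespace import RDF, XSD

__all__ = [
    "DEFAULT_ENDPOINT",
    "EndpointClient",
    "StaticEndpointClient",
    "UrllibEndpointClient",
    "EnrichmentResult",
    "EnrichmentOutcome",
    "build_accession_query",
    "build_pdb_query",
    "enrich",
]

logger = logging.getLogger(__name__)

DEFAULT_ENDPOINT = "https://sparql.uniprot.org/sparql"

# UniProt core predicates used in the query templates; configurable because
# remote vocabularies evolve independently of this package
DEFAULT_PREDICATES = {
    "core": "http://purl.uniprot.org/core/",
    "mnemonic": "http://purl.uniprot.org/core/mnemonic",
    "fullName": "http://purl.uniprot.org/core/fullName",
    "recommendedName": "http://purl.uniprot.org/core/recommendedName",
    "organism": "http://purl.uniprot.org/core/organism",
    "scientificName": "http://purl.uniprot.org/core/scientificName",
    "encodedBy": "http://purl.uniprot.org/core/encodedBy",
    "skosPrefLabel": "http://www.w3.org/2004/02/skos/core#prefLabel",
    "existence": "http://purl.uniprot.org/core/existence",
    "rdfsSeeAlso": "http://www.w3.org/2000/01/rdf-schema#seeAlso",
}


class EndpointClient(Protocol):
    """The only channel to remote data: execute a query, return rows."""

    def execute(self, query_text: str) -> Sequence[dict]:  # pragma: no cover
        ...


@dataclass
class StaticEndpointClient:
    """Offline client serving canned rows keyed by accession/PDB id.

    ``responses`` maps a key to a list of row dicts (the keys a live
    endpoint would bind: protein_name, organism_name, gene_name, ncbi_id,
    entry_name, db, protein_existence, accession).  Used by tests and the
    CLI ``--offline`` mode.
    """

    responses: dict[str, list[dict]]

    @classmethod
    def from_json(cls, path: str) -> "StaticEndpointClient":
        with open(path) as fh:
            return cls(json.load(fh))

    def execute(self, query_text: str) -> list[dict]:
        for key, rows in self.responses.items():
            if f'"{_escape(key)}"' in query_text:
                return rows
        return []


class UrllibEndpointClient:
    """Live SPARQL-over-HTTP client (stdlib only); not used by the tests."""

    def __init__(self, endpoint: str = DEFAULT_ENDPOINT, timeout: float = 30.0):
        self.endpoint = endpoint
        self.timeout = timeout

    def execute(self, query_text: str) -> list[dict]:  # pragma: no cover - network
        import urllib.parse
        import urllib.request

        url = self.endpoint + "?" + urllib.parse.urlencode(
            {"query": query_text, "format": "json"}
        )
        req = urllib.request.Request(url, headers={"Accept": "application/sparql-results+json"})
        with urllib.request.urlopen(req, timeout=self.timeout) as resp:
            payload = json.load(resp)
        rows = []
        for binding in payload.get("results", {}).get("bindings", []):
            rows.append({k: v.get("value") for k, v in binding.items()})
        return rows


@dataclass
class EnrichmentResult:
    """Selected protein record plus any unselected ambiguous candidates."""

    key: str
    protein: ProteinRecord
    ambiguous_matches: list[ProteinRecord] = field(default_factory=list)

    @property
    def is_ambiguous(self) -> bool:
        return bool(self.ambiguous_matches)


@dataclass
class EnrichmentOutcome:
    results: list[EnrichmentResult]
    failures: dict[str, str]
    graph: TripleGraph


def _escape(text: str) -> str:
    """Escape a string for inclusion in a SPARQL literal."""
    return text.replace("\\", "\\\\").replace('"', '\\"').replace("\n", "\\n")


def build_accession_query(
    accession: str,
    endpoint: str = DEFAULT_ENDPOINT,
    predicates: dict | None = None,
) -> str:
    """Federated query aggregating protein name, organism, gene and NCBI id
    for a UniProtKB accession.  Deterministic for fixed inputs."""
    if not accession:
        raise SalonError("accession must be non-empty")
    p = {**DEFAULT_PREDICATES, **(predicates or {})}
    acc = _escape(accession)
    return f"""\
PREFIX up: <{p['core']}>
SELECT ?protein_name ?organism_name ?gene_name ?ncbi_id ?entry_name
WHERE {{
  SERVICE <{endpoint}> {{
    ?protein <{p['mnemonic']}> ?entry_name ;
             <{p['recommendedName']}> ?rn ;
             <{p['organism']}> ?org .
    ?rn <{p['fullName']}> ?protein_name .
    ?org <{p['scientificName']}> ?organism_name .
    OPTIONAL {{ ?protein <{p['encodedBy']}> ?gene . ?gene <{p['skosPrefLabel']}> ?gene_name . }}
    OPTIONAL {{ ?protein <{p['rdfsSeeAlso']}> ?ncbi_id . }}
    FILTER ( STRENDS( STR(?protein), "{acc}" ) )
  }}
}}
"""


def build_pdb_query(
    pdb_id: str,
    endpoint: str = DEFAULT_ENDPOINT,
    predicates: dict | None = None,
) -> str:
    """Federated query retrieving the seven description-line fields (db,
    unique identifier, entry name, protein name, organism name, gene name,
    protein existence) for entries cross-referenced to a PDB id."""
    if not pdb_id:
        raise SalonError("pdb_id must be non-empty")
    p = {**DEFAULT_PREDICATES, **(predicates or {})}
    pdb = _escape(pdb_id)
    return f"""\
PREFIX up: <{p['core']}>
SELECT ?db ?unique_identifier ?entry_name ?protein_name ?organism_name ?gene_name ?protein_existence
WHERE {{
  SERVICE <{endpoint}> {{
    ?protein <{p['rdfsSeeAlso']}> ?xref ;
             <{p['mnemonic']}> ?entry_name ;
             <{p['recommendedName']}> ?rn ;
             <{p['organism']}> ?org ;
             <{p['existence']}> ?protein_existence .
    ?rn <{p['fullName']}> ?protein_name .
    ?org <{p['scientificName']}> ?organism_name .
    OPTIONAL {{ ?protein <{p['encodedBy']}> ?gene . ?gene <{p['skosPrefLabel']}> ?gene_name . }}
    FILTER ( STRENDS( STR(?xref), "{pdb}" ) )
    BIND ( "sp" AS ?db )
    BIND ( STRAFTER( STR(?protein), "uniprot/" ) AS ?unique_identifier )
  }}
}}
"""


def _record_from_row(row: dict, fallback_accession: str) -> ProteinRecord:
    pe = row.get("protein_existence")
    return ProteinRecord(
        accession_number=row.get("accession") or row.get("unique_identifier") or fallback_accession,
        entry_name=row.get("entry_name"),
        protein_name=row.get("protein_name"),
        organism_name=row.get("organism_name"),
        gene_name=row.get("gene_name"),
        protein_existence=int(pe) if pe not in (None, "") else None,
        db_tag=row.get("db"),
        ncbi_id=row.get("ncbi_id"),
    )


def _select(records: list[ProteinRecord]) -> tuple[ProteinRecord, list[ProteinRecord]]:
    # strongest protein-existence evidence first (PE=1 best), then accession
    ranked = sorted(
        records,
        key=lambda r: (r.protein_existence if r.protein_existence is not None else 99,
                       r.accession_number),
    )
    return ranked[0], ranked[1:]


def _merge_protein(graph: TripleGraph, policy: IriPolicy, alignment: Alignment,
                   record: ProteinRecord) -> None:
    aln_iri = URIRef(policy.base + policy.sanitize(alignment.alignment_id))
    prot_iri = mint_iri(policy, "protein", record.accession_number)
    graph.add(prot_iri, RDF.type, SALON["Protein"])
    graph.add(aln_iri, SALON["hasAssociationWithProtein"], prot_iri)
    literals = {
        "accessionNumber": record.accession_number,
        "db": record.db_tag,
        "entryName": record.entry_name,
        "proteinName": record.protein_name,
        "organismName": record.organism_name,
        "geneName": record.gene_name,
        "ncbiIdentifier": record.ncbi_id,
    }
    for pname, value in literals.items():
        if value is not None:
            graph.add(prot_iri, SALON[pname], Literal(str(value)))
    if record.protein_existence is not None:
        graph.add(
            prot_iri,
            SALON["proteinExistence"],
            Literal(record.protein_existence, datatype=XSD.integer),
        )
    for pdb in record.pdb_ids:
        graph.add(prot_iri, SALON["pdbIdentifier"], Literal(pdb))


def enrich(
    alignment: Alignment,
    client: EndpointClient,
    policy: IriPolicy | None = None,
    graph: TripleGraph | None = None,
    endpoint: str = DEFAULT_ENDPOINT,
) -> EnrichmentOutcome:
    """Enrich an alignment with protein records for its accession numbers.

    One query per distinct accession; returned rows are merged into *graph*
    (default: a fresh mapping of the alignment) as Protein individuals
    linked by ``hasAssociationWithProtein``.  Sequence residues and
    alignment structure are never mutated; a failing client call yields a
    per-accession failure entry instead of an exception.
    """
    policy = policy or IriPolicy()
    if graph is None:
        graph = to_rdf(alignment, policy=policy)
    accessions = sorted(
        {
            seq.accession_number
            for sub in alignment.sub_alignments
            for seq in sub.sequences
            if seq.accession_number
        }
    )
    results: list[EnrichmentResult] = []
    failures: dict[str, str] = {}
    for acc in accessions:
        query = build_accession_query(acc, endpoint=endpoint)
        try:
            rows = list(client.execute(query))
        except Exception as exc:  # failure isolation per accession
            logger.warning("enrichment query for %s failed: %s", acc, exc)
            failures[acc] = str(exc)
            continue
        if not rows:
            failures[acc] = "no rows returned"
            continue
        records = [_record_from_row(row, acc) for row in rows]
        selected, others = _select(records)
        _merge_protein(graph, policy, alignment, selected)
        results.append(EnrichmentResult(key=acc, protein=selected, ambiguous_matches=others))
    return EnrichmentOutcome(results=results, failures=failures, graph=graph)
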