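"""Generation of FASTA description lines in the UniProtKB and NCBI dialects.

FASTA has no strict header standard; UniProtKB and NCBI prescribe different
field layouts and third-party tools break on inconsistent lines.  These
builders emit standardized description lines from :class:`ProteinRecord`
annotations:

* UniProtKB: ``>db|UniqueIdentifier|EntryName ProteinName OS=Organism
  GN=Gene PE=N`` — absent optional fields omit their tag entirely.
* NCBI: ``>accession description [Organism]`` — the organism bracket is
  omitted when unknown.
"""

from __future__ import annotations

from .errors import SalonError
from .model import ProteinRecord

__all__ = ["uniprot_header", "ncbi_header", "record_from_fields", "fields_from_record"]


def uniprot_header(record: ProteinRecord) -> str:
    """UniProtKB description line for *record* (``db_tag`` defaults to sp)."""
    if not record.accession_number:
        raise SalonError("UniProtKB header requires a unique identifier")
    db = record.db_tag or "sp"
    parts = [f">{db}|{record.accession_number}|{record.entry_name or ''}"]
    if record.protein_name:
        parts.append(record.protein_name)
    if record.organism_name:
        parts.append(f"OS={record.organism_name}")
    if record.gene_name:
        parts.append(f"GN={record.gene_name}")
    if record.protein_existence is not None:
        parts.append(f"PE={record.protein_existence}")
    header = " ".join(parts)
    if "\n" in header:
        raise SalonError("header fields must not contain newlines")
    return header


def ncbi_header(record: ProteinRecord) -> str:
    """NCBI description line for *record*."""
    if not record.accession_number:
        raise SalonError("NCBI header requires an accession")
    header = f">{record.accession_number}"
    description = record.protein_name or record.entry_name
    if description:
        header += f" {description}"
    if record.organism_name:
        header += f" [{record.organism_name}]"
    if "\n" in header:
        raise SalonError("header fields must not contain newlines")
    return header


def record_from_fields(fields: dict) -> ProteinRecord:
    """Build a :class:`ProteinRecord` from dialect-parsed header fields."""
    accession = fields.get("unique_identifier") or fields.get("accession")
    if not accession:
        raise SalonError("parsed fields carry no accession/unique identifier")
    return ProteinRecord(
        accession_number=accession,
        entry_name=fields.get("entry_name"),
        protein_name=fields.get("protein_name") or fields.get("description"),
        organism_name=fields.get("organism_name") or fields.get("organism"),
        gene_name=fields.get("gene_name"),
        protein_existence=fields.get("protein_existence"),
        db_tag=fields.get("db"),
    )


def fields_from_record(record: ProteinRecord, dialect: str) -> dict:
    """Dialect field map for *record*, omitting absent values."""
    if dialect == "uniprotkb":
        fields = {
            "db": record.db_tag or "sp",
            "unique_identifier": record.accession_number,
            "entry_name": record.entry_name,
            "protein_name": record.protein_name,
            "organism_name": record.organism_name,
            "gene_name": record.gene_name,
            "protein_existence": record.protein_existence,
        }
    elif dialect == "ncbi":
        fields = {
            "accession": record.accession_number,
            "description": record.protein_name or record.entry_name,
            "organism": record.organism_name,
        }
    else:
        raise SalonError(f"unknown header dialect: {dialect!r}")
    return {k: v for k, v in fields.items() if v is not None}
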