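"""FASTA reading/writing with UniProtKB and NCBI description-line dialects.

Records are split with Biopython's FASTA parser; the dialect layer then
interprets the description line:

* ``uniprotkb`` — ``db|UniqueIdentifier|EntryName ProteinName OS=.. OX=..
  GN=.. PE=.. SV=..``; unknown ``XY=`` tags are retained verbatim.
* ``ncbi`` — ``accession description [organism]``.
* ``raw`` — the header is kept unparsed.

Missing optional fields are absent from ``parsed_fields`` (never empty
strings), so generate→parse is the identity on populated fields.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field

from Bio.SeqIO.FastaIO import SimpleFastaParser

from .errors import FastaDialectError, FastaFormatError

__all__ = ["FastaRecord", "parse_fasta", "write_fasta", "DIALECTS"]

DIALECTS = ("uniprotkb", "ncbi", "raw")

_UNIPROT_HEAD = re.compile(r"^([^|\s]+)\|([^|\s]*)\|(\S*)\s*(.*)$", re.S)
_TAG = re.compile(r"(?:^|\s)([A-Z]{2})=")
_KNOWN_TAGS = {
    "OS": "organism_name",
    "OX": "organism_taxid",
    "GN": "gene_name",
    "PE": "protein_existence",
    "SV": "sequence_version",
}


@dataclass
class FastaRecord:
    """One FASTA record: raw header (without '>'), parsed fields, residues."""

    raw_header: str
    residues: str
    parsed_fields: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if "\n" in self.raw_header:
            raise FastaFormatError("header must not contain a newline")
        if not self.residues:
            raise FastaFormatError(f"record {self.raw_header!r} has no residues")


def _parse_uniprot_header(header: str) -> dict:
    if header.count("|") < 2:
        raise FastaDialectError(
            f"UniProtKB header needs db|id|entry segments: {header!r}"
        )
    m = _UNIPROT_HEAD.match(header)
    if not m:
        raise FastaDialectError(f"cannot parse UniProtKB header: {header!r}")
    db, uid, entry, rest = m.groups()
    fields: dict = {"db": db, "unique_identifier": uid}
    if entry:
        fields["entry_name"] = entry

    tags = list(_TAG.finditer(rest))
    name_end = tags[0].start() if tags else len(rest)
    protein_name = rest[:name_end].strip()
    if protein_name:
        fields["protein_name"] = protein_name
    extra_tags: list[str] = []
    for i, t in enumerate(tags):
        value_end = tags[i + 1].start() if i + 1 < len(tags) else len(rest)
        value = rest[t.end() : value_end].strip()
        tag = t.group(1)
        key = _KNOWN_TAGS.get(tag)
        if key is None:
            extra_tags.append(f"{tag}={value}")
        elif value:
            fields[key] = int(value) if tag == "PE" else value
    if extra_tags:
        fields["extra_tags"] = extra_tags
    return fields


def _build_uniprot_header(fields: dict) -> str:
    parts = [
        "{}|{}|{}".format(
            fields.get("db", "sp"),
            fields.get("unique_identifier", ""),
            fields.get("entry_name", ""),
        )
    ]
    if fields.get("protein_name"):
        parts.append(str(fields["protein_name"]))
    for tag, key in _KNOWN_TAGS.items():
        if fields.get(key) is not None:
            parts.append(f"{tag}={fields[key]}")
    parts.extend(fields.get("extra_tags", ()))
    return " ".join(parts)


def _parse_ncbi_header(header: str) -> dict:
    header = header.strip()
    if not header:
        raise FastaDialectError("empty NCBI header")
    accession, _, rest = header.partition(" ")
    fields: dict = {"accession": accession}
    rest = rest.strip()
    if rest.endswith("]") and "[" in rest:
        bracket = rest.rindex("[")
        organism = rest[bracket + 1 : -1].strip()
        if organism:
            fields["organism"] = organism
        rest = rest[:bracket].strip()
    if rest:
        fields["description"] = rest
    return fields


def _build_ncbi_header(fields: dict) -> str:
    header = str(fields.get("accession", ""))
    if fields.get("description"):
        header += f" {fields['description']}"
    if fields.get("organism"):
        header += f" [{fields['organism']}]"
    return header


def parse_fasta(text: str, dialect: str = "raw") -> list[FastaRecord]:
    """Parse FASTA text into records, interpreting headers per *dialect*.

    Never drops a record: the result has one entry per '>' line.  Residues
    are uppercased; gap symbols are preserved.
    """
    if dialect not in DIALECTS:
        raise FastaDialectError(
            f"unknown dialect {dialect!r}; expected one of {DIALECTS}"
        )
    if not text.strip():
        raise FastaFormatError("empty FASTA input")
    if not text.lstrip().startswith(">"):
        raise FastaFormatError("FASTA input must start with a '>' header line")
    records = []
    for header, seq in SimpleFastaParser(io.StringIO(text)):
        residues = "".join(seq.split()).upper()
        parsed: dict = {}
        if dialect == "uniprotkb":
            parsed = _parse_uniprot_header(header)
        elif dialect == "ncbi":
            parsed = _parse_ncbi_header(header)
        records.append(FastaRecord(raw_header=header, residues=residues, parsed_fields=parsed))
    return records


def write_fasta(records: list[FastaRecord], dialect: str = "raw", line_width: int = 60) -> str:
    """Serialize records; headers are regenerated from parsed fields.

    With dialect ``raw`` (or when a record has no parsed fields) the raw
    header is emitted verbatim.  parse∘write is the identity on parsed
    fields and residues.
    """
    if line_width < 1:
        raise FastaFormatError("line_width must be >= 1")
    out: list[str] = []
    for rec in records:
        if dialect == "uniprotkb" and rec.parsed_fields:
            header = _build_uniprot_header(rec.parsed_fields)
        elif dialect == "ncbi" and rec.parsed_fields:
            header = _build_ncbi_header(rec.parsed_fields)
        else:
            header = rec.raw_header
        out.append(">" + header)
        for i in range(0, len(rec.residues), line_width):
            out.append(rec.residues[i : i + line_width])
    return "\n".join(out) + "\n"
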