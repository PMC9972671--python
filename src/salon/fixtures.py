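"""Seeded synthetic alignment generator.

Emulates BAliBASE-style annotated alignments at a controllable level of
conservation and gappiness so that the whole pipeline (MACSIM XML, RDF
mapping, scoring, validation) can be exercised without downloads.  Exactly
``round(conservation * n_columns)`` columns are totally conserved (one
residue type, no gap); the remaining columns are guaranteed not to be, with
gaps placed independently at ``gap_rate`` per cell.  Generation is a pure
function of the spec: identical spec + seed give byte-identical output.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .errors import SalonError
from .macsim import write_macsim
from .model import (
    Alignment,
    AlignmentSequence,
    ConstructionMethod,
    Feature,
    SubAlignment,
    build_columns,
)

__all__ = [
    "FixtureSpec",
    "generate",
    "generate_macsim",
    "with_columns",
    "PROTEIN_ALPHABET",
    "DNA_ALPHABET",
]

#: the 20 standard amino acids — matches the 20-residue entropy bound
PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
DNA_ALPHABET = "ACGT"

_FEATURE_TYPES = ("DOMAIN", "STRAND", "HELIX", "MOTIF", "SITE")
_ORGANISMS = (
    "Homo sapiens",
    "Mus musculus",
    "Saccharomyces cerevisiae",
    "Escherichia coli",
)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic alignment."""

    n_sequences: int = 4
    n_columns: int = 30
    molecule: str = "Protein"
    conservation: float = 0.5
    gap_rate: float = 0.1
    n_features: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sequences < 1 or self.n_columns < 1:
            raise SalonError("n_sequences and n_columns must be >= 1")
        if self.molecule not in ("DNA", "Protein"):
            raise SalonError("molecule must be 'DNA' or 'Protein'")
        if not (0.0 <= self.conservation <= 1.0 and 0.0 <= self.gap_rate <= 1.0):
            raise SalonError("conservation and gap_rate must lie in [0, 1]")
        if self.n_features < 0:
            raise SalonError("n_features must be >= 0")


def _nonconserved_column(rng: random.Random, n: int, alphabet: str, gap_rate: float) -> list[str]:
    """A column of n cells that is guaranteed not totally conserved."""
    while True:
        cells = [
            "-" if rng.random() < gap_rate else rng.choice(alphabet)
            for _ in range(n)
        ]
        # totally conserved means one residue type and no gap; n == 1 cannot
        # avoid it, so a single-sequence spec yields all-conserved columns
        if n == 1:
            return cells
        if "-" in cells or len(set(cells)) > 1:
            return cells


def generate(spec: FixtureSpec) -> Alignment:
    """Generate one alignment with a single sub-alignment per the spec."""
    rng = random.Random(spec.seed)
    alphabet = PROTEIN_ALPHABET if spec.molecule == "Protein" else DNA_ALPHABET
    n_conserved = round(spec.conservation * spec.n_columns)
    conserved_positions = set(rng.sample(range(spec.n_columns), n_conserved))

    columns: list[list[str]] = []
    for i in range(spec.n_columns):
        if i in conserved_positions:
            columns.append([rng.choice(alphabet)] * spec.n_sequences)
        else:
            columns.append(
                _nonconserved_column(rng, spec.n_sequences, alphabet, spec.gap_rate)
            )

    sequences = []
    for s in range(spec.n_sequences):
        residues = "".join(col[s] for col in columns)
        features = []
        for _ in range(spec.n_features if s == 0 else 0):
            fstart = rng.randint(1, spec.n_columns)
            fstop = rng.randint(fstart, spec.n_columns)
            features.append(
                Feature(
                    ftype=rng.choice(_FEATURE_TYPES),
                    fstart=fstart,
                    fstop=fstop,
                    fnote=f"synthetic feature {fstart}-{fstop}",
                )
            )
        features.sort(key=lambda f: (f.fstart, f.fstop, f.ftype))
        sequences.append(
            AlignmentSequence(
                identifier=f"seq{s + 1:03d}",
                residues=residues,
                accession_number=f"P{rng.randint(0, 99999):05d}",
                organism=rng.choice(_ORGANISMS),
                keywords=(),
                molecule=spec.molecule,  # type: ignore[arg-type]
                features=tuple(features),
            )
        )

    alignment_id = f"SYN{spec.seed:05d}"
    sub = SubAlignment(
        name=alignment_id,
        sequences=tuple(sequences),
        construction_method=ConstructionMethod("synthetic_generator", "stochastic"),
        gap_character="-",
    )
    alignment = Alignment(alignment_id=alignment_id, sub_alignments=(sub,))
    return alignment


def generate_macsim(spec: FixtureSpec) -> str:
    """MACSIM XML text for the generated alignment (deterministic)."""
    return write_macsim(generate(spec))


def with_columns(alignment: Alignment) -> Alignment:
    """Copy of *alignment* with columns materialized from the first
    sub-alignment."""
    return Alignment(
        alignment_id=alignment.alignment_id,
        sub_alignments=alignment.sub_alignments,
        alignment_scores=alignment.alignment_scores,
        columns=build_columns(alignment.sub_alignments[0]),
    )
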