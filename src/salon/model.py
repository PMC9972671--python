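"""Typed in-memory model of sequence alignments.

The object model mirrors the SALON schema: an :class:`Alignment` holds one or
more :class:`SubAlignment` blocks (subsets of sequences sharing a property,
e.g. a cluster), each holding aligned :class:`AlignmentSequence` records with
optional annotated :class:`Feature` regions.  Columns are derived from the
sequences by transposition; scores are attached to alignments and columns via
:class:`Score` objects that point at a :class:`ScoreFunction` carrying its
declared bounds.  Constructors enforce structural invariants (equal aligned
lengths, feature coordinates inside the sequence); cardinality and score-bound
checking is the job of :mod:`salon.validation`, not of the constructors.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

from .errors import (
    EmptyColumnError,
    MixedGapError,
    RaggedAlignmentError,
    SalonError,
)

__all__ = [
    "Feature",
    "AlignmentSequence",
    "AlignmentColumn",
    "SubAlignment",
    "Alignment",
    "ScoreFunction",
    "Score",
    "ReliabilityMeasure",
    "ConstructionMethod",
    "ProteinRecord",
    "build_columns",
    "consensus_character",
    "detect_gap_character",
    "GAP_ALPHABET",
]

#: gap symbols recognised in aligned sequences; anything else is a residue
GAP_ALPHABET = ("-", ".")


@dataclass(frozen=True)
class Feature:
    """An annotated region of a sequence, 1-based inclusive coordinates."""

    ftype: str
    fstart: int
    fstop: int
    fnote: Optional[str] = None
    fscore: Optional[float] = None

    def __post_init__(self) -> None:
        if not (1 <= self.fstart <= self.fstop):
            raise SalonError(
                f"feature {self.ftype!r}: need 1 <= fstart <= fstop, "
                f"got fstart={self.fstart}, fstop={self.fstop}"
            )


@dataclass(frozen=True)
class AlignmentSequence:
    """One aligned sequence (gaps included) plus its annotations.

    ``length`` is derived from the aligned string (gaps counted) when not
    supplied.  ``molecule`` selects the DNA/Protein subclass used in the RDF
    mapping.
    """

    identifier: str
    residues: str
    accession_number: Optional[str] = None
    length: Optional[int] = None
    organism: Optional[str] = None
    keywords: tuple[str, ...] = ()
    molecule: Literal["DNA", "Protein"] = "Protein"
    features: tuple[Feature, ...] = ()
    extras: tuple[str, ...] = ()  # pass-through XML snippets from richer inputs

    def __post_init__(self) -> None:
        if not self.identifier:
            raise SalonError("sequence identifier must be non-empty")
        if self.molecule not in ("DNA", "Protein"):
            raise SalonError(f"unknown molecule kind: {self.molecule!r}")
        if self.length is None:
            object.__setattr__(self, "length", len(self.residues))
        elif self.length != len(self.residues):
            raise SalonError(
                f"sequence {self.identifier!r}: declared length {self.length} "
                f"!= aligned string length {len(self.residues)}"
            )
        for f in self.features:
            if f.fstop > len(self.residues):
                raise SalonError(
                    f"feature {f.ftype!r} on {self.identifier!r}: fstop={f.fstop} "
                    f"exceeds sequence length {len(self.residues)}"
                )

    @property
    def salon_class(self) -> str:
        return "ProteinAlignmentSequence" if self.molecule == "Protein" else "DNAAlignmentSequence"


@dataclass(frozen=True)
class ScoreFunction:
    """A scoring function with declared bounds.

    ``kind`` says whether it scores whole alignments or single columns.
    Bounds may be left unset; validation then skips bound checks for scores
    under this function.
    """

    name: str
    kind: Literal["alignment", "column"]
    score_min: Optional[float] = None
    score_max: Optional[float] = None
    optimization: Literal["maximization", "minimization"] = "maximization"

    def __post_init__(self) -> None:
        if self.score_min is not None and self.score_max is not None:
            if self.score_min > self.score_max:
                raise SalonError(
                    f"score function {self.name!r}: score_min > score_max"
                )


@dataclass(frozen=True)
class Score:
    """A score value under a function; bounds are checked by validation."""

    value: float
    function: ScoreFunction


@dataclass(frozen=True)
class ReliabilityMeasure:
    """A per-column confidence measure (e.g. GUIDANCE, Heads-or-Tails).

    ``unreliable_when`` must be set explicitly: below_cutoff flags columns
    whose confidence falls strictly below the cutoff (the usual GUIDANCE
    filtering direction), above_cutoff the opposite.  Optional declared range
    bounds make out-of-range scores an error rather than silently clamped.
    """

    name: str
    score_cutoff: float
    unreliable_when: Literal["below_cutoff", "above_cutoff"]
    score_min: Optional[float] = None
    score_max: Optional[float] = None

    def __post_init__(self) -> None:
        if self.unreliable_when not in ("below_cutoff", "above_cutoff"):
            raise SalonError(
                "unreliable_when must be 'below_cutoff' or 'above_cutoff'"
            )


@dataclass(frozen=True)
class ConstructionMethod:
    name: str
    approach: Literal["deterministic", "stochastic"]

    def __post_init__(self) -> None:
        if self.approach not in ("deterministic", "stochastic"):
            raise SalonError(f"unknown approach: {self.approach!r}")


@dataclass(frozen=True)
class AlignmentColumn:
    """One column: position (1-based), per-sequence characters, derived data."""

    at_sequence_index: int
    column: str
    consensus_character: Optional[str] = None
    column_weight: Optional[int] = None
    column_scores: tuple[Score, ...] = ()

    def __post_init__(self) -> None:
        if self.at_sequence_index < 1:
            raise SalonError("at_sequence_index is 1-based and must be >= 1")
        if not self.column:
            raise EmptyColumnError("column string must be non-empty")


@dataclass(frozen=True)
class SubAlignment:
    """A subset of the alignment's sequences with a common gap character."""

    name: str
    sequences: tuple[AlignmentSequence, ...]
    construction_method: Optional[ConstructionMethod] = None
    gap_character: str = "-"
    extras: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.gap_character) != 1:
            raise SalonError("gap_character must be a single character")
        if self.sequences:
            ref = len(self.sequences[0].residues)
            for seq in self.sequences[1:]:
                if len(seq.residues) != ref:
                    raise RaggedAlignmentError(
                        f"sequence {seq.identifier!r} has aligned length "
                        f"{len(seq.residues)}, expected {ref}"
                    )


@dataclass(frozen=True)
class Alignment:
    """A pairwise or multiple sequence alignment."""

    alignment_id: str
    sub_alignments: tuple[SubAlignment, ...]
    alignment_scores: tuple[Score, ...] = ()
    columns: tuple[AlignmentColumn, ...] = ()

    def __post_init__(self) -> None:
        if not self.alignment_id:
            raise SalonError("alignment_id must be non-empty")


@dataclass(frozen=True)
class ProteinRecord:
    """Protein annotations gathered from a reference database entry."""

    accession_number: str
    entry_name: Optional[str] = None
    protein_name: Optional[str] = None
    organism_name: Optional[str] = None
    gene_name: Optional[str] = None
    protein_existence: Optional[int] = None
    db_tag: Optional[str] = None
    ncbi_id: Optional[str] = None
    pdb_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.accession_number:
            raise SalonError("accession_number must be non-empty")


def consensus_character(column: str, gap_character: str = "-") -> str:
    """Most frequent non-gap character of a column.

    Ties break lexicographically; an all-gap column returns the gap
    character itself.
    """
    if not column:
        raise EmptyColumnError("cannot take the consensus of an empty column")
    counts = Counter(c for c in column if c != gap_character)
    if not counts:
        return gap_character
    best = max(counts.items(), key=lambda kv: (kv[1], -ord(kv[0][0])))
    # max over (count, -ord) picks highest count, then lexicographically
    # smallest character among ties
    return best[0]


def build_columns(sub: SubAlignment) -> tuple[AlignmentColumn, ...]:
    """Transpose a sub-alignment into columns (1-based positions).

    Column *i* concatenates character *i* of each sequence in input order;
    the consensus character is filled in.
    """
    if not sub.sequences:
        raise SalonError("cannot build columns of an empty sub-alignment")
    ref = len(sub.sequences[0].residues)
    for seq in sub.sequences:
        if len(seq.residues) != ref:
            raise RaggedAlignmentError(
                f"sequence {seq.identifier!r} has aligned length "
                f"{len(seq.residues)}, expected {ref}"
            )
    cols = []
    for i in range(ref):
        text = "".join(seq.residues[i] for seq in sub.sequences)
        cols.append(
            AlignmentColumn(
                at_sequence_index=i + 1,
                column=text,
                consensus_character=consensus_character(text, sub.gap_character),
            )
        )
    return tuple(cols)


def detect_gap_character(sequences: Sequence[str]) -> str:
    """Infer the gap character ('-' or '.') used by aligned strings.

    Defaults to '-' when no gap symbol occurs; a mixture of both symbols is
    an error rather than a silent guess.
    """
    if not sequences:
        raise SalonError("need at least one sequence")
    present = {g for g in GAP_ALPHABET for s in sequences if g in s}
    if len(present) > 1:
        raise MixedGapError("sequences mix '-' and '.' gap symbols")
    return present.pop() if present else "-"
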