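"""Column- and alignment-level score functions.

Three built-in metrics quantify the quality of a multiple alignment:

* **percent totally conserved columns** — a column scores 1 iff every row
  holds the same non-gap residue; the alignment score is the percentage of
  such columns (0–100).
* **percent non-gaps** — a column scores 1 iff it contains no gap; alignment
  score again a percentage.
* **entropy** — Shannon entropy in bits of the non-gap residue frequencies,
  ranging from 0 (a single residue type) to log2(20) ≈ 4.322 bits when all
  20 amino acids are equally represented; the alignment score is the sum
  over columns.

Reliability measures (GUIDANCE, Heads-or-Tails) are consumed, not computed:
given per-column confidence scores and a cutoff, columns on the wrong side
of the cutoff (strictly — the cutoff itself always passes) are flagged as
unreliably aligned.
"""

from __future__ import annotations

import math
from collections import Counter
from typing import Iterable, Sequence

from scipy.stats import entropy as _shannon_entropy

from .errors import AllGapColumnError, EmptyColumnError, SalonError, ScoreRangeError
from .model import (
    Alignment,
    ReliabilityMeasure,
    Score,
    ScoreFunction,
    build_columns,
)

__all__ = [
    "column_entropy",
    "conserved_column_score",
    "non_gap_column_score",
    "alignment_percentage_score",
    "alignment_entropy_score",
    "flag_unreliable_columns",
    "catalog",
    "score_alignment",
    "MAX_COLUMN_ENTROPY",
]

#: maximum per-column entropy: 20 equiprobable amino acids, log2(20)
MAX_COLUMN_ENTROPY = math.log2(20)


def column_entropy(column: str, gap_character: str = "-") -> float:
    """Shannon entropy (bits) of the non-gap residue frequencies of a column."""
    if not column:
        raise EmptyColumnError("cannot score an empty column")
    counts = Counter(c for c in column if c != gap_character)
    if not counts:
        raise AllGapColumnError("entropy undefined on an all-gap column")
    return float(_shannon_entropy(list(counts.values()), base=2))


def conserved_column_score(column: str, gap_character: str = "-") -> int:
    """1 iff the column is totally conserved (one residue type, no gap)."""
    if not column:
        raise EmptyColumnError("cannot score an empty column")
    return int(gap_character not in column and len(set(column)) == 1)


def non_gap_column_score(column: str, gap_character: str = "-") -> int:
    """1 iff the column contains no gap character."""
    if not column:
        raise EmptyColumnError("cannot score an empty column")
    return int(gap_character not in column)


def alignment_percentage_score(column_scores: Sequence[float]) -> float:
    """Percentage of columns scoring 1: ``100 * sum / n``, in [0, 100]."""
    if not column_scores:
        raise SalonError("need at least one column score")
    return 100.0 * sum(column_scores) / len(column_scores)


def alignment_entropy_score(columns: Iterable[str], gap_character: str = "-") -> float:
    """Sum of per-column entropies over the alignment."""
    values = [column_entropy(c, gap_character) for c in columns]
    if not values:
        raise SalonError("need at least one column")
    return float(sum(values))


def flag_unreliable_columns(
    column_scores: Sequence[float], measure: ReliabilityMeasure
) -> list[int]:
    """1-based indices of columns flagged unreliable by *measure*.

    Comparison with the cutoff is strict in both directions, so a score
    exactly at the cutoff is never flagged.  A score outside the measure's
    declared range raises rather than being clamped.
    """
    flagged = []
    for i, s in enumerate(column_scores, start=1):
        if measure.score_min is not None and s < measure.score_min:
            raise ScoreRangeError(
                f"column {i}: score {s} below declared minimum {measure.score_min}"
            )
        if measure.score_max is not None and s > measure.score_max:
            raise ScoreRangeError(
                f"column {i}: score {s} above declared maximum {measure.score_max}"
            )
        if measure.unreliable_when == "below_cutoff":
            if s < measure.score_cutoff:
                flagged.append(i)
        elif s > measure.score_cutoff:
            flagged.append(i)
    return flagged


class ScoreFunctionCatalog:
    """Registry of named score functions and their per-column scorers."""

    def __init__(self) -> None:
        self._entries: dict = {}

    def register(self, name, column_scorer, column_fn_factory, alignment_fn_factory, aggregator):
        self._entries[name] = (column_scorer, column_fn_factory, alignment_fn_factory, aggregator)

    def names(self) -> list[str]:
        return sorted(self._entries)

    def __contains__(self, name: str) -> bool:
        return name in self._entries

    def __getitem__(self, name: str):
        if name not in self._entries:
            raise SalonError(
                f"unknown score function {name!r}; available: {', '.join(self.names())}"
            )
        return self._entries[name]


def _percentage_catalog_entry(name: str):
    return (
        lambda n_cols: ScoreFunction(f"{name}_column", "column", 0.0, 1.0),
        lambda n_cols: ScoreFunction(name, "alignment", 0.0, 100.0),
        lambda scores: alignment_percentage_score(scores),
    )


catalog = ScoreFunctionCatalog()
catalog.register(
    "percent_totally_conserved",
    conserved_column_score,
    *_percentage_catalog_entry("percent_totally_conserved"),
)
catalog.register(
    "percent_non_gaps",
    non_gap_column_score,
    *_percentage_catalog_entry("percent_non_gaps"),
)
catalog.register(
    "entropy",
    column_entropy,
    lambda n_cols: ScoreFunction("entropy_column", "column", 0.0, MAX_COLUMN_ENTROPY),
    # alignment-level maximum: one maximal column entropy per column
    lambda n_cols: ScoreFunction("entropy", "alignment", 0.0, n_cols * MAX_COLUMN_ENTROPY),
    lambda scores: float(sum(scores)),
)


def score_alignment(alignment: Alignment, function_name: str, gap_character: str | None = None):
    """Score every column of the first sub-alignment plus the whole alignment.

    Returns ``(column_scores, alignment_score)`` where both carry
    :class:`~salon.model.Score` objects with bounded functions attached.
    """
    column_scorer, col_fn_factory, aln_fn_factory, aggregate = catalog[function_name]
    if not alignment.sub_alignments:
        raise SalonError("alignment has no sub-alignments to score")
    sub = alignment.sub_alignments[0]
    gap = gap_character or sub.gap_character
    columns = alignment.columns or build_columns(sub)
    n = len(columns)
    col_fn = col_fn_factory(n)
    aln_fn = aln_fn_factory(n)
    col_scores = [Score(float(column_scorer(c.column, gap)), col_fn) for c in columns]
    aln_score = Score(float(aggregate([s.value for s in col_scores])), aln_fn)
    return col_scores, aln_score
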