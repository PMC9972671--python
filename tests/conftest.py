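import pytest

from salon.fixtures import FixtureSpec, generate, with_columns
from salon.model import (
    Alignment,
    AlignmentColumn,
    AlignmentSequence,
    Score,
    ScoreFunction,
    SubAlignment,
)
from salon.schema import builtin_schema


@pytest.fixture(scope="session")
def registry():
    return builtin_schema()


@pytest.fixture
def small_alignment():
    """Two protein sequences, one with an accession, no gaps."""
    seqs = (
        AlignmentSequence(identifier="1aab_", residues="MKVLA", accession_number="P69905"),
        AlignmentSequence(identifier="2lef_A", residues="MKV-A"),
    )
    sub = SubAlignment(name="BB11001", sequences=seqs, gap_character="-")
    return Alignment(alignment_id="BB11001", sub_alignments=(sub,))


@pytest.fixture
def worked_example():
    """An alignment score of 95 under a 0-100 maximization function and one
    column score of 1 under a 0-1 function: the published worked example of
    a correct alignment."""
    aln_fn = ScoreFunction("overall_quality", "alignment", 0.0, 100.0)
    col_fn = ScoreFunction("percent_totally_conserved_column", "column", 0.0, 1.0)
    seqs = (
        AlignmentSequence(identifier="s1", residues="MK"),
        AlignmentSequence(identifier="s2", residues="MK"),
    )
    sub = SubAlignment(name="fig", sequences=seqs)
    col = AlignmentColumn(1, "MM", column_scores=(Score(1.0, col_fn),))
    return Alignment(
        alignment_id="FIG2",
        sub_alignments=(sub,),
        alignment_scores=(Score(95.0, aln_fn),),
        columns=(col,),
    )


@pytest.fixture
def seeded_alignment():
    return with_columns(generate(FixtureSpec(seed=11, n_sequences=4, n_columns=20)))
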