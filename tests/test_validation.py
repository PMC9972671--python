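"""Validation rules: score bounds, cardinality, reliability, aggregation."""

import itertools

import pytest

from salon.errors import MissingScoreError
from salon.model import (
    Alignment,
    AlignmentColumn,
    AlignmentSequence,
    ReliabilityMeasure,
    Score,
    ScoreFunction,
    SubAlignment,
)
from salon.validation import (
    RULE_IDS,
    check_cardinality,
    check_reliability,
    check_score_bounds,
    export_swrl_rules,
    validate,
)

ALN_FN = ScoreFunction("quality", "alignment", 0.0, 100.0)
COL_FN = ScoreFunction("col_quality", "column", 0.0, 1.0)


class TestScoreBounds:
    @pytest.mark.parametrize("value", [95.0, 0.0, 100.0])
    def test_within_inclusive_bounds(self, value):
        assert check_score_bounds(Score(value, ALN_FN)) == []

    @pytest.mark.parametrize(
        "value,fn,rule",
        [
            (101.0, ALN_FN, "alignment_score_gt_max"),
            (-1.0, ALN_FN, "alignment_score_lt_min"),
            (1.5, COL_FN, "column_score_gt_max"),
            (-0.5, COL_FN, "column_score_lt_min"),
        ],
    )
    def test_each_incorrectness_rule(self, value, fn, rule):
        violations = check_score_bounds(Score(value, fn))
        assert [v.rule_id for v in violations] == [rule]

    def test_exhaustive_interval_oracle(self):
        """Brute force over (score, bounds) pairs: the bound verdict always
        matches a direct interval test and triggers at most one rule."""
        values = [-10.0, -0.1, 0.0, 0.5, 1.0, 1.1, 50.0, 100.0, 100.5]
        bounds = [(0.0, 1.0), (0.0, 100.0), (-5.0, 5.0)]
        for kind in ("alignment", "column"):
            for value, (lo, hi) in itertools.product(values, bounds):
                fn = ScoreFunction("f", kind, lo, hi)
                violations = check_score_bounds(Score(value, fn))
                assert len(violations) <= 1
                assert bool(violations) == (not lo <= value <= hi)
                if violations:
                    expected = f"{kind}_score_{'gt_max' if value > hi else 'lt_min'}"
                    assert violations[0].rule_id == expected

    def test_metamorphic_scaling(self):
        """Scaling a score and its bounds by any positive constant leaves
        the verdict unchanged."""
        for value, lo, hi in [(95.0, 0.0, 100.0), (101.0, 0.0, 100.0), (-1.0, 0.0, 1.0)]:
            base = check_score_bounds(Score(value, ScoreFunction("f", "alignment", lo, hi)))
            for k in (0.01, 2.0, 1000.0):
                scaled = check_score_bounds(
                    Score(value * k, ScoreFunction("f", "alignment", lo * k, hi * k))
                )
                assert [v.rule_id for v in scaled] == [v.rule_id for v in base]

    def test_missing_bounds_disable_check(self):
        fn = ScoreFunction("unbounded", "alignment")
        assert check_score_bounds(Score(1e9, fn)) == []


def _alignment(n_seqs, n_subs=1):
    subs = tuple(
        SubAlignment(
            name=f"sub{j}",
            sequences=tuple(
                AlignmentSequence(identifier=f"s{j}_{i}", residues="MK")
                for i in range(n_seqs)
            ),
        )
        for j in range(n_subs)
    )
    return Alignment("A1", subs)


class TestCardinality:
    def test_one_sequence_fails(self):
        violations = check_cardinality(_alignment(1))
        assert [v.rule_id for v in violations] == ["subalignment_min_sequences"]

    def test_two_sequences_pass(self):
        assert check_cardinality(_alignment(2)) == []

    def test_no_subalignments_fails(self):
        violations = check_cardinality(Alignment("A1", ()))
        assert [v.rule_id for v in violations] == ["alignment_min_subalignments"]


def _with_reliability_scores(values, fn_name="GUIDANCE"):
    fn = ScoreFunction(fn_name, "column", 0.0, 1.0)
    cols = tuple(
        AlignmentColumn(i + 1, "MK", column_scores=(Score(v, fn),))
        for i, v in enumerate(values)
    )
    base = _alignment(2)
    return Alignment(base.alignment_id, base.sub_alignments, columns=cols)


class TestReliability:
    def test_flags_below_cutoff(self):
        aln = _with_reliability_scores([0.9, 0.2])
        measure = ReliabilityMeasure("GUIDANCE", 0.5, "below_cutoff")
        violations = check_reliability(aln, measure)
        assert [v.rule_id for v in violations] == ["unreliable_column"]
        assert violations[0].subject.endswith("column2")

    def test_all_above_cutoff_clean(self):
        aln = _with_reliability_scores([0.9, 0.8])
        assert check_reliability(aln, ReliabilityMeasure("GUIDANCE", 0.5, "below_cutoff")) == []

    def test_missing_score_names_column(self):
        aln = _with_reliability_scores([0.9, 0.8, 0.7], fn_name="other")
        with pytest.raises(MissingScoreError, match="column 1"):
            check_reliability(aln, ReliabilityMeasure("GUIDANCE", 0.5, "below_cutoff"))


class TestValidate:
    def test_worked_example_is_correct(self, worked_example):
        report = validate(worked_example)
        assert report.verdict == "correct"
        assert report.violations == []

    def test_perturbed_alignment_score(self, worked_example):
        broken = Alignment(
            worked_example.alignment_id,
            worked_example.sub_alignments,
            alignment_scores=(Score(-1.0, worked_example.alignment_scores[0].function),),
            columns=worked_example.columns,
        )
        report = validate(broken)
        assert report.verdict == "incorrect"
        assert [v.rule_id for v in report.violations] == ["alignment_score_lt_min"]

    def test_single_sequence_subalignment_incorrect(self):
        report = validate(_alignment(1))
        assert report.verdict == "incorrect"
        assert {v.rule_id for v in report.violations} == {"subalignment_min_sequences"}

    def test_unreliability_does_not_flip_verdict(self, worked_example):
        fn = ScoreFunction("GUIDANCE", "column", 0.0, 1.0)
        cols = tuple(
            AlignmentColumn(
                c.at_sequence_index,
                c.column,
                column_scores=c.column_scores + (Score(0.1, fn),),
            )
            for c in worked_example.columns
        )
        aln = Alignment(
            worked_example.alignment_id,
            worked_example.sub_alignments,
            alignment_scores=worked_example.alignment_scores,
            columns=cols,
        )
        report = validate(
            aln, measures=[ReliabilityMeasure("GUIDANCE", 0.5, "below_cutoff")]
        )
        assert report.verdict == "correct"
        assert report.unreliable_columns == [1]
        assert any(v.rule_id == "unreliable_column" for v in report.violations)

    def test_validate_is_pure_and_deterministic(self, worked_example):
        r1 = validate(worked_example)
        r2 = validate(worked_example)
        assert r1.to_dict() == r2.to_dict()


def test_rule_id_inventory():
    assert {
        "column_score_gt_max",
        "column_score_lt_min",
        "alignment_score_gt_max",
        "alignment_score_lt_min",
    } < RULE_IDS


def test_swrl_rule_export():
    rules = export_swrl_rules()
    assert len(rules) == 6
    assert all("->" in text for text in rules.values())
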