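"""Alignment validation: score bounds, cardinalities, reliability.

Re-implements natively the rule set published with the SALON ontology as
SWRL rules, so no triple store or OWL reasoner is needed:

* **correctness** — every alignment-level and column-level score lies within
  the declared ``[scoreMin, scoreMax]`` of its score function (bounds
  inclusive).
* **incorrectness** — four mutually exclusive rules: column score above max,
  column score below min, alignment score above max, alignment score below
  min.
* **unreliability** — columns whose confidence under a reliability measure
  falls on the wrong side of the cutoff are flagged.  Unreliable columns are
  a filtering aid, not an incorrectness: they never flip the verdict.

Cardinality constraints from the schema (an alignment has at least one
sub-alignment; a sub-alignment has at least two sequences) are checked in
the same pass.  For users who do run a SWRL-capable reasoner,
:func:`export_swrl_rules` emits the equivalent rule texts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal

from .errors import MissingScoreError
from .model import Alignment, ReliabilityMeasure, Score
from .scoring import flag_unreliable_columns
from .schema import SchemaRegistry, builtin_schema

__all__ = [
    "RULE_IDS",
    "Violation",
    "ValidationReport",
    "check_score_bounds",
    "check_cardinality",
    "check_reliability",
    "validate",
    "export_swrl_rules",
]

logger = logging.getLogger(__name__)

RULE_IDS = frozenset(
    {
        "column_score_gt_max",
        "column_score_lt_min",
        "alignment_score_gt_max",
        "alignment_score_lt_min",
        "unreliable_column",
        "subalignment_min_sequences",
        "alignment_min_subalignments",
        "schema_assertion",
    }
)


@dataclass(frozen=True)
class Violation:
    """One rule finding: closed rule id, subject path, readable detail."""

    rule_id: str
    subject: str
    detail: str

    def __post_init__(self) -> None:
        if self.rule_id not in RULE_IDS:
            raise ValueError(f"unknown rule_id: {self.rule_id!r}")


@dataclass
class ValidationReport:
    """Machine-readable validation outcome.

    ``verdict`` is ``correct`` iff no violation other than
    ``unreliable_column`` entries was found.
    """

    verdict: Literal["correct", "incorrect"]
    violations: list[Violation] = field(default_factory=list)
    unreliable_columns: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "verdict": self.verdict,
            "violations": [
                {"rule_id": v.rule_id, "subject": v.subject, "detail": v.detail}
                for v in self.violations
            ],
            "unreliable_columns": self.unreliable_columns,
        }


def check_score_bounds(score: Score, subject: str = "score") -> list[Violation]:
    """Bound check for one score; at most one violation (bounds inclusive).

    A function with no declared bound on one side disables that side's
    check (with a logged note), mirroring per-function bound declarations.
    """
    fn = score.function
    prefix = "alignment" if fn.kind == "alignment" else "column"
    if fn.score_max is None or fn.score_min is None:
        logger.warning(
            "score function %r lacks declared bounds; bound check skipped for %s",
            fn.name,
            subject,
        )
    if fn.score_max is not None and score.value > fn.score_max:
        return [
            Violation(
                f"{prefix}_score_gt_max",
                subject,
                f"{fn.name}: score {score.value} > scoreMax {fn.score_max}",
            )
        ]
    if fn.score_min is not None and score.value < fn.score_min:
        return [
            Violation(
                f"{prefix}_score_lt_min",
                subject,
                f"{fn.name}: score {score.value} < scoreMin {fn.score_min}",
            )
        ]
    return []


def check_cardinality(alignment: Alignment) -> list[Violation]:
    """Minimum-cardinality checks from the schema."""
    violations = []
    if not alignment.sub_alignments:
        violations.append(
            Violation(
                "alignment_min_subalignments",
                alignment.alignment_id,
                "an alignment contains at least one sub-alignment; found 0",
            )
        )
    for i, sub in enumerate(alignment.sub_alignments, start=1):
        if len(sub.sequences) < 2:
            violations.append(
                Violation(
                    "subalignment_min_sequences",
                    f"{alignment.alignment_id}/sub{i}",
                    f"a sub-alignment has at least two sequences; "
                    f"{sub.name!r} has {len(sub.sequences)}",
                )
            )
    return violations


def check_reliability(
    alignment: Alignment, measure: ReliabilityMeasure
) -> list[Violation]:
    """Flag unreliable columns under *measure*.

    Every materialized column must carry a score whose function name matches
    the measure; a missing score is an error naming the column.
    """
    scores = []
    for col in alignment.columns:
        match = [s for s in col.column_scores if s.function.name == measure.name]
        if not match:
            raise MissingScoreError(
                f"column {col.at_sequence_index} carries no {measure.name!r} score"
            )
        scores.append(match[0].value)
    flagged = flag_unreliable_columns(scores, measure)
    index_of = {i: col.at_sequence_index for i, col in enumerate(alignment.columns, 1)}
    return [
        Violation(
            "unreliable_column",
            f"{alignment.alignment_id}/column{index_of[i]}",
            f"{measure.name}: confidence fails cutoff {measure.score_cutoff} "
            f"({measure.unreliable_when})",
        )
        for i in flagged
    ]


def _schema_assertions(alignment: Alignment, registry: SchemaRegistry) -> list[Violation]:
    violations = []

    def check(s_class: str, pname: str, o_kind: str, subject: str) -> None:
        result = registry.check_assertion(s_class, pname, o_kind)
        if not result.ok:
            violations.append(Violation("schema_assertion", subject, result.detail))

    aid = alignment.alignment_id
    for i, sub in enumerate(alignment.sub_alignments, start=1):
        check("Alignment", "hasSubAlignment", "SubAlignment", aid)
        for seq in sub.sequences:
            check("SubAlignment", "hasSequence", seq.salon_class, f"{aid}/sub{i}")
            for _ in seq.features:
                check(seq.salon_class, "hasFeature", "Feature", seq.identifier)
        if sub.construction_method is not None:
            m_class = (
                "DeterministicApproach"
                if sub.construction_method.approach == "deterministic"
                else "StochasticApproach"
            )
            check("SubAlignment", "hasConstructionMethod", m_class, f"{aid}/sub{i}")
    for _ in alignment.alignment_scores:
        check("Alignment", "hasAlignmentScore", "AlignmentScore", aid)
    for col in alignment.columns:
        check("Alignment", "hasColumn", "AlignmentColumn", aid)
        for _ in col.column_scores:
            check(
                "AlignmentColumn",
                "hasColumnScore",
                "ColumnScore",
                f"{aid}/column{col.at_sequence_index}",
            )
    return violations


def validate(
    alignment: Alignment,
    registry: SchemaRegistry | None = None,
    measures: Iterable[ReliabilityMeasure] = (),
) -> ValidationReport:
    """Run every check and aggregate a deterministic report.

    Score bounds are checked for all alignment-level and column-level
    scores; cardinalities per the schema; reliability per supplied measure;
    and every modeled relation against the schema registry.  All problems
    are reported, never thrown.
    """
    registry = registry or builtin_schema()
    violations: list[Violation] = []
    for j, score in enumerate(alignment.alignment_scores, start=1):
        violations.extend(
            check_score_bounds(score, f"{alignment.alignment_id}/alignmentScore{j}")
        )
    for col in alignment.columns:
        for j, score in enumerate(col.column_scores, start=1):
            violations.extend(
                check_score_bounds(
                    score,
                    f"{alignment.alignment_id}/column{col.at_sequence_index}/score{j}",
                )
            )
    violations.extend(check_cardinality(alignment))
    violations.extend(_schema_assertions(alignment, registry))

    unreliable: list[Violation] = []
    for measure in measures:
        unreliable.extend(check_reliability(alignment, measure))

    verdict = "correct" if not violations else "incorrect"
    report = ValidationReport(
        verdict=verdict,
        violations=violations + unreliable,
        unreliable_columns=sorted(
            int(v.subject.rsplit("column", 1)[-1]) for v in unreliable
        ),
    )
    return report


#: SWRL-syntax rule texts equivalent to the native checks, for users who run
#: an OWL reasoner themselves.
_SWRL_RULES = {
    "correctness": (
        "Alignment(?a) ^ hasAlignmentScore(?a, ?s) ^ score(?s, ?v) ^ "
        "hasAlignmentScoreFunction(?s, ?f) ^ scoreMin(?f, ?min) ^ scoreMax(?f, ?max) ^ "
        "swrlb:greaterThanOrEqual(?v, ?min) ^ swrlb:lessThanOrEqual(?v, ?max) "
        "-> CorrectAlignment(?a)"
    ),
    "incorrectness_alignment_score_lt_min": (
        "Alignment(?a) ^ hasAlignmentScore(?a, ?s) ^ score(?s, ?v) ^ "
        "hasAlignmentScoreFunction(?s, ?f) ^ scoreMin(?f, ?min) ^ "
        "swrlb:lessThan(?v, ?min) -> IncorrectAlignment(?a)"
    ),
    "incorrectness_alignment_score_gt_max": (
        "Alignment(?a) ^ hasAlignmentScore(?a, ?s) ^ score(?s, ?v) ^ "
        "hasAlignmentScoreFunction(?s, ?f) ^ scoreMax(?f, ?max) ^ "
        "swrlb:greaterThan(?v, ?max) -> IncorrectAlignment(?a)"
    ),
    "incorrectness_column_score_lt_min": (
        "AlignmentColumn(?c) ^ hasColumnScore(?c, ?s) ^ score(?s, ?v) ^ "
        "hasColumnScoreFunction(?s, ?f) ^ scoreMin(?f, ?min) ^ "
        "swrlb:lessThan(?v, ?min) -> IncorrectColumn(?c)"
    ),
    "incorrectness_column_score_gt_max": (
        "AlignmentColumn(?c) ^ hasColumnScore(?c, ?s) ^ score(?s, ?v) ^ "
        "hasColumnScoreFunction(?s, ?f) ^ scoreMax(?f, ?max) ^ "
        "swrlb:greaterThan(?v, ?max) -> IncorrectColumn(?c)"
    ),
    "unreliability": (
        "AlignmentColumn(?c) ^ hasColumnScore(?c, ?s) ^ score(?s, ?v) ^ "
        "hasColumnScoreFunction(?s, ?f) ^ ReliabilityMeasure(?f) ^ "
        "scoreCutoff(?f, ?t) ^ swrlb:lessThan(?v, ?t) -> UnreliableColumn(?c)"
    ),
}


def export_swrl_rules() -> dict[str, str]:
    """The rule texts in SWRL human-readable syntax."""
    return dict(_SWRL_RULES)
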