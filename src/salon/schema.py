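"""In-code registry of the SALON schema.

SALON (Sequence ALignment ONtology) describes pairwise and multiple sequence
alignments: alignments contain sub-alignments, sub-alignments contain aligned
sequences, sequences carry features, and alignments/columns carry scores with
declared bounds.  This module encodes the published class hierarchy, the 14
object properties (10 forward, 4 inverses), the data properties with their
datatypes, and the two cardinality constraints, as plain queryable metadata.
Mapping (:mod:`salon.rdf`) and validation (:mod:`salon.validation`) consult it
instead of an OWL reasoner.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Literal, Optional

__all__ = [
    "ClassDef",
    "ObjectPropertyDef",
    "DataPropertyDef",
    "CardinalityRule",
    "AssertionResult",
    "SchemaRegistry",
    "builtin_schema",
]

Datatype = Literal["string", "integer", "decimal", "short"]


@dataclass(frozen=True)
class ClassDef:
    """A SALON class: its name, parent classes and top-level flag."""

    name: str
    parents: tuple[str, ...] = ()
    is_top_level: bool = False


@dataclass(frozen=True)
class ObjectPropertyDef:
    """An object property with declared domain, range and optional inverse."""

    name: str
    domain: str
    range: str
    inverse_of: Optional[str] = None


@dataclass(frozen=True)
class DataPropertyDef:
    """A data property with one or more domain classes and a datatype.

    ``short`` denotes a single-character string (consensus and gap
    characters); ``decimal`` accepts both integers and floats, covering the
    published "Integer or float" ranges.
    """

    name: str
    domains: tuple[str, ...]
    datatype: Datatype

    def __post_init__(self) -> None:
        if not self.domains:
            raise ValueError(f"data property {self.name!r} needs >=1 domain")


@dataclass(frozen=True)
class CardinalityRule:
    """A minimum-cardinality constraint on a class/property pair."""

    on_class: str
    property: str
    min_count: int

    def __post_init__(self) -> None:
        if self.min_count < 0:
            raise ValueError("min_count must be non-negative")


@dataclass(frozen=True)
class AssertionResult:
    """Outcome of :meth:`SchemaRegistry.check_assertion`.

    ``ok`` is True for a schema-conformant assertion; otherwise ``kind`` is
    one of ``unknown-property``, ``domain``, ``range`` or ``datatype`` and
    ``detail`` explains the mismatch.
    """

    ok: bool
    kind: Optional[str] = None
    detail: str = ""

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return self.ok


_OK = AssertionResult(True)


@dataclass
class SchemaRegistry:
    """Queryable store of SALON classes, properties and cardinality rules."""

    classes: dict[str, ClassDef] = field(default_factory=dict)
    object_properties: dict[str, ObjectPropertyDef] = field(default_factory=dict)
    data_properties: dict[str, DataPropertyDef] = field(default_factory=dict)
    cardinality_rules: list[CardinalityRule] = field(default_factory=list)
    # alias class names that appear in the published property tables but
    # denote an already-registered class (e.g. SequenceAlignment ~ Alignment)
    class_aliases: dict[str, str] = field(default_factory=dict)

    # -- registration -------------------------------------------------

    def add_class(self, cdef: ClassDef) -> None:
        self.classes[cdef.name] = cdef

    def add_object_property(self, pdef: ObjectPropertyDef) -> None:
        self.object_properties[pdef.name] = pdef

    def add_data_property(self, pdef: DataPropertyDef) -> None:
        self.data_properties[pdef.name] = pdef

    def add_cardinality_rule(self, rule: CardinalityRule) -> None:
        self.cardinality_rules.append(rule)

    # -- lookups ------------------------------------------------------

    def resolve_class(self, name: str) -> str:
        return self.class_aliases.get(name, name)

    def lookup(self, name: str) -> ObjectPropertyDef | DataPropertyDef:
        """Return the property definition for *name* (object or data)."""
        if name in self.object_properties:
            return self.object_properties[name]
        if name in self.data_properties:
            return self.data_properties[name]
        raise KeyError(f"unknown property: {name}")

    def parents(self, class_name: str) -> tuple[str, ...]:
        cdef = self.classes[self.resolve_class(class_name)]
        return cdef.parents

    def ancestors(self, class_name: str) -> set[str]:
        """Transitive closure of the parent relation (excludes *class_name*)."""
        seen: set[str] = set()
        stack = list(self.parents(class_name))
        while stack:
            p = stack.pop()
            if p not in seen:
                seen.add(p)
                stack.extend(self.parents(p))
        return seen

    def is_a(self, class_name: str, candidate_ancestor: str) -> bool:
        """True when *class_name* equals or descends from *candidate_ancestor*."""
        a = self.resolve_class(class_name)
        b = self.resolve_class(candidate_ancestor)
        return a == b or b in self.ancestors(a)

    def inverse_pairs(self) -> list[tuple[str, str]]:
        """Forward/inverse property name pairs, forward name first."""
        pairs = []
        for pdef in self.object_properties.values():
            if pdef.inverse_of and pdef.name.startswith("has"):
                pairs.append((pdef.name, pdef.inverse_of))
        return sorted(pairs)

    # -- validation hooks ---------------------------------------------

    def check_assertion(
        self, subject_class: str, property: str, object_kind: str
    ) -> AssertionResult:
        """Check one (subject class, property, object class-or-datatype) triple.

        Total for known properties: always returns an :class:`AssertionResult`,
        never raises.  Subclasses of the declared domain/range are accepted.
        """
        if property in self.object_properties:
            pdef = self.object_properties[property]
            if subject_class not in self.classes and subject_class not in self.class_aliases:
                return AssertionResult(False, "domain", f"unknown class {subject_class!r}")
            if not self.is_a(subject_class, pdef.domain):
                return AssertionResult(
                    False,
                    "domain",
                    f"{property}: domain is {pdef.domain}, got {subject_class}",
                )
            if object_kind not in self.classes and object_kind not in self.class_aliases:
                return AssertionResult(False, "range", f"unknown class {object_kind!r}")
            if not self.is_a(object_kind, pdef.range):
                return AssertionResult(
                    False,
                    "range",
                    f"{property}: range is {pdef.range}, got {object_kind}",
                )
            return _OK
        if property in self.data_properties:
            ddef = self.data_properties[property]
            if not any(self.is_a(subject_class, d) for d in ddef.domains):
                return AssertionResult(
                    False,
                    "domain",
                    f"{property}: domain is {'/'.join(ddef.domains)}, got {subject_class}",
                )
            if object_kind != ddef.datatype:
                return AssertionResult(
                    False,
                    "datatype",
                    f"{property}: datatype is {ddef.datatype}, got {object_kind}",
                )
            return _OK
        return AssertionResult(False, "unknown-property", f"unknown property {property!r}")

    def export_summary(self) -> list[dict]:
        """One machine-readable record per class/property, for documentation."""
        records: list[dict] = []
        for c in sorted(self.classes.values(), key=lambda c: c.name):
            records.append(
                {
                    "kind": "class",
                    "name": c.name,
                    "parents": list(c.parents),
                    "top_level": c.is_top_level,
                }
            )
        for p in sorted(self.object_properties.values(), key=lambda p: p.name):
            records.append(
                {
                    "kind": "object_property",
                    "name": p.name,
                    "domain": p.domain,
                    "range": p.range,
                    "inverse_of": p.inverse_of,
                }
            )
        for d in sorted(self.data_properties.values(), key=lambda d: d.name):
            records.append(
                {
                    "kind": "data_property",
                    "name": d.name,
                    "domains": list(d.domains),
                    "datatype": d.datatype,
                }
            )
        for r in self.cardinality_rules:
            records.append(
                {
                    "kind": "cardinality",
                    "on_class": r.on_class,
                    "property": r.property,
                    "min_count": r.min_count,
                }
            )
        return records


# the eleven top-level classes of the ontology
_TOP_LEVEL = (
    "Alignment",
    "AlignmentColumn",
    "AlignmentScore",
    "AlignmentScoreFunction",
    "AlignmentSequence",
    "ColumnScore",
    "ColumnScoreFunction",
    "ConstructionMethod",
    "Feature",
    "Protein",
    "SubAlignment",
)

_SUBCLASSES = (
    ("DNAAlignmentSequence", "AlignmentSequence"),
    ("ProteinAlignmentSequence", "AlignmentSequence"),
    ("DeterministicApproach", "ConstructionMethod"),
    ("StochasticApproach", "ConstructionMethod"),
    ("MaximizationAlignmentScoreFunction", "AlignmentScoreFunction"),
    ("MaximizationColumnScoreFunction", "ColumnScoreFunction"),
    # per-column confidence functions (GUIDANCE, Heads-or-Tails) carry the
    # scoreCutoff property; modeled under ColumnScoreFunction
    ("ReliabilityMeasure", "ColumnScoreFunction"),
)

# (name, domain, range, inverse) — 10 forward properties; 4 declare inverses
_OBJECT_PROPERTIES = (
    ("hasConstructionMethod", "SubAlignment", "ConstructionMethod", None),
    ("hasAlignmentScore", "Alignment", "AlignmentScore", None),
    ("hasAlignmentScoreFunction", "AlignmentScore", "AlignmentScoreFunction", None),
    ("hasColumn", "Alignment", "AlignmentColumn", "isColumnOf"),
    ("hasColumnScore", "AlignmentColumn", "ColumnScore", None),
    ("hasColumnScoreFunction", "ColumnScore", "ColumnScoreFunction", None),
    ("hasSubAlignment", "Alignment", "SubAlignment", "isSubalignmentOf"),
    ("hasFeature", "AlignmentSequence", "Feature", "isFeatureOf"),
    ("hasSequence", "SubAlignment", "AlignmentSequence", "isSequenceOf"),
    # domain printed as SequenceAlignment in the published property table;
    # alias-resolved to Alignment
    ("hasAssociationWithProtein", "SequenceAlignment", "Protein", None),
)

_DATA_PROPERTIES = (
    ("atSequenceIndex", ("AlignmentColumn",), "integer"),
    ("column", ("AlignmentColumn",), "string"),
    ("score", ("AlignmentScore", "ColumnScore"), "decimal"),
    ("scoreMax", ("AlignmentScoreFunction", "ColumnScoreFunction"), "decimal"),
    ("scoreMin", ("AlignmentScoreFunction", "ColumnScoreFunction"), "decimal"),
    ("scoreCutoff", ("ReliabilityMeasure",), "decimal"),
    ("FScore", ("Feature",), "decimal"),
    ("columnWeight", ("AlignmentColumn",), "integer"),
    ("consensusCharacter", ("AlignmentColumn",), "short"),
    ("gapCharacter", ("SubAlignment",), "short"),
    ("accessionNumber", ("AlignmentSequence", "Protein"), "string"),
    ("identifier", ("AlignmentSequence",), "string"),
    ("length", ("AlignmentSequence",), "integer"),
    ("organism", ("AlignmentSequence",), "string"),
    # properties from the XML mapping table and the methods text
    ("subAlignmentName", ("SubAlignment",), "string"),
    ("sequence", ("AlignmentSequence",), "string"),
    ("FType", ("Feature",), "string"),
    ("FStart", ("Feature",), "integer"),
    ("FStop", ("Feature",), "integer"),
    ("FNote", ("Feature",), "string"),
    ("keyword", ("AlignmentSequence",), "string"),
    # protein attributes used by enrichment and FASTA description lines
    ("db", ("Protein",), "string"),
    ("entryName", ("Protein",), "string"),
    ("proteinName", ("Protein",), "string"),
    ("organismName", ("Protein",), "string"),
    ("geneName", ("Protein",), "string"),
    ("proteinExistence", ("Protein",), "integer"),
    ("ncbiIdentifier", ("Protein",), "string"),
    ("pdbIdentifier", ("Protein",), "string"),
)


@lru_cache(maxsize=1)
def builtin_schema() -> SchemaRegistry:
    """The built-in SALON registry.

    Contains every class, object property (with its inverse), data property
    and cardinality rule the schema names: 14 object properties of which 4
    are inverses, the two minimum-cardinality constraints (an alignment has
    at least one sub-alignment; a sub-alignment has at least two sequences),
    and the data-property datatypes.
    """
    reg = SchemaRegistry()
    for name in _TOP_LEVEL:
        reg.add_class(ClassDef(name, (), True))
    for name, parent in _SUBCLASSES:
        reg.add_class(ClassDef(name, (parent,), False))
    reg.class_aliases["SequenceAlignment"] = "Alignment"

    for name, dom, rng, inv in _OBJECT_PROPERTIES:
        reg.add_object_property(ObjectPropertyDef(name, dom, rng, inv))
        if inv:
            reg.add_object_property(ObjectPropertyDef(inv, rng, dom, name))

    for name, doms, dtype in _DATA_PROPERTIES:
        reg.add_data_property(DataPropertyDef(name, doms, dtype))  # type: ignore[arg-type]

    reg.add_cardinality_rule(CardinalityRule("Alignment", "hasSubAlignment", 1))
    reg.add_cardinality_rule(CardinalityRule("SubAlignment", "hasSequence", 2))
    return reg
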