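"""The built-in schema registry: counts, hierarchy, assertion checking."""

import pytest

from salon.schema import builtin_schema


@pytest.fixture(scope="module")
def reg():
    return builtin_schema()


def test_object_property_inventory(reg):
    """14 object properties total, 4 of which are declared inverses."""
    assert len(reg.object_properties) == 14
    inverses = [p for p in reg.object_properties.values() if not p.name.startswith("has")]
    assert sorted(p.name for p in inverses) == [
        "isColumnOf",
        "isFeatureOf",
        "isSequenceOf",
        "isSubalignmentOf",
    ]


def test_published_property_rows(reg):
    rows = {
        "hasConstructionMethod": ("SubAlignment", "ConstructionMethod", None),
        "hasAlignmentScore": ("Alignment", "AlignmentScore", None),
        "hasAlignmentScoreFunction": ("AlignmentScore", "AlignmentScoreFunction", None),
        "hasColumn": ("Alignment", "AlignmentColumn", "isColumnOf"),
        "hasColumnScore": ("AlignmentColumn", "ColumnScore", None),
        "hasColumnScoreFunction": ("ColumnScore", "ColumnScoreFunction", None),
        "hasSubAlignment": ("Alignment", "SubAlignment", "isSubalignmentOf"),
        "hasFeature": ("AlignmentSequence", "Feature", "isFeatureOf"),
        "hasSequence": ("SubAlignment", "AlignmentSequence", "isSequenceOf"),
        "hasAssociationWithProtein": ("SequenceAlignment", "Protein", None),
    }
    for name, (dom, rng, inv) in rows.items():
        pdef = reg.lookup(name)
        assert (pdef.domain, pdef.range, pdef.inverse_of) == (dom, rng, inv), name


def test_inverse_round_trip(reg):
    """lookup(inverse).inverse_of points back at the forward property."""
    pairs = reg.inverse_pairs()
    assert len(pairs) == 4
    for forward, inverse in pairs:
        fdef = reg.lookup(forward)
        idef = reg.lookup(inverse)
        assert idef.inverse_of == forward
        assert (idef.domain, idef.range) == (fdef.range, fdef.domain)


@pytest.mark.parametrize(
    "name,datatype",
    [
        ("identifier", "string"),
        ("accessionNumber", "string"),
        ("organism", "string"),
        ("column", "string"),
        ("atSequenceIndex", "integer"),
        ("columnWeight", "integer"),
        ("length", "integer"),
        ("consensusCharacter", "short"),
        ("gapCharacter", "short"),
        ("score", "decimal"),
        ("scoreMax", "decimal"),
        ("scoreMin", "decimal"),
        ("scoreCutoff", "decimal"),
        ("FScore", "decimal"),
    ],
)
def test_data_property_datatypes(reg, name, datatype):
    ddef = reg.lookup(name)
    assert ddef.datatype == datatype
    assert len(ddef.domains) >= 1


def test_class_hierarchy(reg):
    assert reg.parents("ProteinAlignmentSequence") == ("AlignmentSequence",)
    assert reg.parents("DNAAlignmentSequence") == ("AlignmentSequence",)
    assert reg.parents("StochasticApproach") == ("ConstructionMethod",)
    top = [c for c in reg.classes.values() if c.is_top_level]
    assert len(top) == 11
    # parent references resolve and the hierarchy is acyclic
    for c in reg.classes.values():
        for p in c.parents:
            assert p in reg.classes
        assert c.name not in reg.ancestors(c.name)


@pytest.mark.parametrize(
    "subject,prop,kind,ok,violation_kind",
    [
        ("SubAlignment", "hasSequence", "AlignmentSequence", True, None),
        ("SubAlignment", "hasSequence", "ProteinAlignmentSequence", True, None),
        ("Alignment", "hasSequence", "AlignmentSequence", False, "domain"),
        ("AlignmentColumn", "atSequenceIndex", "integer", True, None),
        ("AlignmentColumn", "atSequenceIndex", "string", False, "datatype"),
        ("Alignment", "hasAssociationWithProtein", "Protein", True, None),  # alias domain
        ("Alignment", "noSuchProperty", "Protein", False, "unknown-property"),
        ("Protein", "accessionNumber", "string", True, None),
        ("Feature", "hasColumn", "AlignmentColumn", False, "domain"),
        ("Alignment", "hasColumn", "Feature", False, "range"),
    ],
)
def test_check_assertion(reg, subject, prop, kind, ok, violation_kind):
    result = reg.check_assertion(subject, prop, kind)
    assert result.ok is ok
    assert result.kind == violation_kind


def test_check_assertion_is_total(reg):
    """Every (class, property, kind) combination returns a result, never raises."""
    kinds = list(reg.classes) + ["string", "integer", "decimal", "short"]
    props = list(reg.object_properties) + list(reg.data_properties)
    for cls in reg.classes:
        for prop in props:
            for kind in kinds[::5]:
                result = reg.check_assertion(cls, prop, kind)
                assert result.ok in (True, False)


def test_cardinality_rules(reg):
    rules = {(r.on_class, r.property): r.min_count for r in reg.cardinality_rules}
    assert rules[("Alignment", "hasSubAlignment")] == 1
    assert rules[("SubAlignment", "hasSequence")] == 2


def test_export_summary(reg):
    records = reg.export_summary()
    kinds = {r["kind"] for r in records}
    assert kinds == {"class", "object_property", "data_property", "cardinality"}
    assert sum(r["kind"] == "object_property" for r in records) == 14
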