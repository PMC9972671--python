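"""Mapping between the alignment model and RDF under the SALON vocabulary.

Instances are minted as deterministic IRIs in the style
``<base>AlignmentId_LocalId`` (e.g. ``salon:BB11001_1aab_`` for sequence
``1aab_`` of alignment ``BB11001``); characters outside ``[A-Za-z0-9_]`` are
replaced by underscores and blank nodes are never used, keeping every entity
globally addressable.  Both a relation and its declared inverse are
materialized (``hasSequence`` and ``isSequenceOf``, etc.), so triple stores
without inference still answer inverse queries.  Literals carry the datatype
registered in the schema; every emitted triple is checked against the schema
registry before it is added.

Reading back (``from_rdf``) accepts forward-only, inverse-only or mixed
graphs.  Entity order is not encoded in RDF, so reconstruction uses fixed
deterministic orderings: sub-alignments by name, sequences by identifier,
columns by position, features by coordinates, scores by function name.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field as dc_field

import rdflib
from rdflib import Literal, Namespace, URIRef
from rdflib.namespace import RDF, XSD

from .errors import SalonError, SchemaViolationError, UnsupportedFormatError
from .model import (
    Alignment,
    AlignmentColumn,
    AlignmentSequence,
    ConstructionMethod,
    Feature,
    Score,
    ScoreFunction,
    SubAlignment,
)
from .schema import SchemaRegistry, builtin_schema

__all__ = [
    "SALON_NAMESPACE",
    "IriPolicy",
    "TripleGraph",
    "mint_iri",
    "to_rdf",
    "from_rdf",
    "serialize",
    "audit_graph",
    "to_sparql_update",
    "FORMATS",
]

SALON_NAMESPACE = "https://w3id.org/salon#"
SALON = Namespace(SALON_NAMESPACE)

#: supported serialization labels -> rdflib plugin names
FORMATS = {
    "turtle": "turtle",
    "rdfxml": "xml",
    "ntriples": "nt",
    "jsonld": "json-ld",
}

_SANITIZE = re.compile(r"[^A-Za-z0-9_]")


@dataclass(frozen=True)
class IriPolicy:
    """How instance IRIs are minted (base namespace + sanitizer)."""

    base: str = SALON_NAMESPACE

    def sanitize(self, text: str) -> str:
        return _SANITIZE.sub("_", text)


def mint_iri(policy: IriPolicy, alignment_id: str, local_id: str) -> URIRef:
    """Deterministic instance IRI ``<base><alignment_id>_<local_id>``."""
    if not alignment_id or not local_id:
        raise SalonError("mint_iri requires non-empty alignment_id and local_id")
    return URIRef(policy.base + policy.sanitize(alignment_id) + "_" + policy.sanitize(local_id))


@dataclass
class TripleGraph:
    """A set of (subject, predicate, object) statements with serialization."""

    base_namespace: str = SALON_NAMESPACE
    graph: rdflib.Graph = dc_field(default_factory=rdflib.Graph)

    def __post_init__(self) -> None:
        self.graph.bind("salon", SALON)
        self.graph.bind("rdf", RDF)

    def add(self, s, p, o) -> None:
        self.graph.add((s, p, o))

    def triples(self) -> set:
        return set(self.graph)

    def __len__(self) -> int:
        return len(self.graph)

    def serialize(self, format: str = "turtle") -> str:
        if format not in FORMATS:
            raise UnsupportedFormatError(
                f"unknown format {format!r}; supported: {', '.join(sorted(FORMATS))}"
            )
        return self.graph.serialize(format=FORMATS[format])


def serialize(graph: TripleGraph, format: str = "turtle") -> str:
    """Serialize to Turtle, RDF/XML, N-Triples or JSON-LD."""
    return graph.serialize(format)


def to_sparql_update(graph: TripleGraph) -> str:
    """An ``INSERT DATA`` update populating a repository with the graph."""
    nt = graph.serialize("ntriples").strip()
    return "INSERT DATA {\n" + nt + "\n}\n"


_DATATYPES = {
    "string": None,
    "short": None,  # single-character string literal
    "integer": XSD.integer,
    "decimal": XSD.decimal,
}


def _literal(value, datatype: str) -> Literal:
    xsd = _DATATYPES[datatype]
    if datatype == "integer":
        return Literal(int(value), datatype=xsd)
    if datatype == "decimal":
        return Literal(str(float(value)), datatype=xsd)
    return Literal(str(value))


class _Emitter:
    """Builds the graph while checking every triple against the registry."""

    def __init__(self, registry: SchemaRegistry, policy: IriPolicy):
        self.registry = registry
        self.policy = policy
        self.graph = TripleGraph(base_namespace=policy.base)

    def typed(self, node: URIRef, class_name: str) -> None:
        if class_name not in self.registry.classes:
            raise SchemaViolationError(f"no registered class {class_name!r}")
        self.graph.add(node, RDF.type, SALON[class_name])

    def relate(self, s_class: str, s, pname: str, o_class: str, o) -> None:
        """Emit a forward object-property triple plus its declared inverse."""
        result = self.registry.check_assertion(s_class, pname, o_class)
        if not result.ok:
            raise SchemaViolationError(f"refusing to emit: {result.detail}")
        self.graph.add(s, SALON[pname], o)
        inverse = self.registry.object_properties[pname].inverse_of
        if inverse:
            self.graph.add(o, SALON[inverse], s)

    def literal(self, s_class: str, s, pname: str, value) -> None:
        if value is None:
            return
        ddef = self.registry.data_properties[pname]
        result = self.registry.check_assertion(s_class, pname, ddef.datatype)
        if not result.ok:
            raise SchemaViolationError(f"refusing to emit: {result.detail}")
        self.graph.add(s, SALON[pname], _literal(value, ddef.datatype))


def _score_function_class(fn: ScoreFunction) -> str:
    if fn.kind == "alignment":
        return (
            "MaximizationAlignmentScoreFunction"
            if fn.optimization == "maximization"
            else "AlignmentScoreFunction"
        )
    return (
        "MaximizationColumnScoreFunction"
        if fn.optimization == "maximization"
        else "ColumnScoreFunction"
    )


def _emit_score(em: _Emitter, aid: str, owner_class: str, owner_iri, score: Score, local: str):
    fn = score.function
    score_class = "AlignmentScore" if fn.kind == "alignment" else "ColumnScore"
    fn_class = _score_function_class(fn)
    score_iri = mint_iri(em.policy, aid, local)
    fn_iri = mint_iri(em.policy, aid, f"function_{fn.name}")
    em.typed(score_iri, score_class)
    em.typed(fn_iri, fn_class)
    if fn.kind == "alignment":
        em.relate(owner_class, owner_iri, "hasAlignmentScore", score_class, score_iri)
        em.relate(score_class, score_iri, "hasAlignmentScoreFunction", fn_class, fn_iri)
    else:
        em.relate(owner_class, owner_iri, "hasColumnScore", score_class, score_iri)
        em.relate(score_class, score_iri, "hasColumnScoreFunction", fn_class, fn_iri)
    em.literal(score_class, score_iri, "score", score.value)
    em.literal(fn_class, fn_iri, "scoreMin", fn.score_min)
    em.literal(fn_class, fn_iri, "scoreMax", fn.score_max)


def to_rdf(
    alignment: Alignment,
    registry: SchemaRegistry | None = None,
    policy: IriPolicy | None = None,
) -> TripleGraph:
    """Map an alignment to SALON triples (forward and inverse relations)."""
    registry = registry or builtin_schema()
    policy = policy or IriPolicy()
    if not alignment.sub_alignments:
        raise SchemaViolationError(
            "an alignment contains at least one sub-alignment; refusing to emit"
        )
    em = _Emitter(registry, policy)
    aid = alignment.alignment_id
    aln_iri = URIRef(policy.base + policy.sanitize(aid))
    em.typed(aln_iri, "Alignment")

    for si, sub in enumerate(alignment.sub_alignments, start=1):
        sub_iri = mint_iri(policy, aid, sub.name if sub.name else f"sub{si:03d}")
        em.typed(sub_iri, "SubAlignment")
        em.relate("Alignment", aln_iri, "hasSubAlignment", "SubAlignment", sub_iri)
        em.literal("SubAlignment", sub_iri, "subAlignmentName", sub.name)
        em.literal("SubAlignment", sub_iri, "gapCharacter", sub.gap_character)
        if sub.construction_method is not None:
            m = sub.construction_method
            m_iri = mint_iri(policy, aid, f"method_{m.name}")
            m_class = (
                "DeterministicApproach"
                if m.approach == "deterministic"
                else "StochasticApproach"
            )
            em.typed(m_iri, m_class)
            em.relate("SubAlignment", sub_iri, "hasConstructionMethod", m_class, m_iri)
        for seq in sub.sequences:
            seq_iri = mint_iri(policy, aid, seq.identifier)
            em.typed(seq_iri, seq.salon_class)
            em.relate("SubAlignment", sub_iri, "hasSequence", seq.salon_class, seq_iri)
            em.literal(seq.salon_class, seq_iri, "identifier", seq.identifier)
            em.literal(seq.salon_class, seq_iri, "sequence", seq.residues)
            em.literal(seq.salon_class, seq_iri, "accessionNumber", seq.accession_number)
            em.literal(seq.salon_class, seq_iri, "length", seq.length)
            em.literal(seq.salon_class, seq_iri, "organism", seq.organism)
            for kw in seq.keywords:
                em.literal(seq.salon_class, seq_iri, "keyword", kw)
            for fi, feat in enumerate(seq.features, start=1):
                f_iri = mint_iri(policy, aid, f"{seq.identifier}_feature{fi:03d}")
                em.typed(f_iri, "Feature")
                em.relate(seq.salon_class, seq_iri, "hasFeature", "Feature", f_iri)
                em.literal("Feature", f_iri, "FType", feat.ftype)
                em.literal("Feature", f_iri, "FStart", feat.fstart)
                em.literal("Feature", f_iri, "FStop", feat.fstop)
                em.literal("Feature", f_iri, "FNote", feat.fnote)
                em.literal("Feature", f_iri, "FScore", feat.fscore)

    for j, score in enumerate(alignment.alignment_scores, start=1):
        _emit_score(em, aid, "Alignment", aln_iri, score, f"alignmentscore{j:03d}")

    for col in alignment.columns:
        col_iri = mint_iri(policy, aid, f"column{col.at_sequence_index:05d}")
        em.typed(col_iri, "AlignmentColumn")
        em.relate("Alignment", aln_iri, "hasColumn", "AlignmentColumn", col_iri)
        em.literal("AlignmentColumn", col_iri, "atSequenceIndex", col.at_sequence_index)
        em.literal("AlignmentColumn", col_iri, "column", col.column)
        em.literal("AlignmentColumn", col_iri, "consensusCharacter", col.consensus_character)
        em.literal("AlignmentColumn", col_iri, "columnWeight", col.column_weight)
        for j, score in enumerate(col.column_scores, start=1):
            _emit_score(
                em,
                aid,
                "AlignmentColumn",
                col_iri,
                score,
                f"column{col.at_sequence_index:05d}_score{j:03d}",
            )
    return em.graph


# ---------------------------------------------------------------- reading --


def _local(iri, base: str) -> str:
    text = str(iri)
    if text.startswith(base):
        return text[len(base) :]
    return text.rsplit("#", 1)[-1].rsplit("/", 1)[-1]


def _literal_kind(lit, declared: str | None) -> str:
    if not isinstance(lit, Literal):
        return "iri"
    if lit.datatype == XSD.integer:
        return "integer"
    if lit.datatype in (XSD.decimal, XSD.double, XSD.float):
        return "decimal"
    if declared == "short" and len(str(lit)) == 1:
        return "short"
    return "string"


def audit_graph(graph: rdflib.Graph, registry: SchemaRegistry | None = None) -> list[str]:
    """Schema audit: unknown predicates/classes, domain/range/datatype
    mismatches and untyped subjects, as human-readable findings."""
    registry = registry or builtin_schema()
    findings: list[str] = []

    def type_of(node) -> str | None:
        for t in graph.objects(node, RDF.type):
            name = _local(t, SALON_NAMESPACE)
            if name in registry.classes:
                return name
        return None

    for s, p, o in graph:
        if p == RDF.type:
            name = _local(o, SALON_NAMESPACE)
            if name not in registry.classes and name not in registry.class_aliases:
                findings.append(f"{s}: unknown class {name!r}")
            continue
        pname = _local(p, SALON_NAMESPACE)
        try:
            pdef = registry.lookup(pname)
        except KeyError:
            findings.append(f"{s}: unknown predicate {pname!r}")
            continue
        s_class = type_of(s)
        if s_class is None:
            findings.append(f"{s}: subject of {pname!r} has no rdf:type")
            continue
        declared = getattr(pdef, "datatype", None)
        if isinstance(o, Literal):
            o_kind = _literal_kind(o, declared)
        else:
            o_kind = type_of(o)
            if o_kind is None:
                findings.append(f"{o}: object of {pname!r} has no rdf:type")
                continue
        result = registry.check_assertion(s_class, pname, o_kind)
        if not result.ok:
            findings.append(f"{s}: {result.detail}")
    return findings


class _Reader:
    def __init__(self, graph: rdflib.Graph, registry: SchemaRegistry):
        self.g = graph
        self.registry = registry

    def related(self, node, forward: str) -> list:
        """Objects linked by *forward* or by its inverse, deduplicated."""
        out = set(self.g.objects(node, SALON[forward]))
        inverse = self.registry.object_properties[forward].inverse_of
        if inverse:
            out |= set(self.g.subjects(SALON[inverse], node))
        return sorted(out)

    def value(self, node, pname: str):
        for o in self.g.objects(node, SALON[pname]):
            return o.toPython() if isinstance(o, Literal) else o
        return None

    def values(self, node, pname: str) -> list:
        return sorted(str(o) for o in self.g.objects(node, SALON[pname]))

    def type_name(self, node) -> str | None:
        for t in self.g.objects(node, RDF.type):
            name = _local(t, SALON_NAMESPACE)
            if name in self.registry.classes:
                return name
        return None


def _read_score_function(r: _Reader, fn_iri, aid_local: str) -> ScoreFunction:
    fn_class = r.type_name(fn_iri) or "AlignmentScoreFunction"
    kind = "alignment" if "Alignment" in fn_class else "column"
    optimization = "maximization" if fn_class.startswith("Maximization") else "minimization"
    name = _local(fn_iri, SALON_NAMESPACE)
    prefix = f"{aid_local}_function_"
    if name.startswith(prefix):
        name = name[len(prefix) :]
    smin = r.value(fn_iri, "scoreMin")
    smax = r.value(fn_iri, "scoreMax")
    return ScoreFunction(
        name=name,
        kind=kind,
        score_min=float(smin) if smin is not None else None,
        score_max=float(smax) if smax is not None else None,
        optimization=optimization,
    )


def _read_scores(r: _Reader, owner, aid_local: str, kind: str) -> tuple[Score, ...]:
    prop = "hasAlignmentScore" if kind == "alignment" else "hasColumnScore"
    fn_prop = "hasAlignmentScoreFunction" if kind == "alignment" else "hasColumnScoreFunction"
    scores = []
    for score_iri in r.related(owner, prop):
        value = r.value(score_iri, "score")
        fns = r.related(score_iri, fn_prop)
        fn = (
            _read_score_function(r, fns[0], aid_local)
            if fns
            else ScoreFunction("unknown", kind)  # score without a declared function
        )
        scores.append(Score(float(value) if value is not None else float("nan"), fn))
    return tuple(sorted(scores, key=lambda s: (s.function.name, s.value)))


def from_rdf(
    text: str,
    format: str = "turtle",
    registry: SchemaRegistry | None = None,
    violations: list | None = None,
) -> Alignment:
    """Reconstruct the alignment model from a SALON RDF document.

    Schema findings (unknown predicates, untyped nodes, domain/range
    mismatches) are appended to *violations* when a list is supplied;
    otherwise any finding raises :class:`SchemaViolationError`.  Forward-only
    and inverse-only graphs reconstruct identically.
    """
    if format not in FORMATS:
        raise UnsupportedFormatError(
            f"unknown format {format!r}; supported: {', '.join(sorted(FORMATS))}"
        )
    registry = registry or builtin_schema()
    g = rdflib.Graph()
    g.parse(data=text, format=FORMATS[format])

    findings = audit_graph(g, registry)
    if findings:
        if violations is None:
            raise SchemaViolationError(
                f"{len(findings)} schema violation(s) in RDF input", findings
            )
        violations.extend(findings)

    r = _Reader(g, registry)
    aln_nodes = sorted(set(g.subjects(RDF.type, SALON["Alignment"])))
    if not aln_nodes:
        raise SchemaViolationError("document contains no salon:Alignment individual")
    aln_iri = aln_nodes[0]
    aid_local = _local(aln_iri, SALON_NAMESPACE)

    subs = []
    for sub_iri in r.related(aln_iri, "hasSubAlignment"):
        name = r.value(sub_iri, "subAlignmentName")
        gap = r.value(sub_iri, "gapCharacter") or "-"
        method = None
        for m_iri in r.related(sub_iri, "hasConstructionMethod"):
            m_class = r.type_name(m_iri) or "DeterministicApproach"
            m_name = _local(m_iri, SALON_NAMESPACE)
            prefix = f"{aid_local}_method_"
            if m_name.startswith(prefix):
                m_name = m_name[len(prefix) :]
            method = ConstructionMethod(
                name=m_name,
                approach="stochastic" if m_class == "StochasticApproach" else "deterministic",
            )
        seqs = []
        for seq_iri in r.related(sub_iri, "hasSequence"):
            seq_class = r.type_name(seq_iri)
            identifier = r.value(seq_iri, "identifier")
            if identifier is None:
                identifier = _local(seq_iri, SALON_NAMESPACE)
                prefix = f"{aid_local}_"
                if identifier.startswith(prefix):
                    identifier = identifier[len(prefix) :]
            features = []
            for f_iri in r.related(seq_iri, "hasFeature"):
                fscore = r.value(f_iri, "FScore")
                features.append(
                    Feature(
                        ftype=str(r.value(f_iri, "FType") or ""),
                        fstart=int(r.value(f_iri, "FStart")),
                        fstop=int(r.value(f_iri, "FStop")),
                        fnote=r.value(f_iri, "FNote"),
                        fscore=float(fscore) if fscore is not None else None,
                    )
                )
            features.sort(key=lambda f: (f.fstart, f.fstop, f.ftype))
            length = r.value(seq_iri, "length")
            seqs.append(
                AlignmentSequence(
                    identifier=str(identifier),
                    residues=str(r.value(seq_iri, "sequence") or ""),
                    accession_number=r.value(seq_iri, "accessionNumber"),
                    length=int(length) if length is not None else None,
                    organism=r.value(seq_iri, "organism"),
                    keywords=tuple(r.values(seq_iri, "keyword")),
                    molecule="DNA" if seq_class == "DNAAlignmentSequence" else "Protein",
                    features=tuple(features),
                )
            )
        seqs.sort(key=lambda s: s.identifier)
        subs.append(
            SubAlignment(
                name=str(name) if name is not None else "",
                sequences=tuple(seqs),
                construction_method=method,
                gap_character=str(gap),
            )
        )
    subs.sort(key=lambda s: s.name)

    columns = []
    for col_iri in r.related(aln_iri, "hasColumn"):
        weight = r.value(col_iri, "columnWeight")
        columns.append(
            AlignmentColumn(
                at_sequence_index=int(r.value(col_iri, "atSequenceIndex")),
                column=str(r.value(col_iri, "column")),
                consensus_character=r.value(col_iri, "consensusCharacter"),
                column_weight=int(weight) if weight is not None else None,
                column_scores=_read_scores(r, col_iri, aid_local, "column"),
            )
        )
    columns.sort(key=lambda c: c.at_sequence_index)

    return Alignment(
        alignment_id=aid_local,
        sub_alignments=tuple(subs),
        alignment_scores=_read_scores(r, aln_iri, aid_local, "alignment"),
        columns=tuple(columns),
    )
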