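# salon

Semantic representation, scoring, validation and enrichment of biological
sequence alignments.

Multiple sequence alignments come out of tools like CLUSTAL W or MAFFT in
mutually incompatible text formats, and the rich knowledge that exists about
the aligned sequences (organism, gene, protein names, database
cross-references) is not linked to them.  `salon` represents pairwise and
multiple alignments under the SALON vocabulary — an OWL 2 ontology in which
an *Alignment* contains *SubAlignments* (clusters of sequences), each holding
*AlignmentSequences* with annotated *Features*, and alignments and columns
carry *Scores* under *ScoreFunctions* with declared bounds.  On top of that
typed model the package provides:

* readers/writers for **MACSIM XML** (the annotated-alignment dialect used by
  BAliBASE) and **FASTA** with UniProtKB/NCBI description-line dialects;
* a deterministic mapping to **RDF** (Turtle, RDF/XML, N-Triples, JSON-LD),
  minting instance IRIs such as `salon:BB11001_1aab_` and materializing both
  each object property and its inverse;
* **score functions** — percentage of totally conserved columns, percentage
  of non-gap columns (both 0/1 per column, 0–100 per alignment), and column
  entropy

  H(c) = −Σᵢ pᵢ log₂ pᵢ ∈ [0, log₂ 20 ≈ 4.322] bits,

  where pᵢ are the non-gap residue frequencies of column c;
* native **validation rules** equivalent to the ontology's SWRL rule set:
  a score is *incorrect* when it leaves its function's `[scoreMin, scoreMax]`
  interval (four mutually exclusive rules), a column is *unreliable* when its
  confidence under a reliability measure (e.g. GUIDANCE) falls on the wrong
  side of the cutoff, plus the schema's cardinality constraints (≥ 1
  sub-alignment per alignment, ≥ 2 sequences per sub-alignment);
* **UniProtKB enrichment** via federated SPARQL `SERVICE` queries (through an
  injectable endpoint client; an offline fixture client is included) and
  generation of standardized FASTA description lines in both dialects;
* a **seeded synthetic alignment generator** emulating BAliBASE-style protein
  alignments with controllable conservation and gap rate, so every feature is
  testable without downloads.

It is aimed at bioinformaticians who want alignments as linked data — loaded
into a triple store, validated automatically, or enriched with protein
annotations — without running an OWL reasoner.

## Worked example

Generate a 4-sequence, 10-column synthetic protein alignment with 60 %
conserved columns, score its column entropy, validate it, and map it to RDF:

```bash
salon fixture --seqs 4 --cols 10 --conservation 0.6 --gap-rate 0.1 --seed 1 --out demo.xml
salon score --in demo.xml --function entropy
```

```
column	score
1	0
2	0
3	0
4	0
5	0
6	0
7	2
8	0.918296
9	2
10	2
alignment	6.9183
```

Six columns are totally conserved (entropy 0); columns 7, 9 and 10 hold four
distinct residues (log₂ 4 = 2 bits); column 8 has a gap plus a 2:1 residue
split (0.918 bits).  The alignment-level score is the sum, 6.918 bits.

```bash
salon validate --in demo.xml
```

```
{
  "verdict": "correct",
  "violations": [],
  "unreliable_columns": []
}
```

Every score lies within its function's declared bounds and both cardinality
constraints hold, so the alignment validates as correct (exit code 0; an
incorrect alignment exits 1).

```bash
salon convert --in demo.xml --format turtle | head -n 6
```

```
@prefix salon: <https://w3id.org/salon#> .
@prefix xsd: <http://www.w3.org/2001/XMLSchema#> .

salon:SYN00001 a salon:Alignment ;
    salon:hasSubAlignment salon:SYN00001_SYN00001 .
```

`salon enrich --in demo.xml --offline rows.json --out enriched.ttl` attaches
`salon:hasAssociationWithProtein` links from canned (or live) UniProtKB rows,
and `salon header --dialect uniprotkb --from enriched.ttl --id P69905` prints
a standardized description line such as
`>sp|P69905|HBA_HUMAN Hemoglobin subunit alpha OS=Homo sapiens GN=HBA1 PE=1`.

The same functionality is available as a library; see `salon/__init__.py`
for the public surface and `docs/methods.md` for the underlying model.

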