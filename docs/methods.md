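# Methods

## The model

An alignment is represented as a small typed object graph mirroring the
SALON class hierarchy: `Alignment` → `SubAlignment` → `AlignmentSequence` →
`Feature`, with `AlignmentColumn` derived by transposition and `Score` /
`ScoreFunction` / `ReliabilityMeasure` / `ConstructionMethod` attached where
they belong.  Constructors enforce structural invariants only (equal aligned
lengths within a sub-alignment, 1 ≤ fstart ≤ fstop ≤ sequence length, single
gap character); semantic constraints — minimum cardinalities and score
bounds — are deliberately left to the validation layer, so that invalid
alignments can be represented, validated and reported rather than being
unconstructible.

Conventions chosen where the schema is silent:

* **Coordinates** are 1-based inclusive throughout (column positions,
  feature start/stop), matching the MACSIM feature convention.
* **Sequence length** counts gap characters; it is derived from the aligned
  string when the input does not state it, and a stated length that
  disagrees with the string is an error.
* **Consensus character** is the most frequent non-gap character; ties break
  lexicographically (deterministic); an all-gap column's consensus is the
  gap character itself.
* **Gap alphabet** is `{-, .}`; a file mixing both is rejected rather than
  guessed at; a gapless alignment defaults to `-`.

## Score functions

Percentage-style functions (totally conserved columns, non-gap columns)
score each column 0 or 1 and the alignment `100·k/n`.  "Totally conserved"
is read strictly: a single gap breaks conservation, which makes every
conserved column also a non-gap column (an invariant the tests check
exhaustively over small alphabets).

Column entropy is Shannon entropy, base-2 logarithm, over the frequency
distribution of **non-gap** characters (computed with
`scipy.stats.entropy`).  Both choices are forced by the published bounds:
only a base-2 log over a 20-symbol alphabet gives the stated per-column
maximum of 4.322 ≈ log₂ 20 bits, so gaps cannot count as a 21st symbol.  An
all-gap column has undefined entropy and raises; the caller decides policy.
Comparisons against the printed value 4.322 use an absolute tolerance of
5·10⁻⁴ (three printed decimals).  The alignment-level entropy score is the
sum of the per-column values, and its declared maximum is `n_columns ×
log₂ 20`; the alternative reading "number of sequences × 4.322" is
inconsistent with a per-column sum and is not used.

Reliability measures (GUIDANCE-style per-column confidences) are consumed,
never computed.  Because published usage is contradictory about the
filtering direction, `unreliable_when` (below vs above the cutoff) is a
mandatory explicit field with no default.  Comparisons are strict: a score
exactly at the cutoff always passes.  Scores outside a measure's declared
range raise instead of being clamped.

## Validation

Validation re-implements the ontology's SWRL rule semantics natively so no
triple store or reasoner is required; `export_swrl_rules()` provides the
equivalent rule texts for users who do run one.  The checks are:

* bounds: `scoreMin ≤ value ≤ scoreMax` per score, **inclusive** — the
  worked example's column score of 1 under a [0, 1] function must validate —
  yielding one of four mutually exclusive incorrectness rules otherwise;
  a function missing a bound disables that side's check with a logged note;
* cardinality: ≥ 1 sub-alignment per alignment, ≥ 2 sequences per
  sub-alignment;
* schema assertions: every modeled relation is checked against the
  registry's domains and ranges;
* reliability: unreliable columns are reported as a distinct warning class
  and never flip the correct/incorrect verdict, mirroring their role as a
  pre-analysis filter rather than an error.

The registry itself models only the entities the schema names publicly
(11 top-level classes, the DNA/protein sequence, deterministic/stochastic
method and maximization score-function subclasses, 14 object properties of
which 4 are inverses, the data properties with their datatypes); the
`SequenceAlignment` domain printed for `hasAssociationWithProtein` is kept
as printed and alias-resolved to `Alignment`, `ReliabilityMeasure` is housed
under `ColumnScoreFunction` (its instances score columns), and "integer or
float" ranges are a single `decimal` datatype.

## RDF mapping

Instance IRIs are minted deterministically as
`<base>AlignmentId_LocalId` (default base `https://w3id.org/salon#`,
configurable), with characters outside `[A-Za-z0-9_]` replaced by `_`; blank
nodes are never used.  Forward **and** inverse object-property triples are
both materialized so stores without inference answer inverse queries.
Literals carry the registered datatype; every triple is checked against the
registry before emission.

RDF carries no entity order, so reading a graph back uses fixed
deterministic orderings: sub-alignments by name, sequences by identifier,
features by coordinates, columns by position, scores by function name.
Producers whose sequence order is not lexicographic in the identifiers will
see a reordered (but column-consistent) model after an RDF round-trip; the
synthetic generator names sequences `seq001…` precisely so the orders
coincide.  Score-function names and construction-method names are encoded
in the IRI local part (there is no schema data property for them), so they
round-trip exactly when sanitizer-safe.

## Enrichment

One federated `SELECT … WHERE { SERVICE <endpoint> { … } }` query per
distinct accession retrieves protein name, organism, gene and NCBI
identifier; a second template retrieves the seven description-line fields
from a PDB cross-reference.  The UniProt predicate IRIs are a configurable
mapping, since the remote vocabulary evolves independently.  All remote
access goes through an injected client object; tests and the CLI's
`--offline` mode use canned row fixtures and never touch the network.
Failures degrade per accession — the alignment and its graph are never left
half-mutated.  When one key maps to several entries, the record with the
strongest protein-existence evidence (lowest PE code, PE=1 best) is
selected, ties broken by accession sort, and **all** other candidates are
surfaced for expert review.  Retrieved records are persisted into the local
graph as `Protein` individuals linked by `hasAssociationWithProtein`, so
later header generation is purely local.

## Synthetic data generator

`FixtureSpec` → `generate` emulates a BAliBASE-style annotated protein (or
DNA) alignment: exactly `round(conservation × n_columns)` columns are
totally conserved; the remaining columns are rejection-sampled to guarantee
they are not (impossible for a single-sequence alignment, which exists only
to exercise the cardinality rule negatively); gaps are placed independently
at `gap_rate` per non-conserved cell; features get uniform coordinates
within the alignment.  The protein alphabet is the 20 standard amino acids,
consistent with the entropy bound; DNA is ACGT.  One `random.Random(seed)`
stream drives everything — identical spec and seed give byte-identical
MACSIM XML.  Defaults (4 sequences × 30 columns, conservation 0.5, gap rate
0.1, 2 features) are in the range of small BAliBASE reference alignments.

What the generator does **not** emulate: realistic substitution/indel
processes, phylogenetic correlation between sequences, residue composition
bias, or real feature semantics.  Passing round-trip and scoring tests on
these fixtures therefore demonstrates representational fidelity and rule
correctness, not biological realism of the inputs.

## Numerical and procedural choices

* Entropy via `scipy.stats.entropy(counts, base=2)`; no manual frequency
  normalisation.
* MACSIM parsing via `lxml` (parse errors carry line numbers); FASTA record
  splitting via Biopython's `SimpleFastaParser`; all RDF through `rdflib`.
* MACSIM writing adds one extension element,
  `<construction-method approach="…">`, so the construction method survives
  write/parse cycles; standard files simply lack it.  Unknown MACSIM
  elements are preserved verbatim and re-emitted.
* Residues are uppercased on parse; gap symbols preserved.
* CLI exit codes: 0 success/correct, 1 validation-incorrect, 2 usage or
  I/O error.

## Known limitations

* Only the publicly enumerated subset of the ontology is registered; the
  full published OWL file (30 classes, 27 data properties, 144 axioms) is
  not reconstructed.
* No OWL DL reasoning or general SWRL execution — only the specific rule
  semantics above.
* `from_rdf` reconstructs single-alignment documents (the first `Alignment`
  individual found, deterministically).
* 3D structural annotation is out of scope by design.
* The live UniProt client is provided for convenience and is deliberately
  untested; correctness of enrichment logic is established against the
  injected fixture client.
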