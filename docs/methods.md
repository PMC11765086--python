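# Methods

## Model and assumptions

The package treats antibody cross-reactivity as a pure sequence-conservation
problem: an anti-phosphosite antibody recognizes approximately the 15-mer
centered on the phosphorylated residue, and it is predicted to detect the
orthologous protein in a second species when that neighborhood is
sufficiently conserved. Validated cross-reactive antibody/fly pairs show
identical stretches through the site as short as 6 residues, which motivates
the 6–11 window-length ladder used for reporting. The model deliberately
ignores everything an epitope model could add — position weighting,
physico-chemical similarity beyond a substitution matrix, structural
accessibility — in favor of two auditable statistics.

### Conservation statistics

Given a pair of aligned 15-residue windows with the phosphosite at
position 8:

* **Longest identical run** — the maximal contiguous block of positions,
  containing position 8, at which both windows carry the same canonical
  amino acid. If the site residue itself differs (or is a gap), the run
  is 0. Comparison is case-insensitive; underscores (terminus padding),
  gap sentinels and ambiguity codes (X/U/B/Z) never count as identical.
* **Window qualification at length L** — true when some contiguous
  sub-window of length L containing position 8 is identical at every
  position except at most one, and that one exception (i) is a
  *conservative replacement*, (ii) is not the site, and (iii) is not
  adjacent to the site (site ± 1). Windows containing a gap column never
  qualify: an indel inside the epitope breaks the binding surface, and
  excluding gaps keeps window length well defined.

"Conservative replacement" is operationalized as a strictly positive entry
of a configurable substitution matrix, BLOSUM62 by default. This is
standard, parameter-free and symmetric; the matrix is a configuration knob
rather than a constant.

Three consequences of the exhaustive-window semantics are worth noting.
Qualification is monotone in L (any qualifying window of length L contains
a qualifying window of length L−1 that still covers the site). An identical
run of ≥ 6 guarantees qualification at L = 6. And a single substitution
adjacent to the site does *not* defeat every window length: a window ending
exactly at the site excludes site+1, so short lengths can still qualify —
only substitutions flanking the site on both sides, or long window lengths,
are fully excluded. The allowed replacement may sit at a window edge;
only site adjacency is excluded.

The scorer exposes two equivalent code paths: `score_windows` on a raw
pair of 15-mers (used for flank-peptide comparisons and the `score-pair`
command) and `score_site` on the 15-column slice of a full alignment
centered on the site column (used by the pipeline; columns beyond the
alignment ends are padded with the gap sentinel). For gap-free alignments
the two coincide.

## Pipeline stages and their parameters

| Parameter | Default | Meaning |
| --- | --- | --- |
| `min_rank` | `moderate` | Minimum ortholog confidence rank kept (ordering high > moderate > low; ranks are opaque labels from the ortholog provider) |
| `min_window`/`max_window` | 6 / 11 | Window-length ladder reported (residues) |
| `matrix` | BLOSUM62 | Substitution matrix for both alignment and the conservative-replacement test |
| `gap_open`/`gap_extend` | 11 / 1 | Affine gap costs; a gap of length k costs open + k·extend (BLAST convention) |
| `require_antibody` | true | Drop catalog rows with no antibody catalog number |
| `allow_substitution` | true | Disable to require strict identity within windows |

**Anchoring.** Catalog accessions go stale and isoform coordinates drift,
so each record is validated in a cascade: exact positional check
(`anchored_direct`), whole-protein scan for the flank peptide
(`anchored_shifted`, the corrected position is used downstream), then a
gene-symbol rescue through the identifier map (`rescued_by_symbol`).
Matching is exact — mismatch tolerance belongs to the conservation stage,
not to site validation — and underscore padding in the flank anchors the
match to the protein terminus. Any ambiguity (the peptide at more than one
position, or a rescue hitting more than one gene or protein) fails the
record with a reason code instead of guessing; a false anchor would poison
every downstream alignment. This fail-and-report policy on ambiguity is a
conservative design choice.

**Alignment.** Needleman–Wunsch with affine gaps via
`Bio.Align.PairwiseAligner` in global mode (end gaps penalized). Among
co-optimal alignments the first one enumerated is taken, which is
deterministic for fixed inputs; exact tie-break geometry is therefore a
property of the aligner, not of this package. Letters outside the matrix
alphabet (e.g. selenocysteine U) are scored as X during alignment and
restored afterwards, so identity checks downstream still see them and
refuse to call them conserved. The matrix and gap costs are configurable
because the appropriate choice is a convention, not a derived quantity;
BLOSUM62/11/1 is the field-standard default. All isoforms of every
ortholog are aligned and scored; per-gene summary counts use the longest
isoform (ties broken by lexicographically smallest accession).

**Reporting.** One report row per (site × ortholog gene × isoform). A
source token mapping to several gene ids is pursued under all of them and
flagged `ambiguous_gene` rather than dropped. Every catalog row is
traceable to report rows, a parse reject (with reason code — including
rows excluded by the species filter or the antibody requirement), or an
anchoring-report disposition (`anchor_failed`, `unmapped_gene`,
`unmapped_ortholog`). The pipeline has no randomness; identical inputs
give byte-identical outputs under a fixed row ordering (source gene,
target gene, isoform accession).

## Synthetic data

`cesa.fixtures` generates complete input bundles with planted structure:
random background proteins (uniform over the 20 amino acids, 120–200
residues by default) carrying one planted 15-mer window per gene. Nineteen
conservation classes cover the decision surface: fully identical windows;
identical runs of exactly k = 6..14 bounded by non-conservative
substitutions; a qualifying conservative replacement; replacements
adjacent to the site; a substituted site; an in-epitope deletion; a
low-confidence ortholog; a stale accession requiring symbol rescue; a
stale position requiring the peptide scan; a duplicated peptide forcing an
ambiguity failure; and a two-isoform gene conserved only on the longer
isoform. Planted windows are drawn *without replacement* from the 20 amino
acids so that (a) flanks are locally unique, making anchoring ambiguity a
planted property rather than an accident, and (b) the affine-gap optimum
places gaps exactly at the planted deletion, making the expected alignment
slice predictable. Expected runs and qualified lengths in `truth.tsv` are
derived by the fixture module's own literal-rule enumerator, which is
written independently of the scoring implementation.

What the generator does not emulate: realistic phylogenetic divergence
(edits are rule-targeted, not evolutionary), paralogy, alternative splicing
beyond simple isoform length differences, and real catalog noise beyond the
planted failure classes. Passing the planted-recovery suite therefore
demonstrates that the machinery implements the stated rule exactly — not
that the rule's predictions hold for any particular real proteome pair.

## Numerical and scale choices

Everything is integer or small-float arithmetic; there are no tolerances.
The regression bundle uses 57 genes (three cycles over the 19 classes,
seed 20240), which exercises every class while keeping the full suite
under a few seconds. The alignment oracle in the tests is an independent
three-state Gotoh dynamic program compared on short random sequences;
the window rule is compared against brute-force enumeration on 10,000
seeded random window pairs per run.

## Known limitations

* Conservation is assessed on the primary sequence only; a conserved
  epitope in an inaccessible conformation will still be predicted
  cross-reactive.
* The site residue must be strictly identical; S↔T interchange at the
  phosphosite is treated as non-conserved even though both are
  phospho-acceptors, because the validated benchmark pairs all conserve
  the exact residue.
* Ortholog confidence ranks are consumed as opaque ordered labels; their
  definitions live with the ortholog provider.
* Full-scale catalog analyses depend on licensed catalog releases and
  proteome snapshots that are not shipped here; the package operates on
  whatever flat files the user supplies.
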