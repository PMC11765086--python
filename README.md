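# cesa — cross-species epitope sequence analysis

Phospho-specific antibodies are raised against short phosphopeptides —
roughly the ±7 amino acids around a phosphorylated serine, threonine or
tyrosine — almost always on human, mouse or rat proteins. Many of these
reagents nevertheless detect the orthologous phosphoprotein in model
organisms such as *Drosophila*, because the epitope neighborhood happens to
be conserved. `cesa` predicts which antibodies in a catalog are worth
trying in a second species, by sequence analysis alone.

## What it computes

For each catalog phosphosite the pipeline:

1. **anchors** the epitope on a current full-length protein (validating the
   stated position against the 15-mer flank peptide, scanning for the
   peptide when the position is stale, and falling back to a gene-symbol
   lookup when the accession itself is outdated);
2. **maps** the gene to its ortholog(s) in the target species through a
   flat ortholog table, keeping only high- or moderate-confidence pairs by
   default;
3. **aligns** the source protein globally (Needleman–Wunsch, BLOSUM62,
   affine gaps 11/1) against every isoform of each ortholog;
4. **transfers** the phosphosite through its alignment column; and
5. **scores** conservation of the 15-column neighborhood with two
   statistics:
   * the *longest identical run* `r` — the maximal contiguous block of
     identical residues containing the site (0 if the site itself differs
     or is gapped);
   * per-window *qualification* — for each window length `L ∈ {6..11}`,
     whether some contiguous `L`-window containing the site is identical
     everywhere except at most one conservative replacement
     (BLOSUM62 score > 0) that is neither at the site nor at site ± 1.
     Gap columns inside a window disqualify it.

A site qualifying at cutoff `L = 6` on some isoform of an ortholog marks
that antibody as a candidate cross-reactive reagent; larger cutoffs are
stricter. Per-cutoff summaries count distinct target genes using each
gene's longest isoform.

## Worked example

Score one validated epitope pair directly — the human AKT1 S473 flank
against its fly Akt1 counterpart:

```sh
$ cesa score-pair RPHFPQFSYSASGTA EPLFPQFSYQGDMAS
site_identical  True
longest_identical_run   6
qualified_6     True
qualified_7     False
...
max_qualified_length    6
```

The two 15-mers share the identical stretch `FPQFSY` (6 residues) through
the phosphosite, so the site qualifies at cutoff 6 and at no longer
cutoff — this is an antibody with experimentally confirmed fly
cross-reactivity, sitting right at the empirical conservation floor.

Run the full pipeline on a generated synthetic bundle:

```sh
$ cesa make-fixtures --seed 42 --n-genes 19 --out demo
$ cesa run --catalog demo/catalog.tsv --source-proteome demo/source.fasta \
    --target-proteome demo/target.fasta --gene-map demo/gene_map.tsv \
    --ortholog-table demo/orthologs.tsv --id-map demo/id_map.tsv --out demo/out
cesa INFO pipeline: 18 report rows, dispositions {'scored': 17, 'unmapped_ortholog': 1, 'anchor_failed': 1}
```

Of the 19 planted sites, 17 are scored (18 rows — one gene has two
isoforms), one is dropped because its only ortholog pair is low-confidence,
and one fails anchoring because its flank peptide occurs twice on the
protein. `demo/out/` holds `report.tsv` (one row per site × ortholog ×
isoform), `summary.tsv` (per-cutoff gene counts, e.g. 14 target genes at
cutoff 6 declining to a smaller count at 11), `anchoring.tsv` and
`rejects.tsv`. The bundle's `truth.tsv` states the expected outcome of
every planted site; the test suite checks the pipeline reproduces it
exactly.

To use real data, supply the catalog in the standard
phosphorylation-site dataset dialect (tab-separated with GENE, ACC_ID,
ORGANISM, MOD_RSD, SITE_+/-7_AA, CST_CAT# columns; gzip accepted), FASTA
proteomes, a gene-to-protein map, a DIOPT-style ortholog table and an
identifier map — see `docs/methods.md` for file schemas and parameter
details.

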