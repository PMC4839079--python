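# stagewise

Stage-wise transcriptome and small-RNA expression analysis toolkit for
three-stage, replicated bulk experiments (stages S1/S2/S3, transitions
T1 = S1→S2 and T2 = S2→S3). It provides, as a tested reusable pipeline:

- **restructure** — cluster assembled contigs into transcript units via
  their best cDNA alignment hit (bitscore → e-value → lexicographic
  tie-break), aggregate contig counts and merge GO annotations to the
  transcript level.
- **normalize** — quantile normalization with a zero-preserving
  modification (features with a raw count of zero in a sample receive no
  expression) and per-library scaling to one million quantile-normalized
  reads (**rpmqn**).
- **expression** — expressed-set calling (≥ threshold in *all* replicates
  of a stage), three-set Venn partitioning, and half-away-from-zero
  percentage reporting.
- **diffexpr** — a filter-cascade DE caller: minimum expression in the
  higher stage, minimum fold change, replicate CV bound in both stages,
  pooled-variance Student's t-test, Benjamini–Hochberg FDR over the
  filter-passing set of each transition.
- **profiles** — z-scored stage-mean profiles, k-means clustering with
  centered-correlation dissimilarity (best-of-restarts, deterministic),
  PCA of replicate samples, and Pearson/complete-linkage replicate
  dendrograms in Newick format.
- **enrichment** — bootstrap GO-term over-representation (resampled set
  counts vs. the annotated universe; with-replacement by default, a
  without-replacement mode behind a flag), minimum-count filter and BH FDR.
- **srna** — read collapsing to distinct sequences (retaining reads
  > 15 nt), length-class profiling (18–28 nt window), exact substring
  matching against mature miRNAs, sRNA count-matrix construction, and the
  sRNA→target stage-mean anticorrelation filter.
- **simulate** — a fully seeded synthetic-data generator (negative-binomial
  counts with planted fold changes along 12 profile archetypes, planted GO
  enrichments, sRNA libraries with 21/24-nt peaks, planted miRNA matches
  and anticorrelated target pairs) with ground-truth labels, so the whole
  pipeline is testable end to end without external data.

## CLI

All functionality is exposed through the `stagewise` entry point:

```sh
stagewise simulate --out-dir sim --seed 1 --n-features 2000
stagewise normalize --design sim/design.tsv --out rpmqn.tsv sim/counts.tsv
stagewise expressed --design sim/design.tsv --out venn.json rpmqn.tsv
stagewise de --design sim/design.tsv --transition T2 --out de.tsv \
    --summary-out de.json rpmqn.tsv
stagewise cluster --design sim/design.tsv --out-prefix clust rpmqn.tsv
stagewise enrich --go sim/go.tsv --out enrich.tsv features.txt
stagewise restructure --counts contig_counts.tsv --hits hits.tsv \
    --design design.tsv --out-prefix tx
stagewise srna collapse --out lib.tsv sim/srna_S1a.fastq
stagewise srna lengths --out hist.tsv sim/srna_S1a.fastq
stagewise srna mirmatch --mature sim/mature_mirna.fasta --out matches.tsv \
    sim/srna_S1a.fastq
stagewise srna targetfilter --srna-expr srna_rpmqn.tsv --tx-expr rpmqn.tsv \
    --design sim/design.tsv --out pairs_filtered.tsv sim/pairs.tsv
```

Every subcommand accepts `--config <yaml>` (flat key–value file exposing
every pipeline threshold; unknown keys are rejected) and `--verbose`
(logs to stderr; results never go to stderr). Identical inputs, config and
seed produce byte-identical outputs.

Formats: TSV for matrices, designs (`sample_id`/`stage`), alignment hits
(12-column tabular), GO annotation and pair tables; FASTA/FASTQ for
sequences; JSON for structured reports.

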