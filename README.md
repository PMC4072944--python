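# paralogbind

Comparative regulatory genomics for paralogous transcription factors on
tiling microarrays.

Many developmental transcription factors come in coexpressed paralog pairs
that can partially substitute for one another — a classic example being the
*Drosophila* group B Sox proteins, whose binding programmes in wild-type and
reciprocal-mutant embryos reveal compensation, interdependency and unique
functions. `paralogbind` implements the computational side of such a study
as a tested, reusable pipeline, exercised end-to-end on synthetic tiling
arrays with planted ground truth:

* **Binding-interval calling.** Replicate probe log₂ ratios are quantile
  normalised, smoothed with a running median over a ±250 bp window, and
  thresholded at a false-discovery-rate target estimated by sign-flip
  (antiprofile) interval counting: FDR(t) ≈ N(−x ≥ t) / N(x ≥ t), made
  monotone by a running minimum. Intervals are maximal probe runs above
  threshold (≥ 3 probes, gaps ≤ 200 bp). A *core set* keeps DamID intervals
  supported by ≥ 1 bp of ChIP overlap.
* **Joint profile comparison.** All datasets are quantile normalised
  together, so one common threshold *t* (default: just above the 95th
  percentile of the pooled distribution) separates bound from unbound in
  every dataset. Regions of a three-way state segmentation — factor A in
  wild type (bA), factor B in wild type (bB), factor A in the B mutant
  (bM) — are assigned one of five event types:

  | bA | bB | bM | change | event |
  |----|----|----|-----------------|-------------|
  | ✓ | · | ✓ | ≥ δ | increased |
  | ✓ | · | ✓ | < δ | no change |
  | ✓ | · | ✗ | | loss |
  | ✗ | ✓ | ✓ | | compensation |
  | ✗ | ✗ | ✓ | | de novo |

  with δ = 1 log₂ unit by default; anything else is reported as
  unclassified.
* **Expression trend scoring.** A replicated 5-timepoint mutant-vs-control
  log-ratio course is fitted gene-wise; variances are shrunk toward a
  scaled-F prior fitted by method of moments on log s² (empirical-Bayes
  moderation), each timepoint is tested with a moderated t and the course
  with a moderated F, both Benjamini–Hochberg adjusted. Significant genes
  get −1/0/+1 scores per timepoint and fall into
  downregulated / upregulated / variable classes.
* **Annotation and overlap statistics.** Interval midpoints are assigned to
  the closest TSS within ±10 kb (gene-boundary fallback), classified by
  genomic feature (UTR > exon > intron, "mixed" across genes), profiled
  against per-base tracks, and scanned with PWMs whose match p-values are
  computed exactly by dynamic programming over a 0-order background.
  Interval-set overlaps are scored with Monte-Carlo z-scores against a
  length-matched uniform-placement null; gene sets are compared through
  orthology maps and flat hypergeometric term enrichment.
* **Direct targets** are the intersection of trend-scored genes with
  core-bound genes, plus an explicit manual rescue list.

## Worked example

```sh
paralogbind run-all --outdir demo --seed 7
cat demo/report.txt
```

```
paralogbind synthetic run
==============================
core intervals: 39
event table: {'event': ['no_change', 'compensation', 'increased', 'de_novo', 'loss', 'unclassified'], 'regions': [8, 8, 8, 8, 16, 32], 'genes': [7, 8, 8, 8, 14, 26], 'planted_regions': [8, 8, 8, 8, 16, 0]}
trend partition: {'none': 54, 'down': 10, 'up': 10, 'variable': 6}
direct targets: {'down': 6, 'up': 6, 'variable': 4, 'none': 0, 'total': 16}
```

The run simulates a two-chromosome genome with a planted binding landscape
(8 regions per event type, 16 losses, plus background regions the
classifier deliberately leaves unclassified) and a planted expression time
course (10 down, 10 up, 6 variable genes). The report shows the event
classifier recovering every planted region count exactly at this noise
level (amplitude 3 log₂ units, noise sd 0.3), the trend partition matching
the planted classes, and 16 direct targets — the genes that are both
trend-scored and assigned to a core binding interval. `demo/` also contains
the fixtures (FASTA/GFF3/BED/SGR/TSV), the called intervals per FDR level,
the event BED and the per-gene trend table.

Each stage is also exposed as a library function
(`paralogbind.binding.call_at_fdr_levels`,
`paralogbind.compare.classify_events`, `paralogbind.expression.run_de`, …)
and as a CLI subcommand (`simulate`, `call`, `compare`, `de`, `annotate`,
`overlap`, `targets`).

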