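# Methods

## Scope and model

`paralogbind` reimplements, as a library, the analysis layer of a
tiling-array study of two paralogous DNA-binding factors (A and B) assayed
by DamID/ChIP in wild type and in the null mutant of the other paralog,
together with a replicated mutant-vs-control expression time course. The
deliverable is the analysis machinery plus a synthetic benchmark with
planted ground truth; genome-scale counts from any particular organism are
outside what a desk-scale synthetic run can or should reproduce.

## Binding-interval calling

Replicate probe log₂ ratios are quantile normalised (column ranks mapped to
the across-column mean of order statistics, ties averaged), combined by
replicate mean, and smoothed with a running median over probes whose
midpoints fall within ±`half_width` (default 250 bp); the window score is
undefined where fewer than `min_probes` (3) probes cover the window.
Medians were chosen over means for robustness to single-probe outliers and
because the resulting scores are exactly testable (a one-probe spike
disappears; a constant profile is a fixed point).

The FDR threshold uses the antiprofile estimator: at candidate threshold
*t*, FDR(*t*) is the number of intervals called on the sign-flipped score
track divided by the number called on the real track, made monotone
nonincreasing by a running minimum over increasing *t*; the smallest *t*
meeting the target is returned, and an explicit error is raised when no
threshold achieves it (e.g. an all-zero track). This estimator assumes the
null score distribution is symmetric about zero — true for the synthetic
noise model and a reasonable approximation for centred array data — and
needs no distributional fit. Candidate thresholds are a 100-point quantile
grid of the positive scores; a denser grid changes thresholds by less than
the inter-probe score resolution.

Intervals are maximal runs of probes at or above threshold with inter-probe
gaps (next start − previous end) ≤ `max_gap` (200 bp) and ≥ `min_probes`
probes, spanning first probe start to last probe end. The core set retains
reference (DamID) intervals overlapping ≥ 1 bp (half-open) with any support
(ChIP) interval, keeping reference coordinates and recording supporting
labels; DamID is the reference because it integrates binding over a longer
developmental window.

## Joint comparison and the five event types

All datasets to be compared are quantile normalised *together* on one probe
layout, so equal values correspond to equal empirical quantiles in every
dataset and a single common threshold is meaningful. The automatic
threshold is taken infinitesimally above the stated pooled quantile
(default 0.95): probes at the quantile value itself are background, which
keeps the rule well defined when the pooled distribution has an atom there
(the noise-free limit). Regions come from segmenting identical per-probe
boolean states (broken at chromosome changes and gaps > `max_gap`), with
runs shorter than `min_run` (3 probes) treated as background in pairwise
comparison; event regions are evaluated on region-mean scores rather than
per-probe majorities, which stabilises the boolean states near the
threshold.

The three-way truth table (bA = wild-type A bound, bB = wild-type B bound,
bM = A bound in the B mutant, Δ = mutant minus wild-type region mean):
increased (bA ∧ bM ∧ Δ ≥ δ), no change (bA ∧ bM ∧ |Δ| < δ), loss
(bA ∧ ¬bM, regardless of bB), compensation (¬bA ∧ bB ∧ bM), de novo
(¬bA ∧ ¬bB ∧ bM); every other bound combination is reported as
unclassified rather than silently dropped — this includes partial
reductions (bA ∧ bM ∧ Δ ≤ −δ) and B-only binding. δ defaults to 1 log₂
unit on the jointly normalised scale; whether "increased binding" should be
a fixed margin or a statistical test is genuinely open, and a fixed margin
keeps the classifier deterministic and auditable.

## Expression trend scoring

Input is a long-format (gene, timepoint, replicate, value) table of log₂
mutant/control ratios; raw intensities can instead be passed through an
arsinh generalised-log transform with per-array median centring. This
transform is a simplified variance stabiliser: it is monotone per array and
turns scale factors into removable shifts, but it does not fit the
full intensity-dependent calibration of dedicated variance-stabilising
normalisation, which is out of scope.

Per gene we fit timepoint means and a pooled residual variance s² on
df = Σₜ(nₜ−1) degrees of freedom (cells with missing replicates are
dropped and df recomputed; genes with an empty timepoint cell are dropped
with a warning). The prior s² ~ s0²·F(df, d0) is fitted by method of
moments on log s² using digamma/trigamma moments; when the observed spread
of log s² does not exceed chi-square sampling spread, d0 is flagged
infinite and s0² is the mean variance. Posterior variances are
(d0·s0² + df·s²)/(d0 + df). Moderated t per timepoint uses
mean/(s̃·√(1/nₜ)) on d0 + df degrees of freedom; the overall moderated F
is the mean squared t across timepoints on (T, d0 + df) (normal/chi-square
limits when d0 is infinite). Benjamini–Hochberg adjustment is applied to
the overall F p-values across genes and to each timepoint's t p-values
across genes.

Scoring: a gene is eligible if its overall-F q ≤ `alpha_overall` (0.05);
eligible genes score sign(mean) at timepoints with per-timepoint q ≤
`alpha_timepoint` (0.05), else 0. Whether per-timepoint significance
should gate the nonzero scores, or overall significance alone suffices, is
underdetermined; the double gate was chosen because it makes the score
vector fully reproducible from stated thresholds and controls the
per-timepoint sign error. Classes: down (only −1 among nonzero scores), up
(only +1), variable (both signs), none (all zero); the partition is
exhaustive and exclusive by construction.

## Annotation

Intervals are anchored at their midpoint, matching the midpoint-based
feature analysis; the assignment window is ±10 kb around the anchor.
Closest TSS wins, then closest gene start/end, then unassigned; ties break
to the lexicographically smaller gene id so results are deterministic.
Feature classification at the midpoint base uses UTR > exon > intron
precedence within one gene (UTRs are exon subsets but are counted
separately), "mixed" when overlapping genes disagree, intergenic when no
gene covers the base.

PWM scanning scores log₂ odds against a 0-order background (estimated from
the scanned sequence with A/T and C/G symmetrisation, so the match set is
strand symmetric); windows containing N are skipped. P-values are exact:
per-column scores are discretised to 1/1000 of the total score range and
the null score distribution is built by convolution across columns, giving
the survival function at any score. With the default p ≤ 1e-4 cutoff,
motifs of width < 7 cannot reach significance under a uniform background
(the best possible p is 4⁻ʷ) — an inherent property of exact PWM p-values,
not a defect.

## Overlap statistics

The overlap z-score compares the number of query intervals hitting the
other set against a Monte-Carlo null that preserves the query's interval
count and length multiset but re-places each interval uniformly among all
valid (universe region, start) slots. The null deliberately ignores
inter-interval spacing and chromatin structure; it is the simplest
defensible placement null and is declared in the result metadata. Null
standard deviations of zero (saturated overlap) yield a flagged undefined
z. Term enrichment is a flat hypergeometric upper tail per term with BH
adjustment — no ontology-graph propagation.

## Synthetic benchmark

The generator emulates: a random genome at a stated GC composition with
stranded gene models (exons from random interior cuts, terminal UTRs as a
fraction of gene length); a tiled probe layout (default 100 bp spacing,
50 bp probes, typical of high-density tiling designs); four binding
datasets (A and B in wild type, each in the other's mutant, 3 replicates,
matching standard replication for such assays) and an optional ChIP-class
re-simulation for core-set construction; and a 5-timepoint, 4-replicate
expression course.

Planted enrichment is a flat plateau of stated log₂ amplitude over each
region — interval-level truth that keeps the caller's oracles exact — and
a probe's expected value is the *sum* of planted amplitudes covering it,
so the noise-free profile is exactly additive. Default amplitude 3 with
noise sd 0.3 gives signal-to-noise 10; "increased" events gain 2 log₂
units in the mutant.

The planted landscape is balanced: region multiplicities are chosen so all
four datasets share one signal distribution (per unit: 1× no change,
compensation, increased, de novo and reduced, 2× loss and unique-B, 1×
strong unique-B). Joint quantile normalisation forces identical marginal
distributions onto all datasets, so it is amplitude-preserving only when
the underlying distributions already agree — which genome-scale profiles
of comparably active factors do, and which a naive unbalanced planting
does not. The filler categories (reduced, unique-B) both provide that
balance and exercise the classifier's unclassified routes. Expression
trends are planted preferentially (50%) on genes near planted binding so
the direct-target intersection is populated; the variable-class template
is (−, −, +, +, 0) across five timepoints, configurable.

What the synthetic data does *not* model: dye bias and spatial artefacts,
sequence-driven probe affinity, DamID methylation persistence across
stages, correlated noise between replicates, and peaked (non-plateau)
enrichment shapes. Passing tests therefore demonstrate correctness of the
algorithms under their stated assumptions, not robustness to every real
array pathology.

## Problem sizes and numerical choices

Tests and the acceptance script run on two-chromosome genomes of 150–400 kb
(3,500–8,000 probes), 4 planted regions per event unit, 20 seeds for the
stochastic suites, 100 repetitions for z-score calibration, and 1,000–5,000
genes for the expression calibrations; these sizes were chosen so each
suite completes in minutes on one CPU while leaving Monte-Carlo error well
below the tested tolerances. Degenerate inputs are handled explicitly:
all-zero score tracks raise a no-threshold error, constant columns map to
the quantile-normalisation reference mean, all-equal variances flag an
infinite prior df, empty reference or CRM sets warn and return empty
results, and saturated overlap nulls flag an undefined z-score.

## Known limitations

The FDR estimator is structure-only with respect to any published interval
counts (the original window scoring is not fully specified by its users);
the vsn replacement is a simplification; the comparison supports pairwise
and three-way designs only; and the placement null for overlap z-scores
ignores genomic covariates, so its z-magnitudes are not comparable to
segmentation-aware nulls.
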