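# Methods

## The analysis model

`cadchart` operates on interval-level summaries, not reads: a union ATAC
peak set with per-sample RPKM, per-gene FPKM/raw-count expression matrices,
and binned histone-mark coverage. Upstream steps (trimming, alignment, peak
calling, track generation) are out of scope; the package starts where a
peak-by-sample signal matrix exists or can be computed from fragment BED
records by midpoint counting.

### Empirical-FDR threshold calibration

Open vs closed chromatin is decided by a single global RPKM cutoff shared
by all samples. Background regions are drawn length-matched from the
genomic space outside the union peak set; at a candidate threshold *t* the
empirical FDR is the count of background values ≥ *t* divided by the count
of peak values ≥ *t* (the standard empirical-null exceedance ratio; all
samples pooled). The calibrated threshold is the smallest grid point (grid:
0.01-RPKM steps from 0 to the 99.9th percentile of pooled peak values)
whose FDR meets the target, default 1%.

The raw exceedance ratio is not mathematically monotone in *t* — at extreme
thresholds small counts can make it tick upward — so the curve object also
carries a non-increasing envelope (running minimum along the grid) for
diagnostics. Both forms select the same calibrated threshold, because the
smallest grid point under the target is identical under a running minimum.
If no grid point reaches the target, calibration fails loudly and reports
the minimum FDR achieved rather than returning a boundary value.

Boundary convention: signal exactly equal to the threshold is called open
("below the threshold" is closed). Stage-level signal is the mean RPKM of
the stage's replicates; the mean is the least surprising reducer and keeps
the per-stage chart independent of replicate count.

### Module charting

Each peak's binary trajectory across the ordered stages (primed first,
naïve last) receives exactly one of six labels. Modules 1 and 5 are the
constant trajectories. Module 2 (open-to-closed) requires monotone loss —
open at the first stage, closed at the last, with no reopening; transient
reopening demotes a trajectory to the residual class. Module 3 requires
closure at the first stage and openness from the first day-8 stage through
the end; module 4 requires closure at both ends with at least one open
intermediate stage. Module 6 is defined as everything else: it is the only
definition that makes the classification total, which exhaustive
enumeration over all patterns up to 7 stages verifies. The day-8 anchor
index is configurable (default 1, the second stage).

Nearest-gene annotation minimizes |peak center − TSS| with ties broken to
the gene earlier in coordinate order (determinism over biology-free
arbitrariness). The signed distance is negative upstream on the gene's
strand. Categories: promoter within ±2,000 bp of the TSS (configurable),
genic when the center falls in the gene's merged-exon span, else distal
intergenic.

### Discordance calling

The comparison pair is the two day-8 populations. Candidate genes must own
at least one peak open in both populations. "Similar accessibility" is
formalized as |log₂ fold change| ≤ 0.5 between the two stage-level ATAC
values (with a pseudocount of 1); when a gene has several shared-open peaks
the one with the largest mean signal represents it. Differential expression
is a Welch two-sample t-test on log₂(FPKM+1) with Benjamini–Hochberg
correction; fold changes come from group means of FPKM+1. A
negative-binomial count model was deliberately not reimplemented here: the
discordance logic needs a ranked, calibrated differential call, and the
self-contained Welch/BH combination keeps the package dependency-light and
its null behavior transparent. Defaults: |RNA log₂FC| ≥ 1, q ≤ 0.05. Genes
route to the "up" set when expression is higher in the RFP-positive
population, "down" otherwise; swapping the group labels exactly swaps the
sets, and tightening any threshold can only shrink them.

### Profiles and mark comparison

Binned coverage is treated as a piecewise-constant function whose integral
over any range is exact; profile bins are therefore conservative (bin mean
× bin width sums to the windowed signal integral to 1e-9 relative error).
Peak-centered profiles use 50-bp bins over ±3 kb (120 bins); gene-body mode
rescales the merged-exon span to 100 body bins with fixed-width flanks,
reversing minus-strand rows. k-means clustering (scikit-learn, seeded,
n_init=10) relabels clusters 1..k by descending mean signal, matching the
heatmap convention of strongest cluster first; k defaults to 3. The mark
comparison reduces each locus to its window mean and reports per-locus
log₂((A + c)/(B + c)) with pseudocount c = 1 RPKM to stabilize ratios near
zero, plus the per-mark mean absolute difference and the strongest mark.

## The synthetic-data generator

The generator emulates the statistical skeleton of the transition data:

- **Geometry.** Two 2-Mb chromosomes, 2,000 non-overlapping peaks of
  300–800 bp placed by random gap layout; one gene per peak with its TSS at
  the peak center and a 2-kb merged-exon span.
- **Stages and replicates.** Five ordered stages
  (pESC, d8_RFPneg, d8_RFPpos, RFPpos_GFPpos, nESC), three replicates each.
- **Module mix.** Each peak draws a module from (17.03%, 7%, 31.56%,
  34.51%, 5%, 4.9%); the three dominant proportions are the peak
  composition reported for the real transition, and the remainder is split
  plausibly across the minor classes. Each module contributes its canonical
  trajectory.
- **Signal.** Log-normal open and closed RPKM distributions (log-means 5.0
  and 0.7, sd 0.8: ~0.7% overlap, comfortably below the 2% separability
  budget), drawn once per peak as a locus amplitude and shared across
  stages in the same state, with i.i.d. log-normal replicate noise
  (sd 0.2). Treating amplitude as a locus property is what makes
  shared-open peaks genuinely "similar" between the day-8 populations.
- **Expression.** FPKM follows the peak's chromatin state, except for a
  designated discordant fraction (5% up + 5% down of shared-open genes)
  whose day-8 expression states are decoupled from chromatin. Raw counts
  are Poisson draws at a 20M-fragment library scale.
- **Histone marks.** Binned (50 bp) tracks for H3K4me3 and H3K27ac in the
  two day-8 populations: a low log-normal baseline plus a Gaussian bump
  (σ = 300 bp) per peak whose amplitude follows the expression state; at
  discordant loci the two populations split symmetrically by the
  configured per-mark log₂ effects (defaults 2.0 for H3K27ac, 1.0 for
  H3K4me3 — the acetylation mark separates more strongly by construction,
  and the config rejects the reverse ordering).
- **Fragments (optional).** Per-sample fragment BEDs with Poisson counts
  proportional to each peak's RPKM plus sparse uniform background, so the
  full pipeline (counting → RPKM → calibration) can run from raw-ish input.
- **Replicate peak calls.** The union peaks with 2% independent dropout per
  replicate, feeding the ≥2-replicate merge step.

What the generator does *not* emulate: sequence content, Tn5 insertion
bias, fragment-length structure, copy-number or mappability artifacts,
overdispersed (non-Poisson) counts, peak-width/signal correlation, or
inter-gene correlation. Passing tests therefore demonstrate that the
algorithms are correct under the assumed statistical structure, not that
the thresholds transfer verbatim to any real dataset.

## Numerical and design choices

- Coordinates are 0-based half-open throughout (BED dialect).
- Replicate merging counts support per base pair and merges maximal
  supported runs; this resolves the ambiguity of partial overlaps in a
  two-step intersect-then-merge description.
- Background shuffling computes, per region length, the exact set of legal
  start positions (chromosome gaps minus the exclusion set, shrunk by the
  length) and samples uniformly from it. This is measure-equivalent to
  rejection sampling against the same legal space but cannot fail on
  feasible-but-tiny placements, and it makes infeasibility (no legal start
  anywhere) an immediate, explicit error.
- Fragment counting assigns each fragment by its midpoint — a single,
  unambiguous assignment that avoids double counting across adjacent
  intervals.
- Pipeline problem sizes in the test suite (300–2,000 peaks, 0.5–2 Mb
  chromosomes) were chosen as the smallest scales at which the binomial
  recovery checks retain power; the acceptance study uses 50,000 values per
  arm, matching the scale at which a 1% FDR estimate has ~0.06 percentage
  points of Monte-Carlo error.

## Known limitations

- The empirical-FDR estimator's exact form in the original processing chain
  is underdetermined; the background-over-peak exceedance ratio used here
  is the standard construction and is what the single published global
  threshold implies, but alternatives (e.g. background exceedance fraction
  alone) would calibrate differently.
- The Welch/BH differential-expression stage is a deliberate substitute for
  a negative-binomial count model; gene counts near the detection floor are
  handled by the +1 pseudocount rather than dispersion shrinkage, so very
  low-expression genes are conservatively ranked.
- `classify_pattern` reads module 2 as strictly monotone loss; if a real
  charting tolerated transient reopening, those trajectories land in
  module 6 here.
- Profile building accepts binned text coverage only; bigWig input should
  be binned upstream.
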