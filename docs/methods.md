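# Methods

## Overview

`se-landscape` implements a super-enhancer (SE) discovery and
prioritization workflow for matched tumor/normal H3K27ac ChIP-seq
designs, together with a ground-truthed synthetic-data generator used to
validate every stage end to end. The workflow is:

1. **Per-sample SE calling** (ROSE-style): remove blacklisted peaks,
   drop peaks within 2 kb of the nearest transcription start site (TSS),
   stitch the survivors within 12.5 kb, rank stitched regions by
   aggregate H3K27ac signal, and separate SEs from typical enhancers at
   the hockey-stick cutoff.
2. **Consensus and differential analysis**: merge per-sample SEs into a
   non-overlapping consensus universe, quantify each region per sample as
   RPKM, inspect samples by PCA, and call differential SEs with the
   Wilcoxon rank-sum test, Benjamini–Hochberg (BH) FDR adjustment, and
   fold-change gates (> 1.5 up, < 0.67 down).
3. **Target integration**: assign each SE the gene with the nearest TSS,
   intersect differential SE target genes with direction-matched
   differentially expressed genes (DEGs), screen transcription factors
   (TFs) for binding-site occupancy of the SE constituents and target
   promoter, rank surviving TFs by expression correlation with the
   target, and localize the top TF's motif by PWM scanning.
4. **Survival screen**: dichotomize an independent cohort at the median
   expression of each candidate gene and flag genes with log-rank
   p < alpha and Cox hazard ratio > 1 (high expression, poorer survival).

## Per-sample SE calling

**TSS exclusion.** Distance from a TSS point `t` to a peak `[s, e)` is 0
if `s <= t < e`, else `min(|t - s|, |t - (e-1)|)`. A peak is kept iff its
distance to the nearest TSS is >= `d` (default 2,000 bp, inclusive
boundary, strand-agnostic). By default exclusion is applied to individual
peaks *before* stitching (`tss_mode="pre"`); `tss_mode="post"` instead
drops stitched regions wholly contained within a single TSS's exclusion
window, as the original ROSE implementation does.

**Stitching.** Same-chromosome peaks merge transitively whenever the gap
`next.start - prev.end` is <= the window (default 12,500 bp; a gap of
exactly 12,500 merges). Overlapping peaks always merge. The sweep-line
implementation is verified against an independent
adjacency-plus-connected-components oracle.

**Signal and cutoff.** A stitched region's signal is the sum of its
constituent peak signals (for narrowPeak input, column 7, signalValue),
optionally minus a matched control sum, floored at 0. Signals are sorted
ascending and both rank and signal scaled to [0, 1]; the cutoff is the
point minimizing (scaled signal − scaled rank) — equivalently where the
tangent to the ranked curve has slope 1. Ties break toward the largest
index (fewest SEs, the conservative choice). Regions with signal
*strictly greater* than the cutoff signal are SEs, so the tangent point
itself is typical. Degenerate inputs (n < 3, or a flat signal vector)
place the cutoff at the maximum, yielding zero SEs. The cutoff is
invariant under positive affine transforms of the signal vector.

## Consensus and differential analysis

**Consensus merge** uses overlap-or-book-ended semantics (gap 0 merges),
mirroring common `merge` defaults; ids are assigned deterministically in
coordinate order (`SE_0001`, ...). Provenance (which samples contributed
which SEs) is retained.

**RPKM**: `count * 1e9 / (length_bp * library_size)`.

**PCA** treats samples as observations and regions as variables,
centered, unscaled by default (singular value decomposition; variance
explained sums to 1 over non-null components).

**Wilcoxon rank-sum**: exact p by enumeration when both groups have
<= 10 observations and the pooled data contain no ties; otherwise the
normal approximation with tie-corrected variance and continuity
correction. Two-sided throughout. The test is unpaired, following the
analysis design this emulates, even though samples are paired; a paired
signed-rank option exists but is off by default.

**Fold change** is the ratio of group means of RPKM with a pseudocount of
0.01 RPKM in both numerator and denominator, so regions absent in one
group remain finite. The default call requires the BH q-value < 0.05
*and* the fold-change gate; `require_fdr=false` reproduces a
fold-change-only reading.

## Target integration

Nearest-gene assignment measures region-to-TSS-point distance (0 when
the TSS is inside the region), strand-agnostic, ties broken by
lexicographically smallest gene id; a chromosome without any TSS yields
an explicit unassigned record. DEG tables are inputs with schema
(gene_id, log2fc, q, direction); a minimal Wilcoxon+fold-change helper
exists for synthetic tests only. The TF funnel is a generic overlap
classifier: a TF hits a query region iff any of its sites overlaps it by
>= 1 bp. PWMs are built from count matrices with a pseudocount of 0.8
split by the background composition (JASPAR convention) and scanned on
both strands; hits are reported at forward coordinates when the score
reaches `min_fraction` (default 0.8) of the maximum attainable score.
Windows containing N never match. The fraction-of-max threshold is used
instead of a p-value-calibrated one to keep scanning self-contained.

## Survival screen

Median split: high iff value > median (midpoint for even n); ties go to
"low". Kaplan-Meier curves and the log-rank test come from lifelines;
degenerate tables (no events, zero variance, or an empty group) report
chi2 = 0, p = 1 rather than erroring so genome-wide screens do not
abort. The univariate Cox model maximizes the Breslow partial likelihood
by Newton iteration (tolerance 1e-8 on beta, at most 50 iterations, step
clipped to ±2 to survive near-separated data), with Wald standard errors
from the observed information and `ci95 = exp(beta ± 1.96 se)`. Breslow
tie handling was chosen over Efron because it is the simplest
differentiable form; the Newton estimate is verified against a dense
grid search of the same likelihood and against parameter recovery from
simulated exponential hazards. Hazard ratios are reported for the binary
high-vs-low indicator (not continuous expression), matching the
median-split design of the screen. A constant covariate returns the
convention beta = 0, hr = 1, p = 1.

## Synthetic-data generator

The generator emulates a desk-scale version of the study design: 9
matched tumor/normal pairs profiled over 500 candidate enhancer loci on
a 2 x 10 Mb synthetic genome, with 50 tumor-enriched and 50
normal-enriched loci planted at a 4-fold count effect.

* **Counts** are negative binomial in the mean–dispersion
  parameterization (variance = mu + mu²/k, k = 20), capturing ChIP-seq
  overdispersion. Per-locus activity is a mean-normalized lognormal
  (sigma = 0.6), giving the heavy-tailed signal distribution the
  hockey-stick cutoff expects; each tumor and its matched normal share a
  per-locus lognormal baseline (sigma = 0.3), so the unpaired test
  downstream is conservative. The base mean is 200 reads per locus;
  library sizes are uniform on 8–12 M and scale the means, so RPKM is
  unbiased across samples.
* **Geometry.** Each locus holds 3–8 peaks (400–1,200 bp wide, gaps
  200–1,200 bp), so every locus stitches into one region at 12.5 kb
  while inter-locus gaps (> 16 kb) never merge. Each locus's gene TSS
  sits 3 kb past its last peak — outside the 2 kb exclusion but the
  nearest TSS by a wide margin. Promoter peaks (straddling each TSS) and
  junk peaks inside blacklist intervals are planted to exercise both
  filters.
* **Expression** for locus genes is lognormal around a mean shifted by
  the locus's z-scored log activity with coupling 0.8 (the target
  SE-to-expression correlation); TF and decoy genes are independent
  noise, except the driver TF, whose expression tracks the driver gene
  (sd 0.15 on the log2 scale).
* **Driver designation.** The most active tumor-enriched locus (largest
  baseline multiplier) is the driver, mirroring the discovery of a
  robustly active SE; its gene drives the survival cohort and its first
  and last constituent peaks (plus the promoter) carry the driver TF's
  binding sites. Three decoy TFs also occupy all three regions, so the
  correlation ranking — not the occupancy funnel alone — must identify
  the driver TF.
* **Survival cohort**: 300 subjects, exponential times with hazard
  `h0 * exp(0.7 * z(driver expression))`, h0 = 0.1; 30% of subjects are
  censored uniformly before their event time, giving an exact configured
  censoring fraction.
* **Motif sequences**: 100 sequences of 500 bp with the 10-bp AP-1-like
  consensus ATGACTCATC planted once each at a recorded position and
  strand. Backgrounds are rejection-sampled so the planted occurrence is
  the only one on either strand — zero-false-positive recovery is a
  property of the generator, not luck.
* **Reproducibility**: one RNG stream per file type, all spawned from
  the master seed, so adding a file type does not perturb existing
  outputs; outputs are byte-identical per seed.

**What the generator does not emulate**: read-level artifacts (mappability,
GC bias, fragment-length effects), copy-number confounding, inter-locus
correlation, batch structure, or realistic gene density. Passing the
recovery tests therefore demonstrates that the *procedure* is implemented
correctly and recovers planted structure under its stated assumptions,
not that it would achieve the same operating characteristics on real
cohorts.

## Numerical choices and degenerate inputs

* Coordinates are 0-based half-open everywhere internally; 1-based
  genome-browser coordinates are converted at the boundary.
* Blacklist removal drops a peak on any >= 1 bp overlap.
* Chromosome names are matched exactly; `strip_chr_prefix` opts into
  normalization, never silently.
* BH q-values are computed by statsmodels and cross-checked against the
  direct step-up definition in tests.
* The hockey-stick tie-break, the strictly-greater SE rule, the
  median-split ties-to-low rule, and the Cox constant-covariate
  convention are all fixed and documented above so reruns are
  deterministic; `call_superenhancers` output is independent of input
  peak order.

## Problem sizes used in validation

The test suite and acceptance script run at desk scale: 500-region
simulations with 18 samples (a few seconds each), 10–20 seeded
replicates for recovery rates, 1e5-replicate permutation oracles for the
rank-sum comparison, 5e4-replicate label permutations on 60-vs-60
cohorts for the log-rank comparison, and an n = 500 cohort for Cox
parameter recovery. These sizes were chosen so the whole validation runs
in a few minutes on one CPU while leaving the statistical comparisons
well-powered.

## Known limitations

* SE signal is taken from peak-caller signal attributions, not re-read
  from alignments; input-DNA handling is limited to linear subtraction.
* The DEG step is an input contract, not a modeled analysis.
* The log-rank p-value is asymptotic (chi-square, 1 df); for very small
  groups it can drift ~0.01 from the exact permutation p.
* Multivariate/adjusted Cox models, Efron ties, paired mixed models, and
  Hi-C-informed target assignment are out of scope.
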