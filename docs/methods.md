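# Methods

`hybridase` analyzes an F1 hybrid against its two parents on three data
layers — plot-level agronomic trials, bulk RNA-seq expression, and
per-site allele read depths — plus GO over-representation of the
resulting gene sets. Every stage can be driven by the bundled
synthetic-data generator, which plants known effects so the whole
pipeline is testable without external data.

## Field-trial analysis

**Model.** Each location is a randomized complete block design (RCBD).
The per-location working model is ordinary least squares,

    trait ~ genotype + block + retained row/column trend covariates,

with genotype in cell-means coding, block sum-to-zero coded and all
covariates mean-centered, so the genotype coefficients are adjusted
means at the average block and covariate value. Block is fitted as a
*fixed* effect. In the balanced designs this package targets, genotype
contrasts (which annihilate the block space) have the same estimates as
a random-block mixed model; what the mixed model would add — a separate
residual variance per location — is supplied by the pooled stage, which
combines per-location contrasts by inverse-variance weighting with
Satterthwaite degrees of freedom. REML variance-component estimation and
anisotropic spatial covariance structures are deliberately out of scope;
spatial structure is handled only through polynomial trend covariates.

**Outlier screen.** One pass, no iteration: under the saturated trend
model (genotype + block + full 4th-degree row and column polynomials),
plots with externally studentized residual |t| > 3 are dropped. The
externally studentized residual is exactly the leave-one-out prediction
t statistic; a brute-force leave-one-out refit is used as the test
oracle. When the model fit is numerically exact (noise-free synthetic
data) the residual sum of squares is snapped to zero and no outliers are
flagged, since studentizing a zero residual by a zero variance is
meaningless.

**Trend-covariate selection.** Backward elimination over
{row¹..row⁴, col¹..col⁴} (centered powers of the grid coordinates).
At each step the highest remaining order on each non-frozen axis is
tested by the partial F test of dropping it from the current model —
equivalent to its sequential (Type-1) test when covariates are ordered
by degree. Non-significant terms (α = 0.05) are removed highest order
first; when both axes tie at the same degree the larger p goes first.
Once an axis's top remaining order is significant the axis is frozen:
every lower order on it is retained regardless of its own p (the
hierarchy rule). Constant coordinates are excluded a priori.

**Contrasts.** Single-degree-of-freedom linear contrasts of adjusted
means, e.g. mid-parent heterosis `{F1: +1, P1: −1/2, P2: −1/2}`;
t statistics on the residual df. One-sided p-values (used for yield and
harvestable protein, hypothesized direction F1 > mid-parent) are half
the two-sided p when the estimate has the hypothesized sign, else one
minus that half. With zero residual variance (noise-free data) the
estimate is exact: p = 1 if it is zero, else 0. `harvestable_protein`
is derived per plot as yield × protein/100 (kg/ha) when absent; the
moisture basis of the published per-hectare protein figures is not
stated, so the derived column is labeled derived and its agreement with
published values rests on the printed means.

**Degenerate inputs.** A one-plot-per-genotype table of published means
is accepted: the outlier screen and covariate selection are skipped
(recorded in the report's `gaps`), estimates are differences of means,
and standard errors/p-values are NaN.

## Expression classification

Differential expression of the F1 against each parent, per location,
uses the two-fold rule: significant iff |log2 FC| ≥ 1 (inclusive) *and*
a Welch two-sample test on log2(value + pseudocount) across replicates
gives p < α (default 0.05). The Welch test is replaceable plumbing
standing in for a full RNA-seq differential pipeline; the fold-change
gate is the substantive criterion and is isolated behind one operation.
Pseudocount default 1.0 FPKM prevents log 0 and must be scaled together
with the data for scale invariance. No multiple-testing correction is
applied by default; BH-FDR is available as an option. Zero-variance
groups are decided by the gate alone (p set to 1 when the means agree,
0 when they differ), so noise-free data classify exactly.

Per-gene calls vs the two parents combine into categories: up (down)
vs both parents is non-additive `above_both` (`below_both`); a gene
significant up vs one parent and down vs the other is a flagged
crossover counted in *neither* non-additive category; otherwise the
single-parent categories or `not_de`. Cross-location concordance is the
shared significant set, its direction-agreement fraction, and the
squared Pearson correlation of log2 fold changes over that set
(undefined below 3 shared genes).

## Allele-specific bias

1. **Splice masking.** Sites within 2 bp (inclusive) of a junction
   boundary are dropped — alignment is unreliable there. Junction BED
   intervals are 0-based half-open introns; the 1-based exonic
   boundaries are `start` and `end + 1`, both masked.
2. **Parent-specific SNPs.** A site is retained iff every replicate of
   exactly one parent, at both locations, is effectively homozygous for
   the alternative allele, every replicate of the other parent is
   effectively homozygous reference, and all parental replicates have
   depth ≥ 8. "Effectively homozygous" means minor-allele read fraction
   ≤ 0.05 — a pragmatic stand-in for a genotype caller, since read
   counts, not genotype likelihoods, are this stage's input. Zero-depth
   replicates fail the depth criterion (site rejected, not an error).
3. **F1 fractions.** Per-replicate origin-allele fraction, and a pooled
   fraction from *summed read counts* over depth-passing replicates
   (fraction of the reads, not a mean of per-replicate fractions).
4. **Bias call.** Biased iff the majority allele's pooled fraction is
   strictly greater than 0.73 *and* every passing replicate lies on the
   same side of 0.5 as the pooled fraction. This is the strictest plain
   reading of "consistently across a location"; requiring every
   replicate to exceed 0.73 individually is a recognized alternative.
   A replicate at exactly 0.5 breaks consistency. The fixed 0.73
   threshold is the default; it coincides with two standard deviations
   of the fraction distribution in the motivating data, and an
   empirical threshold 0.5 + 2·SD of the observed pooled fractions
   (sample SD about their mean, floored at 0.5, requiring ≥ 30
   fractions) is available opt-in. Whether that 2-SD statistic should
   be computed on pooled fractions, per-replicate fractions or
   log-ratios is not derivable from its verbal definition; pooled
   fractions were chosen as the quantity the threshold is applied to.
5. **Downstream.** Cross-location r² of pooled fractions (all SNPs and
   the biased-at-either subset) plus the count of SNPs switching
   favored allele between locations; per-gene bias consistency (all
   biased SNPs of a gene favoring one parent); a Fisher exact test of
   methylation-associated substitutions (C→T, G→A — the classes
   inflated by 5-methylcytosine deamination) against bias status; and a
   20-bin fraction histogram per alt-allele parent of origin, in
   percent of panel SNPs.

Coordinates are 1-based (VCF convention) throughout; multi-allelic and
indel records are excluded at load time with counts in the manifest.

## Enrichment

Upper-tail hypergeometric over-representation per GO term:
p = P(X ≥ k) for k study hits of a term annotating K of N background
genes with study size n. The background is the set of genes expressed
in the tissue at that location (mean across samples > 1 FPKM by
default). Terms under 5 background genes are skipped; BH-FDR is
reported alongside raw p. Annotation is flat gene → term sets;
GO-graph ancestor closure is an opt-in utility, off by default, because
published SEA listings are term-level with the annotation as given.

## Synthetic-data generator

The generator's defaults mirror the motivating study's design: two
locations; RCBD with 5 blocks, per block 1 F1, 3 F2 and 6 of each
parent; expression for 3 genotypes × 4 replicates × 2 locations at
33 000 genes; 4 390 SNPs with 241 planted biased sites in 191 genes.

* **Trial.** Plot value = entry mean + Gaussian block effect
  (per location × block) + row/column polynomial trends on centered
  coordinates + Gaussian residual. F1 entries sit at the parents'
  mid-parent value plus `heterosis_shift`, so the planted contrast
  equals the shift exactly. Within a location each block is one grid
  column and the randomized entry order gives the row, so row trends
  vary within blocks while column trends are confounded with blocks —
  as in a real serpentine layout.
* **Expression.** Log-normal, mean-preserving replicate noise with
  coefficient of variation `replicate_cv` (default 0.2 — replicate
  variability of FPKM is not published, so this is a free choice) and
  a per-(gene, location) log-normal environment factor. Planted
  categories set genotype means from a baseline b (log-normal around
  20 FPKM, floored at 2 so a planted fold of 4 survives the
  pseudocount) — see the table in the module docstring. Default
  category fractions put ~1 % of genes differential vs a single parent
  and ~25/~6 genes above/below both parents per 33 000, the scale
  observed in leaf tissue.
* **Allele depths.** Depths are Poisson(`depth_mean`, default 50);
  F1 alt counts are Binomial(depth, p) with p = 0.5 for unbiased and
  p = `bias_level` (default 0.9) toward the favored parent for biased
  SNPs; a beta-binomial overdispersion knob (default 0) exists because
  real ASE data are overdispersed. The wild-derived parent carries
  residual heterozygosity: each (SNP, parental replicate) flips to
  heterozygous with probability 0.125 — the expectation for an
  F4-derived line — which correctly disqualifies the site from the
  parent-specific list. A configurable fraction of sites (default 5 %,
  a free choice) is placed within 2 bp of an intron boundary. Biased
  SNPs are grouped round-robin into `n_biased_genes` genes with one
  favored parent per gene, so multi-SNP genes are internally
  consistent; the generator does not plant the few inconsistent
  multi-SNP genes real data show.

What passing tests on this generator do **not** show: robustness to
overdispersed counts (unless the knob is turned), to unbalanced or
incomplete block designs, to alignment artifacts beyond the splice
mask, or to annotation-version effects in enrichment — published
enrichment p-values depend on a specific historical annotation release
and are not reproduction targets.

## Numerical choices

* Exact model fits (RSS ≤ 1e−10 · ‖y‖²) are treated as zero-residual:
  no outliers, exact contrasts.
* Contrast coefficients must sum to 0 within 1e−8; estimates within
  1e−8 of zero (relative to the largest mean) count as zero when the
  residual variance is zero.
* Histogram bins are half-open [lo, hi) with the last bin closed
  (`numpy.histogram` convention).
* Pipeline randomness flows from one seed through SHA-256-derived
  per-stage substreams, so any stage can be rerun independently and
  reproducibly; all analytic outputs are plain TSV/CSV and reruns are
  byte-identical.

## Problem sizes used in the checks

The test suite and the acceptance script run the generators at reduced
sizes chosen to keep every check sharp: 2 000 SNPs for bias recovery,
800 genes for the noise-free round trip, 500 single-location trials of
30 plots for the type-I calibration, ten ≤ 20-site toy tables for the
filter-oracle equivalence, and a 2 000-gene / 600-SNP configuration for
the byte-identity rerun. These sizes are the package's own choices; the
statistical properties they verify are size-free.

## Known limitations

* Fixed-effect blocks and inverse-variance pooling replace the mixed
  model; with unbalanced data after outlier removal the equivalence to
  a random-block analysis is approximate.
* The Welch-on-log2 test is not a negative-binomial count model; its
  calibration on FPKM-like values is what the null simulations verify.
* The parent-specific filter's "effectively homozygous" rule is a
  threshold heuristic, not a genotype-likelihood caller.
* Enrichment treats annotation as flat sets; without ancestor closure,
  term p-values are not comparable across annotation releases.
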