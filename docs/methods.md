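# Methods

## Asymmetry traits

For a paired left/right trait (L, R) the signed angular asymmetry is
θ = arcsin((L − R)/√(2(L² + R²))), the angle between the point (L, R)
and the diagonal L = R. Four plans are derived per pair: I (signed,
raw), II = |I|, III (signed, z-standardized L and R), IV = |III|. Plans
III/IV standardize each side by its sample mean and SD over the
non-missing subjects of the analysis phase, so different ancestry phases
are standardized separately. The point L = R = 0 has no direction and is
treated as missing rather than zero. Useful identities, all enforced as
tests: θ is invariant to positive rescaling of (L, R); θ(R, L) = −θ(L, R);
|θ| ≤ π/4 on nonnegative pairs with equality exactly when one side is 0;
on strictly positive pairs θ is a monotone transform of the traditional
index (L − R)/(L + R) (Spearman correlation 1).

Trait QC drops a derived trait when fewer than 1,000 non-missing values
remain or when a single value accounts for more than half of them.
Normalization is a rank-based inverse-normal transform (average ranks,
offset (r − 0.5)/n); when more than 25% of the non-missing values are
tied at one value the rank transform is a poor choice and plain
z-scaling is used instead. The 25% trigger is this package's own
definition of a "poor" rank transform; any monotone criterion would do,
and the cutoff only matters for heavily discretized traits.

## Synthetic cohorts

Genotypes follow a haplotype-copying model: SNPs are organized in blocks
(default 20 SNPs, 10 kb spacing, so a block spans 200 kb) sharing one
allele frequency drawn from `maf_range`; along a block each haplotype
allele copies its left neighbour with probability `ld_decay` (default
0.95) or is redrawn at the block frequency. This preserves the marginal
frequency exactly and gives adjacent-SNP dosage correlation `ld_decay`,
hence r² decaying geometrically with distance — enough structure to make
clumping meaningful while staying fully controllable. Blocks never cross
chromosome boundaries in effect because copying is restarted at each
block. Replication phases reuse the same panel; an ancestry-shifted
phase perturbs each SNP's frequency on the logit scale with a
configurable SD, and a second-time-period phase redraws only measurement
noise.

Traits are built as L = base + common + g/2 + e_L and
R = base + common − g/2 + e_R, with `common` a shared subject-level
factor and g the genetic asymmetry component Σ βᵢ·dosageᵢ plus optional
covariate terms. Each causal SNP's `variance_explained` vᵢ is the
fraction of Var(L − R) it accounts for; with residual noise SD σ the
generator solves Var(L − R) = 2σ²/(1 − Σv) and
βᵢ = √(vᵢ·Var(L − R)/Var(dosageᵢ)). The fractions must sum below 1, and
σ = 0 with nonzero v is rejected as unsatisfiable. Covariates are age
uniform on [40, 69], sex Bernoulli(1/2), and 20 standard-normal
PC-like columns.

What the generator does *not* emulate: realistic phenotype covariance
across trait pairs, imputation dosage uncertainty, population
stratification correlated with genotype, or X-chromosome inheritance.
Passing recovery tests therefore demonstrate correctness of the
statistical machinery on well-specified data, not robustness to those
real-data complications.

## Association scan

The scan is per-SNP ordinary least squares of the residualized,
normalized trait on dosage with pairwise-complete subjects. On unrelated
cohorts — which the generator produces — this is the model to which a
sparse-GRM mixed-model scan reduces, so OLS is used as the scan and the
GRM machinery (standardized-dosage GRM, sparsification at 0.05, and
iterative removal of subjects with more than 100 nonzero relatives) is
kept as stand-alone utilities for the relatedness-pruning procedure.
The covariate design uses age, age², age×sex, age²×sex, the PCs, and a
sex main effect: the interactions without the main effect would make
their coefficients depend on the age origin, so hierarchical inclusion
is the package's choice. The genomic inflation factor is
median(χ²)/0.4549 from the P-value vector. Hardy–Weinberg is the 1-df
chi-square on genotype counts — the appropriate scale for a 10⁻⁶
threshold and far cheaper than the exact test.

Clumping is greedy and PLINK-compatible: smallest P first (ties broken
by chromosome then position), members are unassigned SNPs below `p2`
within 250 kb center-to-center on the same chromosome with dosage
r² ≥ 0.5 to the index. Equivalence with a brute-force re-scanning
implementation is asserted on 200 random instances.

### Detection power at the recovery conditions

The recovery suite plants 5 causal SNPs each explaining 1% of
asymmetry-difference variance in 4,000 subjects. The per-SNP
noncentrality is √(n·v/(1−v)) ≈ 6.36 against the two-sided 5×10⁻⁸
threshold (z = 5.45), i.e. ≈ 0.82 power per locus; the probability of
recovering all five loci in one scan is then roughly 0.82⁵ ≈ 0.37 (LD
tagging raises the per-locus figure to ≈ 0.86 and the joint rate to
≈ 0.46, the level the suite observes). A locus counts as detected when a
genome-wide-significant index SNP lies within the 250 kb clump radius of
the causal SNP; index SNPs outside every causal window are false
positives (moderately linked satellites of a causal SNP inside the
window carry real signal and are not).

## Replication indexes

Sign concordance excludes zero or missing effect sizes from the trial
count and tests the concordant count against Binomial(n, 1/2), upper
tail: the scientific question is excess concordance, so all replication
binomials are one-sided. The QTL replication test counts replication-scan
P values of discovery index SNPs below 0.05/n and compares with
Binomial(n, 0.05/n). For k = 1 this tail equals 1 − (1 − 0.05/n)ⁿ, which
lies in (1 − e^(−0.05), 0.05] for every n and is nearly independent of
n — so the statistic is reproducible without knowing the exact trial
count. Effect-size correlation uses the top 200 index SNPs from clumping
the discovery scan at p1 = p2 = 10⁻⁴; when fewer exist, all are used.

## Gene mapping

A SNP (1-based position) maps to a gene (0-based half-open intervals)
only when contained in exactly one gene; multi-gene and intergenic SNPs
are dropped, with no nearest-gene fallback (a configurable flank,
default 0, exists for sensitivity analyses). Gene sets from two
annotation routes merge by set union. Containment is the single
criterion; feature-level precedence (exonic vs intronic) is out of
scope.

## Clade enrichment

Focal-set enrichment in a clade is the upper binomial tail
P(X ≥ k | n, p) with p the background proportion of the clade; per-clade
flags use unadjusted P < 0.05. Focal genes absent from the background
map are excluded with a warning. Tree degeneration merges all clades
strictly more ancient than a boundary (default Tetrapoda) into one
"ancient" stratum, conserving gene counts. The stepwise procedure
recomputes all clade tests, selects the minimum-P clade while it is
below α, removes that clade's genes from both focal and background sets
(proportions renormalize over the remaining clades), and repeats; ties
go to the more ancient clade for determinism. Each round strictly
shrinks the clade list, so the loop terminates within the number of
clades.

## Expression analyses

BSI = log₂(x̄_brain / mean of non-brain organ means), with replicate
means per organ. In cross-species comparisons an organ enters a gene's
BSI only when non-missing and above the expression threshold (default
RPKM-like 1, swept over 0.5/1/1.5) in *both* species, brain included;
the same organ set is then used for both species and at least one
non-brain organ must remain. The threshold's both-species reading is the
package's resolution of an ambiguity in how such filters are usually
stated; it is the symmetric choice and cannot bias the paired test's
direction. The species comparison is a one-tailed Wilcoxon signed-rank
across genes (zero differences dropped; an all-zero comparison reports
P = 1). DEG-set enrichment is the upper hypergeometric tail with
Bonferroni across the sets tested; the brain up/down classification is a
two-sided equal-variance t-test per gene with threshold 0.05/n_genes and
class by the sign of the mean difference.

The hemispheric asymmetry level is AL = |L̄ − R̄|/√(2(L̄² + R̄²)) on
replicate-mean expression — exactly |sin θ| of the plan-I angle,
without the arcsine. Values are first put on a relative scale (each
sample divided by its total across genes) and entries below 10⁻⁷ of the
sample total are masked as missing; a side with no surviving replicate
makes the AL missing. Over nonnegative expression AL ≤ 1/√2; over
unconstrained real pairs its supremum is 1, attained at L = −R — both
bounds are verified numerically. Group tests are one-sided rank-sums of
focal vs other genes, overall or per region with Benjamini–Hochberg
across regions. Cross-donor averaging restricts to shared regions,
correlates stacked (gene, region) pairs present in both donors, and
averages per-gene means across donors, falling back to the present donor
when one side is missing (a strict-both mode is available).

## Numerical choices and problem sizes

All generators are pure functions of their configuration including the
seed (NumPy PCG64 with structured seed lists). The scan runs in float32
with pairwise-complete masks; monomorphic SNPs yield missing statistics;
P values are clipped away from 0 only at the float tiny boundary.
Calibration suites use independent-SNP panels (block size 1), because
median-λ and Kolmogorov–Smirnov uniformity checks assume independent
tests; LD-linked panels keep uniform marginals but violate the KS
sampling model. The test suite's simulation sizes — 4,000 subjects ×
10⁴ SNPs × 50 seeds for recovery, 100 seeds for enrichment and BSI
recovery at a few hundred genes — were chosen as the smallest designs
whose power bounds are sharp under the analysis above.

## Known limitations

- The scan is OLS; no mixed-model correction is applied, so related
  cohorts require pruning rather than modeling.
- The LD model is blockwise stationary copying; it does not reproduce
  recombination hotspots or long-range LD.
- bestNormalize-style transform selection is reduced to rank-INT with a
  tie-triggered z-scale fallback.
- Gene-age maps, DEG sets and ortholog tables are consumed as given;
  building them is out of scope.
- Developmental-stage labels in expression tensors are opaque; no
  cross-species stage harmonization is attempted.
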