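# Methods

## Model and procedure

`permgsa` tests the joint association of the SNPs in a gene-set with a
trait.  The set statistic is T = Σ −log₁₀(pᵢ) over the set's SNPs, with pᵢ
from an additive single-SNP regression (linear for quantitative traits,
logistic for case/control; Wald test on the genotype coefficient, optional
numeric covariates).  The null distribution of T is obtained by permuting
the phenotype vector and re-running the scan; the self-contained empirical
p-value is the tie-inclusive exceedance fraction count{T_perm ≥ T_obs}/N.
The tie-inclusive ≥ for the self-contained count and the strict < for the
competitive count are both deliberate: the self-contained estimator never
understates significance under ties, while the competitive count treats a
draw that merely equals the original as a non-win.  The asymmetry is part
of the estimator definitions, not an accident.

One batch of permuted phenotypes is shared by every set in a run, so a
genome-wide analysis costs one association scan per permutation regardless
of the number of sets.  The gene-based test is the same engine applied to
singleton sets.  Because only the phenotype is permuted, covariate rows
stay attached to their genotype rows; under the null this breaks any
phenotype–covariate association.  A residual-permutation scheme would
preserve it and is noted as future work.

Under the global null, −log₁₀(p) of one SNP is 1/(2 ln 10) times a χ² with
2 df (the constant is computed at full precision internally, 0.21715…, and
rounds to 0.217).  For M independent SNPs Var(T) = 4·(1/(2 ln 10))²·M =
0.18861…·M.  The effective SNP number of a set is

    M_eff = 0.189 · M_obs² / Var̂(T_perm),

with the sample variance over permutations (N−1 denominator).  M_eff equals
M_obs under independence and shrinks as LD inflates the null variance.
Below 30 permutations the estimate is flagged unstable (a warning, not an
error); a degenerate null with zero variance is an error.

The competitive test draws control sets matched to the original either on
the number of genes (uniform sampling without replacement from the gene
pool) or on M_eff (greedy accumulation of genes using per-gene effective
counts computed from singleton nulls of the same scan, relative tolerance
0.05; a draw retries up to 20 random orders before declaring the pool
exhausted, since a single greedy pass can strand itself when every
remaining gene overshoots the tolerance band).  Pools may be restricted to
intragenic SNPs, intergenic SNPs (accumulated singly, one effective SNP
each), or all SNPs.  Draws exclude the original set's genes by default to
prevent signal leakage into the competitive null; genes are sampled without
replacement within a draw and with replacement across draws so the pool is
not progressively depleted.

With summary statistics instead of raw genotypes, the null is built from a
reference genotype panel scanned against phenotypes simulated under the
null.  The simulated phenotypes are independent standard-normal draws: any
genotype-independent phenotype yields the correct null for the scan
statistic, and the normal choice keeps the linear model exact.  The
observed statistic sums the user-supplied p-values over exactly the SNPs
covered by the panel, so both sides of the comparison cover the same SNPs;
a set with under 50% coverage is excluded.

## Per-SNP association

Additive coding (0/1/2 copies of allele A1).  Samples with missing
phenotype or covariates are dropped globally; missing genotypes are dropped
per SNP, identically in the linear and logistic paths.  A SNP that is
constant among analyzed samples, has fewer complete samples than model
parameters + 1, or whose logistic fit fails to converge yields an undefined
p-value.  Undefined SNPs are excluded from set sums and from M_obs using
the observed-scan definition on both real and permuted sides — consistency
between the two is what keeps the empirical p-value valid.

The fitters are vectorized across SNPs and permutations: closed-form
weighted least squares with per-SNP missingness masks for the linear model,
and a batched Newton–Raphson IRLS (at most 100 iterations, step tolerance
1e−8, linear predictor clipped at ±30 for overflow safety, a 1e−10 ridge on
the Hessian solely to keep the batched solve alive on degenerate problems)
for the logistic model.  Agreement with reference GLM fits is verified in
the tests to 1e−6 relative on p-values.  Exact fits (zero residual
variance) report the smallest positive double rather than zero, keeping
log-transforms finite.

## Quality control

SNPs are removed when minor allele frequency < 0.01, Hardy–Weinberg
exact-test p < 1e−5, or missing rate > 5% (all thresholds adjustable).  The
HWE exact test enumerates the conditional distribution of heterozygote
counts given allele counts in log-space; for case/control data it is
computed in controls only, for quantitative traits in all samples.

## Synthetic data generator

Genotypes: blocks of SNPs share a latent equicorrelated Gaussian (pairwise
correlation `within_block_r`, default 0); the latent value is cut at the
Hardy–Weinberg boundaries for the SNP's minor-allele frequency, drawn
uniformly from `maf_range` (default 0.1–0.5).  Blocks are independent.
Missing calls are planted uniformly at `missing_rate` (default 0).  This
produces a tunable within/between-block r² contrast and realistic genotype
margins.  It does **not** emulate distance-dependent LD decay, MAF–LD
coupling, population structure, genotyping batch effects, or departures
from HWE — so passing calibration here shows correctness of the inferential
machinery under its stated assumptions, not robustness to stratified or
artefact-laden data (for stratification the intended mitigation is
principal-component covariates plus competitive testing).

Phenotypes: quantitative traits are y = Σ √v·zᵢ + √(1−Σv)·ε with zᵢ the
standardized causal genotypes, so v is the variance explained per causal
SNP.  Binary traits threshold the same unit-variance liability at the
prevalence quantile; a logistic alternative with a per-allele odds ratio
(intercept solved numerically to hit the prevalence) is selectable.

Annotation: genes claim consecutive runs of SNPs (sizes drawn from a range
and repaired to hit the exact genic total; infeasible combinations error),
with intergenic SNPs spread evenly between genes, so each gene interval
contains exactly its SNPs.  Gene-sets sample genes without replacement;
designated causal SNPs produce a SET_CAUSAL collecting their carrier genes.

## Evaluation protocol and problem sizes

Type-I error: replicate datasets with genotype panels regenerated and
null phenotypes drawn fresh; the rate is the mean fraction of sets with
p_self below the nominal level.  Power: planted causal sets, detection at
Benjamini–Hochberg FDR < 0.05 (BH chosen as the standard step-up
procedure), relative power summarized by an upper-tail hypergeometric test.

The shipped checks use desk-scale sizes chosen once: 500 samples × 400 SNPs
(100 genes of 4 SNPs, block r = 0.3), 200 sets of 10 genes, 500
permutations, 20 replicate datasets for type-I; 2000 samples, 5 causal SNPs
at 2% variance each, 49 null sets plus the causal set, 500 permutations, 20
replicates for power; 2000 permutations on 1000 samples × 100 LD-free SNPs
for the variance-law recovery.  These estimate the same quantities as
large-scale runs with wider Monte-Carlo bands.

## Numerical and interface choices

- Coordinates are 1-based with both interval ends inclusive, matching
  .bim positions; flanks (≤ 100 kb each side) are applied in genomic
  coordinates regardless of strand by default, with an optional
  strand-aware mode — whether flanking should follow strand is genuinely
  ambiguous, so the simple convention is the default and documented.
- The empirical p-value uses the raw count/N estimator, so p = 0 is
  possible (it means "below 1/N"); a smoothed (k+1)/(N+1) estimator is
  available behind a flag.
- A SNP belonging to several member genes of one set contributes once.
- PLINK 1 .bed I/O is SNP-major only; phenotype decoding follows the PLINK
  convention (1 = control, 2 = case, −9/0 = missing, anything else
  quantitative).  A companion writer exists for fixtures and round-trips.
- Gene-set files are one set per line: name followed by gene symbols
  (GMT-like, no description column).
- All randomness flows from a single user-visible seed per run; results
  are reproducible bit-for-bit from (inputs, parameters, seed).

## Limitations

Self-contained results on highly polygenic traits should be read with
care: the global null is rarely literally true, which is why competitive
testing (conditional on a significant self-contained result) is the
recommended interpretation route.  The competitive eff-SNPs matching uses
per-gene effective counts summed over genes, which ignores between-gene LD
within a draw.  Dosages, VCF/BGEN input, PLINK 2 formats, mixed-model
association, and adaptive permutation stopping are out of scope.
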