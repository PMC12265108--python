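# Methods

## The eGene identification problem

Let `Y` be the `n x p` fully processed expression matrix (individuals x
genes), `S_j` the `n x q_j` dosage matrix of the SNPs within 1 Mb of gene
j's transcription start site, and `X` the `n x K` covariate matrix. The
working model per gene is

    Y[, j] = 1 b0 + S_j b1 + X b2 + eps,

and gene j is a *cis-eGene* iff at least one entry of `b1` is nonzero. The
statistical difficulty is the nested multiplicity: thousands of genes,
each with up to tens of thousands of local SNPs in strong linkage
disequilibrium (LD).

All callers here follow the two-step recipe: (1) reduce each gene to a
single score or P value; (2) control the FDR across genes.

## The per-gene score and the partial-correlation/P-value correspondence

The gene score is `T = max_snp |r|`, the largest absolute partial
correlation between expression and a local SNP dosage after both are
residualized on `[1 | X]`. The t statistic of the SNP coefficient in the
full linear model `y ~ 1 + snp + X` is `t = r sqrt(df) / sqrt(1 - r^2)`
with `df = n - K - 2`, a strictly monotone map, so "max |r|" and "min
linear-model P value" are interchangeable and a whole cis window can be
scanned with one matrix product on standardized residuals. All P values in
the package flow through this single `df = n - K - 2` convention.

## The two permutation callers

Both compare `T_exp` (observed) with `T_bg[1..B]` computed on B copies of
the expression whose sample rows were permuted. One uniform permutation
per replicate is shared by all genes; this preserves each gene's marginal
null and is what lets a replicate be scored with the same aggregated
matrix products as the observed data. Genotype residuals are computed once
and held fixed.

* **standard variant** (`run_standard`, default `B = 1000`): the *raw*
  expression column is permuted and then residualized, per replicate. The
  gene-level P value is the proportions formula
  `(1 + #{b: T_bg[b] >= T_exp}) / (B + 1)`, followed by Storey q values
  (`lambda = 0.5`; BH and BY available) and calls at `q <= target`.
* **clipper variant** (`run_clipper`, `B = 1` or `20..100`, intended for
  n > 450): the expression is residualized once and the *residuals* are
  permuted. Per gene the contrast score is `C = T_exp - max_b T_bg`; under
  the null C is symmetric around zero, so the left tail estimates the
  false discoveries in the right tail (Clipper, Ge et al. 2021):

      FDRhat(t) = (1 + #{C_j <= -t}) / max(1, #{C_j >= t}),

  with cutoff the smallest candidate `t = |C_j|` satisfying
  `FDRhat(t) <= target`, ties discovered inclusively, and per-gene q value
  `min_{t <= C_j} FDRhat(t)` clamped to [0, 1]. The `max_b` aggregation
  for B > 1 reduces to the B = 1 rule and preserves the outlying-right-
  tail logic; note that for B > 1 the null contrasts are left-shifted
  rather than symmetric, so the estimator becomes conservative as B grows.

The permute-then-residualize (standard) versus residualize-then-permute
(clipper) orders are implemented as genuinely distinct code paths: the
former is the classic direct-permutation scheme, the latter is what makes
a single permutation reusable across the contrastive estimator.

Permutations are drawn from counter-derived substreams of one master seed
(`SeedSequence(seed, spawn_key=(b,))`), so replicate b is reproducible in
isolation and results are independent of scheduling.

Complexity is `O(B p q_bar n)` for both variants; with `B = 1` the clipper
variant does roughly one nominal pass worth of work.

## Comparator gene-level procedures

* **Beta approximation** (`run_beta`): fit Beta(a, b) by maximum
  likelihood (moment-matched start) to the B permutation minima of the
  nominal P value; the gene P value is the fitted CDF at the observed
  minimum. Falls back to proportions if the fit fails. Interpolates
  between the `1/(B+1)` grid points of the proportions formula.
* **Effective-test-count correction** (`run_eigenmt`): per gene, SNPs are
  split into consecutive non-overlapping windows of 200; in each window
  the effective test count is the smallest k whose top-k eigenvalues of
  the SNP correlation matrix reach 99% of total variance; the gene P value
  is `min(1, p_min x M_eff)` with `M_eff` the summed counts. BH across
  genes by default (the original tool's pairing). The 99% rule counts
  low-variance LD remnants, so `M_eff` systematically exceeds the
  effective test count implied by the permutation null — the source of its
  power deficit.
* **Simes** (`run_simes`): gene P value `min_k (m p_(k) / k)`;
  Benjamini-Yekutieli across genes by default (TreeQTL's default), Storey
  or BH by flag.
* **Naive all-pairs calling** (`run_naive`): BH across every gene-SNP pair
  at the target, a gene called iff any of its pairs is significant. Kept
  as a negative control: each true eGene contributes many LD-correlated
  significant pairs, inflating the BH threshold, and the false pairs it
  admits scatter across distinct null genes, so the *gene-level* FDR is
  not controlled.

## Covariate-count selection

Expression PCs serve as inferred covariates. Two selectors over the
variance-explained scree of the column-standardized matrix:

* **BE / parallel analysis** (`choose_k_be`, `n_perm = 20`,
  `alpha = 0.05`): permute each gene column independently; keep leading
  PCs whose observed variance explained exceeds the 95th permutation
  percentile at that index, stopping at the first failure (contiguity by
  construction).
* **Elbow** (`choose_k_elbow`): the index with maximal perpendicular
  distance from the chord joining the scree endpoints; invariant to
  rescaling; degenerate (straight-line) screes return 1.

BE recovers planted covariate counts well on bulk-shaped matrices; on
pseudobulk single-cell matrices it tends to overshoot, which is why the
elbow is offered as the alternative.

## Synthetic data generator

`simulate_dataset` emulates a bulk eQTL cohort under the model above.
Defaults: `n = 838`, `p = 1000` genes, `K = 20` standard-normal covariates
(all returned as known), 20% eGenes with one causal SNP each, genotype PVE
0.02 among eGenes, covariate PVE 0.5, 500 SNPs per gene with MAF uniform
on (0.05, 0.5).

Genotypes: dosages {0,1,2} from a latent Gaussian thresholded at
Hardy-Weinberg quantiles. LD is haplotype-block structured — AR(1) latent
correlation 0.99 within blocks of 10 consecutive SNPs, independence across
blocks, one MAF per block (SNPs riding the same haplotypes share allele
frequency). This reproduces two features of real cis windows that matter
for method comparison and that a weak-chain copula does not: (i) each
causal SNP has several near-redundant LD partners, so pair-level scans
yield many significant pairs per eGene (driving the naive caller's FDR
inflation), and (ii) the effective number of tests at the decision
threshold is several-fold smaller than the 99%-variance eigenvalue count
(driving the power gap between permutation calibration and
effective-test-count corrections).

Effect construction: the genotype component of an eGene is the causal
dosage combination projected orthogonal to `[1 | X]`, so the analysis-side
partial correlation recovers exactly the planted fraction; covariate and
noise components are scaled to their exact in-sample variance fractions.
Two effect-size conventions:

* `effect_scaling = "expected"` (default): causal coefficients are drawn
  from a Gaussian prior scaled so the realized per-gene genotype variance
  fraction averages PVEGenotype across eGenes (chi-square spread across
  genes). A cohort-level mean PVE of 0.02 then leaves a sizable share of
  eGenes near the detection boundary, which is what makes power
  differences between methods visible.
* `effect_scaling = "realized"`: each eGene is rescaled so its in-sample
  fraction equals PVEGenotype exactly (every eGene equally strong) —
  used for calibration-style checks and worst/best-case reasoning.

Realized per-gene fractions are recorded in `SimTruth.realized_pves`.
`evaluate_calls` reports the false-discovery proportion
(`FD / max(1, discoveries)`) and power (`TD / #eGenes`).

What the generator does **not** emulate: real haplotype mosaics and
recombination-rate variation, population structure and relatedness, rare
variants (MAF < 0.05), non-Gaussian expression noise, trans effects, and
covariates correlated with genotype. Passing tests therefore support the
calibration and ordering claims under a stylized but LD-realistic null,
not performance on any particular real cohort.

## Numerical choices and degenerate inputs

* Residualization via least squares on `[1 | X]`; rank-deficient designs
  are rejected naming the collinear columns.
* Correlations on population-scaled (1/n) standardized residuals (the
  scaling cancels in r); zero-variance residual SNP columns are dropped
  per gene; genes with no usable SNPs or zero residual expression variance
  are excluded from testing and from the multiple-testing denominator,
  with a warning.
* `|r| = 1` maps to P = 0; `df < 1` is an error.
* Proportions P values use the add-one rule, so P >= 1/(B+1) > 0 and the
  beta fit never sees exact zeros.
* Storey's pi0 at a single `lambda = 0.5`; pi0 = 0 clamps to 1/m with a
  warning.
* Cis windows are closed intervals `|pos - TSS| <= 1 Mb`, no strand
  adjustment. Expression BED column 2 is 0-based, TSS = start + 1.
* The SNP minor-allele filters combine with AND: folded MAF >= 0.01 and
  >= 10 individuals carrying >= 0.5 dosage of the minor allele.
  Multiallelic VCF records are skipped with a warning; sporadic missing
  genotypes are mean-imputed with a warning.
* Samples are matched across matrices by id intersection, preserving
  expression-matrix order.

## Problem sizes used in the test suite and acceptance script

Simulation-study checks run at n = 838, 300 genes, 200 SNPs per gene, 20%
eGenes, over 10 seeds — the cohort dimensions above with the gene count
reduced, chosen so a full multi-method replication completes comfortably
on one CPU while leaving ~60 true eGenes per cohort for stable FDP/power
estimates. FDR calibration is checked at B = 200 (clipper at B = 1);
power and concordance are checked at the standard variant's default
B = 1000. The distinction matters because at 300 genes the `1/(B+1)`
resolution of the proportions P value interacts with the Storey step-up:
a cohort needs roughly 25 floor-level genes for any discovery, so the
standard variant's per-cohort power is occasionally all-or-nothing at
B = 200 (an artifact of the reduced permutation count that B = 1000
removes; FDR control holds either way). Since permutation replicates are
counter-derived substreams, the B = 200 scores are exactly the first 200
columns of the B = 1000 run and both settings are scored from one pass.

## Known limitations

* The B > 1 contrastive aggregation (`max_b`) is conservative rather than
  exactly symmetric under the null; B = 1 is the analyzed case.
* The clipper estimator needs at least `1/target` discoverable genes to
  call anything (add-one numerator), so very small gene panels yield zero
  discoveries by construction.
* eigenMT-style windows are non-overlapping; the original tool's exact
  windowing may differ in boundary handling.
* No LMM/GLMM support: related individuals or repeated cells violate the
  exchangeability the permutation schemes rely on.
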