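# Methods

This note documents the statistical machinery implemented in `snpset`, the
choices made where the design was open, and what the synthetic experiments
do and do not demonstrate.

## Data model and preparation

Genotypes are additive minor-allele dosages (0/1/2) with `NaN` for missing
calls.  The minor allele is always determined from the sample allele
frequencies, not from VCF REF/ALT orientation; columns whose ALT frequency
exceeds 0.5 are recoded as `2 − dosage`.  Missing entries are excluded
from frequency estimation and mean-imputed (per variant) wherever dosages
enter a model — this preserves additive semantics and requires no
imputation machinery.

Minor-allele frequencies are folded (`maf = min(f, 1−f) ≤ 0.5`); a variant
is *rare* iff maf < 0.01 (strict) and *common* otherwise.  Preparation
applies two filters: variants carried by ≤ 1 individual are removed
(monomorphic variants included — they carry no information and break
standardization), and genes whose rare variants are collectively carried
by < 1% of individuals are removed (genes without rare variants are kept;
the rule is vacuous for them and their common variants remain testable).

Population-structure scores are the top-k left singular scores of the
mean-centered dosage matrix restricted to variants with maf > 0.10,
optionally thinned to a minimum base-pair spacing by a greedy
left-to-right scan per chromosome.  Each component's sign is fixed by
requiring a non-negative loading sum, making outputs reproducible.  The
PCA uses centered minor-allele counts (not variance-normalized), computed
directly by SVD so the sign convention and rank-deficient cases are under
explicit control.

## Collapsing scores

Madsen–Browning weights are estimated from the unaffected group with the
original +1/+2 pseudocount, `q_k = (m_k^U + 1)/(2 n^U + 2)`,
`w_k = sqrt(n q_k (1−q_k))`, so control-absent variants still get finite
weight.  Per-sample class scores are `Σ_k I_ik / w_k` over the gene's rare
variants of a functional class, and `WS_combined = WS_syn + 2·WS_nonsyn`
up-weights nonsynonymous variation.

The common-variant summary score is `Σ_k c_k I_ik` with
`c_k = m_k^A/(2 n^A) − m_k^U/(2 n^U)`: the case/control allele-frequency
contrast, which is the fitted-component direction for a binary response
when no covariance rescaling is applied.  The coefficient function is a
pluggable argument so a variance-rescaled variant can be substituted.
Because the downstream models standardize their inputs, the score's
overall scale is irrelevant.

Both weight estimation and coefficient estimation accept an explicit
source dataset: in the two-stage pipeline they are estimated on the
screening replicate and applied to the testing replicate, avoiding reuse
of the testing phenotypes.

## Logistic score test

For `logit P(y=1) = X'β + Z'a + (s·Z)'b` the package tests H₀: a = b = 0
with the efficient score: U is the score of the tested block at the null
MLE (fit by IRLS on X alone), and the efficient information is the tested
block of the information matrix minus the cross-information projected
through the nuisance block (Schur complement).  Constant columns and
columns collinear with the covariates (or with each other) are pruned by a
pivoted-QR rank screen on covariate-residualized columns, with the degrees
of freedom reduced accordingly.  The statistic is referred to chi-square
with df equal to the retained column count.  A finite-difference oracle
(numerical score and information of the raw log-likelihood) pins this
construction to the likelihood itself in the tests.

The null fit is a small hand-written IRLS (relative log-likelihood
tolerance 1e-10, at most 100 iterations) with explicit separation
detection (|coef| > 30 aborts with advice to use a penalized fit).  It is
cross-checked against statsmodels GLM in the unit tests; keeping it local
makes the hot simulation loops cheap and the convergence/separation
policy explicit.

## Kernel machine variance-component test

The semiparametric model puts the genetic main effect and the G×E effect
in RKHSs with kernels K and K̃; testing their absence is testing that two
variance components are zero.  The score statistics are the quadratic
forms `q = (y−μ̂)' K (y−μ̂)/2` at the null fit.  Kernels are linear
(`z'z̃`) or quadratic (`(1+z'z̃)²`, which carries pairwise interaction
features); inputs are column-standardized, and the G×E kernel consumes
rows of standardized Z multiplied by the binary exposure — in the linear
case this reproduces the parametric `s·Z` interaction design.

Null moments use the efficient projected covariance
`P0 = D − D X (X'DX)⁻¹ X'D`, `D = diag(μ̂(1−μ̂))`:

* mean: `tr(P0 K)/2` (verified against a parametric bootstrap);
* variance: the Gaussian-type trace `tr(P0 K P0 K)/2` **plus** the
  Bernoulli fourth-cumulant correction
  `Σᵢ K̃ᵢᵢ² (wᵢ − 6wᵢ²)/4` with `K̃ = (I−H)'K(I−H)` the
  covariate-projected kernel.  For diagonal-heavy kernels (notably the
  quadratic kernel) the Gaussian term overstates the binary-response null
  variance several-fold and the resulting test is severely conservative;
  with the correction the measured type-I error of both kernel schemes
  sits near nominal (see the acceptance tests).  All moment computations
  use the low rank of the covariate projection and cost O(q n²).

Each component is matched to κχ²_ν (`κ = var/2mean`, `ν = 2mean²/var`); a
component with null variance below 1e-12 is degenerate and contributes
nothing.  The combined statistic is `Q = q_τ/κ₁ + q_τ̃/κ₂`.  Because Q is
itself a quadratic form (kernel `K/κ₁ + K̃/κ₂`), its null mean and
variance come from the same machinery, and by default Q is referred to a
scaled chi-square matched **jointly** to those moments — this accounts for
the correlation between the two components, which the simpler
"chi-square with ν₁+ν₂ df" rule (also available, `rule="sum_df"`)
ignores.  Only the score test at zero variance components is provided; no
variance-component estimation, and no Davies/saddlepoint mixture p-values.

## Screening and testing stages

Screening runs per gene on the screening replicate, all p-values by
permutation of disease status (affected/unaffected totals preserved;
add-one convention `p = (1+#{stat_b ≥ stat_obs})/(B+1)`, ties counted as
extreme):

1. Hotelling T² on the common-variant dosage vectors, affected vs
   unaffected, separately within each subpopulation (labels from the
   sample table, else k-means with k = 3 on the two PCs);
2. a 2-D Hotelling T² on (WS_syn, WS_nonsyn) over the whole population;
3. Fisher-z contrasts of Corr(G, E | status) for the common summary score
   and for WS_nonsyn, with the classical variance 1/(n_A−3) + 1/(n_U−3).

A gene passes when any *available* test has p below the threshold
(default 0.1); tests whose preconditions fail (no common variants,
constant scores, groups below 4) are recorded as unavailable, never as
p = 1.  Hotelling permutation p-values are computed for all B draws at
once through the exact identity `T² = (N−2)R²/(1−R²)` (R² from regressing
the group indicator on a full-rank basis of the centered data; the total
scatter is permutation-invariant), and the Fisher-z statistics through
group-sum algebra — both fast paths are pinned to the direct
implementations in the unit tests.  Within one screening replicate the
permuted label matrices are shared across genes (common random numbers);
per-gene p-values are unaffected, and the induced across-gene dependence
only touches Monte-Carlo noise in the pass decisions.

The testing stage runs on the paired replicate with covariates
(intercept, age, sex, two PCs, exposure) and five methods: logistic score
test with raw common genotypes or with the common summary score (each
plus WS_combined, analytic chi-square p-values), and three kernel-machine
methods (linear kernel with WS_combined or WS_nonsyn, quadratic kernel
with WS_combined; standardized inputs).  Weights and summary-score
coefficients come from the screening replicate.  Per method, p-values are
Holm-adjusted across the genes that passed screening and a gene is
selected when adjusted p < 0.1; selections are tallied across pairs.  The
no-screening mode passes every gene to testing for comparison.

## Synthetic cohorts

The generator emulates a mini-exome case-control study of unrelated
individuals.  Defaults (chosen once; configurable):

| parameter | default | note |
|---|---|---|
| n_samples | 697 | with fixed totals option (209 affected, 488 unaffected) |
| subpopulations | EUR/ASN/AFR, (0.40, 0.35, 0.25) | Balding–Nichols Fst = 0.05 at common variants |
| rare fraction | 0.74 | realized per dataset; rare MAF log-uniform on [1/(2n), 0.01), common uniform on [0.01, 0.5] |
| variants per gene | 2 + Poisson(mean − 2), mean 7.6 | matches the emulated study's ~24.5k variants over ~3.2k genes |
| nonsynonymous fraction | 0.65 | |
| exposure prevalence | 0.30 | binary smoking indicator |
| disease prevalence | 0.30 | intercept solved by root finding per cohort |
| covariate effects | age 0.01/yr (centered), sex 0.2, smoke 0.4 | log-odds |

Because frequencies drawn near the 1% boundary would otherwise leak
across it, a variant's frequency is redrawn (up to 20 times) until its
realized class matches its designed class, so the configured rare
fraction describes the data, not merely the sampling probability.  Causal
genes contribute marginal common-variant effects, a standardized
rare-burden effect, an exposure × burden interaction, and an optional
product interaction of the gene's first two common variants.  Fixed
case/control totals are enforced by redrawing the status vector (cheap:
the totals are hit every ~30 draws at n ≈ 700).  Replicate pairs share
one fixed genotype panel — as in the emulated study design — with
phenotypes and exposure re-simulated per replicate from seeds derived
deterministically from the master seed.

What the generator does **not** emulate: linkage disequilibrium within or
between genes, related individuals, locus heterogeneity tied to a real
disease architecture, genotyping error, or covariate-confounded exposure.
Calibration and recovery results on these cohorts therefore demonstrate
the statistics' internal correctness and relative behavior, not field
performance on real exomes.

## Experiment sizes

The bundled experiments use sizes that keep the full suite in the
minutes range on one CPU: calibration at n = 400 with 2000 null
replicates per kernel scheme; power curves with 500 replicates per effect
size; the moment identity with 5000 bootstrap draws at n = 300; the
two-stage recovery experiment with 51 genes, 20 replicate pairs and the
default 1000 screening permutations.  The interaction-sensitivity experiment uses a
compact SNP set of six common variants: the quadratic kernel's
pairwise-product features carry the epistatic signal, and a long tail of
rare variants would dilute it into the kernel diagonal, leaving both
tests near the null at any realistic sample size.

## Known limitations

* Analytic chi-square p-values (score test, moment-matched kernel test)
  are asymptotic; in the far tail (deep Holm cutoffs) they can drift from
  permutation truth, especially for genes with very few rare-allele
  carriers.  The screening stage is permutation-exact, the testing stage
  analytic, mirroring the two-stage design.
* The Fisher-z contrast assumes approximate bivariate normality within
  status groups; with a binary exposure it is a pragmatic screen, not an
  exact test (the pipeline uses its permutation version).
* Hotelling T² uses a pseudoinverse under rank deficiency and then
  reports permutation p-values only.
* Multi-allelic VCF records must be split upstream; no phasing, no
  kinship handling.
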