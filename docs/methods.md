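# Methods

This note records the generative model, the statistical procedures, the
numerical choices, and the limits of what the test suite demonstrates.

## Data-generating model

One bi-allelic QTL with minor allele frequency *q* ∈ (0, 0.5]; genotypes are
sums of two independent Bernoulli(*q*) alleles, hence in Hardy–Weinberg
equilibrium with frequencies (*p*², 2*pq*, *q*²), *p* = 1 − *q*. The minor
allele is the effect allele and genotypes count minor alleles.

Each of *k* traits (default *k* = 3) is built additively:

* per-allele effect `a_j = sign_j · sqrt(h²_j / (2pq))` — the unique value
  for which the QTL term `a_j G` has variance `a_j² · 2pq = h²_j`, so with
  residual variance 1 − *h²_j* the trait has unit variance and the QTL
  explains exactly *h²_j*. Effects are larger for rarer alleles at fixed
  *h²*, matching the empirical rarity–effect-size relationship.
* residuals drawn from MVN(0, Σ_e) with `Σ_e[j,j] = 1 − h²_j` and
  `Σ_e[j,l] = rE · sqrt((1−h²_j)(1−h²_l))`. *rE* is implemented as a
  *correlation* so that it is invariant to *h²*; positive definiteness
  (equicorrelation requires rE > −1/(k−1)) is checked at construction.
* traits are centered and scaled per replicate using the sample mean and
  sample SD (ddof = 1), i.e. the simulated traits themselves are
  standardized, not the population quantities.

The QTL-induced cross-trait covariance before scaling is `a_j a_l · 2pq`,
so the sign of the genetic correlation *rG* equals `sign_j · sign_l`. The
total pairwise trait correlation at large *n* is
`rE·sqrt((1−h²_j)(1−h²_l)) + sign_j sign_l · sqrt(h²_j h²_l)`; the test
suite verifies this, the HWE proportions, and the recovery of *h²* by
regression at n = 10⁶.

Monomorphic genotype draws (realistically possible only at tiny *nq*) are
**not** silently re-drawn: downstream methods raise `MonomorphicInputError`
and the evaluation harness counts these errors, because silent re-draws
would bias permutation null distributions. At the study's smallest *nq*
(N = 1000, q = 0.01) the monomorphic probability is ~2·10⁻⁹.

Reproducibility: a scenario's master seed spawns one child seed per
replicate (`numpy.random.SeedSequence`), so replicates are independent,
individually reproducible, and safe to parallelize; each dataset's
permutation stream is spawned from the same child.

### Scenario grids

The default grid is 30 scenarios: sign patterns (1,0,0), (±1,1,0),
(±1,1,1) × rE ∈ {0, 0.3, 0.7} × MAF ∈ {0.01, 0.4}, h² = 0.1% per associated
trait, N = 1000, 1000 replicates, 10 permutations per replicate.
Supplementary grids: MAF ∈ {0.05, 0.10, 0.25} (same sign patterns) and an
unequal-heritability grid h² = (0.1%, 0.2%, 0.05%) for the three-trait
patterns.

## Association procedures

**CCA (`cca`).** With a single genotype variable the first canonical
correlation between G and the traits satisfies r² = R² of the OLS
regression of G on the traits, and Rao's F for Wilks' Λ is exact:
`F = ((n−1−k)/k) · r²/(1−r²)` on (k, n−1−k) df. This is numerically
identical to a MANOVA of the traits on genotype (asserted against
statsmodels' MANOVA in the tests) and is invariant under invertible affine
recombinations of the traits. Detail: canonical trait loadings.

**Conjugate multivariate-regression Bayes factor (`bayes`).** Model
Y = 1μ′ + Gβ′ + E with rows of E iid N(0, Σ); prior β|Σ ~ N(m₀, v_b Σ) with
v_b = 0.02; Σ ~ inverse-Wishart with density
|Σ|^−(ν+k+1)/2 exp(−tr(SΣ⁻¹)/2), S = 6·I, ν = 4 by default. The intercept
carries a flat prior, handled by centering (effective sample size m = n−1).
Integrating β and Σ gives matrix-variate-t marginals; the ratio collapses
to

    BF = (1 + v_b s_g)^(−k/2) · ( |S + R₀| / |S + R₁| )^((ν+m)/2)

with s_g = Σ gc², R₀ = Yc′Yc, R₁ = R₀ − (Yc′gc)(Yc′gc)′/(1/v_b + s_g).
The k = 1 case is verified against direct numerical integration of the
(β, σ²) posterior. The inverse-Wishart convention (scale-matrix form and
df) is not uniquely pinned down by the two published scalars, so both are
exposed as explicit `BayesPriors` parameters; the chosen defaults reproduce
the published null-threshold band for the log₁₀ BF (all 30 scenario
thresholds fall within [−0.05, 0.44]). Dosage (non-integer) genotypes are
accepted as-is.

**Reverse ordinal regression (`ordinal`).** Proportional-odds (cumulative
logit) regression of the genotype category (0 < 1 < 2) on all traits
jointly; the statistic is the LRT against the intercepts-only model on one
df per non-constant trait. The fitter is a native Newton maximization with
analytic gradient and Hessian, started at β = 0 with empirical
cumulative-logit cutpoints (the starting log-likelihood is then exactly the
null maximum), with step halving when the likelihood fails to improve or
the cutpoint ordering breaks. It matches statsmodels' `OrderedModel` to
~10⁻⁶ in p. When the rarest genotype category has fewer than 5
observations it is merged into its neighbor, reducing to binary logistic
regression in the two-category case — the regime where polr-style fitters
are known to fail at MAF ≤ 5%. Exhausting the iteration budget raises
`ConvergenceError` with diagnostics; the harness counts such replicates
instead of aborting.

**Partition-averaged Bayes factor (`bimbam`).** All 3^k − 2^k assignments
of traits to {unaffected U, directly affected D, indirectly affected I}
with at least one D are enumerated (guarded at k ≤ 10). A partition's BF
against the global null factorizes into per-trait terms: each D trait is
regressed on genotype with the U traits (plus intercept) as covariates,
using the conjugate normal–inverse-gamma BF with effect prior
N(0, σ_a²σ²), flat priors on covariate coefficients, Jeffreys prior on σ²,
averaged with equal weight over the σ_a grid {0.1, 0.2} (the standardized
trait scale makes σ_a unitless). I-trait factors (I regressed on D and U,
genotype excluded) are identical under null and alternative and cancel.
The overall BF is the uniform-weight average over partitions; the detail
carries each trait's marginal posterior probability of U/D/I given
association. The univariate conjugate BF is verified against
triple-quadrature integration.

**Principal component of heritability (`pch`).** Repeated training/test
splits (default 150 training individuals, 200 splits for the observed
statistic); within each training subset, 50 bootstrap bags each estimate
the trait combination maximizing the heritable variance fraction — weights
∝ Σ̂_e⁻¹â, where â are per-trait genotype slopes and Σ̂_e the residual
covariance — normalized to unit length and sign-aligned before averaging
across bags. Held-out individuals are scored with the averaged weights and
the score regressed on genotype; split-level t statistics are averaged.
The null distribution comes from genotype permutations (default 1000, at
50 splits each); the final p refers the observed statistic to a t
distribution whose scale and degrees of freedom are moment-matched (df
from the excess kurtosis of the permutation null, clamped to [5, 10⁶]).
Under-specified details of the original procedure (subset sampling without
replacement, mean aggregation across splits, moment-matched df) are
explicit `PCHSettings`; defaults follow the published protocol
(50/200/50/150/1000). Splits whose training or test genotypes are constant
are skipped and counted.

**Univariate family (`uv`, `uvpca`, `meta`, `fisher`, `tates`).**
Per-trait OLS slope t-tests (two-sided, n−2 df). The family-wise UV
statistic is the per-replicate minimum p, whose permutation null defines
the adjusted threshold (≈ 1 − 0.95^(1/3) ≈ 1.7% for three independent
traits, less stringent under correlation). UV-PCA applies the same test to
the first principal component (covariance-based; the traits are already
standardized). The meta-analysis uses signed inverse-normal Z scores
weighted by sqrt(n) (`Z = Σ√n_j Z_j / sqrt(Σ n_j)`), so opposite effect
directions cancel; Fisher's method uses −2Σln p on 2k df and is direction
blind. p-values at the boundary are clamped at 10⁻³⁰⁰ with a warning —
far outside any regime the study explores.

**TATES (`tates`).** Extended Simes: sort p₍₁₎ ≤ … ≤ p₍ₖ₎, map the
*sample* trait correlation matrix of the analyzed dataset to a p-value
correlation matrix, and return `min_j m_e·p₍ⱼ₎/m_e(j)` where m_e(j) is the
Li–Ji effective number of tests among the top-j traits
(`Σ 1(λ≥1) + (λ−⌊λ⌋)` over eigenvalues of the absolute p-value correlation
submatrix; the floor uses a 10⁻⁹ tolerance so integer eigenvalues of
perfectly correlated blocks land on the correct side of the
discontinuity). The trait-to-p-value correlation map is computed by
deterministic 2-D Gauss–Hermite quadrature of E[p₁p₂] for a bivariate
normal Z pair (48 nodes, tabulated on a 201-point grid and interpolated):
self-contained, noise-free, and verified against Monte Carlo to <0.01.
A "polynomial" mode accepts user-supplied mapping coefficients for
compatibility with the original implementation; an `use_abs` switch
controls whether the absolute correlation matrix enters the
eigen-decomposition (default: absolute).

## Threshold and power protocol

Per scenario: 1,000 replicate datasets; 10 trait-row permutations each
(trait-trait correlations preserved exactly, genotype fixed), giving
M = 10,000 permuted null replicates. The empirical threshold is the mean of
the ⌊αM⌋-th and (⌊αM⌋+1)-th order statistics in the significance direction
(ascending p, descending log₁₀ BF) — at M = 10,000, α = 5% the mean of the
500th and 501st — leaving exactly 500 replicates significant absent ties
(ties trigger a warning with the achieved rate). Significance is strict
(`p < threshold`, `BF > threshold`). Power is the percentage of the 1,000
observed replicates on the significant side, with a Wilson 95% binomial CI
(the CI method is a package choice; only the CI width range was reported
upstream). The generalized order-statistic indices keep reduced-M runs
well defined. PCH keeps its internal permutation p-value, which is then
compared against the harness-derived empirical threshold like any other
p-value.

The vectorized engines in `_batch` (used by the harness for the seven
closed-form methods) permute the genotype vector rather than the trait
rows — an identical pairing change, since every measure depends only on
the genotype–trait pairing and the unpermuted trait structure — and are
asserted to agree with the scalar API to 10⁻⁸. Ordinal, partition-BF and
PCH run per replicate.

## Problem sizes used by the tests and the acceptance script

All threshold and power checks run the full protocol (N = 1000, 1,000
replicates × 10 permutations = 10,000 null replicates per scenario; 30
scenarios for the BF threshold range). Reduced sizes appear only where the
quantity does not require the full protocol: the negative-rG meta-analysis
comparison uses 600 replicates, and PCH calibration uses reduced
`PCHSettings`, consistent with its qualitative assessment — the bagged
subset procedure is orders of magnitude more expensive than the
closed-form methods and its published description leaves aggregation
details open, so only the direction of its behavior (threshold mildly
above 5%, calibrated null) is asserted, not a band.

## What the simulations do and do not show

The generator reproduces the study conditions exactly: a single additive
bi-allelic QTL, multivariate-normal equicorrelated residuals, standardized
traits, no linkage disequilibrium, no covariates, no missing data, no
outliers, no family structure, and at most three traits. Passing tests
demonstrate correctness of the statistics and reproduction of the
published threshold/power structure *under this model*; they say nothing
about robustness to non-normal traits, ascertainment, genotype-calling
error, or relatedness — all documented failure modes of some of these
methods on real data. Binary traits, multi-SNP scans, and mixed-model
corrections are out of scope.

## Numerical choices

* R² values are clipped to [0, 1−10⁻¹⁵] before F transforms; log-BF uses
  `slogdet`; p clamping epsilon 10⁻³⁰⁰.
* Rank-deficient trait matrices raise `RankDeficientError` (smallest
  eigenvalue ≤ 10⁻¹⁰ of the largest); constant traits are dropped (with a
  warning and df reduction) only in the ordinal model, where they carry no
  information.
* The Newton fitter declares convergence at max-gradient < 10⁻⁸ (or a
  < 10⁻¹² likelihood improvement with gradient < 10⁻⁴) within 60
  iterations.
* Threshold ordering uses stable sorts; the BF threshold shifts
  equivariantly with constant shifts of the measures (tested).
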