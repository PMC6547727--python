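# Methods

## The model

polymix treats the per-allele additive effects of a variant on two traits,
(β₁ⱼ, β₂ⱼ), as draws from a four-component Gaussian mixture:

    (β₁ⱼ, β₂ⱼ) ~ π₀·δ₀ + π₁·N(0, Σ₁) + π₂·N(0, Σ₂) + π₁₂·N(0, Σ₁₂)

with Σ₁ = diag(σ₁², 0), Σ₂ = diag(0, σ₂²), and Σ₁₂ carrying both variances
and the effect-size correlation ρ₁₂.  π₁ and π₂ weight variants causal for
one trait only, π₁₂ variants causal for both, and π₀ = 1 − π₁ − π₂ − π₁₂ the
null.  The same parameters apply to every variant; effect variance is
independent of allele frequency (the per-allele convention — the synthetic
generator can violate this deliberately, see below).

GWAS z-scores relate to the causal effects through LD:

    z·ⱼ = δ·ⱼ + residual,   δ·ⱼ = √N·ⱼ Σᵢ √Hᵢ rᵢⱼ β·ᵢ

where rᵢⱼ is the allelic correlation between variants i and j, Hᵢ = 2pᵢ(1−pᵢ)
the heterozygosity, N the GWAS sample size, and the residual pair is
N(0, [[σ₀₁², ρ₀σ₀₁σ₀₂], [·, σ₀₂²]]) — the "variance distortion", absorbing
uncontrolled stratification and sample overlap (the analogue of the
LD-score-regression intercepts).

Derived quantities:

* SNP heritability (observed scale): h² = π₁ᵘ · H_total · σ_β², with
  H_total = Σⱼ 2pⱼ(1−pⱼ) over the reference.
* genome-wide genetic correlation: r_g = ρ₁₂ π₁₂ / √(π₁ᵘ π₂ᵘ), where
  π₁ᵘ = π₁ + π₁₂ and π₂ᵘ = π₂ + π₁₂.  For traits with a K-fold polygenicity
  difference this bounds r_g ≤ ρ₁₂/√K, with equality when the sparser
  trait's causal set is nested in the denser one's.
* Venn counts: π_c · M_ref, rescaled so the reported variants jointly explain
  a set fraction (default 90%) of each component's heritability — under a
  Gaussian effect prior a large share of "causal" variants carry negligible
  effects, and the rescaling avoids counting them.

## Likelihood evaluators

Three interchangeable evaluators compute the per-SNP density of z given the
parameters and the SNP's LD context (ℓⱼ = Σᵢ Hᵢ rᵢⱼ², m4ⱼ = Σᵢ Hᵢ² rᵢⱼ⁴,
stored neighbours with rᵢⱼ² ≥ 0.05 within the window, self term included):

1. **fast** — method of moments.  Each causal arm c is approximated by a
   two-point mixture with adjusted weight π′_c = ℓπ_c/η_c and variance
   η_c Σ_c, η_c = π_c ℓ + (1−π_c)·m4/ℓ.  This matches second and fourth
   moments exactly (the r⁴ term is what carries the kurtosis).  Convolving
   the three arms gives an 8-component bivariate Gaussian mixture.  Cheap and
   differentiable in distribution shape, but a genuine approximation: on
   desk-scale panels (≈30 stored neighbours per SNP, π·m ≈ 0.1) its ML
   estimate of π is biased upward by ~60%.
2. **full** — Monte Carlo.  K replicates draw a causal configuration over the
   SNP's stored neighbours from (π₀, π₁, π₂, π₁₂) and average the implied
   Gaussians.  Exact as K → ∞, but the K needed to de-bias the fit is far
   beyond a single-workstation budget.
3. **conv** — deterministic sparse-regime evaluation of the same marginal as
   (2): the empty and single-causal-neighbour configurations are enumerated
   exactly (their probability mass is 1 − O((mπ)²)), and all multi-neighbour
   configurations are pooled into one Gaussian with the exact mass and
   conditional mean covariance.  Error is O((mπ)³) in mass; against the
   Monte-Carlo evaluator at K = 2·10⁵ it agrees to <2% pointwise.  This is
   the default for the final fit stages; π recovery on desk panels is
   unbiased (mean/truth 0.98 at π = 3·10⁻³).

The conv evaluator is valid when mπ is small (sparse architectures and/or
thin LD windows).  At biobank-reference scale (thousands of neighbours,
mπ ≫ 1) the fast or full evaluators are the appropriate choices; the
cross-checks in the test suite compare all three on toy contexts.

Right-censoring: with `censor_z` set (conventionally 5.45, the two-sided
z for α = 5·10⁻⁸), SNPs with |z| above the threshold contribute the model
tail mass P(|Z| > z_t) instead of the density.  For finite Gaussian mixtures
this tail is computed analytically (scipy normal survival functions;
bivariate rectangles via the multivariate normal CDF), not by numerical
integration.

## Fit procedure

SNPs are weighted by random pruning (default 64 iterations at r² < 0.1): each
iteration retains a maximal subset with all pairwise r² below threshold,
visiting SNPs in an independently shuffled order; wⱼ is the retention
frequency.  Σwⱼ is by construction the mean retained-subset size and serves
as the effective SNP count n in BIC = k ln n − 2F; AIC = 2k − 2F (k = 2 for
the infinitesimal model, k = 3 for the univariate mixture).

Univariate, three Nelder–Mead stages in transformed coordinates
(a, b) = (log πσ², log π/σ²) — nearly independent axes of the surface:

1. π = 1 (infinitesimal) fit of σ²_inf = πσ² and σ₀².
2. split the product under the constraint πσ² = σ²_inf by searching b.
   The constraint is anchored at *both* the stage-1 ML product and a
   moment-based product (weighted mean z² against N·ℓ with σ₀² ≈ 1), with a
   coarse scan of b from π = 10⁻⁵…0.5 at each anchor; the better optimum
   wins.  The double anchor matters: on sparse architectures the
   infinitesimal family cannot represent the kurtosis and its ML product can
   collapse to zero against an inflated intercept.
3. unconstrained joint fit of (a, b, log σ₀²) under the `model` evaluator
   (default conv).

Bivariate, univariate parameters frozen:

* ρ₀ is pinned before optimization from the low-|z| SNPs (both
  |z| < 1.64·σ₀): these are null-dominated, so their weighted correlation is
  an attenuated image of ρ₀ under square truncation of a bivariate normal;
  the attenuation map is computed by Gauss–Legendre quadrature and inverted.
  Rationale: when the genetic signal dominates (mean χ² ≫ 1), the joint
  likelihood in (r_g, ρ₀) is a near-flat ridge (only a weighted sum of the
  two is identified) and joint ML returns arbitrary ρ₀.
* Stage A: infinitesimal (π₁₂ = 1) fast-model fit of r_g alone.
* Stage B: fit π₁₂ (logit of the fraction of min(π₁ᵘ, π₂ᵘ)), with ρ₁₂ derived
  from the stage-A r_g as ρ₁₂ = r_g √(π₁ᵘπ₂ᵘ)/π₁₂, clipped to [−1, 1] with
  the clipping flagged; a coarse grid over the overlap fraction seeds the
  simplex.
* Stage C (default on): release (π₁₂, ρ₁₂) jointly and keep the polish only
  if it improves the objective.

Nelder–Mead settings: max 500 iterations per stage, function tolerance 10⁻⁴
(log-likelihood units), parameter tolerance 10⁻⁴ in transformed coordinates.
π is floored at 10⁻⁷ and capped at 1 by quadratic penalties in transformed
space; correlations are clipped to |ρ| ≤ 1 − 10⁻⁶ to keep component
covariances nonsingular.

## Standard errors

Observed Fisher information of the fast-model weighted log-likelihood, in
transformed coordinates — logit for the π's, log for the σ²'s, and the erf
scale (ρ = erf(u)) for correlations, so normal draws can never leave the
valid domain.  The Hessian uses central differences (step 10⁻³, one
Richardson extrapolation); a non-positive-definite Hessian triggers a
marginal-only fallback (flagged).  Errors of derived quantities (h², r_g,
Venn counts) are propagated by sampling 1000 parameter vectors from the
transformed-space normal and reporting the standard deviation of the
function values; failed draws (e.g. weight sums exceeding 1) are discarded
and counted, with >10% failures an error.

Agreement with a 50-block delete-one jackknife holds within a factor 1.5 in
the asymptotic regime (tested at π = 0.01, i.e. ~50 causal SNPs on the 5K
test panel).  With only a dozen causal variants the jackknife distribution
over blocks is intrinsically heavy-tailed and the two estimators answer
slightly different questions; the test condition is chosen to probe the
methodology, not that corner.

## Q–Q curves and power

Data Q–Q curves are weighted empirical quantiles of p = 2(1 − Φ(|z|)), with
pruning weights; the 95% band is the binomial half-width
1.96·√(q(1−q)/Σw) on the quantile scale, mapped through the observed
quantile function.  The quantile is a right-continuous step function, which
makes the curve exactly invariant under duplicating SNPs with split weights.

Model curves are parametric in z: x = −log₁₀ P_model(|Z| ≥ z),
y = −log₁₀ 2(1−Φ(z)), averaged over a random ~1% sample of SNP contexts.
For the univariate mixture the survival is analytic (Gaussian tails), so the
curve has no integration error even at extreme quantiles.  Conditional
curves integrate the bivariate density over the secondary stratum
|z₂| ≥ z(t) per component (each 8-component term factorizes into a marginal
times a conditional Gaussian tail); strata are nested at p ≤ 0.1, 0.01,
0.001 plus all SNPs.

Power curves S(N) — the proportion of h² captured by genome-wide-significant
SNPs at sample size N — integrate C(z, N, j) = ∫ δ² P(z|δ) P(δ|j) dδ with
z|δ ~ N(δ, σ₀²) by 64-node Gauss–Hermite quadrature over the effect prior,
on a z grid of ±38 with step 0.05, averaged over the context sample.

## The synthetic generator

`make_panel` builds a block-diagonal LD reference: blocks of configurable
size with geometric correlation decay r = φ^|i−j| (default φ = 0.9, block
50, giving ~28 stored neighbours per interior SNP at the r² ≥ 0.05 storage
threshold and heterozygosity-adjusted LD scores of ~1–3.5), and MAF from a
1/p-shaped spectrum truncated at 0.05 (uniform and folded-beta spectra
available).  `draw_effects` draws component labels i.i.d. per SNP (optionally
modulated by per-SNP enrichment multipliers, mean-normalized to preserve
expected causal counts) and effects with variance H^S σ² — S = 0 is the
model's own assumption, S = −1 the standardized-genotype convention.  When an
h² target is given, effects are rescaled per trait so the realized
Σ β²H matches the target exactly (a mild conditioning of the Gaussian prior,
accepted for the sake of replicate comparability).  `simulate_z` is the
exact generative counterpart of the likelihood (same truncated-LD sums,
correlated residuals); `simulate_genotype_gwas` provides an independent
route via latent-AR(1)-threshold genotypes and per-SNP regression, used for
cross-simulator concordance checks.

What the generator does **not** emulate: coalescent LD fine structure
(haplotype blocks here are literal blocks), MAF–LD coupling, population
stratification, and genuity of the per-SNP sample-size column (constant N).
Passing tests therefore demonstrate correctness of the estimator under its
own assumptions plus the two programmed violations (MAF-dependence,
enrichment), not robustness to everything real data does.

## Study conditions and problem sizes

Desk-scale studies use M = 20,000 SNPs (tests use 5,000–10,000), block 50,
φ = 0.9, N = 100,000, h² = 0.4 back-solved on the panel, π = 3·10⁻³ — i.e.
60 causal variants carrying the full h², which concentrates per-variant
power compared with a genome-wide reference.  This is the standard
consequence of scaling the architecture down while keeping h² and N fixed;
the sensitivity analyses (S = −0.75 bias on π₁₂; spurious overlap under
shared log-normal block enrichment, sd = ln 2) are run at 10 replicate seeds
in `scripts/acceptance.py` and at 3–4 seeds in the test suite.

## Known limitations

* The conv evaluator degrades as mπ grows (multi-hit mass no longer small);
  beyond mπ ≈ 1 prefer the fast evaluator for search and the Monte-Carlo
  full model for refinement.
* ρ₀ pinning assumes the low-|z| set is null-dominated; for extremely
  polygenic, weakly powered data a small genetic leakage into that set
  biases ρ₀ slightly toward r_g.
* AIC/BIC for the bivariate stage report k = 3 (π₁₂, ρ₁₂, ρ₀); model
  selection headlines rely on the univariate k = 2 vs k = 3 comparison.
* Heritability is reported on the observed scale only; no liability
  conversion, no annotation partitioning, single non-null component per
  trait.
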