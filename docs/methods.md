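# Methods

## Model

A twin pair contributes the 4-vector y = (x₁, y₁, x₂, y₂): traits X and Y for
twins 1 and 2. Within each individual, each trait loads on latent
additive-genetic (A), shared-environment (C) and unique-environment (E)
factors with path coefficients a, c, e on the standard-deviation scale; the
traits may be connected by a direct causal regression at the phenotype level
(b_yx for X → Y, b_xy for Y → X) and/or by correlations r_A, r_C, r_E between
the trait-specific latent factors (non-causal confounding). Cross-twin factor
sharing is the standard twin-design structure: A shared at α = 1 (MZ) or ½
(DZ), C at 1, E at 0. The implied covariance for a class with causal matrix B
(block-diagonal over twins, zeros across twins) is

    Σ = (I − B)⁻¹ Ψ (I − B)⁻ᵀ

with Ψ the pre-causal covariance: within-person variances a² + c² + e² per
trait, within-person cross-trait covariance r_A a_x a_y + r_C c_x c_y +
r_E e_x e_y, cross-twin same-trait covariance α a² + c², and cross-twin
cross-trait covariance α r_A a_x a_y + r_C c_x c_y. Only three of
{b_yx, b_xy, r_A, r_C, r_E} can be free simultaneously; the mixture variants
therefore fix r_C = r_E = 0 and optionally free r_A (shared across classes,
or — as a configurable extension — one r_A per class).

The mixture has four pair-level classes per zygosity group, one per
combination of the two twins' causal directions. Structural parameters
(a, c, e paths and both b's) are shared across classes; classes differ in
which b enters which twin's block of B and in their means. Phenotypic means
are parameterized directly per causal direction, equated across twin order
and zygosity; a twin in a discordant pair takes the means of its own
direction, so the full mixture carries only four free means. Mixing
proportions are estimated separately for MZ and DZ pairs with the two
discordant weights tied (twin ordering is arbitrary, so the discordant
configurations are exchangeable). Observed-data log-likelihood, posteriors
and the relative entropy index Ent = 1 − (N ln C)⁻¹ Σ(−p ln p) follow the
standard finite-mixture forms; densities are evaluated through Cholesky
factors with log-sum-exp stabilisation, and probabilities below 1e−300 are
treated as exact zeros in entropy sums (0·ln 0 = 0 continuity).

A bidirectional class (both b's active in both twins) exists in the simulator
as a robustness generating condition only; fitted mixtures never include it.
Its reduced form requires |1 − b_yx b_xy| > 0, and a singular (I − B) raises
a dedicated error.

## Estimation

Six variants are fitted: the 4-class mixture, the concordant-only 2-class
mixture, unidirectional DoC (X → Y and Y → X), bidirectional DoC, and the
correlated-factors model (no causal paths, r_A, r_C, r_E free). Free-parameter
counts: 6 variance paths, plus causal paths per variant (1, 1, 2, 2 for the
DoC variants and mixtures, 0 for correlated factors), plus means (4 for
mixtures, 2 otherwise), plus weights (2 per zygosity for the tied 4-class
mixture, 1 for the 2-class), plus confound parameters. Fit statistics use
df = 4·n_pairs − k (four observed statistics per complete pair) and
AIC = −2LL + 2k.

Mixtures are fitted by EM. The E-step computes posterior class probabilities;
the weight update is the closed-form posterior mean with the discordant pair
pooled; the M-step maximises the expected complete-data log-likelihood over
the structural parameters numerically (BFGS, warm-started, a few iterations
per cycle — a generalised EM step). Because all pairs in a (class, zygosity)
cell share one implied mean and covariance, the M-step objective depends on
the data only through posterior-weighted first/second moments, so its cost is
independent of sample size; moments and objective are evaluated in a
vectorised kernel that also batches the finite-difference gradient.
Single-class variants are maximised directly by BFGS on the exact Gaussian
log-likelihood expressed through per-zygosity sufficient statistics. The
reported −2LL is always recomputed from the observed-data mixture likelihood
at the final estimates, so both routes answer to the same objective.

Numerical choices: convergence at relative log-likelihood change ≤ 1e−8 with
at most 2000 EM cycles; correlations optimised through a tanh bijection to
(−1, 1) and weights through softmax coordinates; non-positive-definite
covariances during search are rejected by a penalty, never crash; ACE paths
are sign-indeterminate, so estimates are normalised to nonnegative loadings
with the factor correlations re-signed accordingly. Multi-start is standard
for mixture likelihoods: start 0 is a method-of-moments-style start
(Falconer-type variance decomposition, regression-based b's, quantile-split
class means), further starts are jittered; the default is 10 starts, and
replication studies in the tests and acceptance script use 1–2 starts under
well-separated conditions, where the moment start is reliably in the basin of
the global optimum. Classes are structurally anchored (distinct B patterns
and direction-specific means), so no generic label-switching correction is
applied; a warning is raised if the two concordant classes' implied moments
coincide at the solution, where the mixture is unidentified. Nested fits can
be compared by a chi-square likelihood-ratio test; comparisons that cross a
mixture boundary violate the usual regularity conditions and carry a caveat
flag, directing users to AIC. Observed-information standard errors (numerical
Hessian) are available behind `compute_se=True`; they are off by default
because the Hessian costs O(k²) likelihood evaluations.

## Simulator and generating conditions

Datasets are drawn from the implied mixture of 4-variate Gaussians: per
zygosity and class, pair counts are allocated at exact proportions
(largest-remainder rounding; a multinomial option exists), 4-vectors sampled
via Cholesky factors, blocks merged and shuffled, true labels retained for
validation only. Seeded runs are bit-reproducible.

Held-fixed defaults (every sweep varies exactly one quantity): pre-causal
variance proportions X: A = 0.5, C = 0.2, E = 0.3 and Y: A = 0.2, C = 0.3,
E = 0.5 — deliberately distinct modes of inheritance, which DoC resolution
requires; b_yx = b_xy = 0.5; X → Y direction means at 0 with offsets
(δ_x, δ_y) = (0.5, 0.5) added to the Y → X direction (only the difference is
identified); no latent confounding; equal 25% class weights; 2500 MZ + 2500
DZ pairs. Sweeps: concordant mixing split P⁺ ∈ {0.1…0.6}; bidirectional
fraction ∈ {0.10, 0.15, 0.20}; mean offsets over
{(0.1,0.1), (0.5,0.1), (1.5,0.1), (0.5,0.5), (1.5,1.5)}; causal effects over
{(0.1,0.1), (0.1,0.5), (0.1,0.8), (0.5,0.5), (0.8,0.8)}; trait-Y additive
variance ∈ {0.1, 0.3, 0.4, 0.5, 0.6} with trait X fixed at 0.7 (C:E splits of
the remaining variance kept at the default 2:3 and 3:5 ratios); genetic
confounding r_A ∈ {0.1, 0.15, 0.2, 0.25, 0.3}.

What the generator does and does not emulate: it produces exactly
multivariate-normal classes with complete data and known zygosity — the
model's own assumptions. Passing tests therefore demonstrate correctness of
the likelihood, estimation and selection machinery under the model, not
robustness to measurement error, non-normality (e.g. questionnaire scaling
artifacts, which can mimic spurious mixtures), missingness, assortative
mating or gene–environment interplay, none of which are modelled.

## Experiment runners and problem sizes

`run_model_comparison` fits all six variants to one dataset, recomputing
ΔAIC from the AIC column (ties broken toward fewer parameters) and flagging
non-converged rows rather than dropping them; later variants reuse nested
solutions as warm starts, which also guarantees the analytic nesting bound
−2LL(full) ≤ −2LL(nested) numerically. `run_entropy_sweep` reports, per grid
point, both the mean per-replication entropy (the headline number) and the
entropy of a fresh dataset evaluated at replication-averaged estimates —
both, because either reading is defensible for a replication-averaged
summary — with Monte-Carlo standard errors; grid points with under 50%
convergence are flagged unusable. The default replication count is 100 per
grid point with the count exposed as a parameter; the test suite and
acceptance script use 2–20 replications per condition (100 for parameter
recovery) at 5000 pairs, sizes chosen to keep Monte-Carlo standard errors
small relative to the effects being checked.

## Known limitations

- Entropy computed from a *fitted* mixture is biased upward when classes are
  nearly unidentified (weakly separated classes let weights drift toward the
  boundary, sharpening posteriors spuriously); at 5000 pairs this inflation
  is modest, at a few hundred pairs it is large. The per-replication mean
  entropy should be read alongside its Monte-Carlo standard error.
- Under the default generating conditions the ceiling on classification is
  set by true class overlap: even at mean offsets of 1.5 within-unit-variance
  traits, the Bayes-posterior entropy is ≈ 0.47, so reports of near-perfect
  classification require far stronger separation than these conditions
  provide.
- Class-specific r_A is estimable in principle but weakly identified at
  moderate n; the shared-r_A mode is the default.
- Ordinal phenotypes, missing data, sex-limitation/5-group designs,
  non-additive genetic components and more than two phenotypes are out of
  scope.
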