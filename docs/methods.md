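# Methods

## Model class and likelihood decomposition

`pbpmc` targets posteriors of the form
π(θ, ξ | y) ∝ π(y | ξ, θ) · π(ξ | θ) · π(θ) in which the latent vector ξ
admits a topological order: each ξₑ depends only on lower-indexed latents,
so π(ξ | θ) = ∏ₑ π(ξₑ | ξ_{e′<e}, θ).  A `DagModel` stores the three
pieces separately — per-node conditional families with parameter maps,
observation terms with *explicit* latent dependency sets, and per-parameter
priors — because the joint-update acceptance ratio needs them separately
and because explicit dependency sets make single-site delta evaluation
exact and auditable (`ChainState.audit` recomputes caches from scratch).
Impossible states propagate `-inf` log-likelihoods instead of raising, so
the Metropolis–Hastings step rejects them naturally; deterministic derived
quantities (the population trajectory in the logistic benchmark) are
computed fields, not latent nodes.

## Transition kernels

A kernel maps (initial ID parameters, proposed ID parameters, current
value) to a proposed value subject to two requirements: *marginal
preservation* (an input distributed as the initial ID yields an output
distributed exactly as the proposed ID) and the *identity limit* (equal
parameters return the input unchanged, so small parameter moves keep
acceptance near one).  Eleven families are implemented; each case branches
on which parameter grew or shrank (ties are routed to the branch that
returns the identity).  Because the kernels preserve marginals, their own
sampling density cancels out of the acceptance ratio; only ID densities at
the initial and proposed values remain.

Notable constructions:

* **Normal/lognormal** mix a deterministic affine rescale with fresh noise
  through the tunable constant κ (default 0.03; κ = 0 is the pure rescale,
  κ = 1 independent resampling).  The branch algebra satisfies
  α²σᵢ² + κ(σₚ² − σᵢ²) = σₚ² exactly, which the test suite asserts
  symbolically.
* **Exponential, rate increase**: the proposal is min(ξᵢ, X) with
  X ~ Exp(rₚ − rᵢ) — the minimum of independent exponentials has the summed
  rate.
* **Negative binomial, z decrease**: ξᵢ is decomposed uniformly at random
  into r geometric components (conditional on an iid geometric sum, every
  composition is equally likely), and each component is thinned by
  min(g, Geom(1 − zₚ/zᵢ)).  This is exact and satisfies both conditions by
  construction.
* **Joint two-parameter moves** (beta, binomial, negative binomial) are
  decomposed into two sequential single-parameter sub-moves; each preserves
  marginals, hence so does the composition.

`check_condition1` verifies marginal preservation independently of the
samplers: for discrete families it pushes the exact initial pmf through
the analytically enumerated transition law on a truncated grid (tail mass
< 1e−12) and reports the max absolute deviation (observed ≈ 1e−13); for
continuous families it reports a Monte Carlo Kolmogorov–Smirnov distance
against the target CDF (bound 3/√n).

## Importance distributions

* **ID₀** is the model conditional itself; proposals are then model-based
  proposals and the acceptance ratio collapses to observation × prior,
  which the engine-level tests assert on every proposal to 1e−9.
* **ID₁** multiplies in the node's own observation terms.  Bernoulli nodes
  use the exact two-point normalization.  Normal nodes use a quadratic
  (Laplace) expansion of the observation log-density around the prior mean
  with one Newton refinement of the expansion point; derivatives are taken
  by central finite differences in the generic path and analytically in
  the compiled benchmark paths.  When the local curvature carries no
  information the mean is shifted along the gradient and the prior variance
  kept.  For normal observation terms the expansion is exact.
* **ID₂** additionally integrates each child node out against its own
  observation.  It is implemented for normal nodes whose children are
  normal with conditional mean affine in ξₑ (slope recovered by evaluating
  the child's parameter map at two points), which covers normal chains and
  the pedigree mixed model exactly; anything else raises, directing the
  user to ID₁.  A child whose co-parent has a *higher* index is skipped so
  the ID remains a function of (ξ_{e′<e}, θ, y) only — that child's record
  instead informs its later-indexed parent.  Skipping information can only
  reduce proposal quality, never bias the posterior: the acceptance ratio
  uses the same ID for the forward and reverse directions.

ID quality is measured, not assumed: the acceptance-ordering test runs the
mixed benchmark at a fixed jump scale under ID₀/ID₁/ID₂ and checks the
acceptance rate is non-decreasing in the level (observed ≈ 0.10 / 0.30 /
0.33 at 400 individuals).

## Engine

One PBP update: (1) propose all parameters jointly from a multivariate
normal random walk with covariance j²Σ_θ; (2) regenerate each latent in
topological order through its kernel, accumulating the ID-density
correction; (3) accept or reject everything at once.  Bounded parameters
can declare a proposal coordinate (`log` over (lo, ∞), `logit` over a
finite support); the walk then lives in the transformed space and the
exact Jacobian ratio enters the acceptance probability.  This matters in
practice: plain proposals near a support boundary (persistence φ ≈ 1,
variances near 0) make the acceptance rate strongly state-dependent.

Every U-th update (default U = 4) is a standard sweep: single-site
Metropolis or registered Gibbs moves over all latents (randomized scan
order, which makes the sweep kernel reversible) followed by per-parameter
random-walk/Gibbs moves.  With `ids=None` the engine runs this sweep
exclusively — the baseline sampler.

**Adaptation** happens only during burn-in, in two stages.  For the first
70%, Σ_θ is re-estimated every 50 updates from a growing window of
transformed parameter samples (10% shrinkage toward its diagonal, jitter
to positive definiteness) and j follows multiplicative feedback
j ← j·exp(0.5(α_window − α*)) toward the target α* = 0.33.  For the final
30%, Σ_θ is frozen and j is tuned by a measure-then-correct loop: j is
held fixed for blocks of ten windows and corrected once per block through
the empirical α ∝ 1/j power law (full step when off by more than 2×,
damped 0.8 otherwise, clamped to [0.02, 10]).  The fixed-j blocks exist
because acceptance measured *while j itself is moving* proved to be a
biased estimate of the acceptance at the final j.  After burn-in
everything is frozen, so the sampling phase is a plain (non-adaptive)
Markov chain.  Single-site step sizes adapt analogously toward 0.44
(latents) and 0.30 (parameters).

Initialization draws θ⁰ from the priors (or declared initializers for
improper priors) and ξ⁰ by forward simulation, retrying up to 100 times
until the observation likelihood is finite.

**Compiled fast paths.**  Each benchmark attaches vectorized
(diagnostic: all individuals conditionally independent) or numba-compiled
(stochastic volatility, mixed, logistic: sequential recurrences) latent
sweeps and likelihood evaluators with the same semantics as the generic
per-node path.  The test suite cross-validates them: likelihoods agree to
1e−7, compiled ID₀ sweeps satisfy the same correction identity, and
compiled and generic chains agree in posterior means within Monte Carlo
error.  The compiled standard sweeps use a fixed scan order (each
single-site move preserves the posterior, so the sweep remains valid
MCMC even though it is not reversible as a composite).

## Benchmark generators

The generators *are* the study conditions; their defaults are the
generating scenarios used throughout the tests.

* **Diagnostic-test model** — P = 1000 individuals, prevalence 0.5, two
  tests with sensitivity 0.6 and specificity 0.9.  Flat priors with the
  conventional identifiability constraint Se + Sp > 1 (a scenario flag;
  disabled for the 3-individual instance whose posterior is enumerable in
  closed form via beta integrals).  The baseline registers exact
  beta-conjugate Gibbs draws (truncated where the constraint binds).
* **Stochastic volatility (Student-t)** — E = 3000 days (tests use 1000),
  μ = −10, φ = 0.99, ν = 12, σ² = 0.0121; h₁ starts from the AR(1)
  stationary law.  Priors: flat on μ and σ²; (φ+1)/2 ~ Beta(20, 1.5) and
  ν − 2 ~ Exp(0.1) — the conventional weakly-informative choices, which
  keep the sampler off the φ → 1 ridge where μ decouples and which
  regularize a tail parameter that series of this length barely identify.
* **Mixed (animal) model** — 4 generations × 1000 (tests: ×100) randomly
  mated individuals, r² = 0.5, total variance 1, fixed effects = intercept
  + one binary covariate.  Founders a ~ N(0, σ_a²), non-founders
  a ~ N((a_s + a_d)/2, σ_a²/2); the implied covariance is σ_a²A with A by
  the tabular method (diagonal 1 + A_{sd}/2; the Mendelian-sampling
  variance is not reduced for inbred parents).  The Monte Carlo
  covariance test verifies this identity on a 5-individual pedigree.
* **Logistic population model** — T = 401 steps of size τ = 0.1, r_b =
  0.6, μ = 0.3, K = 100, capture probability p = 0.5, M = 21 equally
  spaced trap counts, founding population P₀ = 5 (the generator resamples
  a step only if it would drive the population negative; inference instead
  assigns such trajectories zero likelihood).  Birth means are clamped at
  zero when P > K.  Priors: flat on r_b and K; μ ~ Gamma(mean 0.3,
  CV 0.25) and p ~ Beta(10, 10), the semi-informative stand-ins for
  mark–recapture knowledge.  Because trap counts inform each step through
  *future* observations, the data-folding IDs do not apply and this
  benchmark runs with ID₀.

What the generators deliberately do not emulate: real measurement
artifacts (missing records, reporting delays, heavy-tailed pedigree
errors), model misspecification (the fitted model is always the generating
model), and real market or field data.  Passing recovery tests therefore
demonstrates correctness of the samplers under the stated models, not
robustness to misspecification.

## Diagnostics

Effective sample size uses the initial-positive-sequence rule: ESS =
N / (1 + 2Σρ̂ₖ) with the autocorrelation sum truncated at the last
strictly positive pair sum ρ̂₂ₖ + ρ̂₂ₖ₊₁ (autocovariances via FFT).
Constant and super-efficient (antithetic) series are capped at N with a
warning.  The estimator is cross-checked against an independent reference
implementation in the test suite.  Wall-clock figures (e.g. time per 100
effective samples) are a function of hardware and are intentionally not
asserted anywhere.

## Problem sizes and numerical choices

The test suite runs the benchmarks at: diagnostic P = 1000 with 10⁵
retained updates; stochastic volatility E = 1000 with 5×10⁴; logistic
T = 401 with 10⁵; mixed model 400 individuals with 2×10⁴ plus three
1.4×10⁴-update fixed-j runs for the acceptance ordering; burn-in 10⁴
throughout.  The exactly-enumerable diagnostic instance uses 3 individuals
and 10⁶ updates per sampler.  Tolerances: 1e−10 for exact-enumeration
kernel checks, 3/√n for Monte Carlo KS checks, 1e−9 for the acceptance
algebra identities, total variation 0.01 against enumeration, 95% credible
intervals for recovery, ±10 percentage points for acceptance-rate control.

Known limitations: ID₂ is restricted to the normal-affine case; the
negative-binomial z-moves need integer r; improper posteriors (e.g. flat
priors on a weakly identified persistence parameter) can produce sticky
boundary ridges that defeat any fixed-scale proposal — the benchmark
priors avoid this by construction; and the logistic model's single-site
sweep costs O(T) per site because changing one birth/death count shifts
the entire subsequent trajectory.
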