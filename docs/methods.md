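# Methods

## Model

`heckselect` fits the classical bivariate-normal sample selection model: a
latent outcome `y* = β₀ + x'β + ε₁` observed only when a latent selection
index `s* = α₀ + w'α + ε₂` is positive, with `(ε₁, ε₂)` bivariate normal,
`Var(ε₁) = σ²`, `Var(ε₂) = 1` (the index scale is unidentified, so it is
fixed), and correlation ρ. Missingness is MCAR when α = 0 and ρ = 0, MAR
when ρ = 0, and MNAR otherwise; ρ ≠ 0 is exactly the case where complete-case
regression is biased and the selection correction carries information.

All error-scale computation uses the reparametrization
**ρ̃ = ρσ** (error covariance) and **σ̃² = σ²(1 − ρ²)** (conditional outcome
variance). These are the *stored* quantities everywhere — `ModelParams`
derives (σ, ρ) on demand — because (a) the Gibbs conditionals are conjugate
in (ρ̃, σ̃²) and (b) it removes any chance of the two parametrizations
drifting apart. A bonus is numerical robustness: quantities like
√(1 − ρ²) = σ̃/σ are computed exactly even when an optimizer wanders to
|ρ̃| ≫ σ̃.

Tail-sensitive functions (log Φ, the inverse Mills ratio λ, κ) are computed
through `scipy.special.log_ndtr`, which switches internally to a scaled
complementary-error-function expansion for very negative arguments; λ is
accurate to at least u = −40 (verified against arbitrary-precision
evaluation in the tests).

## Priors and elicitation

Each slope carries a continuous spike-and-slab prior
`coef | γ, v ~ (1−γ) N(0, τ₀² v) + γ N(0, τ₁² v)` with a latent mixing scale
`v` whose law sets the marginal family: degenerate at 1 (normal),
exponential with mean 2 (Laplace with scale τ), or inverse-gamma(ν/2, ν/2)
(Student-t with ν degrees of freedom, default ν = 3, configurable). Spike,
slab, and intercept components may use different families. Class II priors
additionally scale the outcome-equation coefficient variances by σ̃², so
effect sizes are judged against unexplained noise; whether the *outcome
intercept* also receives the σ̃² factor is genuinely ambiguous, so it is a
flag (`scale_outcome_intercept`, off by default).

Indicators are iid Bernoulli(r) with `r ~ Beta(a₀, b₀)` shared across both
equations, giving a Beta-Binomial model-size prior with automatic
multiplicity correction. Defaults (`default_spec`):

| parameter | default | role |
|---|---|---|
| τ₀,β | (np)^(−1/2) | outcome spike sd; shrinks with n and dimension |
| τ₀,α | (nq)^(−1/2) | selection spike sd |
| τ₁,β | (4 log 500)^(−1/2) √(log n) | outcome slab sd; equals 0.5 at n = 500, grows with log n |
| τ₁,α | √3/π ≈ 0.551 | selection slab sd, matching the probit (logistic-variance) scale |
| (a₀, b₀) | (1, 1) or (1, p+q) | flat over model size vs monotone-sparse |
| τ (for ρ̃) | 5 | ρ̃ \| σ̃ ~ N(0, τσ̃²); induces a U-shaped (≈Beta(1/2,1/2)) prior on ρ |
| (c, d) | (1, 1) | σ̃² ~ InvGamma(c, d) |
| η (intercepts) | 100 | weakly informative; "large" is all that matters |

Two printed forms of the slab-sd formula circulate with opposite exponents
on the log ratio; they agree at n = 500. The increasing-in-n form is used
here, consistent with a slab variance proportional to log n. Laplace
components divide τ by √2 so their marginal variance equals the normal
family's at the same τ (2(τ/√2)² = τ²). Slab/spike sensitivity multipliers
(×2, ×0.5, …) are plain scalars on `default_spec`.

The inclusion weights use **fully normalized** Gaussian component densities
(the 1/(τ√v) factors included). This is what makes the calibration
arithmetic come out: at spike sd 1/√500, slab sd 0.5, r = 1/2, a coefficient
of 0.15 has inclusion weight ≈ 0.96 and 0.05 has ≈ 0.14 — the numbers the
default C_β is derived from. Without the normalizers neither value is
reproducible.

## Gibbs sampler

One sweep is the fixed scan (no random scan — fixed order keeps chains
bit-reproducible given a seed):

1. `s*_i` — truncated normals; censored units on (−∞, 0) with mean
   α₀ + w'α and unit variance, selected units on (0, ∞) with the
   ρ̃-adjusted mean and variance σ̃²/(ρ̃² + σ̃²).
2. (α₀, α) — joint Gaussian. The block appears in the likelihood twice:
   the s* regression (all units, unit variance) and the selection residual
   inside the outcome equation (selected units). Precision
   W̃'W̃ + (ρ̃²/σ̃²) W̃₁'W̃₁ + D⁻¹.
3. (β₀, β, ρ̃) — joint Gaussian: y regressed on (1, x, e) over selected
   units, e = s* − α₀ − w'α, noise σ̃².
4. σ̃² — inverse gamma with shape c + (1 + n₁)/2 and rate
   d + ρ̃²/(2τ) + ½Σ(residual)²; under Class II the σ̃²-scaled coefficient
   priors add p/2 to the shape and Σβ_j²/(2τ²_γ v_j) to the rate.
5–7. indicators γ (Bernoulli, normalized-density weights including the
   mixing-density ratio when spike and slab families differ), then
   r ~ Beta(a₀ + Σγ, b₀ + p + q − Σγ).
8–10. mixing scales: v = 1 (normal); 1/v ~ InverseGaussian(τ/|coef|, 1)
   (Laplace; Gamma(1/2, rate 1/2) in the coef → 0 limit);
   v ~ InvGamma((ν+1)/2, (ν + coef²/τ²)/2) (Student-t). Intercept scales
   analogous with η.

The Gaussian blocks in Steps 2–3 are not taken from a printed formula; they
are derived from the complete-data factorization and *pinned to the joint*:
the test suite's master oracle checks, for every block and both prior
classes and all families, that the conditional log-density difference
between two states equals the complete-data joint log-posterior difference
to 1e−8 (`log_joint` in `gibbs.py` is the single source of truth).

Numerical choices: precision matrices are factorized by Cholesky with a
jitter escalation (1e−10 × 10^k, k = 0..3) and a logged warning on retry;
truncated-normal draws delegate to `scipy.stats.truncnorm`, which is robust
beyond standardized bounds of ±8 (verified against an exponential-rejection
tail oracle at bound 10); inclusion weights are computed in log space.

Initialization: `mle` mode starts at the full-model ML estimates with γ set
by 5%-level Wald significance; any MLE failure falls back (with a logged
warning, never an exception) to the `null` start — all coefficients 0,
σ̃² = 1, ρ̃ = 0, empty model, r at its prior mean, mixing scales at their
prior means. Default chain lengths are 10,000 sweeps with 1,250 burn-in for
simulation work; indicator chains mix slowly, so 50,000/5,000 is recommended
for real applications. Thinning is supported but defaults to 1.

## Frequentist baselines

* **Probit** (statsmodels) for the selection equation; perfect separation is
  reported via the convergence flag.
* **Two-step**: probit, then OLS of y on (1, x, λ̂) over selected units. The
  IMR coefficient δ̂ estimates σρ and is reported as such — no (σ, ρ)
  back-out. A collinearity flag fires when less than 1% of the IMR column's
  variance is unexplained by (1, x) (the near-linear-IMR, no-exclusion
  pathology); the 1e−2 threshold separates the pathological case (measured
  ≈ 3e−3) from a well-identified one (≈ 0.6) by two orders of magnitude.
* **MLE**: BFGS with the analytic score on (α₀, α, β₀, β, ρ̃, log σ̃²) —
  positivity and |ρ| < 1 hold by construction. Multi-start (two-step start,
  then a null start); convergence is declared honestly (optimizer success or
  small gradient, plus a positive-definite observed information when
  standard errors are requested). Degenerate proposals from the line search
  are rejected with a large finite objective value.
* **Forward stepwise**: starts from the null model, each round ML-fits every
  single-variable addition to either equation and accepts the
  BIC-minimizing one; stops when no addition lowers BIC.
  BIC = −2ℓ + k log n with **n the total sample size** (the likelihood
  integrates selected and censored units alike) and k counting intercepts,
  active slopes, σ̃² and ρ̃. Exact ties break deterministically: selection
  equation before outcome, then lowest column index. Candidates that fail to
  converge are skipped with a logged warning — occasional failures are
  expected in this model class and are part of the method's observed
  behaviour, not an error.

## Synthetic data

The generator emulates a sparse two-equation design: covariates are
AR(1)-correlated standard normals (corr decay^|j−k|, default decay 0.5),
shared by both equations (no exclusion restriction) unless p < q, in which
case the trailing selection covariates act as exclusions. Active
coefficients default to α = (0.5, 1, 1.5, 0, …)/√2 and
β = (0.25, 0.5, 1, 0, …) — small/medium/large effects — with β₀ = 0.5,
σ = 1. The selection intercept is **calibrated on the realized covariate
matrix**: a bracketed root-find (tolerance 1e−10) solves
mean_i Φ(α₀ + w_i'α) = 1 − target missingness (default 0.30). Calibrating on
the empirical average rather than the population integral makes the target
exactly testable and ties the intercept to the simulated covariates.
Replicates within a scenario hold the covariates fixed and redraw only the
errors (`simulate_given_covariates`).

What the generator does *not* emulate: non-normal errors, heteroscedasticity
unrelated to selection, discrete or collinear real-world covariates, and
covariate measurement error. Passing tests therefore demonstrate
correctness of the algorithms under the model's own assumptions, not
robustness to their violation.

## Posterior summaries

PIPs are indicator means over stored draws; the median probability model
includes a variable iff its PIP is **strictly** greater than 0.5 (a PIP of
exactly one half is excluded). Selection performance is summarized by
TPR/TNR over the concatenated p + q slots, the exact-recovery indicator
(TMR), and per-equation model sizes. Model-conditional posteriors subset the
chain to iterations whose joint (γ^O, γ^S) configuration equals the target
model — the subsets partition the chain — and report medians, SDs and
central 95% intervals for included coefficients only.

Out-of-sample comparison uses leave-one-out elpd estimated by importance
sampling over the model-conditional draws, with Pareto-smoothed weights
(`arviz.psislw`) and per-unit tail-shape diagnostics reported. Per-unit
likelihoods use the full selection likelihood: the bivariate term for
selected units, log Φ(−α₀ − w'α) for censored ones. A model must have been
visited a minimum number of times to be comparable (default 100 draws; the
threshold is configurable and genuinely arbitrary).

## Problem sizes used in the test suite

The packaged checks run at sizes chosen to make Monte-Carlo error small
relative to the asserted effects while keeping the whole suite desk-scale:
conditional-ratio oracles on n = 12; the Metropolis cross-check on n = 30
with p = q = 2 (the marginalized posterior sums 2^(p+q) configurations, so
small m is essential); parameter recovery at n = 2000; PIP checks at
n = 1000, p = q = 10 with 10,000 sweeps; and the stepwise over-selection
scenario at n = 500, p = q = 50 with 20 replicates on a fixed covariate
draw. Monte-Carlo tolerances are stated in standard errors of the quantity
being estimated, with conservative effective-sample-size deflation for
autocorrelated chains.

## Known limitations

* The sampler's cost per sweep is dominated by n truncated-normal draws and
  (p+1)² / (q+1)² factorizations; it is not intended for p or q in the
  hundreds.
* A single inclusion probability r couples both equations; separate
  per-equation sparsity levels are not supported.
* Indicator chains mix slowly when a predictor sits near the
  inclusion boundary; PIPs near 0.5 deserve longer chains and the
  model-conditional summaries rather than marginal ones.
* Errors are bivariate normal only; heavy-tailed or skewed error families
  are out of scope.
* Two-step standard errors are the naive OLS ones (the IMR column is
  treated as known); they are fine for starting values and rough
  diagnostics, not for inference.
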