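# Methods

## Model

The package fits a joint Bayesian model for clustered count data whose binary
exposure of interest is observed only through fallible assessments.

*Outcome model.* Counts `y_ij` (subject *i*, cluster *j*) are Poisson with a
known multiplicative offset `r_ij` (defaulting to 1 when the data carry no
exposure-time or size column) and a log-linear rate

    log λ_ij = β₀ + u_j + β₁ x_ij + Σ_k β_k z_ijk,   u_j ~ N(0, σ²).

*Exposure model.* The true exposure `x_ij` is Bernoulli with a logistic link

    logit π_ij = γ₀ + v_j + Σ_k γ_k z_ijk,   v_j ~ N(0, ν²).

The outcome-model and exposure-model covariate sets may coincide (as in the
bundled simulator) or be configured separately by column name.

*Measurement model.* Misclassification is nondifferential: an assessment
`x_t` depends on the data only through the true exposure, with sensitivity
`S_t = P(x_t = 1 | x = 1)` and specificity `C_t = P(x_t = 0 | x = 0)`. Two
assessments are conditionally independent given `x`, so their joint
likelihood is the product of the two single-test kernels (a property the test
suite asserts to machine tolerance).

Three fitting modes share this machinery: `naive` substitutes the first
assessment for the truth and fits only the outcome model; `one_test` and
`two_test` treat `x_ij` as latent and fit all three parts jointly.

## Priors

Regression coefficients get mean-zero normal priors **parameterized by
variance** — 10 for every γ, 100 for every β. This matters for users coming
from BUGS dialects, which parameterize normals by precision; here
"normal(0, 10)" always means variance 10. The random-intercept SDs σ and ν
get uniform(0, 3) priors (density −∞ outside the support). Each sensitivity
and specificity gets a beta prior.

With a single assessment the likelihood cannot separate (S₁, C₁) from the
exposure prevalence, so `one_test` mode *refuses* flat beta(1, 1) shapes and
requires informative ones; the simulation harness uses beta(10, 8) for S₁
(prior mean 0.556, 95% interval roughly 0.33–0.77) and beta(165.7, 9.7) for
C₁ (prior mean 0.945, tight), which encode that unexposed subjects rarely
report exposure while truly exposed subjects underreport substantially.

With two conditionally independent assessments the operating characteristics
are identified by the data — but only up to the latent-relabeling map
`x → 1 − x`, `S_t → 1 − C_t`, `C_t → 1 − S_t`, `γ → −γ`, `β₁ → −β₁`,
`β₀ → β₀ + β₁`, under which the likelihood is exactly invariant. Under flat
S/C priors the posterior is therefore bimodal, and a chain can settle in the
mirror mode (it did, in one replicate of an early ten-replicate run, with
S₁ ≈ 0.06 and a sign-flipped exposure effect). `two_test` mode resolves this
with the standard better-than-chance convention: the joint prior is
restricted to `S_t + C_t > 1` for each test. In `one_test` mode the
informative priors carry that role, and the sampler warns if retained draws
cross the `S₁ + C₁ = 1` boundary.

## Sampler

The model is fitted by a purpose-built Metropolis-within-Gibbs sampler with
data augmentation. One sweep:

1. **Latent exposure** — every `x_ij` is drawn from its exact Bernoulli full
   conditional, a two-point Bayes ratio combining the exposure probability,
   the Poisson likelihood at `x = 1` vs `x = 0`, and the measurement
   likelihood of the observed assessments. Computed stably as a single
   per-subject logit; vectorized over all subjects.
2. **Regression coefficients** — scalar random-walk Metropolis for β₀, β₁,
   each β_k, γ₀, each γ_k, against the joint log posterior. The Poisson
   linear predictor is cached and updated incrementally, so a scalar update
   costs one vector exponential at most.
3. **Random intercepts** — u (and v) proposed for all clusters at once and
   accepted cluster-by-cluster; their full conditionals are independent
   given the rest, so the parallel accept/reject is a valid Gibbs scan.
4. **Random-effect SDs** — σ and ν by random-walk Metropolis on the log
   scale with the log-Jacobian, respecting the uniform(0, 3) upper bound.
5. **Sensitivities/specificities** — conjugate beta draws from the
   augmented-data cross-tabulation (e.g. `S₁ ~ beta(a + TP, b + FN)`); in
   `two_test` mode each coordinate is drawn from its beta conditional
   truncated to the better-than-chance region by inverse-CDF sampling, a
   valid Gibbs scan of the truncated joint.

Proposal scales adapt by Robbins–Monro toward 0.44 per-block acceptance
during burn-in only and are frozen afterwards, so the post-burn-in kernel is
a fixed composition preserving detailed balance. Initialization: coefficients
at 0, SDs at 0.1, S/C at their prior means, latent x at the first assessment.

Correctness is established three ways: all log-densities are cross-checked
against scipy.stats and brute-force per-subject enumeration; the latent-x
conditional and the conjugate S/C updates are checked against closed forms;
and two Geweke-style joint-distribution ("getting it right") tests — one for
the one-test kernel, one for the two-test kernel with truncated S/C priors —
compare prior draws with successive-conditional chain draws on a miniature
2-cluster model, requiring every monitored first and second moment to agree
within four Monte Carlo standard errors.

Posterior summaries are means, sample SDs, and equal-tailed 95% credible
intervals from the empirical 2.5%/97.5% quantiles (numpy's linear
interpolation rule); equal-tailed intervals match the BUGS-style convention.
Coverage scoring uses closed interval endpoints (a measure-zero choice,
fixed for reproducibility).

## Synthetic-data generator

`SimDesign` defaults encode the simulation-study conditions: N = 25 clusters
of 200 subjects; exposure model `logit π = −1.5 + v_j − 0.21 z₁ − 0.16 z₂ +
0.19 z₃ − 0.29 z₄`; outcome model `log λ = 0.85 + u_j + 0.4 x + 0.25 z₁ −
0.2 z₂ − 0.18 z₃ − 0.05 z₄`; σ = ν = 0.1; test 1 with S₁ = 0.55, C₁ = 0.95;
test 2 (conditionally independent given x) with S₂ = 0.7, C₂ = 0.8; offset
r ≡ 1. Marginal exposure prevalence is about 0.18.

The covariates z₁..z₄ are drawn as independent standard normals. This is the
generator's main idealization — and the one degree of freedom the study
conditions leave open — since real survey covariates are correlated and
partly discrete ("uniform" and "bernoulli" alternatives are available).
Cluster sizes are equal and non-informative; no zero-inflation. Passing
tests on these data show the estimator recovers the generating process under
correct model specification; they say nothing about robustness to covariate
correlation, informative cluster sizes, or differential misclassification,
all of which are out of scope.

## Simulation study

`run_study` simulates replicate datasets (seeds spawned from one master seed
via `numpy.random.SeedSequence`, so the study is fully deterministic and
parallelizable), fits each requested mode per replicate, and aggregates per
parameter: truth, average posterior mean, average posterior SD, and
empirical coverage of the 95% interval. The default profile is 10 replicates
with 3000 retained draws after 1500 burn-in sweeps per fit — sized so the
whole three-mode study runs in a few minutes on one CPU while leaving
per-fit Monte Carlo error on β₁ near 0.004 (effective sample size ≈ 75–550
depending on the block) — with a 50-replicate profile behind a flag for
longer runs. A replicate whose fit fails is excluded and counted; none fail
under the default conditions.

Under this generator the study reproduces the qualitative findings sharply:
the naive exposure-effect estimate is attenuated toward the null in every
replicate with empirical coverage 0, the corrected models recover β₁ with
near-nominal coverage, and the corrected posterior SDs are inflated relative
to the naive ones — the price of honesty about the measurement process.

One quantitative caveat is documented rather than hidden. Classical
attenuation for a binary covariate observed with S₁ = 0.55, C₁ = 0.95 at
prevalence ≈ 0.18 retains a fraction `P(x=1|x₁=1) − P(x=1|x₁=0) ≈ 0.6` of
the effect, so the naive posterior mean under this design is ≈ 0.25 (an
independent Poisson-GLM fit on a 100 000-subject draw gives 0.248), not ≈ 0;
correspondingly the naive intercept lands near 0.89 rather than 0.94. Some
published figures for the naive model under nominally identical settings
show total attenuation (β₁ ≈ 0, β₀ ≈ 0.94) — numerically consistent with an
assessment that is *independent* of the true exposure, not one with the
stated operating characteristics. The harness follows the stated generative
design and reports what it implies.

## Numerical choices and limitations

- Poisson and Bernoulli log-kernels are written out explicitly (hot path);
  scipy.stats serves as the independent oracle in tests, never the
  implementation of the sampler's inner loop.
- S/C draws are clipped to [1e−12, 1 − 1e−12] to keep downstream logs finite.
- Cluster labels are re-indexed to contiguous integers internally; original
  labels are preserved in outputs.
- Missing values in any used column are a hard error, never dropped.
- The sampler is single-chain; a two-chain comparison can be run by seed.
  HMC/NUTS, model-comparison criteria, misclassified *outcomes*, more than
  two assessments, and differential misclassification are out of scope.
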