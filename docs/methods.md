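# Methods

## The cascade model

A group of `n` bees faces a standardised threat. Bee `j`'s latent
aggressiveness, together with the pheromone-dependent stinging threshold,
is observable only through the marginal sting probabilities
`r_k = P(bee stings | pheromone level k)`, `k = 0..n−1`; the package
therefore parameterises the model directly by the monotone vector
`0 ≤ r_0 ≤ … ≤ r_{n−1} ≤ 1` and never materialises the latent variables.
Assumptions: one sting releases exactly one pheromone unit; no pheromone
degradation within a trial; spatial homogeneity (every bee senses the same
level); a bee stings at most once and does so immediately when its level is
reached; several bees may sting in the same step.

Equivalently, each bee falls into an aggressiveness *category*: category
`j` stings as soon as the level reaches `j` (probability band
`q_0 = r_0`, `q_j = r_j − r_{j−1}`), category ∞ never stings
(`q_∞ = 1 − r_{n−1}`). Given a category assignment the outcome is
deterministic — the least fixed point of `g(k) = #{bees with category ≤ k}`
— which is what the enumeration oracle exploits.

### Exact terminal distribution

`outcome_distribution` runs a dynamic programme over states `(m, c)` —
`m` remaining bees, all of which last declined at level `c` (sentinel
`⊥`, `r_⊥ = 0`, for the initial state). In state `(m, c)` the level is
`k = n − m` and each remaining bee stings with probability
`(r_k − r_c)/(1 − r_c)`; the number of new stings is binomial, zero new
stings absorbs at count `k`. There are O(n²) states, so the distribution
for `n = 10` costs microseconds — fast enough to sit inside optimiser and
sampler loops without caching tricks.

Numerical choices: a state with `r_c = 1` is unreachable (probability
zero) and is pruned rather than divided by; ties `r_k = r_c` give zero
conditional recruitment, which simply stalls the cascade and is allowed by
the non-strict monotonicity constraint.

### Polynomial form

The same recursion in fraction-free form,
`D̃(m, c) = (1 − r_c)^m · D(m, c)`, cancels all denominators
telescopically and yields the terminal reachability functions
`f_k(r_0..r_{n−1})` as genuine polynomials with exact rational
coefficients (sympy). They are indexed by the observable final sting
count, serialise to a canonical sorted-monomial text form and to JSON, and
agree with the numeric route to 1e-10 everywhere tested. Symbolic size
grows quickly; the default cap is `n ≤ 12` (`n = 10` takes tens of
seconds once, then is cached).

## Inference

**Likelihood.** A dataset is the count vector `c_0..c_n` of `N` i.i.d.
trials. The exact multinomial log-likelihood is `Σ c_k log f_k(θ)`;
classes with `c_k = 0` contribute nothing, and any observed class with
model probability zero gives −∞. Infeasible θ also map to −∞ (a
zero-prior convention serving the sampler) rather than raising.

**Point estimation** (`l2_fit`) minimises
`Σ_k (f_k(θ) − c_k/N)²` — the squared distance between predicted outcome
probabilities and observed frequencies — by multi-start L-BFGS-B. The
feasible region is mapped onto a box: the agnostic vector is
reparameterised as a basal probability plus fractional non-negative
increments (`r_k = r_{k−1} + x_k(1 − r_{k−1})`, a bijection from the unit
cube onto the monotone simplex); the linear increment is scaled by
`(1 − r_0)/(n − 1)`; Hill scale parameters are optimised in log space
inside configurable bounds (defaults `K_m ∈ [10⁻³, 50]` pheromone units,
`n_H ∈ [10⁻², 10]` — wide enough to include a near-step and a near-linear
curve at every group size used here; the admissible ranges are a package
choice, documented not asserted as canonical). Defaults: 10 restarts,
seeded.

**Sampling** (`metropolis_hastings`) is a random-walk Metropolis scheme
with independent per-coordinate Gaussian proposals of configurable scale,
a uniform prior over the feasible region (boundary handling by rejection),
and the standard acceptance ratio `min(1, L(θ′)/L(θ))`. The full chain
(repeats included) is recorded: posterior means and equal-tailed credible
intervals need the chain, not just the accepted points, to be unbiased.
Default burn-in fraction 0.25. Traces export to CSV and JSON summaries.

**Local sensitivity** perturbs one parameter at a time by uniform draws in
`±scale` (default 0.05, 100 draws), skipping and counting draws that leave
the feasible region, and reports the mean absolute change of the L2
objective per unit perturbation. As the scale shrinks this converges to
the absolute gradient (verified against finite differences). On the
bundled data the score of `r_9` is orders of magnitude below that of
`r_0`: late parameters only enter through rare high-count outcomes, which
is exactly why their estimates are the most uncertain. A parameter pinned
by an exact tie in a monotone vector has no feasible one-sided
neighbourhood and scores zero by convention.

## Model selection

Shapes are compared with `AIC = n_obs·log(RSS/n_obs) + 2k` (natural log;
`RSS = 0` returns −∞ with a warning) on three fit variants:

1. outcome-probability residuals (`n_obs = n + 1` classes),
2. dose-response residuals against the agnostic estimates `r̂_i`
   (`n_obs = n` parameter values),
3. variant 2 with each residual divided by its uncertainty scale, taken as
   the reciprocal of the normalised local-sensitivity score of `r̂_i`
   (weights floored at the smallest positive score when ties zero one
   out). Weighted fits use weighted least squares and the weighted R² uses
   the precision-weighted mean in its total sum of squares, making it
   invariant under uniform weight rescaling.

The number of fitted observations per variant and the sensitivity-based
weighting are package design decisions: the weighting reconstructs the
idea of discounting poorly-constrained parameters, and is documented as a
reconstruction rather than a canonical formula. The selected model is
validated by R² on the parameter variant (the regression of the fitted
dose-response curve on the shape-free estimates) and by a Shapiro-Wilk
residual normality check. On the bundled group-of-10 table the linear
model wins all three variants with R² ≈ 0.926 unweighted and ≈ 0.945
weighted.

## Group-size trends

Each group size is fitted independently (no shared parameters across
sizes). Size 1 is a Bernoulli model with the closed form `r_0 = c_1/N`.
The per-size linear slope, linear intercept and agnostic `r_0` are each
correlated with group size by Pearson's test (two-sided p from the t
distribution with `len − 2` degrees of freedom). The slope series excludes
size 1, where the increment is unidentified because no pheromone step can
occur.

## Synthetic data

The generator draws each condition's count table from the exact terminal
distribution in a single multinomial draw (default) or by per-trial
cascade simulation (cross-check backend; the two are statistically
identical and chi-square-compared in tests). The master seed spawns one
substream per group size keyed by the size itself, so conditions never
perturb one another, and every dataset carries a provenance record that
regenerates it exactly. Default generating truths sit away from the
boundaries (e.g. linear `r_0 = 0.2`, `Δ = 0.05` at `n = 10`, 92 trials —
the experimental sample size) so that all outcome classes have
non-trivial probability; these are test conditions, not estimates.

What the generator does *not* emulate: colony identity and between-colony
variability, test-duration effects, non-stationary pheromone levels, or
any deviation from i.i.d. trials. Passing recovery tests therefore show
the inference machinery is correct under the model's own assumptions, not
that real colonies satisfy them.

## Problem sizes used by the test suite

Oracle equivalence is exercised for `n = 2..6` (100 random monotone
vectors per size, three independent computation routes at 1e-12/1e-10);
recovery uses 50 seeded replicates of 92 trials with 4000-iteration
chains; the sampler is checked against a 1000×1000 midpoint quadrature of
the exact two-bee posterior; trend recovery uses 7 synthetic group sizes ×
800 trials (alternative) and 100 replicates of 5 sizes × 150 trials
(null). These sizes were chosen so the whole suite runs in a few minutes
while keeping every stochastic bound at three standard errors or better.

## Known limitations

* The symbolic route is exponential in monomial count; it is a
  verification and export tool, not the computational path.
* The weighted-R² reconstruction is one defensible reading of
  "sensitivity-weighted residuals"; other normalisations would shift the
  weighted R² by a few percentage points.
* The MH sampler is a basic scheme (no adaptation, no tempering); for the
  10-parameter agnostic model at small N it mixes slowly and long chains
  are needed for stable tail quantiles.
* Printed per-size correlation values from external datasets are not
  reproducible from bundled data; the trend machinery is validated on
  synthetic studies instead.
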