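# stingcascade

Exact inference for honeybee collective stinging from end-point counts.

When a honeybee colony defends against a vertebrate intruder, each sting
releases one unit of sting alarm pheromone (SAP) that recruits further
bees, producing a chain reaction. In arena experiments only the *outcome* of
this cascade is observable: the number of stingers left in a dummy predator
at the end of a trial. `stingcascade` links that group-level observable to
the individual-level dose-response — the probability `r_k` that a single bee
stings when `k` stings have already occurred — and infers `r_0 ≤ r_1 ≤ … ≤
r_{n-1}` from repeated trials with groups of `n` bees.

## The model

Each trial is a discrete-time cascade: at step 0 every bee stings
independently with probability `r_0`; after each step that produced at least
one new sting, every remaining bee (which last declined at level `c`) stings
with the conditional probability `(r_k − r_c)/(1 − r_c)`, where `k` is the
current sting count; the trial absorbs when a step yields no new sting. The
terminal count `K(∞) ∈ {0..n}` has an exact distribution computed by a
dynamic programme over (remaining bees, last-declined level) — for `n = 2`
it is the closed form

```
P(K=0) = (1 − r0)²,  P(K=1) = 2 r0 (1 − r1),  P(K=2) = r0² + 2 r0 (r1 − r0).
```

The same distribution is available as exact-rational polynomials
`f_k(r_0..r_{n-1})`, one per terminal outcome class, via a fraction-free
version of the recursion.

On top of the forward model the package provides:

* **Shape hypotheses** — agnostic (`n` free monotone parameters), linear
  (`r_i = r_0 + i·Δ`) and sigmoidal (Hill curve
  `r_i = r_0 + (V_max − r_0)/(1 + (K_m/i)^{n_H})`).
* **Fitting** — multi-start least-squares on outcome frequencies, and
  random-walk Metropolis-Hastings on the exact multinomial likelihood for
  credible intervals.
* **Model selection** — AIC (`n·log(RSS/n) + 2k`) across three fit
  variants, plus R² validation and residual normality diagnostics.
* **Group-size trends** — independent per-size fits and Pearson tests of
  slope/intercept/`r_0` against group size.
* **Synthetic data** — seed-reproducible generators for every pipeline
  stage, with provenance records.

## Worked example

```python
>>> import stingcascade as sc
>>> data = sc.fig2_counts()          # bundled 92-trial table for groups of 10
>>> data.counts
(22, 14, 19, 11, 4, 10, 8, 2, 2, 0, 0)
>>> fit = sc.l2_fit(data, "linear", sc.FitConfig(restarts=8, seed=0))
>>> [round(v, 4) for v in fit.shape.theta]
[0.1385, 0.0566]
>>> report = sc.compare_models(data, config=sc.FitConfig(restarts=8, seed=0))
>>> report.selected
'linear'
>>> round(100 * report.r2_unweighted, 1)
92.6
```

Reading: the best-fitting linear dose-response starts at a basal sting
probability of about 0.14 and gains about 0.057 per unit of alarm pheromone;
the linear model beats the sigmoidal one on AIC in all three fit variants,
and explains ~93% of the variance of the shape-free parameter estimates
(~95% with sensitivity-weighted residuals).

The same pipeline is scriptable from the shell:

```bash
stingcascade functions -n 2                 # the closed-form polynomials
stingcascade select --input counts.csv      # AIC comparison + R²
stingcascade mcmc --input counts.csv --shape linear --init 0.2,0.05 \
    --iterations 100000 --seed 1 --trace-csv trace.csv
```

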