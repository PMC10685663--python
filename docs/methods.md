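# Methods

## The model

`splinesurv` estimates long-term survival by synthesising two kinds of
evidence in one Bayesian model: right-censored individual-level survival
times (typically a clinical trial), and aggregate "external" counts stating
that of `n_j` people alive at time `u_j`, `r_j` survived to `v_j` (registry
tables, population life tables, or elicited judgements converted to
pseudo-counts).

The baseline hazard is an M-spline:

    h(t) = eta * sum_{i=1..n} p_i b_i(t),      sum_i p_i = 1,  p_i > 0

where the basis functions `b_i` are non-negative polynomial splines (cubic
by default) on a knot grid, so any non-negative weighting is a valid hazard.
The basis is built from B-splines via `M_i(t) = k B_i(t) / (t_{i+k} - t_i)`
(order `k` = degree + 1, boundary knots repeated to multiplicity `k`), which
gives `n = internal knots + degree + 1` functions, each integrating to one
over the boundary interval. The last basis term is held constant beyond the
upper boundary knot, so extrapolated hazards are flat (exponential tail)
unless a mechanism says otherwise; the cumulative hazard uses the integrated
(I-spline) basis, whose last column continues linearly there.

Because B-splines sum to one, the weight vector proportional to the knot
spans `(t_{i+k} - t_i)` makes the hazard exactly constant; these
constant-hazard weights anchor both the prior and several exact reductions
used in the tests (with them the model *is* the exponential distribution,
to machine precision).

### Covariate effects

Proportional hazards act on the scale, `eta(x) = eta0 exp(beta'x)`.
Non-proportional effects act on the weights through a multinomial logit,
`log(p_i(x)/p_1(x)) = gamma_i + delta_i'x`, letting the hazard ratio differ
in each region of time. A hierarchical prior `delta_is ~ Normal(0, tau_s)`
partially pools the per-region departures; `gamma_i ~ Logistic(mu_i, sigma)`
with `mu` set to the constant-hazard weights' logits, so `sigma` is a
smoothness dial: `sigma = 0` forces a constant hazard, values near 1 let the
data drive the shape. The Logistic prior on `gamma_i(x)` with a covariate
shift is implemented as fixed-effect shifts on the logit scale — the only
reading under which `gamma` stays a finite parameter vector.

### Mechanisms

* **Additive background (relative survival).** `h = h_b + h_c` with `h_b`
  known and piecewise constant; survivals multiply. `S_b` is computed
  exactly (rate × interval overlap), no quadrature.
* **Mixture cure.** `S = p + (1-p) S_0`, applied either to the overall model
  or to the excess hazard inside the additive mechanism (cure on the overall
  hazard combined with a background table is rejected as incoherent). The
  equivalent decreasing-hazard form `h = (1-p) f_0 / (p + (1-p) S_0)` is
  what the hazard functions return; the two algebraic forms agree to 1e-10
  on a grid in the tests.
* **Treatment-effect waning.** Applied at prediction only, never in the
  likelihood: the model is fitted first, then the treated hazard is
  `h(t|x=0) * hr(t)` where `log hr(t)` declines linearly from its fitted
  value at `t_min` to zero at `t_max`. With an additive background the
  "fitted hazard ratio" is anchored at the overall hazard ratio at `t_min`
  (which reduces to `exp(beta)` for pure proportional hazards), and for
  `t <= t_min` the fitted model's own treated hazard is used, so the
  prediction is exactly the no-waning prediction up to `t_min`. For
  non-proportional models the anchor time is `t_min` (the choice is
  otherwise unidentified).

### Likelihood and priors

Individual rows contribute `d log h(t|x) - H(t|x)`; external rows contribute
a binomial log-kernel with success probability `q_j = S(v_j|x_j)/S(u_j|x_j)`
(survival over the interval conditional on being alive at its start). The
binomial coefficient uses log-gamma functions so real-valued counts are
accepted — needed because an elicited Beta(a, b) judgement converts to
pseudo-data `r = a, n = a + b` with possibly non-integer shapes. The
conversion treats the elicited Beta as the posterior from a vague Beta(0, 0)
prior; it is an exact round trip (`r, n - r` back to `a, b`).

Default priors (all user-overridable): `log eta0 ~ Normal(0, 20)`,
`beta ~ Normal(0, 2.5)`, `sigma ~ Gamma(2, 1)`, `tau_s ~ Gamma(2, 1)`
(no standard reference exists for the `tau` hyperprior; mirroring `sigma`'s
default is this package's choice), `cure_p ~ Beta(1, 1)`.

### Prior calibration

`sigma` is hard to interpret directly, so `prior_hazard_sim` simulates
hazard curves from the joint prior on a 100-point grid from zero to the
highest knot, and summarises each by the variability ratio
`rho = q90 / q10` of its values (linear-interpolation quantiles).
`calibrate_sigma` searches Gamma hyperparameters so the implied prior on
`rho` has a requested median and upper quantile (defaults: median 2, 97.5%
point 16). The search uses common random numbers — fixed uniform deviates
mapped through the Gamma quantile function — so the simulated objective is
smooth and a coarse grid plus Nelder-Mead converges reliably.
`calibrate_eta` does the analogous search for the Normal prior on
`log eta0`, targeting prior quantiles of restricted mean survival (the
original procedure for this calibration is not published, so a
simulation-based search mirroring the `rho` calibration is used).

## Sampling

The posterior is explored with an affine-invariant ensemble sampler (emcee)
on an unconstrained parameterisation (`log sigma`, `log tau`, logit cure
probability, with Jacobian terms). Ensemble methods suit this model: the
dimension is modest (about `n + covariates + 2`) and the likelihood for the
whole walker ensemble is evaluated at once using spline design matrices
precomputed at the observed times, so one fit costs a few thousand small
dense matrix products. The `gamma` block is sampled directly on the centred
parameterisation. Walkers are initialised near the constant-hazard fit at
the crude event rate, warmup steps are discarded, and the ensemble is
partitioned into groups treated as chains for split-R-hat and effective
sample size (via ArviZ); R-hat above 1.1 raises a warning, not an error.
Fits are bit-reproducible given a seed. Defaults are 4 chains, 1000 warmup
and 1000 kept ensemble steps; the test-suite and acceptance runs use
400-800 steps with 14-30 walkers, which this model's scale supports — the
reported diagnostics make the Monte Carlo quality auditable in every run.

Model comparison uses Pareto-smoothed importance-sampling leave-one-out
cross-validation (`arviz.loo`) on the pointwise log-likelihood, with
`LOOIC = -2 * sum(elpd_i)`. Each external aggregate row counts as one
observation unit by default — well-defined for real-valued counts;
`looic(post, external=...)` instead expands integer-count rows into their
`n` Bernoulli event indicators.

## Outputs

All summaries are draw-wise: quantities (survival, hazard, RMST,
incremental RMST) are computed per posterior draw and then summarised by the
median and equal-tailed credible interval — never by plugging parameter
quantiles into the model. RMST integrates each draw's survival curve by
composite Gauss-Legendre quadrature (100 nodes per knot-delimited segment,
with extra breakpoints at the waning window); incremental RMST is
differenced per draw so between-arm posterior correlation is preserved.
Kaplan-Meier reference curves come from lifelines and are checked against a
direct product-limit computation in the tests. Tables are tidy:
one row per (quantity, time, profile).

## Synthetic data

`simulate_individual` inverts the model's own survivor function by
vectorised bisection (tolerance 1e-10), so any mechanism combination is
simulable from exactly the process the model assumes; cured individuals
(target quantile below the survival floor) must be removed by the stated
administrative censoring. `simulate_external` draws binomial survivor counts
row-independently.

`fixture_cetuximab_like` is a synthetic stand-in for a typical oncology
evidence base: a 400-patient two-arm trial followed for 5 years, annual
control-arm registry counts of 500 at risk from 5 to 25 years, and a
background mortality table rising from 0.01 to 0.07 per year by age band.
The true excess hazard is `0.03 + 0.30 exp(-t/1.5)` projected onto the
spline basis (non-negative least squares), and treatment multiplies the
excess hazard by 0.7. These sizes mirror the scale of the case this kind of
model is built for; the generating truth ships with the data so recovery is
checkable. What passing recovery tests on this fixture shows is that the
pipeline estimates long-horizon RMST with honest uncertainty *when the
model class contains the truth*; it does not certify behaviour under real
data pathologies (covariate-dependent censoring, registry/trial population
drift, misspecified background tables).

## Numerical choices and edge cases

* Basis evaluation at knots is right-continuous; times beyond the boundary
  clip to the boundary for the M-spline and continue linearly for the
  I-spline.
* Duplicate default knots (heavily tied event times) are collapsed with a
  warning; an empty event-time vector is an error.
* `q_j` is clipped to [0, 1] before the binomial kernel; `S(u_j) = 0` is an
  error ("no survivors possible at interval start").
* `rho` is infinite (and flagged by the caller) when the 10% quantile of a
  prior curve is exactly zero.
* Softmax weights subtract the row maximum before exponentiation; the
  implicit first logit is zero.
* Very long RMST horizons extrapolate the constant-hazard tail; with a cure
  mechanism and vanishing boundary excess hazard the unrestricted mean does
  not exist, so only restricted means are exposed.

## Known limitations

* No left truncation, interval censoring, or time-varying covariates.
* Cure probability cannot depend on covariates.
* The ensemble sampler mixes more slowly than gradient-based samplers on
  strongly correlated posteriors (e.g. hierarchical non-proportional models
  with many covariates); watch the reported R-hat/ESS and increase steps.
* Knot choice remains the user's responsibility beyond the quantile default;
  LOOIC comparisons support, but do not automate, that choice.
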