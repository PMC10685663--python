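# splinesurv

Bayesian survival extrapolation with flexible M-spline hazards and external
aggregate data.

Health-policy decisions often hinge on *long-term* survival estimated from
*short-term* trial follow-up. Fitting a parametric curve to five years of
data and reading off year twenty is an assumption, not an estimate.
`splinesurv` instead represents every available source of evidence in one
Bayesian model:

* **individual-level right-censored survival times** (e.g. a trial arm),
* any number of **aggregate external datasets** — rows of the form
  "of `n_j` alive at `u_j`, `r_j` survived to `v_j`" — covering disease
  registries, population life tables, and **elicited judgements** (a
  Beta(a, b) belief about a survival probability converts exactly to
  pseudo-counts `r = a`, `n = a + b`),
* an optional known piecewise-constant **background hazard** (additive
  hazards / relative survival),
* optional **mixture cure** and **treatment-effect waning** mechanisms.

The hazard is an M-spline — a positive weighted sum of polynomial basis
functions,

    h(t | x) = eta(x) * Σᵢ pᵢ(x) bᵢ(t),        Σᵢ pᵢ(x) = 1,

with proportional covariate effects on the scale
(`eta(x) = eta₀ exp(β'x)`) and, optionally, non-proportional effects on the
weights through multinomial-logistic regression. A hierarchical prior
`γᵢ ~ Logistic(μᵢ, σ)` shrinks the weights toward an exactly constant
hazard, so the fitted flexibility is learned from the data: extrapolations
are confident only where some data source (or stated judgement) makes them
so. Decision-relevant outputs — survival, hazard, restricted mean survival
time (RMST = ∫₀ᵀ S(t) dt) and between-arm RMST differences — are computed
draw-wise with full posterior uncertainty. See `docs/methods.md` for the
model in detail.

## Worked example

A synthetic scenario bundled with the package mimics a typical oncology
evidence base: a 400-patient two-arm trial censored at 5 years, annual
registry survivor counts for the control arm from 5 to 25 years, and a
background mortality table — with the generating truth included.

```python
import numpy as np
from splinesurv import (
    ModelSpec, default_knots, fit, fixture_cetuximab_like,
    irmst, looic, rmst,
)

scenario = fixture_cetuximab_like(seed=7)
trial, registry = scenario["individual"], scenario["external"]

knots = default_knots(trial.event_times, n_basis=10,
                      extra_knots=[10, 15, 20], upper_boundary=25)
spec = ModelSpec(knots=knots, ph_covariates=("treat",),
                 background=scenario["background"])
post = fit(trial, registry, spec, chains=4, warmup=800, draws=600, seed=1)

print("max R-hat:", round(post.diagnostics["rhat"].max(), 3))
print(rmst(post, 20, {"treat": 0.0}).round(2).to_string(index=False))
print(irmst(post, 20, {"treat": 1.0}, {"treat": 0.0}).round(2).to_string(index=False))
print("LOOIC:", round(looic(post)["looic"], 1))
print("truth rmst20 control:", round(scenario["rmst20_control"], 2))
```

prints

```
max R-hat: 1.09
quantity  time profile  median  lower  upper
    rmst    20 treat=0    8.91    8.0   9.94
quantity  time            profile  median  lower  upper
   irmst    20 treat=1 vs treat=0    3.18   1.21   5.01
LOOIC: 1119.2
truth rmst20 control: 9.08
```

The 20-year restricted mean for the control arm is estimated at 8.9 years
(95% credible interval 8.0 to 9.9), covering the known truth 9.08 — an
interval this narrow at a 20-year horizon is only possible because the
registry rows inform the 5-to-25-year hazard; refitting without them
roughly triples the interval width. The incremental RMST row says treatment
adds about 3.2 years of restricted mean survival. To ask "what if the
treatment effect wanes after the trial?", pass a waning window at
prediction time:

```python
from splinesurv import WaningSpec
irmst(post, 20, {"treat": 1.0}, {"treat": 0.0},
      waning=WaningSpec(t_min=5, t_max=6, treatment="treat"))
```

which shrinks the incremental estimate, since the treated hazard ratio is
interpolated log-linearly to 1 between years 5 and 6.

## Command line

The same pipeline is scriptable from a YAML config (see
`tests/test_cli.py` for a complete one):

```sh
splinesurv simulate         --config config.yaml   # synthetic data + truth
splinesurv fit              --config config.yaml   # draws, diagnostics, loglik
splinesurv summarise        --config config.yaml   # tidy CSV summary tables
splinesurv calibrate-priors --config config.yaml   # smoothness prior search
```

Every run records its seed, config hash and package versions in a metadata
JSON; re-running with the same config and seed reproduces outputs
bit-identically.

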