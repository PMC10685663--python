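"""Hazard, survival, likelihood and prior for the M-spline survival model.

The baseline hazard is ``h(t) = eta * sum_i p_i b_i(t)`` where ``b_i`` is the
M-spline basis and the weights ``p_i`` sum to one.  Covariates act on the
scale (proportional hazards, ``eta(x) = eta0 exp(beta' x)``) and, optionally,
on the weights through a multinomial-logit model
``log(p_i(x)/p_1(x)) = gamma_i + delta_i' x`` which allows the hazard ratio
to vary over time (non-proportional hazards).  On top of this core, three
mechanisms may be switched on:

* additive background hazard (relative survival): ``h = h_b + h_c`` with
  ``h_b`` known and piecewise constant, survivals multiply;
* mixture cure: ``S = p + (1 - p) S_0``, applied to the overall model or to
  the excess hazard inside the additive mechanism;
* treatment-effect waning: the treated/control hazard ratio interpolates
  log-linearly to one over a stated window.  Waning is a prediction-time
  adjustment only; it never enters the likelihood.

Priors: ``gamma_i ~ Logistic(mu_i, sigma)`` with ``mu`` chosen so the prior
mean weights give a constant hazard, ``log eta0 ~ Normal(0, 20)``,
``beta ~ Normal(0, 2.5)``, ``sigma ~ Gamma(2, 1)``,
``delta_is ~ Normal(0, tau_s)`` with ``tau_s ~ Gamma(2, 1)``, and a Beta
prior on the cure probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .data_model import BackgroundHazard, ExternalData, IndividualData
from .spline_basis import KnotSet, constant_hazard_coefs, ispline_eval, mspline_eval

__all__ = [
    "PriorSpec",
    "WaningSpec",
    "ModelSpec",
    "ParameterDraw",
    "coefficients",
    "hazard",
    "cumhaz",
    "survival",
    "cure_survival",
    "cure_hazard",
    "additive_combine",
    "waning_hr",
    "loglik_individual",
    "loglik_external",
    "logprior",
    "constant_logit_means",
]


@dataclass(frozen=True)
class PriorSpec:
    """Prior hyperparameters (location/scale or shape/rate pairs)."""

    log_eta0: tuple[float, float] = (0.0, 20.0)  # Normal(mean, sd)
    beta_sd: float = 2.5  # Normal(0, sd) per log hazard ratio
    sigma: tuple[float, float] = (2.0, 1.0)  # Gamma(shape, rate)
    tau: tuple[float, float] = (2.0, 1.0)  # Gamma(shape, rate)
    cure: tuple[float, float] = (1.0, 1.0)  # Beta(a, b)

    def to_dict(self) -> dict:
        return {
            "log_eta0": list(self.log_eta0),
            "beta_sd": self.beta_sd,
            "sigma": list(self.sigma),
            "tau": list(self.tau),
            "cure": list(self.cure),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PriorSpec":
        kw = {}
        for k in ("log_eta0", "sigma", "tau", "cure"):
            if k in d:
                kw[k] = tuple(d[k])
        if "beta_sd" in d:
            kw["beta_sd"] = float(d["beta_sd"])
        return cls(**kw)


@dataclass(frozen=True)
class WaningSpec:
    """Treatment-effect waning window: the log hazard ratio of the treatment
    covariate declines linearly from its fitted value at ``t_min`` to zero at
    ``t_max``."""

    t_min: float
    t_max: float
    treatment: str

    def __post_init__(self):
        if not 0 < self.t_min < self.t_max:
            raise ValueError("need 0 < t_min < t_max")

    def to_dict(self) -> dict:
        return {"t_min": self.t_min, "t_max": self.t_max, "treatment": self.treatment}

    @classmethod
    def from_dict(cls, d: dict) -> "WaningSpec":
        return cls(float(d["t_min"]), float(d["t_max"]), str(d["treatment"]))


@dataclass(frozen=True)
class ModelSpec:
    """Model structure: knots, covariate roles, mechanisms and priors."""

    knots: KnotSet
    ph_covariates: tuple[str, ...] = ()
    nonph_covariates: tuple[str, ...] = ()
    background: BackgroundHazard | None = None
    cure: str = "none"  # "none" | "overall" | "excess"
    waning: WaningSpec | None = None
    priors: PriorSpec = field(default_factory=PriorSpec)

    def __post_init__(self):
        object.__setattr__(self, "ph_covariates", tuple(self.ph_covariates))
        object.__setattr__(self, "nonph_covariates", tuple(self.nonph_covariates))
        if self.cure not in ("none", "overall", "excess"):
            raise ValueError("cure must be 'none', 'overall' or 'excess'")
        if self.cure == "excess" and self.background is None:
            raise ValueError("cure on the excess hazard requires a background hazard")
        if self.cure == "overall" and self.background is not None:
            raise ValueError(
                "with a background hazard, apply cure to the excess hazard"
            )
        if self.waning is not None and self.waning.treatment not in (
            self.ph_covariates + self.nonph_covariates
        ):
            raise ValueError("waning treatment covariate must be in the model")

    @property
    def n_basis(self) -> int:
        return self.knots.n_basis

    @property
    def has_cure(self) -> bool:
        return self.cure != "none"

    def to_dict(self) -> dict:
        d = {
            "knots": self.knots.to_dict(),
            "ph_covariates": list(self.ph_covariates),
            "nonph_covariates": list(self.nonph_covariates),
            "cure": self.cure,
            "priors": self.priors.to_dict(),
        }
        if self.background is not None:
            d["background"] = {
                "breakpoints": self.background.breakpoints.tolist(),
                "rates": self.background.rates.tolist(),
            }
        if self.waning is not None:
            d["waning"] = self.waning.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        bg = d.get("background")
        wn = d.get("waning")
        return cls(
            knots=KnotSet.from_dict(d["knots"]),
            ph_covariates=tuple(d.get("ph_covariates", ())),
            nonph_covariates=tuple(d.get("nonph_covariates", ())),
            background=BackgroundHazard(bg["breakpoints"], bg["rates"]) if bg else None,
            cure=d.get("cure", "none"),
            waning=WaningSpec.from_dict(wn) if wn else None,
            priors=PriorSpec.from_dict(d.get("priors", {})),
        )


@dataclass
class ParameterDraw:
    """One realisation of the model parameters.

    ``gamma`` holds the baseline logit weights for basis terms 2..n
    (``gamma_1 = 0`` is implicit); ``delta`` is (n-1, n_nonph) with the same
    convention for its implicit first row.
    """

    log_eta0: float
    gamma: np.ndarray
    sigma: float
    beta: np.ndarray = field(default_factory=lambda: np.zeros(0))
    delta: np.ndarray | None = None
    tau: np.ndarray | None = None
    cure_p: float | None = None

    def __post_init__(self):
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.delta is not None:
            self.delta = np.atleast_2d(np.asarray(self.delta, dtype=float))
        if self.tau is not None:
            self.tau = np.atleast_1d(np.asarray(self.tau, dtype=float))
            if np.any(self.tau <= 0):
                raise ValueError("tau must be positive")
        if self.cure_p is not None and not 0 <= self.cure_p <= 1:
            raise ValueError("cure_p must be in [0, 1]")


# ---------------------------------------------------------------------------
# Covariate plumbing


def _x_vector(names: tuple[str, ...], x) -> np.ndarray:
    if not names:
        return np.zeros(0)
    if x is None:
        return np.zeros(len(names))
    if isinstance(x, dict):
        missing = [n for n in names if n not in x]
        if missing:
            raise ValueError(f"profile missing covariates: {missing}")
        return np.array([float(x[n]) for n in names])
    return np.atleast_1d(np.asarray(x, dtype=float))


def _design(names: tuple[str, ...], cov: pd.DataFrame, nrow: int) -> np.ndarray:
    if not names:
        return np.zeros((nrow, 0))
    missing = [n for n in names if n not in cov.columns]
    if missing:
        raise ValueError(f"data missing model covariates: {missing}")
    return cov[list(names)].to_numpy(dtype=float)


def constant_logit_means(knots: KnotSet) -> np.ndarray:
    """Logit-scale locations ``mu_i = log(p_i / p_1)`` (i = 2..n) of the
    constant-hazard weights; the prior mean of ``gamma``."""
    p, _ = constant_hazard_coefs(knots)
    return np.log(p[1:] / p[0])


def _softmax0(logits: np.ndarray) -> np.ndarray:
    """Softmax over the last axis with an implicit leading zero entry."""
    full = np.concatenate(
        [np.zeros(logits.shape[:-1] + (1,)), logits], axis=-1
    )
    full -= full.max(axis=-1, keepdims=True)
    e = np.exp(full)
    return e / e.sum(axis=-1, keepdims=True)


def coefficients(draw: ParameterDraw, x, spec: ModelSpec) -> np.ndarray:
    """Spline weights p(x): softmax of (0, gamma_i + delta_i' x_nonph)."""
    logits = np.asarray(draw.gamma, dtype=float)
    if logits.shape[-1] != spec.n_basis - 1:
        raise ValueError("gamma length must be n_basis - 1")
    if spec.nonph_covariates:
        if draw.delta is None:
            raise ValueError("non-PH covariates declared but draw has no delta")
        xn = _x_vector(spec.nonph_covariates, x)
        if draw.delta.shape != (spec.n_basis - 1, len(spec.nonph_covariates)):
            raise ValueError("delta must be (n_basis - 1, n_nonph_covariates)")
        logits = logits + draw.delta @ xn
    return _softmax0(logits)


def _eta(draw: ParameterDraw, x, spec: ModelSpec) -> float:
    xp = _x_vector(spec.ph_covariates, x)
    if xp.size != len(spec.ph_covariates):
        raise ValueError("covariate vector does not match ph_covariates")
    return float(np.exp(draw.log_eta0 + (draw.beta[: xp.size] @ xp if xp.size else 0.0)))


def _check_times(t) -> np.ndarray:
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    return t


def _core_hazard(t, draw, x, spec):
    t = _check_times(t)
    p = coefficients(draw, x, spec)
    B = mspline_eval(spec.knots, t).values
    return _eta(draw, x, spec) * (B @ p)


def _core_cumhaz(t, draw, x, spec):
    t = _check_times(t)
    p = coefficients(draw, x, spec)
    I = ispline_eval(spec.knots, t).values
    return _eta(draw, x, spec) * (I @ p)


def cure_survival(t, draw, x, spec) -> np.ndarray:
    """Mixture-cure survival ``p + (1 - p) S_0(t)`` over the spline model."""
    if draw.cure_p is None:
        raise ValueError("cure mechanism requires cure_p in the draw")
    S0 = np.exp(-_core_cumhaz(t, draw, x, spec))
    return draw.cure_p + (1 - draw.cure_p) * S0


def cure_hazard(t, draw, x, spec) -> np.ndarray:
    """Mixture-cure hazard ``(1 - p) f_0(t) / (p + (1 - p) S_0(t))``; the
    population hazard declines to zero as survival approaches the cure
    fraction."""
    if draw.cure_p is None:
        raise ValueError("cure mechanism requires cure_p in the draw")
    H0 = _core_cumhaz(t, draw, x, spec)
    S0 = np.exp(-H0)
    f0 = _core_hazard(t, draw, x, spec) * S0
    return (1 - draw.cure_p) * f0 / (draw.cure_p + (1 - draw.cure_p) * S0)


def additive_combine(t, background: BackgroundHazard, excess_hazard=None,
                     excess_survival=None):
    """Combine a known background with an excess (disease-specific) component:
    hazards add, survivals multiply.  Returns whichever of (hazard, survival)
    was supplied, combined."""
    t = _check_times(t)
    out = []
    if excess_hazard is not None:
        out.append(background.hazard(t) + np.asarray(excess_hazard, dtype=float))
    if excess_survival is not None:
        out.append(background.survival(t) * np.asarray(excess_survival, dtype=float))
    if len(out) == 1:
        return out[0]
    return tuple(out)


def hazard(t, draw: ParameterDraw, x, spec: ModelSpec) -> np.ndarray:
    """Overall hazard with mechanisms applied (cure, then background)."""
    if spec.cure == "overall":
        return cure_hazard(t, draw, x, spec)
    if spec.cure == "excess":
        h_exc = cure_hazard(t, draw, x, spec)
    else:
        h_exc = _core_hazard(t, draw, x, spec)
    if spec.background is not None:
        return additive_combine(t, spec.background, excess_hazard=h_exc)
    return h_exc


def survival(t, draw: ParameterDraw, x, spec: ModelSpec) -> np.ndarray:
    """Overall survivor function with mechanisms applied."""
    if spec.cure == "overall":
        return cure_survival(t, draw, x, spec)
    if spec.cure == "excess":
        S_exc = cure_survival(t, draw, x, spec)
    else:
        S_exc = np.exp(-_core_cumhaz(t, draw, x, spec))
    if spec.background is not None:
        return additive_combine(t, spec.background, excess_survival=S_exc)
    return S_exc


def cumhaz(t, draw: ParameterDraw, x, spec: ModelSpec) -> np.ndarray:
    """Overall cumulative hazard, ``-log S(t)`` (computed analytically)."""
    if not spec.has_cure:
        H = _core_cumhaz(t, draw, x, spec)
        if spec.background is not None:
            H = H + spec.background.cumhaz(_check_times(t))
        return H
    with np.errstate(divide="ignore"):
        return -np.log(survival(t, draw, x, spec))


def waning_hr(t, hr_tmin: float, w: WaningSpec) -> np.ndarray:
    """Time-dependent hazard ratio under waning: equal to ``hr_tmin`` up to
    ``t_min``, one from ``t_max``, log-linear in between."""
    if hr_tmin <= 0:
        raise ValueError("hazard ratio must be positive")
    t = np.atleast_1d(np.asarray(t, dtype=float))
    frac = np.clip((w.t_max - t) / (w.t_max - w.t_min), 0.0, 1.0)
    return np.exp(np.log(hr_tmin) * frac)


# ---------------------------------------------------------------------------
# Likelihood


def loglik_individual(data: IndividualData, draw: ParameterDraw,
                      spec: ModelSpec) -> np.ndarray:
    """Per-observation log-likelihood: ``d log h(t|x) - H(t|x)``."""
    h = _rowwise_hazard(data.time, data.covariates, draw, spec, cumulative=False)
    H = _rowwise_hazard(data.time, data.covariates, draw, spec, cumulative=True)
    with np.errstate(divide="ignore"):
        ll = data.event * np.log(h) - H
    return ll


def _rowwise_hazard(times, cov, draw, spec, cumulative):
    """Evaluate h or H at per-row times with per-row covariates."""
    func = cumhaz if cumulative else hazard
    t = np.asarray(times, dtype=float)
    names = tuple(dict.fromkeys(spec.ph_covariates + spec.nonph_covariates))
    if not names:
        return func(t, draw, None, spec)
    X = _design(names, cov, len(t))
    out = np.empty(len(t))
    _, inv = np.unique(X, axis=0, return_inverse=True)
    for g in np.unique(inv):
        rows = inv == g
        x = dict(zip(names, X[rows][0]))
        out[rows] = func(t[rows], draw, x, spec)
    return out


def loglik_external(data: ExternalData, draw: ParameterDraw,
                    spec: ModelSpec) -> np.ndarray:
    """Per-row binomial log-likelihood of surviving (u, v] given alive at u.

    Success probability ``q = S(v|x) / S(u|x)``; the binomial coefficient is
    evaluated with log-gamma functions so real-valued counts are accepted.
    """
    Su = _rowwise_hazard(data.u, data.covariates, draw, spec, cumulative=True)
    Sv = _rowwise_hazard(data.v, data.covariates, draw, spec, cumulative=True)
    Su, Sv = np.exp(-Su), np.exp(-Sv)
    if np.any(Su <= 0):
        raise ValueError("no survivors possible at interval start")
    q = np.clip(Sv / Su, 0.0, 1.0)
    return binomial_logpmf(data.r, data.n, q)


def binomial_logpmf(r, n, q) -> np.ndarray:
    """Binomial log-pmf with the log-gamma (real-valued count) coefficient."""
    r = np.asarray(r, dtype=float)
    n = np.asarray(n, dtype=float)
    q = np.asarray(q, dtype=float)
    coef = special.gammaln(n + 1) - special.gammaln(r + 1) - special.gammaln(n - r + 1)
    return coef + special.xlogy(r, q) + special.xlog1py(n - r, -q)


# ---------------------------------------------------------------------------
# Prior


def logprior(draw: ParameterDraw, spec: ModelSpec) -> float:
    """Joint log prior density of a draw under the spec's priors."""
    if draw.sigma <= 0:
        return -np.inf
    pr = spec.priors
    mu = constant_logit_means(spec.knots)
    lp = stats.logistic.logpdf(draw.gamma, loc=mu, scale=draw.sigma).sum()
    lp += stats.norm.logpdf(draw.log_eta0, pr.log_eta0[0], pr.log_eta0[1])
    lp += stats.gamma.logpdf(draw.sigma, pr.sigma[0], scale=1 / pr.sigma[1])
    if len(spec.ph_covariates):
        lp += stats.norm.logpdf(draw.beta[: len(spec.ph_covariates)], 0,
                                pr.beta_sd).sum()
    if len(spec.nonph_covariates):
        if draw.delta is None or draw.tau is None:
            raise ValueError("non-PH model requires delta and tau in the draw")
        if np.any(draw.tau <= 0):
            return -np.inf
        lp += stats.norm.logpdf(draw.delta, 0, draw.tau[None, :]).sum()
        lp += stats.gamma.logpdf(draw.tau, pr.tau[0], scale=1 / pr.tau[1]).sum()
    if spec.has_cure:
        if draw.cure_p is None:
            raise ValueError("cure mechanism requires cure_p in the draw")
        lp += stats.beta.logpdf(draw.cure_p, pr.cure[0], pr.cure[1])
    return float(lp)
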