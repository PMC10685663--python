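import numpy as np
import pytest

from splinesurv import (
    IndividualData,
    KnotSet,
    ModelSpec,
    ParameterDraw,
    constant_hazard_coefs,
    default_knots,
)
from splinesurv.model_core import constant_logit_means


@pytest.fixture(scope="session")
def knots():
    """Small cubic knot set used across unit tests."""
    return KnotSet(internal_knots=(1.0, 2.0, 3.0), upper_boundary=5.0)


@pytest.fixture(scope="session")
def spec(knots):
    return ModelSpec(knots=knots)


@pytest.fixture(scope="session")
def constant_draw(knots):
    """Draw whose hazard is exactly 0.2 everywhere."""
    _, c = constant_hazard_coefs(knots)
    return ParameterDraw(
        log_eta0=np.log(0.2 / c), gamma=constant_logit_means(knots), sigma=1.0
    )


@pytest.fixture(scope="session")
def wiggly_draw(knots):
    """Draw with clearly non-constant hazard."""
    rng = np.random.default_rng(42)
    mu = constant_logit_means(knots)
    return ParameterDraw(
        log_eta0=0.3, gamma=mu + rng.normal(0, 1.2, mu.size), sigma=1.0
    )


@pytest.fixture(scope="session")
def exponential_data():
    """n=200 exponential(0.2) survival with ~20% independent censoring."""
    rng = np.random.default_rng(7)
    t = rng.exponential(1 / 0.2, 200)
    c = rng.exponential(1 / 0.05, 200)
    return IndividualData(time=np.minimum(t, c), event=(t <= c).astype(int))


@pytest.fixture(scope="session")
def fitted_fixture():
    """One joint fit of the trial+registry+background scenario, shared by
    output-summary tests (modest draw counts)."""
    import warnings

    from splinesurv import fit, fixture_cetuximab_like

    fx = fixture_cetuximab_like(seed=7)
    knots = default_knots(
        fx["individual"].event_times, n_basis=10,
        extra_knots=[10.0, 15.0, 20.0], upper_boundary=25.0,
    )
    spec_fit = ModelSpec(
        knots=knots, ph_covariates=("treat",), background=fx["background"],
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        post = fit(fx["individual"], fx["external"], spec_fit,
                   chains=4, warmup=500, draws=400, seed=11)
    return {"post": post, **fx}
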