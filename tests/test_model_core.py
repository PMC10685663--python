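import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import binom

from splinesurv import (
    BackgroundHazard,
    ExternalData,
    IndividualData,
    KnotSet,
    ModelSpec,
    ParameterDraw,
    WaningSpec,
    coefficients,
    constant_hazard_coefs,
    cumhaz,
    hazard,
    loglik_external,
    loglik_individual,
    logprior,
    survival,
    waning_hr,
)
from splinesurv.model_core import (
    constant_logit_means,
    cure_hazard,
    cure_survival,
    additive_combine,
)


class TestCoefficients:
    def test_zero_logits_give_uniform_weights(self, spec):
        d = ParameterDraw(log_eta0=0.0, gamma=np.zeros(spec.n_basis - 1),
                          sigma=1.0)
        p = coefficients(d, None, spec)
        assert np.allclose(p, 1 / spec.n_basis)

    def test_weights_normalised_for_any_draw(self, wiggly_draw, spec):
        p = coefficients(wiggly_draw, None, spec)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(p > 0)

    def test_delta_shifts_odds_multiplicatively(self, knots):
        spec_np = ModelSpec(knots=knots, nonph_covariates=("treat",))
        n = knots.n_basis
        delta = np.ones((n - 1, 1))
        base = ParameterDraw(log_eta0=0.0, gamma=np.linspace(-1, 1, n - 1),
                             sigma=1.0, delta=delta, tau=np.array([1.0]))
        p0 = coefficients(base, {"treat": 0.0}, spec_np)
        p1 = coefficients(base, {"treat": 1.0}, spec_np)
        odds0 = p0[1:] / p0[0]
        odds1 = p1[1:] / p1[0]
        assert np.allclose(odds1 / odds0, np.e)


class TestHazardSurvival:
    def test_constant_weights_give_flat_hazard(self, constant_draw, spec):
        t = np.linspace(0, 8, 50)
        assert np.allclose(hazard(t, constant_draw, None, spec), 0.2)

    def test_exponential_survival_closed_form(self, constant_draw, spec):
        t = np.linspace(0, 8, 50)
        assert np.allclose(survival(t, constant_draw, None, spec),
                           np.exp(-0.2 * t), atol=1e-8)

    def test_ph_hazard_ratio_constant_in_time(self, knots, wiggly_draw):
        spec_ph = ModelSpec(knots=knots, ph_covariates=("treat",))
        d = ParameterDraw(log_eta0=wiggly_draw.log_eta0,
                          gamma=wiggly_draw.gamma, sigma=1.0,
                          beta=np.array([-0.4]))
        t = np.array([0.5, 1.0, 4.0, 7.0])
        ratio = (hazard(t, d, {"treat": 1.0}, spec_ph)
                 / hazard(t, d, {"treat": 0.0}, spec_ph))
        assert np.allclose(ratio, np.exp(-0.4))

    def test_nonph_hazard_ratio_varies_in_time(self, knots):
        spec_np = ModelSpec(knots=knots, ph_covariates=("treat",),
                            nonph_covariates=("treat",))
        n = knots.n_basis
        rng = np.random.default_rng(3)
        d = ParameterDraw(log_eta0=0.0, gamma=constant_logit_means(knots),
                          sigma=1.0, beta=np.array([0.0]),
                          delta=rng.normal(0, 1, (n - 1, 1)),
                          tau=np.array([1.0]))
        hr = lambda t: float(hazard([t], d, {"treat": 1.0}, spec_np)[0]
                             / hazard([t], d, {"treat": 0.0}, spec_np)[0])
        assert abs(hr(1.0) - hr(4.0)) > 0.05

    def test_cumhaz_matches_quadrature(self, wiggly_draw, spec):
        for T in (2.5, 7.0):
            oracle, _ = quad(lambda s: hazard([s], wiggly_draw, None, spec)[0],
                             0, T, limit=300)
            assert cumhaz([T], wiggly_draw, None, spec)[0] == pytest.approx(
                oracle, abs=1e-6)

    def test_linear_cumhaz_beyond_boundary(self, wiggly_draw, spec, knots):
        u = knots.upper_boundary
        h_tail = hazard([u + 3.0], wiggly_draw, None, spec)[0]
        H1 = cumhaz([u + 1.0], wiggly_draw, None, spec)[0]
        H2 = cumhaz([u + 2.0], wiggly_draw, None, spec)[0]
        assert H2 - H1 == pytest.approx(h_tail, rel=1e-10)

    def test_negative_time_rejected(self, constant_draw, spec):
        with pytest.raises(ValueError):
            hazard([-1.0], constant_draw, None, spec)


class TestCure:
    def test_survival_substitution(self, knots, wiggly_draw):
        spec_c = ModelSpec(knots=knots, cure="overall")
        d = ParameterDraw(log_eta0=wiggly_draw.log_eta0,
                          gamma=wiggly_draw.gamma, sigma=1.0, cure_p=0.3)
        # find t where uncured survival is 0.5, check S = 0.3 + 0.7*0.5
        base = ModelSpec(knots=knots)
        d0 = ParameterDraw(log_eta0=d.log_eta0, gamma=d.gamma, sigma=1.0)
        from scipy.optimize import brentq
        t_half = brentq(lambda t: survival([t], d0, None, base)[0] - 0.5, 0, 50)
        assert cure_survival([t_half], d, None, spec_c)[0] == pytest.approx(
            0.3 + 0.7 * 0.5, abs=1e-10)

    def test_survival_converges_to_cure_fraction(self, knots, wiggly_draw):
        spec_c = ModelSpec(knots=knots, cure="overall")
        d = ParameterDraw(log_eta0=wiggly_draw.log_eta0,
                          gamma=wiggly_draw.gamma, sigma=1.0, cure_p=0.3)
        assert survival([1e4], d, None, spec_c)[0] == pytest.approx(0.3,
                                                                    abs=1e-6)

    def test_two_hazard_forms_agree(self, knots, wiggly_draw):
        """(1-p) f0 / (p + (1-p) S0)  ==  f0 / (p/(1-p) + S0)."""
        spec_c = ModelSpec(knots=knots, cure="overall")
        base = ModelSpec(knots=knots)
        d = ParameterDraw(log_eta0=wiggly_draw.log_eta0,
                          gamma=wiggly_draw.gamma, sigma=1.0, cure_p=0.3)
        d0 = ParameterDraw(log_eta0=d.log_eta0, gamma=d.gamma, sigma=1.0)
        t = np.linspace(0.01, 10, 200)
        S0 = survival(t, d0, None, base)
        f0 = hazard(t, d0, None, base) * S0
        alt = f0 / (0.3 / 0.7 + S0)
        assert np.allclose(cure_hazard(t, d, None, spec_c), alt, atol=1e-10)

    def test_cure_without_probability_rejected(self, knots, wiggly_draw):
        spec_c = ModelSpec(knots=knots, cure="overall")
        d = ParameterDraw(log_eta0=0.0, gamma=wiggly_draw.gamma, sigma=1.0)
        with pytest.raises(ValueError, match="cure"):
            cure_survival([1.0], d, None, spec_c)


class TestAdditive:
    def test_zero_background_is_identity(self, wiggly_draw, knots):
        bg0 = BackgroundHazard(breakpoints=[0.0], rates=[0.0])
        spec_b = ModelSpec(knots=knots, background=bg0)
        base = ModelSpec(knots=knots)
        t = np.linspace(0, 8, 30)
        assert np.array_equal(hazard(t, wiggly_draw, None, spec_b),
                              hazard(t, wiggly_draw, None, base))
        assert np.array_equal(survival(t, wiggly_draw, None, spec_b),
                              survival(t, wiggly_draw, None, base))

    def test_constant_rates_multiply_exponentials(self, knots, constant_draw):
        bg = BackgroundHazard(breakpoints=[0.0], rates=[0.02])
        spec_b = ModelSpec(knots=knots, background=bg)
        # excess constant 0.2 => overall S = exp(-0.22 t) inside the boundary
        t = np.linspace(0, 5, 20)
        assert np.allclose(survival(t, constant_draw, None, spec_b),
                           np.exp(-0.22 * t), atol=1e-10)

    def test_two_interval_background_overlap(self):
        bg = BackgroundHazard(breakpoints=[0.0, 10.0], rates=[0.01, 0.05])
        S = additive_combine([12.0], bg, excess_survival=np.array([1.0]))
        assert S[0] == pytest.approx(np.exp(-0.2))


class TestWaning:
    def test_log_linear_midpoint(self):
        w = WaningSpec(t_min=5.0, t_max=6.0, treatment="treat")
        assert waning_hr([5.5], 0.5, w)[0] == pytest.approx(np.sqrt(0.5))

    def test_unity_beyond_tmax_and_identity_before_tmin(self):
        w = WaningSpec(t_min=5.0, t_max=6.0, treatment="treat")
        assert waning_hr([7.0], 0.5, w)[0] == 1.0
        assert waning_hr([2.0], 0.5, w)[0] == 0.5
        assert np.all(waning_hr(np.linspace(0, 10, 50), 1.0, w) == 1.0)

    def test_continuous_and_monotone(self):
        w = WaningSpec(t_min=5.0, t_max=8.0, treatment="treat")
        t = np.linspace(0, 10, 1001)
        hr = waning_hr(t, 0.5, w)
        assert np.all(np.diff(hr) >= 0)
        assert np.max(np.abs(np.diff(hr))) < 0.01  # no jumps

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            WaningSpec(t_min=6.0, t_max=5.0, treatment="treat")


class TestLikelihood:
    def test_exponential_closed_forms(self, constant_draw, spec):
        data = IndividualData(time=[3.0, 2.0], event=[0, 1])
        ll = loglik_individual(data, constant_draw, spec)
        assert ll[0] == pytest.approx(-0.2 * 3.0, abs=1e-10)
        assert ll[1] == pytest.approx(np.log(0.2) - 0.2 * 2.0, abs=1e-10)

    def test_exponential_sample_total(self, constant_draw, spec):
        rng = np.random.default_rng(5)
        t = rng.exponential(5.0, 100)
        data = IndividualData(time=t, event=np.ones(100, dtype=int))
        total = loglik_individual(data, constant_draw, spec).sum()
        closed = 100 * np.log(0.2) - 0.2 * t.sum()
        assert total == pytest.approx(closed, abs=1e-8)

    def test_external_binomial_oracle(self, spec, knots):
        # constant hazard chosen so q = S(2)/S(1) = 0.75
        lam = -np.log(0.75)
        _, c = constant_hazard_coefs(knots)
        d = ParameterDraw(log_eta0=np.log(lam / c),
                          gamma=constant_logit_means(knots), sigma=1.0)
        ext = ExternalData(u=[1.0], v=[2.0], n=[4], r=[3])
        ll = loglik_external(ext, d, spec)[0]
        assert ll == pytest.approx(binom.logpmf(3, 4, 0.75), abs=1e-8)
        assert ll == pytest.approx(np.log(4 * 0.75**3 * 0.25), abs=1e-8)

    def test_all_survive_certain_interval(self, constant_draw, spec):
        # q -> 1 gives zero log-likelihood when r = n
        ext = ExternalData(u=[1.0], v=[1.0 + 1e-12], n=[5], r=[5])
        assert loglik_external(ext, constant_draw, spec)[0] == pytest.approx(
            0.0, abs=1e-10)

    def test_nonph_with_zero_delta_identical_to_ph(self, knots, exponential_data):
        spec_ph = ModelSpec(knots=knots, ph_covariates=("treat",))
        spec_np = ModelSpec(knots=knots, ph_covariates=("treat",),
                            nonph_covariates=("treat",))
        rng = np.random.default_rng(0)
        data = IndividualData(
            time=exponential_data.time, event=exponential_data.event,
            covariates={"treat": rng.integers(0, 2, len(exponential_data))
                        .astype(float)},
        )
        gamma = constant_logit_means(knots) + rng.normal(0, 0.5, knots.n_basis - 1)
        d_ph = ParameterDraw(log_eta0=-1.0, gamma=gamma, sigma=1.0,
                             beta=np.array([-0.3]))
        d_np = ParameterDraw(log_eta0=-1.0, gamma=gamma, sigma=1.0,
                             beta=np.array([-0.3]),
                             delta=np.zeros((knots.n_basis - 1, 1)),
                             tau=np.array([0.7]))
        ll_ph = loglik_individual(data, d_ph, spec_ph)
        ll_np = loglik_individual(data, d_np, spec_np)
        assert np.array_equal(ll_ph, ll_np)

    def test_cure_zero_equals_no_cure(self, knots, wiggly_draw):
        spec_c = ModelSpec(knots=knots, cure="overall")
        base = ModelSpec(knots=knots)
        d_c = ParameterDraw(log_eta0=wiggly_draw.log_eta0,
                            gamma=wiggly_draw.gamma, sigma=1.0, cure_p=0.0)
        data = IndividualData(time=[0.5, 2.0, 4.5], event=[1, 1, 0])
        assert np.allclose(loglik_individual(data, d_c, spec_c),
                           loglik_individual(data, wiggly_draw, base),
                           atol=1e-12)


class TestLogPrior:
    def test_logistic_terms_at_location(self, knots):
        spec1 = ModelSpec(knots=knots)
        mu = constant_logit_means(knots)
        d = ParameterDraw(log_eta0=0.0, gamma=mu, sigma=1.0)
        base = logprior(d, spec1)
        # each logistic term contributes log(1/4) at its location with scale 1
        from scipy.stats import gamma as gamma_dist, norm
        expected = (
            (knots.n_basis - 1) * np.log(0.25)
            + norm.logpdf(0.0, 0, 20)
            + gamma_dist.logpdf(1.0, 2, scale=1.0)
        )
        assert base == pytest.approx(expected, abs=1e-12)

    def test_doubling_sigma_at_location_costs_log2_per_term(self, knots):
        spec1 = ModelSpec(knots=knots)
        mu = constant_logit_means(knots)
        d1 = ParameterDraw(log_eta0=0.0, gamma=mu, sigma=1.0)
        d2 = ParameterDraw(log_eta0=0.0, gamma=mu, sigma=2.0)
        from scipy.stats import gamma as gamma_dist
        delta_sigma_prior = (gamma_dist.logpdf(2.0, 2, scale=1.0)
                             - gamma_dist.logpdf(1.0, 2, scale=1.0))
        diff = logprior(d2, spec1) - logprior(d1, spec1) - delta_sigma_prior
        assert diff == pytest.approx(-(knots.n_basis - 1) * np.log(2),
                                     abs=1e-12)

    def test_nonpositive_sigma_impossible(self, knots):
        d = ParameterDraw(log_eta0=0.0, gamma=np.zeros(knots.n_basis - 1),
                          sigma=1.0)
        d.sigma = -1.0  # bypass constructor validation
        assert logprior(d, ModelSpec(knots=knots)) == -np.inf


class TestMonotonicityProperties:
    @pytest.mark.parametrize("mechanism", ["base", "cure", "additive",
                                           "additive_cure"])
    def test_survival_valid_under_all_mechanisms(self, knots, mechanism):
        """S(0)=1, S non-increasing, h >= 0, and -log S == H without cure."""
        rng = np.random.default_rng(11)
        bg = BackgroundHazard(breakpoints=[0.0, 2.0], rates=[0.01, 0.03])
        spec_m = {
            "base": ModelSpec(knots=knots),
            "cure": ModelSpec(knots=knots, cure="overall"),
            "additive": ModelSpec(knots=knots, background=bg),
            "additive_cure": ModelSpec(knots=knots, background=bg,
                                       cure="excess"),
        }[mechanism]
        t = np.linspace(0, 12, 200)
        for _ in range(10):
            d = ParameterDraw(
                log_eta0=rng.normal(-1, 1),
                gamma=constant_logit_means(knots) + rng.normal(0, 1.5,
                                                               knots.n_basis - 1),
                sigma=float(rng.gamma(2, 1)),
                cure_p=float(rng.uniform()) if "cure" in mechanism else None,
            )
            S = survival(t, d, None, spec_m)
            h = hazard(t, d, None, spec_m)
            assert S[0] == pytest.approx(1.0, abs=1e-12)
            assert np.all(np.diff(S) <= 1e-12)
            assert np.all(h >= 0)
            if not spec_m.has_cure:
                assert np.allclose(-np.log(S), cumhaz(t, d, None, spec_m),
                                   atol=1e-8)
            elif mechanism == "cure":
                assert np.all(S >= d.cure_p - 1e-12)
            else:  # cure on the excess: floor is cure_p times S_background
                assert np.all(S >= d.cure_p * np.exp(-bg.cumhaz(t)) - 1e-12)
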