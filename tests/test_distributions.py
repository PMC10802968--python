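"""Distribution functions, censoring-conditional summaries, truncated sampling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, optimize, stats
from scipy.special import ndtr

from censimpute import (
    BSParams,
    WeibullParams,
    bs_pdf,
    bs_quantile,
    bs_sf,
    conditional_mean,
    conditional_median,
    conditional_pdf,
    rng_unconditional,
    sample_truncated,
    weibull_pdf_sf_hazard,
)
from censimpute.distributions import bs_cdf, conditional_sf


class TestWeibull:
    def test_survival_limits_and_median(self, weib_exp):
        _, sf0, _ = weibull_pdf_sf_hazard(1e-12, weib_exp)
        assert sf0 == pytest.approx(1.0)
        # exponential: S(t) = exp(-0.25 t), median at 4 ln 2
        _, sf_med, _ = weibull_pdf_sf_hazard(4 * np.log(2), weib_exp)
        assert sf_med == pytest.approx(0.5, abs=1e-12)

    def test_unit_cumulative_hazard(self):
        p = WeibullParams(2.0, 0.0498)
        t = 0.0498 ** (-0.5)
        _, sf, _ = weibull_pdf_sf_hazard(t, p)
        assert sf == pytest.approx(np.exp(-1), rel=1e-12)

    @pytest.mark.parametrize("alpha,beta", [(0.5, 0.4), (1.0, 0.25), (2.0, 0.05), (3.0, 1.2)])
    def test_hazard_identity(self, alpha, beta):
        p = WeibullParams(alpha, beta)
        for t in np.geomspace(0.05, 20.0, 30):
            pdf, sf, hz = weibull_pdf_sf_hazard(t, p)
            assert abs(hz * sf - pdf) < 1e-10

    def test_matches_scipy_weibull_min(self, weib2):
        lam = weib2.aft_scale
        ref = stats.weibull_min(weib2.shape_alpha, scale=lam)
        t = np.linspace(0.1, 10, 25)
        np.testing.assert_allclose(weib2.pdf(t), ref.pdf(t), rtol=1e-12)
        np.testing.assert_allclose(weib2.sf(t), ref.sf(t), rtol=1e-12)

    def test_aft_scale_round_trip(self, weib2):
        assert weib2.aft_scale ** (-weib2.shape_alpha) == pytest.approx(
            weib2.rate_beta, rel=1e-12
        )

    def test_domain_errors(self, weib2):
        with pytest.raises(ValueError):
            weibull_pdf_sf_hazard(-1.0, weib2)
        with pytest.raises(ValueError):
            WeibullParams(0.0, 1.0)


class TestBirnbaumSaunders:
    def test_pdf_normalizes(self, bs_default):
        val, _ = integrate.quad(lambda t: bs_pdf(t, bs_default), 0, np.inf, limit=200)
        assert val == pytest.approx(1.0, abs=1e-8)

    def test_pdf_is_cdf_derivative(self, bs_default):
        t, h = 4.0, 1e-5
        fd = (bs_cdf(t + h, bs_default) - bs_cdf(t - h, bs_default)) / (2 * h)
        assert bs_pdf(t, bs_default) == pytest.approx(fd, abs=1e-6)

    def test_pdf_matches_normal_transform(self, bs_default):
        # independent route: phi(z) * |dz/dt| with z = (sqrt(t/d)-sqrt(d/t))/g
        g, d, t = 0.5, 4.0, 4.0
        z = (np.sqrt(t / d) - np.sqrt(d / t)) / g
        dz_dt = (1 / (2 * np.sqrt(t * d)) + np.sqrt(d) / (2 * t**1.5)) / g
        oracle = stats.norm.pdf(z) * dz_dt
        assert bs_pdf(t, bs_default) == pytest.approx(oracle, rel=1e-12)

    def test_pdf_matches_scipy_fatiguelife(self, bs_default):
        ref = stats.fatiguelife(bs_default.shape_gamma, scale=bs_default.scale_delta)
        t = np.linspace(0.5, 15, 20)
        np.testing.assert_allclose(bs_pdf(t, bs_default), ref.pdf(t), rtol=1e-10)
        np.testing.assert_allclose(bs_sf(t, bs_default), ref.sf(t), rtol=1e-8)

    def test_sf_values(self, bs_default):
        assert bs_sf(4.0, bs_default) == pytest.approx(0.5, abs=1e-14)
        # xi(1/4) = 1/2 - 2 = -3/2, so S(1) = Phi(3)
        assert bs_sf(1.0, bs_default) == pytest.approx(ndtr(3.0), rel=1e-12)
        num, _ = integrate.quad(lambda t: bs_pdf(t, bs_default), 1.0, np.inf, limit=200)
        assert bs_sf(1.0, bs_default) == pytest.approx(num, abs=1e-9)
        assert bs_sf(1e9, bs_default) < 1e-12

    def test_sf_strictly_decreasing(self, bs_default):
        # strict on the bulk of the support; far tails saturate to equal floats
        t = np.geomspace(0.5, 20, 80)
        assert np.all(np.diff(bs_sf(t, bs_default)) < 0)

    def test_quantile_median_is_scale(self):
        for delta in (0.5, 4.0, 125.0):
            assert bs_quantile(0.5, BSParams(0.7, delta)) == pytest.approx(delta)

    def test_quantile_upper_tail(self, bs_default):
        q = bs_quantile(0.975, bs_default)
        assert q == pytest.approx(10.29, abs=0.01)
        # cross-check by numeric CDF inversion
        inv = optimize.brentq(lambda t: bs_cdf(t, bs_default) - 0.975, 1e-6, 100)
        assert q == pytest.approx(inv, rel=1e-9)

    def test_quantile_cdf_round_trip(self, bs_default):
        qs = np.linspace(0.01, 0.99, 50)
        back = bs_cdf(bs_quantile(qs, bs_default), bs_default)
        assert np.max(np.abs(back - qs)) < 1e-8

    def test_domain_errors(self, bs_default):
        with pytest.raises(ValueError):
            bs_quantile(1.5, bs_default)
        with pytest.raises(ValueError):
            bs_pdf(-2.0, bs_default)


class TestConditional:
    def test_zero_censoring_reduces_to_unconditional(self, weib2, bs_default):
        t = np.linspace(0.5, 10, 11)
        np.testing.assert_allclose(conditional_pdf(t, 0.0, weib2), weib2.pdf(t))
        np.testing.assert_allclose(conditional_pdf(t, 0.0, bs_default), bs_default.pdf(t))

    @pytest.mark.parametrize(
        "model,c",
        [
            (WeibullParams(2.0, 0.25), 2.0),
            (BSParams(0.5, 4.0), 4.0),
            (BSParams(2.0, 4.0), 1.0),
        ],
    )
    def test_conditional_pdf_normalizes(self, model, c):
        val, _ = integrate.quad(
            lambda t: conditional_pdf(t, c, model), c, np.inf, limit=300
        )
        assert val == pytest.approx(1.0, abs=1e-8)
        assert conditional_pdf(0.5 * c, c, model) == 0.0

    def test_exponential_memorylessness(self, weib_exp):
        # for shape 1 the conditional pdf is the unconditional pdf shifted by c
        c = 3.0
        for t in (3.5, 5.0, 9.0):
            assert conditional_pdf(t, c, weib_exp) == pytest.approx(
                float(weib_exp.pdf(t - c)), rel=1e-12
            )

    def test_exponential_conditional_mean_closed_form(self, weib_exp):
        assert conditional_mean(2.0, weib_exp) == pytest.approx(6.0)
        # memorylessness: E(T|T>=c) - c constant in c
        gaps = [conditional_mean(c, weib_exp) - c for c in (0.0, 1.0, 5.0, 20.0)]
        assert np.ptp(gaps) < 1e-12

    def test_unconditional_mean_gamma_formula(self, weib2, bs_default):
        a, b = weib2.shape_alpha, weib2.rate_beta
        from scipy.special import gamma as gamma_fn

        expected = b ** (-1 / a) * gamma_fn(1 + 1 / a)
        assert conditional_mean(0.0, weib2) == pytest.approx(expected, rel=1e-9)
        # BS mean: delta * (1 + gamma^2 / 2)
        assert conditional_mean(0.0, bs_default) == pytest.approx(4.0 * 1.125, rel=1e-8)

    def test_conditional_mean_against_monte_carlo(self, weib2):
        draws = sample_truncated(3.0, weib2, 10**6, seed=11)
        mc, se = draws.mean(), draws.std(ddof=1) / 1000.0
        assert abs(conditional_mean(3.0, weib2) - mc) < 3 * se

    def test_conditional_median_closed_forms(self, weib_exp, weib2, bs_default):
        assert conditional_median(2.0, weib_exp) == pytest.approx(2 + 4 * np.log(2))
        assert conditional_median(0.0, weib2) == pytest.approx(np.sqrt(np.log(2) / 0.25))
        assert conditional_median(0.0, bs_default) == pytest.approx(4.0)

    @pytest.mark.parametrize("alpha", [0.5, 1.0, 2.0])
    @pytest.mark.parametrize("c", [0.0, 1.0, 4.0])
    def test_weibull_median_matches_generic_inversion(self, alpha, c):
        model = WeibullParams(alpha, 0.25)
        closed = conditional_median(c, model)
        generic = optimize.brentq(
            lambda t: conditional_sf(t, c, model) - 0.5, max(c, 1e-12), closed * 10 + 10,
            xtol=1e-13,
        )
        assert abs(closed - generic) < 1e-9

    @pytest.mark.parametrize(
        "model", [WeibullParams(0.7, 0.3), WeibullParams(2.0, 0.25), BSParams(0.5, 4.0)]
    )
    def test_summaries_nondecreasing_and_above_c(self, model):
        cs = [0.0, 0.5, 1.0, 2.0, 5.0]
        means = [conditional_mean(c, model) for c in cs]
        medians = [conditional_median(c, model) for c in cs]
        assert all(m >= c for m, c in zip(means, cs))
        assert all(m >= c for m, c in zip(medians, cs))
        assert np.all(np.diff(means) > 0)
        assert np.all(np.diff(medians) > 0)

    def test_limit_small_c(self, weib2, bs_default):
        for model in (weib2, bs_default):
            assert conditional_mean(1e-9, model) == pytest.approx(
                conditional_mean(0.0, model), rel=1e-6
            )
            assert conditional_median(1e-9, model) == pytest.approx(
                conditional_median(0.0, model), rel=1e-6
            )

    @settings(max_examples=30, deadline=None)
    @given(
        alpha=st.floats(0.3, 4.0),
        beta=st.floats(0.01, 2.0),
        c=st.floats(0.0, 10.0),
    )
    def test_weibull_closed_form_median_property(self, alpha, beta, c):
        model = WeibullParams(alpha, beta)
        med = conditional_median(c, model)
        assert med >= c
        # S(med) must equal 0.5 * S(c)
        assert float(model.sf(med)) == pytest.approx(0.5 * float(model.sf(c)), rel=1e-9)


class TestSampling:
    @pytest.mark.parametrize(
        "model,c",
        [(WeibullParams(2.0, 0.25), 2.0), (BSParams(0.5, 4.0), 3.0)],
    )
    def test_truncation_support(self, model, c):
        draws = sample_truncated(c, model, 10_000, seed=5)
        assert draws.min() >= c

    def test_truncated_median_matches_closed_form(self, weib2):
        draws = sample_truncated(2.0, weib2, 10**6, seed=3)
        assert np.median(draws) == pytest.approx(conditional_median(2.0, weib2), abs=0.01)

    @pytest.mark.parametrize(
        "model,c",
        [(WeibullParams(2.0, 0.25), 2.0), (BSParams(0.5, 4.0), 4.0)],
    )
    def test_truncated_ks_against_analytic_cdf(self, model, c):
        draws = sample_truncated(c, model, 10**5, seed=17)
        cdf = lambda t: 1.0 - np.asarray(conditional_sf(t, c, model))
        stat = stats.kstest(draws, cdf).statistic
        assert stat < 0.01

    def test_seed_reproducibility(self, bs_default):
        a = sample_truncated(1.0, bs_default, 100, seed=9)
        b = sample_truncated(1.0, bs_default, 100, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_unconditional_exponential_mean(self):
        draws = rng_unconditional(WeibullParams(1.0, 0.25), 10**6, seed=2)
        assert draws.mean() == pytest.approx(4.0, abs=0.02)

    def test_unconditional_bs_median(self, bs_default):
        draws = rng_unconditional(bs_default, 10**6, seed=4)
        assert np.median(draws) == pytest.approx(4.0, abs=0.02)

    @pytest.mark.parametrize(
        "model", [WeibullParams(0.5, 0.45), WeibullParams(2.0, 0.05), BSParams(1.0, 4.0)]
    )
    def test_unconditional_ks(self, model):
        draws = rng_unconditional(model, 10**5, seed=23)
        stat = stats.kstest(draws, lambda t: np.asarray(model.cdf(t))).statistic
        assert stat < 0.005
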