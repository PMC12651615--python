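"""Uninformative and leave-one-out empirical prior construction."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import gamma as gamma_dist

from presage import (
    beta_from_moments,
    empirical_prior_exercise,
    empirical_prior_sleep,
    empirical_prior_stress,
    gamma_mle,
    uninformative_prior,
)


class TestUninformative:
    def test_exercise_is_flat_beta(self):
        p = uninformative_prior("exercise").parameters
        assert (p.alpha, p.beta, p.k, p.t) == (1.0, 1.0, 0, 0)

    def test_sleep_is_diffuse_normal_on_the_mean(self):
        p = uninformative_prior("sleep").parameters
        assert (p.mu_prior, p.var_prior) == (7.0, 100.0)
        assert math.sqrt(p.var_prior) == pytest.approx(10.0)  # SD of 10 h

    def test_stress_hyperpriors(self):
        p = uninformative_prior("stress").parameters
        assert p.shape_prior == (2.0, 0.1)
        assert p.rate_prior == (2.0, 0.1)
        assert (p.hurdle_alpha, p.hurdle_beta) == (1.0, 1.0)

    def test_unknown_variable_is_error(self):
        with pytest.raises(ValueError):
            uninformative_prior("caffeine")


class TestBetaMomentMatching:
    def test_uniform_moments_invert_to_uniform(self):
        alpha, beta = beta_from_moments(0.5, 1 / 12)
        assert alpha == pytest.approx(1.0) and beta == pytest.approx(1.0)

    @given(
        m=st.floats(min_value=0.05, max_value=0.95),
        frac=st.floats(min_value=0.01, max_value=0.95),
    )
    @settings(max_examples=200, derandomize=True)
    def test_round_trip_reproduces_moments(self, m, frac):
        v = frac * m * (1 - m)
        alpha, beta = beta_from_moments(m, v)
        mean = alpha / (alpha + beta)
        var = alpha * beta / ((alpha + beta) ** 2 * (alpha + beta + 1))
        assert mean == pytest.approx(m, rel=1e-9)
        assert var == pytest.approx(v, rel=1e-9)

    def test_infeasible_variance_falls_back_mean_matched(self):
        with pytest.warns(RuntimeWarning):
            alpha, beta = beta_from_moments(0.3, 0.5)
        assert alpha + beta == pytest.approx(2.0)
        assert alpha / (alpha + beta) == pytest.approx(0.3)


class TestEmpiricalExercise:
    def test_matches_rate_moments(self):
        rates = [0.1, 0.2, 0.3, 0.5]
        p = empirical_prior_exercise(rates).parameters
        m, v = np.mean(rates), np.var(rates, ddof=1)
        assert p.alpha / (p.alpha + p.beta) == pytest.approx(m)

    def test_identical_rates_take_fallback(self):
        with pytest.warns(RuntimeWarning):
            p = empirical_prior_exercise([0.25, 0.25, 0.25]).parameters
        assert p.alpha / (p.alpha + p.beta) == pytest.approx(0.25)

    def test_leave_one_out_exclusivity(self):
        """Perturbing the target participant's data leaves the prior built
        from the others untouched."""
        rates = {"A": 0.2, "B": 0.4, "C": 0.3}
        loo_for_a = [r for k, r in rates.items() if k != "A"]
        before = empirical_prior_exercise(loo_for_a).parameters
        rates["A"] = 0.9  # target's own data changes
        after = empirical_prior_exercise([r for k, r in rates.items() if k != "A"]).parameters
        assert (before.alpha, before.beta) == (after.alpha, after.beta)


class TestEmpiricalSleep:
    def test_two_person_hand_arithmetic(self):
        p = empirical_prior_sleep([[7.0, 7.0], [8.0, 8.0]]).parameters
        assert p.mu_prior == pytest.approx(7.5)
        assert p.var_prior == pytest.approx(0.5)  # sample variance of {7, 8}

    def test_homogeneous_cohort_hits_variance_floor(self):
        p = empirical_prior_sleep([[7, 8, 6], [7, 8, 6], [8, 7, 6]]).parameters
        assert p.var_prior == pytest.approx(0.25)

    def test_single_person_sample_is_error(self):
        with pytest.raises(ValueError):
            empirical_prior_sleep([[7.0, 8.0]])

    def test_variance_components_recovered_in_simulation(self):
        """Between/within decomposition recovered within 10%.  The sample
        variance of N person means has relative sampling SE sqrt(2/(N-1)),
        so N=2000 persons makes 10% a ~3-sigma band."""
        rng = np.random.default_rng(21)
        between, within = 1.44, 0.81
        records = [
            rng.normal(rng.normal(7, math.sqrt(between)), math.sqrt(within), 28)
            for _ in range(2000)
        ]
        p = empirical_prior_sleep(records).parameters
        assert p.obs_var == pytest.approx(within, rel=0.10)
        # person means carry within-person noise: E[var of means] = between + within/28
        assert p.var_prior == pytest.approx(between + within / 28, rel=0.10)


class TestGammaMLE:
    def test_fitted_mean_equals_sample_mean(self):
        x = [1.0, 4.0]
        shape, rate = gamma_mle(x)
        assert shape / rate == pytest.approx(2.5, rel=1e-8)

    def test_matches_grid_search_oracle(self):
        """Log-likelihood at the Newton solution is within 1e-4 of the best
        point on a fine (shape, rate) grid."""
        x = np.array([1.0, 4.0, 2.0, 6.5, 0.7])
        shape, rate = gamma_mle(x)
        ll_newton = gamma_dist.logpdf(x, a=shape, scale=1 / rate).sum()
        shapes = np.linspace(0.2, 8, 600)
        rates = np.linspace(0.05, 4, 600)
        ll_grid = gamma_dist.logpdf(
            x[None, None, :], a=shapes[:, None, None], scale=1 / rates[None, :, None]
        ).sum(axis=-1)
        assert ll_newton >= ll_grid.max() - 1e-4

    def test_matches_scipy_fit(self):
        x = np.random.default_rng(3).gamma(2.0, 10.0, 200)
        shape, rate = gamma_mle(x)
        shape_sp, _, scale_sp = gamma_dist.fit(x, floc=0)
        assert shape == pytest.approx(shape_sp, rel=1e-4)
        assert rate == pytest.approx(1 / scale_sp, rel=1e-4)

    def test_simulation_recovery_at_n5000(self):
        x = np.random.default_rng(17).gamma(2.0, 10.0, 5000)
        shape, rate = gamma_mle(x)
        assert abs(shape - 2.0) / 2.0 < 0.05
        assert abs(rate - 0.1) / 0.1 < 0.05

    def test_degenerate_data_is_error(self):
        with pytest.raises(ValueError):
            gamma_mle([3.0, 3.0, 3.0])


class TestEmpiricalStress:
    def test_hyperprior_means_equal_mles(self):
        x = np.random.default_rng(5).gamma(2.0, 10.0, 500)
        p = empirical_prior_stress(x, 0.3).parameters
        shape_mle, rate_mle = gamma_mle(x)
        a_s, b_s = p.shape_prior
        a_r, b_r = p.rate_prior
        assert a_s / b_s == pytest.approx(shape_mle, rel=1e-9)
        assert a_r / b_r == pytest.approx(rate_mle, rel=1e-9)
        # cv = 0.5 by default -> Gamma(4, .)
        assert a_s == pytest.approx(4.0)

    def test_scalar_zero_rate_mean_matches_hurdle(self):
        x = np.random.default_rng(5).gamma(2.0, 10.0, 100)
        p = empirical_prior_stress(x, 0.4).parameters
        assert p.hurdle_alpha / (p.hurdle_alpha + p.hurdle_beta) == pytest.approx(0.4)

    def test_per_person_rates_moment_match_hurdle(self):
        x = np.random.default_rng(5).gamma(2.0, 10.0, 100)
        zr = [0.2, 0.3, 0.4, 0.5]
        p = empirical_prior_stress(x, zr).parameters
        m = np.mean(zr)
        v = np.var(zr, ddof=1)
        nu = p.hurdle_alpha + p.hurdle_beta
        assert p.hurdle_alpha / nu == pytest.approx(m, rel=1e-9)
        assert m * (1 - m) / v - 1 == pytest.approx(nu, rel=1e-9)

    def test_too_few_nonzero_values_is_error(self):
        with pytest.raises(ValueError):
            empirical_prior_stress([1.0] * 5, 0.3)
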