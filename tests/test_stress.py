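"""Hurdle-Gamma stress model: sampler, predictive, surprisal."""

import math
import warnings

import numpy as np
import pytest
from scipy.stats import gamma as gamma_dist

from presage import (
    HurdleGammaModel,
    HurdleGammaPosterior,
    HurdleGammaPrior,
    expected_stress,
    fit_hurdle_gamma,
    run_prequential,
    stress_predictive,
    stress_surprisal,
)


def _point_posterior(p_zero, shape, rate):
    return HurdleGammaPosterior(
        p_zero=np.array([p_zero]), shape=np.array([shape]), rate=np.array([rate])
    )


class TestFit:
    def test_hurdle_matches_beta_closed_form(self):
        """Beta(1,1) hurdle prior, 10 observations of which 4 zeros: the
        posterior mean of p_zero is 5/12, and the sampled hurdle marginal
        agrees within 3 Monte-Carlo standard errors."""
        values = [0, 0, 0, 0, 3.0, 1.2, 8.0, 2.2, 5.5, 9.1]
        post = fit_hurdle_gamma(values, seed=3)
        closed = 5 / 12
        se = post.p_zero.std(ddof=1) / math.sqrt(post.n_draws)
        assert abs(post.p_zero.mean() - closed) < 3 * se

    def test_all_zero_record_leaves_gamma_at_prior(self):
        prior = HurdleGammaPrior()
        post = fit_hurdle_gamma([0.0] * 20, prior, seed=4)
        # p_zero concentrated near 1
        assert post.p_zero.mean() > 0.9
        # shape/rate are prior draws: means near the hyperprior mean 2/0.1=20
        a, b = prior.shape_prior
        prior_mean, prior_sd = a / b, math.sqrt(a) / b
        se = prior_sd / math.sqrt(post.n_draws)
        assert abs(post.shape.mean() - prior_mean) < 4 * se
        assert post.diagnostics["sampler"] == "prior"

    def test_prior_only_fit_allowed(self):
        post = fit_hurdle_gamma([], seed=1)
        assert post.n_draws == 2000
        assert np.all(post.shape > 0) and np.all(post.rate > 0)

    def test_rejects_negative_values(self):
        with pytest.raises(ValueError):
            fit_hurdle_gamma([-1.0, 2.0])

    def test_fixed_seed_is_bit_identical(self):
        values = np.random.default_rng(0).gamma(2, 10, 30)
        a = fit_hurdle_gamma(values, seed=9)
        b = fit_hurdle_gamma(values, seed=9)
        assert np.array_equal(a.shape, b.shape)
        assert np.array_equal(a.rate, b.rate)
        assert np.array_equal(a.p_zero, b.p_zero)

    def test_parameter_recovery_at_n500(self):
        """Single-replicate recovery sanity check (the full 50-replicate
        study lives in the acceptance suite)."""
        rng = np.random.default_rng(12)
        x = np.where(rng.random(500) < 0.3, 0.0, rng.gamma(2.0, 10.0, 500))
        post = fit_hurdle_gamma(x, seed=13)
        assert abs(post.p_zero.mean() - 0.3) / 0.3 < 0.15
        assert abs(post.shape.mean() - 2.0) / 2.0 < 0.15
        assert abs(post.rate.mean() - 0.1) / 0.1 < 0.15


class TestExpectedStress:
    @pytest.mark.parametrize(
        "p_zero, shape, rate, expected",
        [
            (1.0, 2.0, 0.1, 0.0),
            (0.0, 2.0, 0.1, 20.0),
            (0.5, 3.0, 1.0, 1.5),
        ],
    )
    def test_degenerate_posteriors(self, p_zero, shape, rate, expected):
        post = _point_posterior(p_zero, shape, rate)
        assert expected_stress(post) == pytest.approx(expected)

    def test_matches_monte_carlo_hurdle_gamma_mean(self, rng):
        p_zero, shape, rate = 0.4, 2.0, 0.25
        draws = np.where(
            rng.random(400_000) < p_zero, 0.0, rng.gamma(shape, 1 / rate, 400_000)
        )
        se = draws.std(ddof=1) / math.sqrt(draws.size)
        post = _point_posterior(p_zero, shape, rate)
        assert abs(expected_stress(post) - draws.mean()) < 3 * se

    def test_empty_posterior_is_error(self):
        post = _point_posterior(0.5, 2.0, 1.0)
        post.p_zero = post.shape = post.rate = np.array([])
        with pytest.raises(ValueError):
            expected_stress(post)


class TestPredictive:
    def test_degenerate_hurdle_puts_all_mass_at_zero(self):
        pred = stress_predictive(_point_posterior(1.0, 2.0, 0.1))
        assert pred.zero_mass == pytest.approx(1.0)
        assert pred.bin_masses.sum() == pytest.approx(0.0, abs=1e-12)

    def test_bin_mass_matches_gamma_cdf_oracle(self):
        """Mass of the unit bin at 20 is (1-p_zero)*[F(20.5)-F(19.5)]."""
        pred = stress_predictive(_point_posterior(0.4, 2.0, 0.1))
        F = gamma_dist(a=2.0, scale=10.0).cdf
        assert pred.mass_at(20) == pytest.approx(0.6 * (F(20.5) - F(19.5)), rel=1e-9)

    def test_masses_sum_to_one_with_tail_folding(self):
        post = fit_hurdle_gamma(
            np.r_[np.zeros(5), np.random.default_rng(1).gamma(2, 30, 20)], seed=2
        )
        pred = stress_predictive(post, bin_width=1.0, support_max=50.0)
        assert pred.zero_mass + pred.bin_masses.sum() == pytest.approx(1.0, abs=1e-9)

    def test_first_bin_covers_small_positive_values(self):
        pred = stress_predictive(_point_posterior(0.3, 2.0, 0.5))
        assert pred.mass_at(0.2) == pred.mass_at(1.0)


class TestSurprisal:
    def test_certain_zero_report(self):
        pred = stress_predictive(_point_posterior(1.0, 2.0, 0.1))
        assert stress_surprisal(0.0, pred) == pytest.approx(0.0)

    def test_half_mass_zero_report(self):
        pred = stress_predictive(_point_posterior(0.5, 2.0, 0.1))
        assert stress_surprisal(0.0, pred) == pytest.approx(math.log(2.0))

    def test_positive_observation_scored_by_bin_mass(self):
        pred = stress_predictive(_point_posterior(0.4, 2.0, 0.1))
        F = gamma_dist(a=2.0, scale=10.0).cdf
        expected = -math.log(0.6 * (F(20.5) - F(19.5)))
        assert stress_surprisal(20.0, pred) == pytest.approx(expected, rel=1e-9)

    def test_vanishing_bin_mass_is_floored_with_warning(self):
        pred = stress_predictive(_point_posterior(0.5, 2.0, 10.0), support_max=50.0)
        with pytest.warns(RuntimeWarning):
            s = stress_surprisal(49.0, pred)
        assert np.isfinite(s) and s > 100


class TestSequentialModel:
    def test_refit_depends_only_on_absorbed_days(self):
        rng = np.random.default_rng(6)
        obs = np.where(rng.random(10) < 0.3, 0.0, rng.gamma(2, 10, 10))
        m = HurdleGammaModel(n_draws=300, n_warmup=200, base_seed=7)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            full = run_prequential(obs, m)
            prefix = run_prequential(
                obs[:5], HurdleGammaModel(n_draws=300, n_warmup=200, base_seed=7)
            )
        assert np.array_equal(full.surprisal[:5], prefix.surprisal)

    def test_trajectory_is_deterministic(self):
        rng = np.random.default_rng(8)
        obs = np.where(rng.random(6) < 0.3, 0.0, rng.gamma(2, 10, 6))
        kwargs = dict(n_draws=300, n_warmup=200, base_seed=3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            a = run_prequential(obs, HurdleGammaModel(**kwargs))
            b = run_prequential(obs, HurdleGammaModel(**kwargs))
        assert np.array_equal(a.surprisal, b.surprisal)
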