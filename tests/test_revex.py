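"""RevEx distribution closed forms, the Gumbel identity, and the fit.

scipy's Gumbel (maximum extreme value) distribution serves as the
independent oracle for every closed form: the RevEx law with amplitude
a and decay rate b is the Gumbel law with location ln(a)/b and scale
1/b.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats
from sklearn.base import clone

import crtlab
from crtlab import (FitError, RevExFitter, RevExParams, ValidationError,
                    cdf, density, fit_revex, model_median, model_mode,
                    quantile, sample, survival_percentile)


@given(a=st.floats(1.5, 1e4), b=st.floats(0.5, 40.0),
       t=st.floats(0.05, 3.0))
@settings(max_examples=200, derandomize=True, deadline=None)
def test_closed_forms_match_gumbel_reparameterization(a, b, t):
    params = RevExParams(a=a, b=b)
    gumbel = stats.gumbel_r(loc=math.log(a) / b, scale=1.0 / b)
    assert cdf(t, params) == pytest.approx(gumbel.cdf(t), abs=1e-12)
    assert density(t, params) == pytest.approx(gumbel.pdf(t), abs=1e-9)
    assert survival_percentile(t, params) == pytest.approx(gumbel.sf(t),
                                                           abs=1e-12)
    assert model_median(params) == pytest.approx(gumbel.median(), rel=1e-12)


def test_survival_and_cdf_are_complementary():
    params = RevExParams()
    ts = np.linspace(0.3, 2.5, 23)
    np.testing.assert_allclose(survival_percentile(ts, params) + cdf(ts, params),
                               1.0, atol=1e-12)


def test_quantile_inverts_cdf():
    params = RevExParams(a=50.0, b=4.0)
    for p in (0.01, 0.5, 0.99):
        assert cdf(quantile(p, params), params) == pytest.approx(p, abs=1e-12)


def test_density_integrates_to_one():
    total, _ = integrate.quad(lambda t: density(t, RevExParams()), 0.0, 5.0)
    assert total == pytest.approx(1.0, abs=1e-6)


def test_mode_and_median_match_numerical_search():
    params = RevExParams()
    grid = np.arange(0.5, 1.5, 1e-4)  # 0.1 ms resolution
    assert grid[np.argmax(density(grid, params))] == pytest.approx(
        model_mode(params), abs=1e-4)
    # median: cdf crosses 0.5 at the closed-form point
    med = model_median(params)
    assert cdf(med, params) == pytest.approx(0.5, abs=1e-12)


def test_mode_is_one_second_when_a_equals_exp_b():
    b = 3.7
    assert model_mode(RevExParams(a=math.exp(b), b=b)) == pytest.approx(1.0)


def test_halving_time_identity():
    """Shifting RT by ln(2)/b exactly halves -ln(CD), the model's
    resources-per-speed reading (~104 ms at the published decay rate)."""
    params = RevExParams()
    shift = math.log(2) / params.b
    ts = np.linspace(0.5, 1.6, 12)
    np.testing.assert_allclose(-np.log(cdf(ts + shift, params)),
                               0.5 * (-np.log(cdf(ts, params))), rtol=1e-12)
    assert shift == pytest.approx(0.1037, abs=2e-4)


def test_parameter_validation():
    with pytest.raises(ValidationError):
        RevExParams(a=-1.0)
    with pytest.raises(ValidationError):
        RevExParams(b=0.0)
    with pytest.raises(ValidationError):
        quantile(1.5)
    with pytest.raises(ValidationError):
        survival_percentile(-0.1)


def test_single_draw_is_quantile_of_seeded_uniform():
    params = RevExParams()
    seed = 99
    u = np.random.default_rng(seed).uniform(size=1)
    assert sample(1, params, seed=seed)[0] == pytest.approx(
        quantile(u[0], params))


def test_empirical_tail_and_median_converge():
    params = RevExParams()
    x = sample(200_000, params, seed=3)
    p_slow = survival_percentile(0.9, params)
    se = math.sqrt(p_slow * (1 - p_slow) / len(x))
    assert abs((x > 0.9).mean() - p_slow) < 3 * se
    se_med = 1.0 / (2 * density(model_median(params), params)
                    * math.sqrt(len(x)))
    assert abs(np.median(x) - model_median(params)) < 3 * se_med


def test_noiseless_inversion_recovers_parameters():
    """Plug-in quantile positions (no sampling noise) invert the fit."""
    params = RevExParams()
    n = 200_000
    x = quantile((np.arange(n) + 0.5) / n, params)
    result = fit_revex(x)
    assert result.params.b == pytest.approx(params.b, rel=1e-3)
    assert result.params.a == pytest.approx(params.a, rel=1e-2)
    assert result.r_squared > 0.999999


def test_fit_requires_enough_values_in_range():
    with pytest.raises(FitError):
        fit_revex(np.full(99, 1.0))


def test_fit_recovery_bias_below_one_percent():
    """Average decay-rate estimate over replicates stays within 1% of
    the generating value (n = 10,000 per replicate)."""
    params = RevExParams()
    rng = np.random.default_rng(12345)
    estimates = [fit_revex(quantile(rng.uniform(size=10_000), params)).params.b
                 for _ in range(100)]
    assert abs(np.mean(estimates) - params.b) < 0.01 * params.b


class TestRevExFitter:
    def test_estimator_interface(self):
        x = sample(20_000, RevExParams(), seed=4)
        est = RevExFitter().fit(x.reshape(-1, 1))
        assert est.b_ == pytest.approx(6.682, rel=0.05)
        assert est.a_ == pytest.approx(263.94, rel=0.3)
        assert est.r_squared_ > 0.99
        assert est.n_used_ <= len(x)
        # sklearn plumbing
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()
        est2 = RevExFitter(fit_low=0.65).set_params(trim=0.01)
        assert est2.trim == 0.01 and est2.fit_low == 0.65

    def test_score_samples_is_log_density(self):
        est = RevExFitter().fit(sample(20_000, RevExParams(), seed=4))
        ts = np.array([0.7, 0.9, 1.2])
        np.testing.assert_allclose(est.score_samples(ts),
                                   np.log(density(ts, est.params_)))

    def test_sample_round_trip(self):
        est = RevExFitter().fit(sample(50_000, RevExParams(), seed=8))
        draws = est.sample(50_000, random_state=0)
        refit = RevExFitter().fit(draws)
        assert refit.b_ == pytest.approx(est.b_, rel=0.05)

    def test_rejects_multicolumn_input(self):
        with pytest.raises(ValidationError):
            RevExFitter().fit(np.ones((10, 2)))
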