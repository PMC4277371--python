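"""Closed forms and samplers of the Poisson-coincidence search model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from emrec.coincidence import (
    EULER_GAMMA,
    SD_LOG10_EXPONENTIAL,
    CoincidenceParams,
    ParameterError,
    coincidence_rate,
    log_time_moments,
    sample_search_times,
    simulate_mechanistic,
    simulate_mechanistic_batch,
)


class TestCoincidenceRate:
    @pytest.mark.parametrize(
        "nu,p,tau,expected",
        [
            (3, 1.0, 1.0, 1.0),  # certain activation: one window
            (2, 0.1, 1.0, 0.01),
            (1, 10 ** (-1.17), 1.0, 10 ** (-1.17)),  # ~0.0676
        ],
    )
    def test_rate_is_p_power_nu_over_tau(self, nu, p, tau, expected):
        assert coincidence_rate(CoincidenceParams(nu=nu, p=p, tau=tau)) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(nu=0, p=0.5, tau=1.0),
            dict(nu=2.5, p=0.5, tau=1.0),
            dict(nu=1, p=0.0, tau=1.0),
            dict(nu=1, p=1.2, tau=1.0),
            dict(nu=1, p=0.5, tau=0.0),
            dict(nu=1, p=0.5, tau=-1.0),
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            CoincidenceParams(**kwargs)


class TestLogTimeMoments:
    def test_mean_matches_monte_carlo_oracle(self):
        # E[log10 t] for t ~ Exp(1) is -gamma/ln10; check against raw draws
        mom = log_time_moments(1.0)
        draws = np.log10(np.random.default_rng(0).exponential(size=1_000_000))
        se = draws.std(ddof=1) / math.sqrt(draws.size)
        assert abs(mom.mean_log10 - draws.mean()) < 3 * se
        assert mom.mean_log10 == pytest.approx(-EULER_GAMMA / math.log(10))

    def test_decade_scale_equivariance(self):
        assert log_time_moments(10.0).mean_log10 == pytest.approx(
            log_time_moments(1.0).mean_log10 - 1.0
        )

    @pytest.mark.parametrize("rate", [0.003, 1.0, 250.0])
    def test_sd_is_rate_independent_constant(self, rate):
        assert round(log_time_moments(rate).sd_log10, 3) == 0.557

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ParameterError):
            log_time_moments(0.0)

    @given(st.floats(min_value=1e-6, max_value=1e6))
    @settings(deadline=None)
    def test_rate_times_ten_lowers_mean_by_one(self, rate):
        a = log_time_moments(rate).mean_log10
        b = log_time_moments(10 * rate).mean_log10
        assert b == pytest.approx(a - 1.0, abs=1e-9)


class TestSampleSearchTimes:
    def test_same_seed_identical_output(self):
        a = sample_search_times(2.0, 1000, rng_seed=42)
        b = sample_search_times(2.0, 1000, rng_seed=42)
        assert np.array_equal(a, b)
        c = sample_search_times(2.0, 1000, method="stepwise", step=0.05, rng_seed=42)
        d = sample_search_times(2.0, 1000, method="stepwise", step=0.05, rng_seed=42)
        assert np.array_equal(c, d)

    def test_exact_sampler_mean_is_inverse_rate(self):
        t = sample_search_times(2.0, 1_000_000, rng_seed=7)
        se = t.std(ddof=1) / math.sqrt(t.size)
        assert abs(t.mean() - 0.5) < 3 * se

    @pytest.mark.parametrize("method,step", [("exact", None), ("stepwise", 0.001)])
    def test_sd_of_log10_times_near_gumbel_constant(self, method, step):
        t = sample_search_times(1.0, 1_000_000, method=method, step=step, rng_seed=3)
        assert np.std(np.log10(t), ddof=1) == pytest.approx(SD_LOG10_EXPONENTIAL, abs=0.01)

    def test_sd_log10_independent_of_rate(self):
        sds = [
            np.std(np.log10(sample_search_times(r, 200_000, rng_seed=5)), ddof=1)
            for r in (0.01, 1.0, 100.0)
        ]
        assert max(sds) - min(sds) < 0.01

    def test_memorylessness(self):
        rate = 1.0
        t = sample_search_times(rate, 100_000, rng_seed=11)
        a = b = 1.0 / rate
        p_cond = np.mean(t[t > a] > a + b)
        p_b = np.mean(t > b)
        n = (t > a).sum()
        se = math.sqrt(p_b * (1 - p_b) * (1 / n + 1 / t.size))
        assert abs(p_cond - p_b) < 4 * se

    @pytest.mark.parametrize("bad", [dict(rate=-1.0, n=10), dict(rate=1.0, n=0)])
    def test_invalid_arguments_rejected(self, bad):
        with pytest.raises(ParameterError):
            sample_search_times(bad["rate"], bad["n"])

    def test_unknown_method_rejected(self):
        with pytest.raises(ParameterError):
            sample_search_times(1.0, 10, method="magic")


class TestMechanisticSimulator:
    def test_certain_activation_hits_first_window(self):
        params = CoincidenceParams(nu=3, p=1.0, tau=0.5)
        assert simulate_mechanistic(params, rng_seed=0) == pytest.approx(0.5)

    def test_single_run_reproducible(self):
        params = CoincidenceParams(nu=2, p=0.3, tau=1.0)
        assert simulate_mechanistic(params, rng_seed=9) == simulate_mechanistic(
            params, rng_seed=9
        )

    def test_no_coincidence_within_max_windows_flags(self):
        params = CoincidenceParams(nu=4, p=0.01, tau=1.0)
        assert simulate_mechanistic(params, max_windows=3, rng_seed=1) is None

    def test_geometric_mean_time(self):
        # nu=1, p=0.2: mean window index 1/p = 5, so mean time 5*tau
        params = CoincidenceParams(nu=1, p=0.2, tau=1.0)
        t = simulate_mechanistic_batch(params, 100_000, rng_seed=2)
        se = np.nanstd(t, ddof=1) / math.sqrt(t.size)
        assert abs(np.nanmean(t) - 5.0) < 3 * se

    def test_batch_matches_literal_single_runs(self):
        # the vectorised batch and the draw-by-draw loop sample one law
        params = CoincidenceParams(nu=2, p=0.4, tau=1.0)
        literal = np.array(
            [simulate_mechanistic(params, rng_seed=1000 + i) for i in range(3000)],
            dtype=float,
        )
        batch = simulate_mechanistic_batch(params, 3000, rng_seed=77)
        assert stats.ks_2samp(literal, batch).pvalue > 0.01

    def test_agrees_with_exponential_closed_form_at_small_p(self):
        params = CoincidenceParams(nu=2, p=0.05, tau=1.0)
        mech = simulate_mechanistic_batch(params, 100_000, rng_seed=4)
        exact = sample_search_times(coincidence_rate(params), 100_000, rng_seed=5)
        assert stats.ks_2samp(mech, exact).statistic < 0.01

    def test_convergence_to_exponential_as_p_shrinks(self):
        ds = []
        for p in (0.5, 0.2, 0.05):
            params = CoincidenceParams(nu=1, p=p, tau=1.0)
            mech = simulate_mechanistic_batch(params, 100_000, rng_seed=6)
            exact = sample_search_times(coincidence_rate(params), 100_000, rng_seed=7)
            ds.append(stats.ks_2samp(mech, exact).statistic)
        assert ds[0] > ds[1] > ds[2]
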