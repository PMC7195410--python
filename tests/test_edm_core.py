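import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flcseason import (
    AnalysisConfig,
    EmbeddingSpec,
    TemperatureModel,
    ccm,
    detect_causality,
    embed,
    gen_coupled_logistic,
    gen_temperature,
    seasonal_surrogates,
    select_embedding,
    simplex_forecast,
    smooth_temperature,
    standardise,
)
from tests.oracles import brute_simplex


class TestStandardise:
    def test_zero_mean_unit_sd(self):
        out = standardise([1.0, 2.0, 3.0])
        assert out.mean() == pytest.approx(0.0, abs=1e-12)
        assert out.std(ddof=1) == pytest.approx(1.0)

    def test_idempotent(self):
        x = np.random.default_rng(0).normal(5, 3, 40)
        once = standardise(x)
        np.testing.assert_allclose(standardise(once), once, atol=1e-12)

    @settings(deadline=None)
    @given(st.floats(-100, 100), st.floats(0.01, 100))
    def test_affine_invariance(self, shift, scale):
        x = np.array([0.3, 1.7, -2.2, 4.1, 0.9])
        np.testing.assert_allclose(
            standardise(scale * x + shift), standardise(x), atol=1e-8
        )

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            standardise([2.0, 2.0, 2.0])


class TestSmoothTemperature:
    def test_exact_line_reproduced_for_any_smoothing(self):
        stamps = pd.date_range("2012-01-01", periods=60, freq="D")
        from flcseason import TemperatureSeries
        s = TemperatureSeries(stamps, 2.0 + 0.1 * np.arange(60.0))
        for smoothing in (0.1, 0.5, 0.9, 1.0):
            out = smooth_temperature(s, smoothing)
            np.testing.assert_allclose(out.values, s.values, atol=1e-6)

    def test_strong_smoothing_shrinks_variance(self, temp):
        out = smooth_temperature(temp, 0.99)
        assert out.values.var() <= temp.daily("mean").var()

    def test_moderate_smoothing_denoises_seasonal_cycle(self):
        noisy = gen_temperature(TemperatureModel(seed=5, noise_sd=2.0), 3)
        clean = gen_temperature(TemperatureModel(seed=5, noise_sd=0.0), 3)
        smoothed = smooth_temperature(noisy, 0.5)
        truth = clean.daily("mean").to_numpy()
        raw = noisy.daily("mean").to_numpy()
        n = min(len(truth), len(smoothed.values))
        rmse_smooth = np.sqrt(np.mean((smoothed.values[:n] - truth[:n])**2))
        rmse_raw = np.sqrt(np.mean((raw[:n] - truth[:n])**2))
        assert rmse_smooth < rmse_raw

    def test_smoothing_monotone_dial(self, temp):
        # rougher fits track the data more closely as the dial decreases
        daily = temp.daily("mean").to_numpy()
        resid = {
            s: np.mean((smooth_temperature(temp, s).values - daily) ** 2)
            for s in (0.1, 0.5, 0.9)
        }
        assert resid[0.1] <= resid[0.5] <= resid[0.9]


class TestEmbed:
    def test_small_example_by_definition(self):
        pts = embed(np.array([1.0, 2, 3, 4, 5]), EmbeddingSpec(E=2, tau=1))
        np.testing.assert_array_equal(
            pts, [[2, 1], [3, 2], [4, 3], [5, 4]]
        )

    def test_identity_for_one_dimension(self):
        x = np.array([3.0, 1.0, 4.0])
        np.testing.assert_array_equal(embed(x, EmbeddingSpec(1)), x[:, None])

    @settings(deadline=None)
    @given(st.integers(1, 6), st.integers(1, 4), st.integers(30, 60))
    def test_count_formula(self, E, tau, n):
        x = np.arange(float(n))
        assert len(embed(x, EmbeddingSpec(E, tau))) == n - (E - 1) * tau

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="short"):
            embed(np.arange(5.0), EmbeddingSpec(E=6, tau=1))


class TestSimplexForecast:
    def test_matches_brute_force_oracle_exactly(self):
        rng = np.random.default_rng(7)
        for n, E, tau, tp in [(30, 2, 1, 1), (50, 3, 1, -2), (40, 1, 2, 1),
                              (45, 4, 1, 0)]:
            x = rng.normal(size=n)
            rho, rmse = simplex_forecast(x, EmbeddingSpec(E, tau, tp))
            rho_o, rmse_o = brute_simplex(x, E, tau, tp)
            assert rho == pytest.approx(rho_o, abs=1e-10)
            assert rmse == pytest.approx(rmse_o, abs=1e-10)

    def test_noise_free_periodic_series_near_perfect(self):
        t = np.arange(200)
        x = np.sin(2 * np.pi * t / 25)
        rho, _ = simplex_forecast(x, EmbeddingSpec(E=3, tau=1, tp=1))
        assert rho > 0.99

    def test_white_noise_unpredictable(self):
        rng = np.random.default_rng(1)
        rhos = []
        for _ in range(5):
            x = rng.normal(size=200)
            for E in (1, 3, 5):
                rho, _ = simplex_forecast(x, EmbeddingSpec(E, 1, 1))
                rhos.append(rho)
        assert abs(np.mean(rhos)) < 0.2

    def test_exact_repeats_handled_with_uniform_weights(self):
        x = np.tile([0.1, 0.5, 0.9, 0.5], 10)
        rho, rmse = simplex_forecast(x, EmbeddingSpec(E=2, tau=1, tp=1))
        assert rmse == pytest.approx(0.0, abs=1e-12)


class TestSelectEmbedding:
    def test_logistic_map_low_dimensional(self):
        x, _ = gen_coupled_logistic(3.8, 3.7, 0.0, 0.0, 500, seed=1)
        assert select_embedding(standardise(x), e_max=10).best_E <= 3

    def test_ties_break_to_smallest_E(self):
        res_cls = select_embedding(np.sin(np.arange(60.0)), e_max=5)
        tied = res_cls.E_values[
            np.isclose(res_cls.rmse, res_cls.rmse.min(), atol=1e-15)
        ]
        assert res_cls.best_E == tied.min()

    def test_infeasible_length_rejected(self):
        with pytest.raises(ValueError, match="feasible"):
            select_embedding(np.arange(3.0), e_max=24)


class TestCcm:
    def test_unidirectional_coupling_detected_with_convergence(self):
        x, y = gen_coupled_logistic(3.8, 3.7, 0.1, 0.0, 1000, seed=2)
        xs, ys = standardise(x), standardise(y)
        spec = EmbeddingSpec(E=2, tau=1, tp=-1)
        rho = ccm(xs, ys, spec, np.array([20, 100, 400]), n_draws=10,
                  seed=0)
        assert rho[-1] > 0.8
        assert rho[-1] > rho[0]

    def test_shuffled_cause_has_no_skill(self):
        x, y = gen_coupled_logistic(3.8, 3.7, 0.1, 0.0, 500, seed=3)
        rng = np.random.default_rng(0)
        y_shuf = rng.permutation(standardise(y))
        rho = ccm(standardise(x), y_shuf, EmbeddingSpec(2, 1, 0),
                  np.array([20, 200, 490]), n_draws=10, seed=0)
        assert np.all(np.abs(rho) < 0.25)

    def test_library_too_small_rejected(self):
        x, y = gen_coupled_logistic(3.8, 3.7, 0.1, 0.0, 100, seed=0)
        with pytest.raises(ValueError, match="E\\+2"):
            ccm(x, y, EmbeddingSpec(3, 1, 0), np.array([4]))


class TestSeasonalSurrogates:
    def make_seasonal(self, n_points=52, resid_sd=0.0, seed=0):
        """Cycle with period = one sampling year (26 biweekly points)."""
        dates = pd.date_range("2012-09-25", periods=n_points, freq="14D")
        rng = np.random.default_rng(seed)
        x = np.sin(2 * np.pi * np.arange(n_points) / 26.0) + rng.normal(
            0, resid_sd, n_points)
        return x, dates

    def test_pure_cycle_reproduced_exactly(self):
        x, dates = self.make_seasonal(resid_sd=0.0)
        sur = seasonal_surrogates(x, dates, n=5, seed=0)
        for s in sur:
            np.testing.assert_allclose(s, x, atol=1e-9)

    def test_seasonal_profile_preserved(self):
        x, dates = self.make_seasonal(resid_sd=0.4, seed=1)
        sur = seasonal_surrogates(x, dates, n=200, seed=0)
        # year-level sums preserved exactly (permutation within years)
        per_year = 26
        for s in sur[:10]:
            assert s[:per_year].sum() == pytest.approx(
                x[:per_year].sum(), abs=1e-9
            )
        # the across-surrogate mean keeps the seasonal shape
        profile_corr = np.corrcoef(sur.mean(axis=0), x)[0, 1]
        assert profile_corr > 0.8

    def test_residual_structure_destroyed(self):
        """Surrogate anomalies are uncorrelated with the original
        anomalies (the within-year ordering is scrambled)."""
        x, dates = self.make_seasonal(resid_sd=0.5, seed=2)
        sur = seasonal_surrogates(x, dates, n=100, seed=0)
        profile = sur.mean(axis=0)
        resid = x - profile
        corrs = [np.corrcoef(s - profile, resid)[0, 1] for s in sur]
        assert abs(np.mean(corrs)) < 0.25

    def test_span_below_one_year_rejected(self):
        dates = pd.date_range("2012-09-25", periods=10, freq="14D")
        with pytest.raises(ValueError, match="annual"):
            seasonal_surrogates(np.arange(10.0), dates, n=3, seed=0)

    def test_requested_count_returned(self):
        x, dates = self.make_seasonal(resid_sd=0.2)
        assert seasonal_surrogates(x, dates, n=17, seed=0).shape == (17, 52)


class TestDetectCausality:
    def test_bidirectional_coupling_detected_both_ways(self):
        x, y = gen_coupled_logistic(3.8, 3.7, 0.1, 0.1, 1000, seed=5)
        cfg = AnalysisConfig(n_library_draws=10, n_surrogates=50)
        res = detect_causality(x, y, cfg, labels=("x", "y"))
        assert res["x xmap y"].verdict and res["y xmap x"].verdict

    def test_independent_seasonal_pair_blocked_by_surrogates(self):
        rng = np.random.default_rng(8)
        dates = pd.date_range("2012-09-25", periods=53, freq="14D")
        t = np.arange(53) * 14.0
        a = np.sin(2 * np.pi * t / 365.25) + rng.normal(0, 0.3, 53)
        b = np.cos(2 * np.pi * t / 365.25 + 0.4) + rng.normal(0, 0.3, 53)
        cfg = AnalysisConfig(n_library_draws=25)
        res = detect_causality(a, b, cfg, dates=dates, labels=("a", "b"))
        assert not res["a xmap b"].verdict
        assert not res["b xmap a"].verdict

    def test_verdict_consistent_with_criteria(self):
        x, y = gen_coupled_logistic(3.8, 3.7, 0.1, 0.0, 600, seed=6)
        cfg = AnalysisConfig(n_library_draws=10, n_surrogates=50)
        res = detect_causality(x, y, cfg, labels=("x", "y"))
        for r in res.values():
            i = list(r.tps).index(r.best_tp)
            expected = (
                r.best_tp <= 0
                and r.rho_by_tp[i] > r.surrogate_q95[i]
                and r.convergence_delta > cfg.convergence_threshold
            )
            assert r.verdict == expected
            assert np.all(np.diff(r.library_sizes) > 0)
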