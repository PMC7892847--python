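"""Covariate-process fitting, simulation, and climate-trend extraction."""

import numpy as np
import pytest

from salmon_lcm.envsim import (
    ClimateTrend,
    CovarianceModel,
    CovariateMatrix,
    GcmEnsemble,
    SingularCovarianceError,
    apply_trend,
    count_correlation_params,
    extract_trend,
    fit_covariance_model,
    simulate_detrended,
)


def brute_force_pairs(n):
    return sum(1 for i in range(n) for j in range(i + 1, n))


class TestCorrelationParamCount:
    @pytest.mark.parametrize("n,expected", [(1, 0), (2, 1), (8, 28)])
    def test_known_counts(self, n, expected):
        assert count_correlation_params(n) == expected

    def test_matches_pair_enumeration_up_to_50(self):
        for n in range(1, 51):
            assert count_correlation_params(n) == brute_force_pairs(n)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            count_correlation_params(0)
        with pytest.raises(TypeError):
            count_correlation_params(2.5)


def ar1_model(names, rho, variances, corr=0.0):
    n = len(names)
    R = np.full((n, n), corr)
    np.fill_diagonal(R, 1.0)
    sd = np.sqrt(np.asarray(variances))
    Q = R * np.outer(sd, sd)
    return CovarianceModel(names, np.zeros(n), rho, Q)


class TestFitCovarianceModel:
    @pytest.mark.parametrize("rho_true", [0.3, 0.0])
    def test_simulate_then_refit_recovers_truth(self, rho_true):
        truth = ar1_model(("a", "b", "c"), rho_true, [1.0, 0.5, 2.0])
        draw = simulate_detrended(truth, 3000, 1, seed=5)[0]
        fit = fit_covariance_model(draw)
        assert abs(float(np.asarray(fit.rho)) - rho_true) < 0.05
        # every pairwise correlation of Q recovered too
        assert np.max(np.abs(fit.correlations() - truth.correlations())) < 0.05

    def test_constant_series_is_singular(self):
        years = np.arange(2000, 2020)
        vals = np.column_stack([np.full(20, 3.0), np.random.default_rng(0).normal(size=20)])
        data = CovariateMatrix(years, ("flat", "ok"), vals)
        with pytest.raises(SingularCovarianceError):
            fit_covariance_model(data)

    def test_too_short_series_rejected(self):
        years = np.arange(2000, 2005)
        data = CovariateMatrix(years, ("x",), np.random.default_rng(0).normal(size=(5, 1)))
        with pytest.raises(ValueError, match="10 years"):
            fit_covariance_model(data)

    def test_recovery_with_cross_correlation(self):
        truth = ar1_model(("a", "b", "c", "d"), 0.4, [1.0, 1.0, 1.0, 1.0], corr=0.5)
        draw = simulate_detrended(truth, 3000, 1, seed=9)[0]
        fit = fit_covariance_model(draw)
        assert abs(float(np.asarray(fit.rho)) - 0.4) < 0.05
        assert np.max(np.abs(fit.correlations() - truth.correlations())) < 0.05


class TestSimulateDetrended:
    def test_zero_process_noise_pins_draws_at_mu(self):
        model = CovarianceModel(("x", "y"), np.array([1.0, -2.0]), 0.7,
                                np.zeros((2, 2)))
        draws = simulate_detrended(model, 10, 3, seed=1)
        for d in draws:
            assert np.allclose(d.values, model.mu)

    def test_same_seed_is_bit_identical(self):
        model = ar1_model(("x", "y"), 0.5, [1.0, 1.0], corr=0.3)
        a = simulate_detrended(model, 50, 4, seed=42)
        b = simulate_detrended(model, 50, 4, seed=42)
        for da, db in zip(a, b):
            assert np.array_equal(da.values, db.values)

    def test_sample_lag1_autocorrelation_matches_rho(self):
        model = ar1_model(("x",), 0.5, [1.0])
        draw = simulate_detrended(model, 5000, 1, seed=3)[0]
        x = draw.values[:, 0] - draw.values[:, 0].mean()
        r1 = (x[1:] @ x[:-1]) / (x @ x)
        assert abs(r1 - 0.5) < 0.05

    def test_long_run_mean_converges_to_mu(self):
        model = CovarianceModel(("x",), np.array([4.0]), 0.6,
                                np.array([[1.0 - 0.6**2]]))
        draw = simulate_detrended(model, 10_000, 1, seed=7)[0]
        x = draw.values[:, 0]
        # stationary variance 1; 3 SE of the mean of an AR(1) sample
        se = np.sqrt((1 + 0.6) / (1 - 0.6) / x.size)
        assert abs(x.mean() - 4.0) < 3 * se


def make_ensemble(members, years=None, covariate="sst_arc", scenario="rcp85"):
    members = np.atleast_2d(np.asarray(members, dtype=float))
    if years is None:
        years = np.arange(2000, 2000 + members.shape[1])
    return GcmEnsemble(covariate, scenario, years, members)


class TestExtractTrend:
    def test_constant_members_give_zero_offsets(self):
        years = np.arange(1995, 2060)
        ens = make_ensemble(np.full((4, years.size), 7.3), years)
        for trend in extract_trend(ens).values():
            assert np.allclose(trend.offsets, 0.0, atol=1e-12)

    def test_linear_anomalies_survive_smoothing_in_interior(self):
        years = np.arange(1990, 2080)
        slope = 0.03
        series = slope * (years - 2015)
        ens = make_ensemble(series[None, :], years)
        trends = extract_trend(ens, window=20)
        h = 10
        interior = slice(h, years.size - h)
        # baseline 2005-2025 is centered on 2015, so anomalies equal the line
        for trend in trends.values():
            assert np.allclose(trend.offsets[interior], series[interior], atol=1e-9)

    def test_median_of_three_members_with_constant_late_anomalies(self):
        # members flat through the baseline, then stepping to 1, 2, 3:
        # anomalies are {1, 2, 3} in the late years, so the Q50 offset is 2
        years = np.arange(2000, 2060)
        late = years > 2025
        members = np.vstack([np.where(late, k, 0.0) for k in (1.0, 2.0, 3.0)])
        trends = extract_trend(make_ensemble(members, years), window=1)
        assert np.allclose(trends[50].offsets[late], 2.0)
        assert np.allclose(trends[25].offsets[late], 1.5)  # linear interpolation
        assert np.allclose(trends[50].offsets[~late], 0.0)

    def test_quantile_ordering(self):
        rng = np.random.default_rng(4)
        years = np.arange(1995, 2090)
        members = rng.normal(0, 1, size=(12, years.size)).cumsum(axis=1) * 0.05
        trends = extract_trend(make_ensemble(members, years))
        assert np.all(trends[25].offsets <= trends[50].offsets + 1e-12)
        assert np.all(trends[50].offsets <= trends[75].offsets + 1e-12)

    def test_missing_baseline_years_error(self):
        years = np.arange(2010, 2060)  # starts after 2005
        ens = make_ensemble(np.zeros((2, years.size)), years)
        with pytest.raises(ValueError, match="baseline"):
            extract_trend(ens)


class TestApplyTrend:
    def setup_method(self):
        rng = np.random.default_rng(8)
        self.years = np.arange(2015, 2030)
        self.draw = CovariateMatrix(self.years, ("t", "f"),
                                    rng.normal(size=(15, 2)))

    def trend(self, offsets, cov="t"):
        return ClimateTrend(cov, "rcp85", 50, self.years, offsets)

    def test_zero_offsets_identity(self):
        out = apply_trend(self.draw, {"t": self.trend(np.zeros(15))})
        assert np.array_equal(out.values, self.draw.values)

    def test_unit_offset_shifts_only_that_column(self):
        out = apply_trend(self.draw, {"t": self.trend(np.ones(15))})
        assert np.allclose(out.values[:, 0], self.draw.values[:, 0] + 1.0)
        assert np.array_equal(out.values[:, 1], self.draw.values[:, 1])

    def test_mean_shift_equals_mean_offset(self):
        offs = np.linspace(0, 2, 15)
        out = apply_trend(self.draw, {"f": self.trend(offs, cov="f")})
        shift = out.values[:, 1].mean() - self.draw.values[:, 1].mean()
        assert np.isclose(shift, offs.mean())

    def test_year_mismatch_error(self):
        short = ClimateTrend("t", "rcp85", 50, self.years[:5], np.zeros(5))
        with pytest.raises(ValueError, match="cover"):
            apply_trend(self.draw, {"t": short})
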