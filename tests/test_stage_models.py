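"""Stage submodels: Gompertz recruitment, transport, SAR, maturation algebra."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from salmon_lcm.stage_models import (
    GompertzStageParams,
    MainstemTable,
    MaturationParams,
    SarParams,
    UpstreamParams,
    effective_spawners,
    fit_gompertz,
    fit_gompertz_pooled,
    gompertz_recruits,
    partition_sar,
    sar_from_ages,
    sar_probability,
    transport_assign,
    upstream_survival,
)


class TestGompertzRecruits:
    def test_zero_stock_is_absorbing(self):
        p = GompertzStageParams(a=2.0, b=-0.5)
        assert gompertz_recruits(0.0, p) == 0.0

    def test_full_compensation_limit_is_flat(self):
        p = GompertzStageParams(a=1.5, b=-1.0)
        for s in (1.0, 10.0, 1e6):
            assert np.isclose(gompertz_recruits(s, p), np.exp(1.5))

    def test_arithmetic_example(self):
        p = GompertzStageParams(a=2.0, b=-0.5)
        # exp(2 + 0.5 ln 100) = exp(2) * 10
        assert np.isclose(gompertz_recruits(100.0, p), np.exp(2.0) * 10.0)

    def test_power_law_closed_form(self):
        p = GompertzStageParams(a=0.7, b=-0.35)
        s = np.array([3.0, 40.0, 900.0])
        assert np.allclose(gompertz_recruits(s, p), np.exp(0.7) * s**0.65)

    def test_unknown_covariate_name_errors(self):
        p = GompertzStageParams(a=1.0, b=-0.2, c={"temp": -0.1})
        with pytest.raises(KeyError, match="temp"):
            gompertz_recruits(10.0, p, covs={"flow": 1.0})

    def test_concave_in_log_stock_for_compensatory_b(self):
        p = GompertzStageParams(a=1.0, b=-0.4)
        logs = np.linspace(0, 8, 50)
        r = np.log([gompertz_recruits(np.exp(ls), p) for ls in logs])
        slopes = np.diff(r) / np.diff(logs)
        assert np.all(np.diff(slopes) <= 1e-9)


class TestFitGompertz:
    def test_noise_free_exact_recovery(self):
        rng = np.random.default_rng(1)
        truth = GompertzStageParams(a=3.0, b=-0.4, c={"flow": 0.2, "temp": -0.1})
        stock = rng.uniform(20, 500, 60)
        covs = {"flow": rng.normal(size=60), "temp": rng.normal(size=60)}
        rec = gompertz_recruits(stock, truth, covs)
        fit, _ = fit_gompertz(stock, rec, covs)
        assert np.isclose(fit.a, truth.a, atol=1e-8)
        assert np.isclose(fit.b, truth.b, atol=1e-8)
        for k in truth.c:
            assert np.isclose(fit.c[k], truth.c[k], atol=1e-8)

    def test_coverage_of_two_se_intervals(self):
        # with sigma_proc=0.3 over 50 years, truth should fall within 2 SE
        # of the estimate in about 95% of replicates
        truth = GompertzStageParams(a=2.5, b=-0.5, c={"x": 0.3}, sigma_proc=0.3)
        hits = 0
        n_rep = 200
        for rep in range(n_rep):
            rng = np.random.default_rng(1000 + rep)
            stock = rng.uniform(20, 500, 50)
            covs = {"x": rng.normal(size=50)}
            rec = gompertz_recruits(stock, truth, covs,
                                    noise=rng.normal(0, 0.3, 50))
            fit, se = fit_gompertz(stock, rec, covs)
            ok = (abs(fit.a - truth.a) <= 2 * se["a"]
                  and abs(fit.b - truth.b) <= 2 * se["b"]
                  and abs(fit.c["x"] - truth.c["x"]) <= 2 * se["x"])
            hits += ok
        assert hits / n_rep >= 0.90

    def test_constant_recruits_give_full_compensation(self):
        rng = np.random.default_rng(2)
        stock = rng.uniform(10, 1000, 40)
        rec = np.full(40, 55.0)
        fit, _ = fit_gompertz(stock, rec)
        assert np.isclose(fit.b, -1.0, atol=1e-10)

    def test_collinear_covariates_rejected(self):
        rng = np.random.default_rng(3)
        stock = rng.uniform(10, 100, 30)
        x = rng.normal(size=30)
        with pytest.raises(ValueError, match="condition number"):
            fit_gompertz(stock, stock * 2.0, {"x1": x, "x2": 2.0 * x})

    def test_partial_pooling_shrinks_toward_grand_mean(self):
        rng = np.random.default_rng(4)
        tables = {}
        for i in range(6):
            truth = GompertzStageParams(a=2.0 + 0.1 * i, b=-0.5, sigma_proc=0.4)
            stock = rng.uniform(20, 400, 25)
            rec = gompertz_recruits(stock, truth, noise=rng.normal(0, 0.4, 25))
            tables[f"pop{i}"] = (stock, rec, {})
        raw = fit_gompertz_pooled(tables, pooling="none")
        pooled = fit_gompertz_pooled(tables, pooling="partial")
        a_raw = np.array([raw[p][0].a for p in tables])
        a_pool = np.array([pooled[p][0].a for p in tables])
        grand = a_raw.mean()
        assert np.var(a_pool - grand) <= np.var(a_raw - grand) + 1e-12


class TestTransportAssign:
    def test_outside_window_never_transported(self):
        assert transport_assign(90, 100, 160, 1.0, 0.0) is False

    def test_certain_transport_inside_window(self):
        assert transport_assign(120, 100, 160, 1.0, 0.999) is True

    def test_within_window_fraction_matches_probability(self):
        rng = np.random.default_rng(5)
        u = rng.random(10_000)
        flags = transport_assign(np.full(10_000, 130), 100, 160, 0.6, u)
        # binomial SE at p=0.6, n=1e4 is ~0.005
        assert abs(flags.mean() - 0.6) < 0.02

    def test_invalid_window(self):
        with pytest.raises(ValueError):
            transport_assign(120, 160, 100, 0.5, 0.5)


class TestSarProbability:
    def test_logistic_identity_at_zero(self):
        p = SarParams(0.0, {})
        assert sar_probability({}, 130, p) == pytest.approx(0.5)

    def test_arithmetic_example(self):
        p = SarParams(-3.0, {"sst": -0.5})
        assert sar_probability({"sst": 2.0}, 130, p) == pytest.approx(
            1 / (1 + np.exp(4.0)), rel=1e-6)

    def test_monotone_in_negative_sst_coefficient(self):
        p = SarParams(-2.0, {"sst": -0.4})
        probs = [sar_probability({"sst": x}, 130, p) for x in np.linspace(-2, 2, 9)]
        assert np.all(np.diff(probs) < 0)

    def test_missing_covariate_errors(self):
        p = SarParams(-2.0, {"sst": -0.4})
        with pytest.raises(KeyError):
            sar_probability({}, 130, p)


class TestMaturationPartition:
    def test_sar_from_ages_examples(self):
        assert sar_from_ages(1000, 0, 0, 0, 0.1, 0.6) == 0.0
        assert sar_from_ages(1000, 100, 50, 10, 0.1, 0.6) == pytest.approx(0.05)
        with pytest.raises(ValueError):
            sar_from_ages(0, 1, 1, 1, 0.1, 0.6)

    def test_all_mature_at_three_collapses_to_jack_ratio(self):
        S3, f3, f4, f5, _ = partition_sar(0.02, MaturationParams(0.7, 1.0, 0.5, 1.0))
        assert S3 == pytest.approx(0.02)
        assert f4 == pytest.approx(0.0)
        assert f5 == pytest.approx(0.0)

    def test_arithmetic_example(self):
        m = MaturationParams(S0=0.7, b3=0.1, b4=0.6, F5=1.0)
        S3, *_ = partition_sar(0.03, m)
        # denominator 0.1 + 0.9*0.7*(0.6 + 0.4*0.7) = 0.6544
        assert S3 == pytest.approx(0.03 / 0.6544, rel=1e-12)

    def test_zero_denominator_errors(self):
        with pytest.raises(ZeroDivisionError):
            partition_sar(0.02, S0=0.0, b3=0.0, b4=0.5)

    def test_implausible_flag_when_first_winter_survival_exceeds_one(self):
        *_, implausible = partition_sar(0.9, MaturationParams(0.1, 0.01, 0.01, 1.0))
        assert bool(implausible)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        S_sar=st.floats(1e-6, 1.0),
        S0=st.floats(0.01, 0.99),
        b3=st.floats(0.0, 1.0),
        b4=st.floats(0.0, 1.0),
    )
    def test_partition_round_trip_is_exact(self, S_sar, S0, b3, b4):
        """Partitioning then reassembling total SAR is an algebraic identity."""
        S3, f3, f4, f5, _ = partition_sar(S_sar, S0=S0, b3=b3, b4=b4)
        back = sar_from_ages(1.0, f3, f4, f5, b3, b4)
        assert abs(back - S_sar) < 1e-12


class TestEffectiveSpawners:
    def test_only_jacks_count_for_nothing(self):
        assert effective_spawners(37.0, 0.0, 0.0, 1.2) == 0.0

    def test_weighted_sum(self):
        assert effective_spawners(5.0, 20.0, 5.0, 1.2) == pytest.approx(26.0)

    def test_equal_weighting_limit(self):
        assert effective_spawners(3.0, 7.0, 11.0, 1.0) == pytest.approx(18.0)


class TestMainstemTable:
    def make_table(self, survivals, temps=None, edges=(-3, 0, 3)):
        survivals = np.asarray(survivals, dtype=float)
        n = survivals.size
        temps = np.asarray(temps if temps is not None else np.zeros(n), float)
        return MainstemTable(
            np.asarray(edges, float), np.array([-3.0, 3.0]),
            temps, np.zeros(n), survivals, np.zeros(n), np.full(n, 0.4))

    def test_single_record_is_deterministic(self):
        t = self.make_table([0.55])
        rng = np.random.default_rng(0)
        for _ in range(5):
            s, a, p = t.sample(0.2, 0.1, rng)
            assert (s, a, p) == (0.55, 0.0, 0.4)

    def test_bin_selection_follows_temperature(self):
        t = self.make_table([0.2, 0.8], temps=[-1.5, 1.5])
        rng = np.random.default_rng(1)
        assert t.sample(-2.0, 0.0, rng)[0] == 0.2
        assert t.sample(2.0, 0.0, rng)[0] == 0.8
        # out-of-range inputs clamp to the nearest bin
        assert t.sample(-99.0, 0.0, rng)[0] == 0.2

    def test_equal_weight_sampling_mean(self):
        t = self.make_table([0.4, 0.6], temps=[1.0, 1.5])
        rng = np.random.default_rng(2)
        s, _, _ = t.sample_many(np.full(10_000, 1.2), np.zeros(10_000), rng)
        assert abs(s.mean() - 0.5) < 0.01

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            self.make_table([])


class TestUpstreamSurvival:
    def test_saturation(self):
        p = UpstreamParams(intercept=10.0)
        assert upstream_survival({}, p) == pytest.approx(1.0, abs=1e-4)

    def test_arithmetic_example(self):
        p = UpstreamParams(intercept=2.0, betas={"temp": -0.3})
        assert upstream_survival({"temp": 0.0}, p) == pytest.approx(
            1 / (1 + np.exp(-2.0)), rel=1e-6)

    def test_monotone_decline_with_warming(self):
        p = UpstreamParams(intercept=2.0, betas={"temp": -0.3})
        s = [upstream_survival({"temp": x}, p) for x in np.linspace(-2, 4, 7)]
        assert np.all(np.diff(s) < 0)

    def test_missing_covariate_errors(self):
        p = UpstreamParams(intercept=2.0, betas={"temp": -0.3})
        with pytest.raises(KeyError):
            upstream_survival({}, p)
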