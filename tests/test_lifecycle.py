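"""Age-structured projection: conservation, timing, determinism, coupling."""

import numpy as np
import pytest

from conftest import climate_free_params, flat_mainstem_table
from salmon_lcm.envsim import ClimateScenario, CovariateMatrix, simulate_detrended
from salmon_lcm.lifecycle import (
    STAGES,
    PopulationState,
    StageValueError,
    run_projection,
    simulate_ensemble,
    step_year,
    trajectories_to_frame,
)
from salmon_lcm.stage_models import MaturationParams, sar_denominator
from salmon_lcm.synthdata import default_covariance_model


def zero_env(n_years, names=("spring_temp", "spring_flow")):
    return {s: np.zeros((n_years, len(names))) for s in STAGES}


def one_year_covs(names=("spring_temp", "spring_flow")):
    covs = {n: 0.0 for n in names}
    return {s: dict(covs) for s in STAGES}


def fresh_state(year=2015, spawners4=100.0):
    return PopulationState(year=year, spawners_by_age={3: 0.0, 4: spawners4, 5: 0.0},
                           parr=0.0, smolts=0.0, ocean=(0.0, 0.0, 0.0))


class TestStepYear:
    def test_zero_spawners_are_absorbing(self):
        params = climate_free_params()
        state = PopulationState(2015, {3: 0.0, 4: 0.0, 5: 0.0}, 0.0, 0.0,
                                (0.0, 0.0, 0.0))
        for _ in range(8):
            state = step_year(state, params, one_year_covs())
        assert state.parr == 0.0 and state.smolts == 0.0
        assert all(v == 0.0 for v in state.spawners_by_age.values())

    def test_lossless_limit_conserves_smolts_into_adults(self):
        # every survival forced to 1, all fish mature at age 4, F5=1:
        # adults out equal smolts in, two years later
        params = climate_free_params(
            a1=0.0, b1=0.0, a2=0.0, b2=0.0, mainstem_survival=1.0,
            sar_intercept=50.0, prespawn=1.0, upstream_intercept=50.0,
            maturation=MaturationParams(S0=1 - 1e-12, b3=0.0, b4=1.0, F5=1.0),
        )
        state = fresh_state(spawners4=100.0)
        smolts_by_year = {}
        adults_by_year = {}
        for _ in range(10):
            state = step_year(state, params, one_year_covs())
            smolts_by_year[state.year] = state.smolts
            adults_by_year[state.year] = state.spawners_by_age[4]
        for y, n2 in smolts_by_year.items():
            if y + 2 in adults_by_year and n2 > 0:
                assert adults_by_year[y + 2] == pytest.approx(n2, rel=1e-9)

    def test_single_generation_matches_hand_computation(self):
        # spreadsheet-style recomputation of one brood with hand-set numbers
        m = MaturationParams(S0=0.7, b3=0.1, b4=0.6, F5=1.2)
        params = climate_free_params(
            a1=2.0, b1=-0.5, a2=1.0, b2=-0.2, mainstem_survival=0.5,
            sar_intercept=-3.0, prespawn=0.8, upstream_intercept=1.0,
            maturation=m,
        )
        E0 = 100.0
        parr = np.exp(2.0 + 0.5 * np.log(E0))                  # 73.891
        smolt = np.exp(1.0 + 0.8 * np.log(parr))               # tributary out
        N2 = smolt * 0.5
        sar = 1 / (1 + np.exp(3.0))
        S3 = sar / float(sar_denominator(0.7, 0.1, 0.6))
        N3 = S3 * N2
        N4 = 0.9 * N3 * 0.7
        N5 = 0.4 * N4 * 0.7
        up = 1 / (1 + np.exp(-1.0)) * 0.8
        state = fresh_state(year=2014, spawners4=E0)
        out = {}
        for _ in range(6):
            state = step_year(state, params, one_year_covs())
            out[state.year] = state
        assert out[2015].parr == pytest.approx(parr, rel=1e-12)
        assert out[2016].smolts == pytest.approx(N2, rel=1e-12)
        assert out[2017].spawners_by_age[3] == pytest.approx(0.1 * N3 * up, rel=1e-12)
        assert out[2018].spawners_by_age[4] == pytest.approx(0.6 * N4 * up, rel=1e-12)
        assert out[2019].spawners_by_age[5] == pytest.approx(N5 * up, rel=1e-12)

    def test_pulse_propagates_only_to_years_three_through_five(self):
        params = climate_free_params()
        state = fresh_state(year=2000, spawners4=500.0)  # pulse brood year 2000
        returns = {}
        for _ in range(9):
            state = step_year(state, params, one_year_covs())
            returns[state.year] = sum(state.spawners_by_age.values())
        assert returns[2001] == 0.0 and returns[2002] == 0.0
        for y in (2003, 2004, 2005):
            assert returns[y] > 0.0
        # no second generation before the pulse's own offspring return
        assert returns[2006] == 0.0


class TestSimulateEnsemble:
    def test_zero_initial_state_stays_zero(self):
        params = climate_free_params(sigma_proc=0.3, day_sd=0.2)
        rng = np.random.default_rng(0)
        res = simulate_ensemble(params, zero_env(20), ("spring_temp", "spring_flow"),
                                np.arange(2015, 2035), 5, init_spawners=0.0, rng=rng)
        assert np.all(res["spawners"] == 0.0)
        assert np.all(res["smolts"] == 0.0)

    def test_matches_independent_scalar_recursion(self):
        # independent brood-by-brood recomputation of the deterministic chain
        params = climate_free_params(a1=3.0, b1=-0.4, a2=2.0, b2=-0.3,
                                     mainstem_survival=0.5, sar_intercept=-3.0,
                                     prespawn=0.8, upstream_intercept=1.0)
        m = params.maturation
        years = np.arange(2015, 2045)
        n = years.size
        res = simulate_ensemble(params, zero_env(n),
                                ("spring_temp", "spring_flow"), years, 1,
                                init_spawners=200.0, stochastic=False)
        up = 1 / (1 + np.exp(-1.0)) * 0.8
        sar = 1 / (1 + np.exp(3.0))
        S3 = sar / float(sar_denominator(m.S0, m.b3, m.b4))
        E = np.zeros(n)
        p4 = np.zeros(n)
        p5 = np.zeros(n)
        for t in range(n):
            E[t] = 200.0 if t < 5 else (p4[t] + m.F5 * p5[t]) * up
            if t + 2 >= n or E[t] <= 0:
                continue
            parr = np.exp(3.0 + 0.6 * np.log(E[t]))
            smolt = np.exp(2.0 + 0.7 * np.log(parr))
            N2 = smolt * 0.5
            N3 = S3 * N2
            N4 = (1 - m.b3) * N3 * m.S0
            N5 = (1 - m.b4) * N4 * m.S0
            if t + 4 < n:
                p4[t + 4] += m.b4 * N4
            if t + 5 < n:
                p5[t + 5] += N5
        assert np.allclose(res["spawners"][0], E, rtol=1e-12)

    def test_nan_covariate_is_reported_with_stage_name(self):
        from dataclasses import replace
        base = climate_free_params()
        params = replace(base, g2=replace(base.g2, c={"spring_temp": 0.1}))
        env = zero_env(10)
        env["tributary"] = np.full((10, 2), np.nan)
        with pytest.raises(StageValueError, match="parr_to_smolt"):
            simulate_ensemble(params, env, ("spring_temp", "spring_flow"),
                              np.arange(2015, 2025), 1, init_spawners=10.0,
                              stochastic=False)


class TestRunProjection:
    def test_identical_seeds_bit_identical(self, detrended_scenario, world):
        params = world.params["sulphur_creek"]
        a = run_projection(params, detrended_scenario, 10, seed=5, init_spawners=200.0)
        b = run_projection(params, detrended_scenario, 10, seed=5, init_spawners=200.0)
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.spawners, tb.spawners)
            assert np.array_equal(ta.smolts, tb.smolts)

    def test_replacement_parameters_hold_median_near_initial(self):
        # deterministic fixed point first: calibrate the SAR intercept so the
        # no-noise growth rate is exactly 1, then check the stochastic median
        params = climate_free_params(a1=4.0, b1=-0.3, a2=2.2, b2=-0.35,
                                     sigma_proc=0.05, day_sd=0.05)
        names = ("spring_temp", "spring_flow")
        years = np.arange(2015, 2090)
        det = simulate_ensemble(params, zero_env(years.size), names, years, 1,
                                init_spawners=150.0, stochastic=False)
        fixed_point = det["spawners"][0, -1]
        assert fixed_point > 0
        model = default_covariance_model()
        draws = simulate_detrended(model, years.size, 500, seed=77,
                                   start_year=2015)
        scen = ClimateScenario(draws)
        trajs = run_projection(params, scen, 500, seed=78,
                               init_spawners=fixed_point)
        median_tail = np.median([t.spawners[-10:].mean() for t in trajs])
        assert abs(median_tail - fixed_point) / fixed_point < 0.10

    def test_zero_survival_stage_collapses_within_a_generation(self, detrended_scenario):
        params = climate_free_params(mainstem_survival=0.0, sigma_proc=0.2,
                                     day_sd=0.2)
        trajs = run_projection(params, detrended_scenario, 5, seed=9,
                               init_spawners=300.0)
        for tr in trajs:
            # spin-up holds 5 years; all later years collapse to zero
            assert np.all(tr.spawners[8:] == 0.0)

    def test_monotone_coupling_in_mainstem_survival(self, detrended_scenario):
        from dataclasses import replace
        lo = climate_free_params(sigma_proc=0.2, day_sd=0.2, mainstem_survival=0.5)
        hi = replace(lo, mainstem=flat_mainstem_table(survival=0.6))
        a = run_projection(lo, detrended_scenario, 20, seed=13, init_spawners=200.0)
        b = run_projection(hi, detrended_scenario, 20, seed=13, init_spawners=200.0)
        for ta, tb in zip(a, b):
            assert np.all(tb.spawners >= ta.spawners - 1e-9)

    def test_short_scenario_is_rejected(self, cov_truth):
        draws = simulate_detrended(cov_truth, 20, 5, seed=1, start_year=2015)
        scen = ClimateScenario(draws)
        params = climate_free_params()
        with pytest.raises(ValueError, match="cover"):
            run_projection(params, scen, 5, seed=1, init_spawners=100.0,
                           years=(2015, 2089))

    def test_too_few_draws_rejected(self, cov_truth):
        draws = simulate_detrended(cov_truth, 75, 3, seed=1, start_year=2015)
        with pytest.raises(ValueError, match="draws"):
            run_projection(climate_free_params(), ClimateScenario(draws), 10,
                           seed=1, init_spawners=100.0)

    def test_trajectory_frame_round_trip(self, detrended_scenario):
        params = climate_free_params(sigma_proc=0.1, day_sd=0.1)
        trajs = run_projection(params, detrended_scenario, 3, seed=2,
                               init_spawners=100.0)
        df = trajectories_to_frame(trajs)
        assert df["simulation"].nunique() == 3
        assert len(df) == 3 * trajs[0].years.size
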