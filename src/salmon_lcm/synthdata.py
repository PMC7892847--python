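"""Synthetic study system: every input the pipeline consumes, generated.

The generators emulate the statistical structure the analysis assumes —
cross-correlated, autocorrelated annual covariate anomalies; GCM ensembles
as a shared smooth trend plus member spread and interannual noise;
redd-derived spawner series with lognormal observation error; and per-fish
Bernoulli return records with AR(1) day effects.  Every generator is
seed-deterministic and returns its ground truth alongside the data so
recovery tests can close the loop.

The default world has eight populations and eight covariates on a
standardized-anomaly scale, sixteen historical years, and equilibrium
spawner abundances spanning roughly 45-600 — the scale of the wild
Snake River spring/summer Chinook populations this pipeline is built
around.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._rng import child_seed, substream
from .calibration import BetaPrior, NormalPrior, PriorSpec
from .envsim import CovarianceModel, CovariateMatrix, GcmEnsemble, simulate_detrended
from .lifecycle import LifecycleParams, run_historical_ensemble
from .sensitivity import ModelVariant
from .stage_models import (
    GompertzStageParams,
    MainstemTable,
    MaturationParams,
    SarParams,
    UpstreamParams,
    sar_probability,
    simulate_ar1_effects,
    transport_assign,
)

__all__ = [
    "DEFAULT_COVARIATES",
    "DEFAULT_POPULATIONS",
    "SyntheticWorld",
    "default_covariance_model",
    "default_lifecycle_params",
    "default_priors",
    "default_variants",
    "default_world",
    "gen_environment",
    "gen_gcm_ensemble",
    "gen_mainstem_table",
    "gen_observed_spawners",
    "gen_freshwater_draws",
    "gen_tagged_fish",
    "write_world",
]

DEFAULT_COVARIATES = (
    "sst_arc", "sst_wa", "upwelling", "summer_air_temp",
    "fall_flow", "summer_flow", "spring_temp", "spring_flow",
)
TEMPERATURE_COVS = ("sst_arc", "sst_wa", "summer_air_temp", "spring_temp")
FLOW_COVS = ("fall_flow", "summer_flow", "spring_flow")

DEFAULT_POPULATIONS = (
    "bear_valley", "secesh", "marsh_creek", "sulphur_creek",
    "valley_creek", "big_creek", "loon_creek", "camas_creek",
)
# log-productivity offsets spreading equilibrium abundance across ~45-600
_POP_A1_OFFSET = {
    "bear_valley": 1.0, "secesh": 0.7, "marsh_creek": 0.35,
    "sulphur_creek": 0.0, "valley_creek": -0.3, "big_creek": -0.6,
    "loon_creek": -1.0, "camas_creek": -1.35,
}

HISTORICAL_YEARS = (2000, 2015)
SAR_SEASON = (99, 189)          # day-of-year window of ocean entry (Apr 9 - Jul 8)
TRANSPORT_WINDOW = (100, 160)


def default_covariance_model(rho: float = 0.4) -> CovarianceModel:
    """Ground-truth covariate process: unit-variance anomalies, one AR
    coefficient, block-structured cross-correlations (temperatures
    positively coupled, flows positively coupled, upwelling opposing the
    ocean temperatures)."""
    n = len(DEFAULT_COVARIATES)
    R = np.full((n, n), 0.15)
    np.fill_diagonal(R, 1.0)
    idx = {name: i for i, name in enumerate(DEFAULT_COVARIATES)}
    for grp, extra in ((TEMPERATURE_COVS, 0.35), (FLOW_COVS, 0.3)):
        for a in grp:
            for b in grp:
                if a != b:
                    R[idx[a], idx[b]] = 0.15 + extra
    for t in ("sst_arc", "sst_wa"):
        R[idx["upwelling"], idx[t]] = R[idx[t], idx["upwelling"]] = -0.25
    # guarantee positive definiteness of the correlation target
    w = np.min(np.linalg.eigvalsh(R))
    if w < 1e-6:
        R = R + (1e-6 - w) * np.eye(n)
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
    Q = R * (1.0 - rho**2)  # stationary variance 1 for every covariate
    return CovarianceModel(DEFAULT_COVARIATES, np.zeros(n), rho, Q)


def gen_environment(
    truth: CovarianceModel,
    n_years: int,
    seed: int,
    start_year: int = HISTORICAL_YEARS[0],
) -> CovariateMatrix:
    """One exact draw from the multivariate AR(1) covariate law."""
    rng = substream(seed, "synth-environment")
    return simulate_detrended(truth, n_years, 1, rng, start_year=start_year)[0]


def gen_gcm_ensemble(
    covariate: str,
    scenario: str,
    n_members: int = 20,
    trend_shape: str = "linear",
    trend_magnitude: float = 2.0,
    noise_sd: float = 0.3,
    member_slope_sd: float = 0.15,
    noise_rho: float = 0.3,
    seed: int = 0,
    years: tuple[int, int] = (1990, 2100),
) -> GcmEnsemble:
    """Synthetic GCM ensemble: shared smooth trend (zero at the 2015
    baseline center), per-member slope perturbation, AR(1) interannual
    noise.  ``trend_magnitude`` is the trend value reached in 2089, in
    covariate units."""
    if n_members < 1:
        raise ValueError("need at least one member")
    if trend_shape not in ("linear", "leveling"):
        raise ValueError("trend_shape must be 'linear' or 'leveling'")
    yr = np.arange(years[0], years[1] + 1)
    s = (yr - 2015) / (2089 - 2015)
    if trend_shape == "linear":
        f = s
    else:  # rises then levels off late in the century
        f = np.tanh(1.8 * s) / np.tanh(1.8)
    base = trend_magnitude * f
    rng = substream(seed, "synth-gcm", covariate, scenario)
    slopes = 1.0 + rng.normal(0.0, member_slope_sd, size=n_members)
    noise = simulate_ar1_effects(yr.size, noise_sd, noise_rho, rng,
                                 size=n_members) if noise_sd > 0 else \
        np.zeros((n_members, yr.size))
    members = slopes[:, None] * base[None, :] + noise
    return GcmEnsemble(covariate, scenario, yr, members)


def gen_mainstem_table(
    seed: int = 0,
    n_records: int = 400,
    temp_effect: float = -0.3,
    flow_effect: float = 0.1,
    shift_per_degree: float = -2.0,
    base_logit_survival: float = 0.3,
    base_p_transport: float = 0.45,
    edges: Sequence[float] = (-3.0, -1.0, 0.0, 1.0, 3.0),
) -> MainstemTable:
    """Synthetic passage table over a spring temperature x flow anomaly grid.

    Emulates the disaggregated output of a daily hydrosystem passage
    reconstruction: records scatter around a monotone response to spring
    conditions (warmer -> lower survival, earlier arrival; wetter ->
    slightly higher survival, less transport)."""
    rng = substream(seed, "synth-mainstem")
    temp = rng.uniform(edges[0], edges[-1], n_records)
    flow = rng.uniform(edges[0], edges[-1], n_records)
    z = (base_logit_survival + temp_effect * temp + flow_effect * flow
         + rng.normal(0.0, 0.2, n_records))
    survival = 1.0 / (1.0 + np.exp(-z))
    shift = shift_per_degree * temp + rng.normal(0.0, 1.0, n_records)
    p_tr = np.clip(base_p_transport - 0.04 * flow + rng.normal(0.0, 0.05, n_records),
                   0.0, 0.95)
    e = np.asarray(edges, dtype=float)
    return MainstemTable(e, e, temp, flow, survival, shift, p_tr)


def default_maturation() -> MaturationParams:
    return MaturationParams(S0=0.7, b3=0.1, b4=0.6, F5=1.1)


def default_priors() -> PriorSpec:
    """Calibration priors, deliberately centered away from the world truth."""
    return PriorSpec(
        S0=BetaPrior(0.6, 10.0),
        b3=BetaPrior(0.15, 10.0),
        b4=BetaPrior(0.5, 10.0),
        F5=NormalPrior(1.0, 0.1),
    )


def default_variants() -> dict[int, ModelVariant]:
    """Covariate models 1-3 (freshwater x marine covariate swaps)."""
    return {
        1: ModelVariant(
            1,
            g2_c={"summer_air_temp": -0.12, "fall_flow": 0.1},
            sar_in_river_betas={"sst_arc": -0.35, "sst_wa": -0.2},
            sar_transported_betas={"sst_arc": -0.3},
        ),
        2: ModelVariant(
            2,
            g2_c={"summer_flow": 0.15},
            sar_in_river_betas={"sst_arc": -0.35, "sst_wa": -0.2},
            sar_transported_betas={"sst_arc": -0.3},
        ),
        3: ModelVariant(
            3,
            g2_c={"summer_air_temp": -0.12, "fall_flow": 0.1},
            sar_in_river_betas={"sst_arc": -0.35, "upwelling": 0.2},
            sar_transported_betas={"sst_wa": -0.25},
        ),
    }


def default_lifecycle_params(
    population: str = "sulphur_creek",
    variant: int = 1,
    mainstem_seed: int = 0,
) -> LifecycleParams:
    """Ground-truth stage parameters for one population under one model."""
    v = default_variants()[variant]
    a1 = 7.85 + _POP_A1_OFFSET.get(population, 0.0)
    return LifecycleParams(
        g1=GompertzStageParams(a=a1, b=-0.25, c={}, sigma_proc=0.25),
        g2=GompertzStageParams(a=3.3, b=-0.4, c=dict(v.g2_c), sigma_proc=0.3),
        mainstem=gen_mainstem_table(seed=mainstem_seed),
        sar_in_river=SarParams(
            intercept=-3.9, betas=dict(v.sar_in_river_betas),
            day_sd=0.3, day_rho=0.9, dayyear_sd=0.2, dayyear_rho=0.8,
            variant="in_river",
        ),
        sar_transported=SarParams(
            intercept=-3.7, betas=dict(v.sar_transported_betas),
            day_sd=0.3, day_rho=0.9, dayyear_sd=0.2, dayyear_rho=0.8,
            variant="transported",
        ),
        maturation=default_maturation(),
        upstream=UpstreamParams(intercept=2.0, betas={"spring_temp": -0.3}),
        prespawn=0.9,
    )


def gen_freshwater_draws(
    params: LifecycleParams,
    n: int = 1000,
    seed: int = 0,
    sd_a: float = 0.15,
    sd_b: float = 0.05,
    sd_c: float = 0.03,
    ab_corr: float = -0.6,
) -> pd.DataFrame:
    """Stand-in posterior draws for the freshwater (Gompertz) parameters.

    Draws jitter the truth with a negative correlation between each stage's
    productivity and density-dependence (the classic stock-recruit
    trade-off), so joint retention has real correlation structure to
    preserve."""
    rng = substream(seed, "synth-freshwater")
    cov = np.array([[sd_a**2, ab_corr * sd_a * sd_b],
                    [ab_corr * sd_a * sd_b, sd_b**2]])
    d1 = rng.multivariate_normal([params.g1.a, params.g1.b], cov, size=n)
    d2 = rng.multivariate_normal([params.g2.a, params.g2.b], cov, size=n)
    out = pd.DataFrame({
        "a1": d1[:, 0], "b1": np.clip(d1[:, 1], -0.95, -0.01),
        "a2": d2[:, 0], "b2": np.clip(d2[:, 1], -0.95, -0.01),
    })
    for name, coef in params.g2.c.items():
        out[f"c2:{name}"] = rng.normal(coef, sd_c, size=n)
    return out


def gen_observed_spawners(
    params: LifecycleParams,
    historical_env: CovariateMatrix,
    obs_cv: float = 0.15,
    expansion: float = 2.0,
    seed: int = 0,
    init_spawners: float | None = None,
    population: str = "pop",
) -> tuple[pd.DataFrame, dict]:
    """Redd-count-style observed spawner series from the true life cycle.

    Runs the truth model over the historical record, converts spawners to
    redds (divide by the redds-to-spawners expansion), perturbs the counts
    with lognormal observation error of coefficient of variation ``obs_cv``,
    and expands back.  Returns the observation table and the recorded truth.
    """
    if obs_cv < 0:
        raise ValueError("obs_cv must be >= 0")
    if init_spawners is None:
        init_spawners = _equilibrium_spawners(params, historical_env)
    res = run_historical_ensemble(
        params, historical_env, 1, seed=child_seed(seed, "synth-observed-run"),
        init_spawners=init_spawners)
    true_spawners = res["spawners"][0]
    rng = substream(seed, "synth-observed-noise")
    sigma = np.sqrt(np.log1p(obs_cv**2))
    noise = (np.exp(rng.normal(-0.5 * sigma**2, sigma, true_spawners.shape))
             if obs_cv > 0 else np.ones_like(true_spawners))
    redds = true_spawners / expansion
    observed = redds * noise * expansion
    df = pd.DataFrame({
        "population": population,
        "year": historical_env.years,
        "spawners": observed,
        "redds": redds * noise,
    })
    truth = {
        "true_spawners": true_spawners.tolist(),
        "init_spawners": float(init_spawners),
        "obs_cv": obs_cv,
        "expansion": expansion,
        "maturation": asdict(params.maturation),
    }
    return df, truth


def _equilibrium_spawners(params: LifecycleParams, env: CovariateMatrix,
                          n_years: int = 120) -> float:
    """Deterministic long-run spawner level at mean covariates."""
    mean_env = CovariateMatrix(
        np.arange(2000, 2000 + n_years), env.names,
        np.tile(env.values.mean(axis=0), (n_years, 1)))
    res = run_historical_ensemble(params, mean_env, 1, seed=0,
                                  init_spawners=100.0, stochastic=False)
    return float(res["spawners"][0, -1])


def gen_tagged_fish(
    sar_params: Mapping[str, SarParams],
    env: CovariateMatrix,
    n_per_year: int = 5000,
    day_mean: float = 130.0,
    day_sd: float = 12.0,
    season: tuple[int, int] = SAR_SEASON,
    transport_window: tuple[int, int] = TRANSPORT_WINDOW,
    p_transport_within: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Per-fish tagging records with AR(1) day and day-by-year effects.

    Each fish gets an arrival day (truncated normal within the season), a
    transport flag from the fixed-calendar rule, and a Bernoulli return
    with probability from its variant's SAR model evaluated with that
    year's realized day-effect curves."""
    if n_per_year < 1:
        raise ValueError("n_per_year must be >= 1")
    rng = substream(seed, "synth-tagged")
    lo, hi = season
    n_days = hi - lo + 1
    years = env.years
    day_curves = {
        v: simulate_ar1_effects(n_days, p.day_sd, p.day_rho, rng)
        for v, p in sar_params.items()
    }
    rows = []
    for yi, year in enumerate(years):
        covs = {name: env.values[yi, j] for j, name in enumerate(env.names)}
        dy_curves = {
            v: simulate_ar1_effects(n_days, p.dayyear_sd, p.dayyear_rho, rng)
            for v, p in sar_params.items()
        }
        days = np.clip(np.round(rng.normal(day_mean, day_sd, n_per_year)),
                       lo, hi).astype(int)
        transported = transport_assign(days, transport_window[0],
                                       transport_window[1], p_transport_within,
                                       rng.random(n_per_year))
        for variant, mask in (("transported", transported), ("in_river", ~transported)):
            p = sar_params[variant]
            d = days[mask]
            prob = sar_probability(
                covs, d, p,
                day_effect=day_curves[variant][d - lo],
                dayyear_effect=dy_curves[variant][d - lo],
            )
            ret = (rng.random(d.size) < prob).astype(int)
            block = pd.DataFrame({
                "year": year, "arrival_day": d,
                "transported": int(variant == "transported"),
                "returned": ret,
            })
            for name in env.names:
                block[name] = covs[name]
            rows.append(block)
    df = pd.concat(rows, ignore_index=True).sort_values(
        ["year", "arrival_day", "transported"]).reset_index(drop=True)
    truth = {v: {
        "intercept": p.intercept, "betas": dict(p.betas),
        "day_sd": p.day_sd, "day_rho": p.day_rho,
        "dayyear_sd": p.dayyear_sd, "dayyear_rho": p.dayyear_rho,
    } for v, p in sar_params.items()}
    return df, truth


@dataclass(frozen=True)
class SyntheticWorld:
    """The full synthetic study system consumed by the pipeline."""

    seed: int
    covariance_truth: CovarianceModel
    historical_env: CovariateMatrix
    params: Mapping[str, LifecycleParams]        # per population (Model 1 truth)
    variants: Mapping[int, ModelVariant]
    priors: PriorSpec
    observed: Mapping[str, pd.DataFrame]
    observed_truth: Mapping[str, dict]
    freshwater_draws: Mapping[str, pd.DataFrame]
    init_spawners: Mapping[str, float]

    @property
    def populations(self) -> tuple[str, ...]:
        return tuple(self.params)


def default_world(
    seed: int,
    populations: Sequence[str] = DEFAULT_POPULATIONS,
    n_freshwater_draws: int = 500,
    obs_cv: float = 0.15,
) -> SyntheticWorld:
    """Assemble the default synthetic study system from one master seed."""
    truth = default_covariance_model()
    hist = gen_environment(
        truth, HISTORICAL_YEARS[1] - HISTORICAL_YEARS[0] + 1,
        seed=child_seed(seed, "world-env"), start_year=HISTORICAL_YEARS[0])
    params, observed, obs_truth, fresh, init = {}, {}, {}, {}, {}
    for pop in populations:
        p = default_lifecycle_params(pop)
        params[pop] = p
        eq = _equilibrium_spawners(p, hist)
        init[pop] = eq
        observed[pop], obs_truth[pop] = gen_observed_spawners(
            p, hist, obs_cv=obs_cv, seed=child_seed(seed, "world-obs", pop),
            init_spawners=eq, population=pop)
        fresh[pop] = gen_freshwater_draws(
            p, n=n_freshwater_draws, seed=child_seed(seed, "world-fresh", pop))
    return SyntheticWorld(
        seed=seed, covariance_truth=truth, historical_env=hist,
        params=params, variants=default_variants(), priors=default_priors(),
        observed=observed, observed_truth=obs_truth,
        freshwater_draws=fresh, init_spawners=init,
    )


def write_world(world: SyntheticWorld, outdir) -> None:
    """Write every CSV the pipeline reads, plus truth sidecars."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    world.historical_env.write_csv(out / "covariates.csv")
    pd.concat(world.observed.values()).to_csv(out / "observed_spawners.csv",
                                              index=False, float_format="%.17g")
    for pop, df in world.freshwater_draws.items():
        df.to_csv(out / f"freshwater_draws_{pop}.csv", index=False,
                  float_format="%.17g")
    next(iter(world.params.values())).mainstem.write_csv(out / "mainstem_table.csv")
    truth = {
        "seed": world.seed,
        "covariance": {
            "rho": float(np.asarray(world.covariance_truth.rho)),
            "Q": np.asarray(world.covariance_truth.Q).tolist(),
            "mu": np.asarray(world.covariance_truth.mu).tolist(),
            "names": list(world.covariance_truth.names),
        },
        "maturation": asdict(default_maturation()),
        "init_spawners": {k: float(v) for k, v in world.init_spawners.items()},
        "observed": {k: v for k, v in world.observed_truth.items()},
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=2))
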