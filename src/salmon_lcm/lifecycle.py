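"""Age-structured life-cycle projection for stream-type Chinook salmon.

One calendar year chains, in order: spawner-to-parr recruitment (Gompertz),
parr-to-smolt tributary rearing (Gompertz with climate covariates), juvenile
mainstem passage (binned empirical emulator with a transported fraction),
ocean entry and smolt-to-adult return partitioned into ages 3/4/5 by the
maturation parameters, adult upstream survival, a constant prespawn
survival, and the age-weighted effective-spawner sum.  Brood-year
alignment: spawners in fall of year t produce parr exposed to year t+1
rearing conditions; smolts migrate in spring of year t+2; jacks return at
t+3 and adults at t+4 (age 4) and t+5 (age 5).

Two implementations share this logic: :func:`step_year` advances a single
:class:`PopulationState` one year (the readable scalar reference), and
:func:`simulate_ensemble` runs many simulations at once with all
stochastic draws pre-generated in a fixed order so that common random
numbers carry across scenario comparisons.  In projection mode the cohort
is represented by its mean ocean-entry day, so the AR(1) day and
day-by-year effects are evaluated at a single day per year and drawn from
their stationary marginal, N(0, day_sd^2 + dayyear_sd^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._rng import substream
from .envsim import ClimateScenario, CovariateMatrix
from .stage_models import (
    GompertzStageParams,
    MainstemTable,
    MaturationParams,
    SarParams,
    UpstreamParams,
    sar_denominator,
    upstream_survival,
)

__all__ = [
    "LifecycleParams",
    "PopulationState",
    "Trajectory",
    "StageValueError",
    "STAGES",
    "step_year",
    "simulate_ensemble",
    "stage_env_from_scenario",
    "run_projection",
    "run_historical_ensemble",
    "trajectories_to_frame",
]

STAGES = ("tributary", "mainstem", "sar", "upstream")
SPINUP_YEARS = 5


class StageValueError(RuntimeError):
    """A stage produced a NaN or negative abundance; names the stage."""

    def __init__(self, stage: str, message: str = ""):
        super().__init__(f"invalid value in stage {stage!r}" + (f": {message}" if message else ""))
        self.stage = stage


@dataclass(frozen=True)
class LifecycleParams:
    """All stage parameters for one population under one model variant."""

    g1: GompertzStageParams            # spawner -> parr
    g2: GompertzStageParams            # parr -> smolt (tributary rearing)
    mainstem: MainstemTable
    sar_in_river: SarParams
    sar_transported: SarParams
    maturation: MaturationParams
    upstream: UpstreamParams
    prespawn: float = 0.9
    spring_temp_cov: str = "spring_temp"
    spring_flow_cov: str = "spring_flow"

    def __post_init__(self):
        if not 0.0 <= self.prespawn <= 1.0:
            raise ValueError("prespawn survival must lie in [0, 1]")


@dataclass(frozen=True)
class PopulationState:
    """State of one population at the end of one calendar year."""

    year: int
    spawners_by_age: Mapping[int, float]
    parr: float
    smolts: float                      # N2: this year's ocean entrants
    ocean: tuple[float, float, float]  # latent (N3, N4, N5) of this entry cohort
    pending: Mapping[int, tuple[float, float, float]] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "spawners_by_age", dict(self.spawners_by_age))
        object.__setattr__(self, "pending", dict(self.pending))
        vals = [self.parr, self.smolts, *self.ocean, *self.spawners_by_age.values()]
        for v in vals:
            if not np.isfinite(v) or v < 0:
                raise ValueError("all counts must be finite and >= 0")


def state_effective_spawners(state: PopulationState, F5: float) -> float:
    s = state.spawners_by_age
    return s.get(4, 0.0) + F5 * s.get(5, 0.0)


@dataclass(frozen=True)
class Trajectory:
    """Annual effective-spawner and smolt series for one simulation."""

    population: str
    simulation: int
    years: np.ndarray
    spawners: np.ndarray
    smolts: np.ndarray

    def __post_init__(self):
        years = np.asarray(self.years, dtype=int)
        spawners = np.asarray(self.spawners, dtype=float)
        smolts = np.asarray(self.smolts, dtype=float)
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "spawners", spawners)
        object.__setattr__(self, "smolts", smolts)
        if spawners.shape != years.shape or smolts.shape != years.shape:
            raise ValueError("series lengths must equal the projection span")
        if np.any(spawners < 0) or np.any(smolts < 0):
            raise ValueError("trajectories cannot contain negative entries")


def _cov_dict(env: np.ndarray, t: int, names: Sequence[str]) -> dict:
    return {name: env[..., t, j] for j, name in enumerate(names)}


def _gompertz_vec(stock, a, b, c: Mapping[str, float], covs: Mapping, eps):
    stock = np.asarray(stock, dtype=float)
    term = 0.0
    for name, coef in c.items():
        term = term + coef * covs[name]
    with np.errstate(divide="ignore"):
        out = np.exp(a + (1.0 + b) * np.log(np.where(stock > 0, stock, 1.0))
                     + term + eps)
    return np.where(stock > 0, out, 0.0)


def _check(stage: str, *arrays):
    for arr in arrays:
        arr = np.asarray(arr)
        if np.any(~np.isfinite(arr)) or np.any(arr < -1e-9):
            raise StageValueError(stage, "NaN or negative abundance")


# ---------------------------------------------------------------------------
# vectorized ensemble kernel


def simulate_ensemble(
    params: LifecycleParams,
    env: Mapping[str, np.ndarray],
    cov_names: Sequence[str],
    years: np.ndarray,
    n_sims: int,
    init_spawners,
    rng: np.random.Generator | None = None,
    overrides: Mapping[str, np.ndarray] | None = None,
    stochastic: bool = True,
) -> dict:
    """Run ``n_sims`` simulations over ``years``.

    ``env`` maps each stage in :data:`STAGES` to an array of shape
    (n_sims, n_years, n_cov) or (n_years, n_cov) (shared across sims).
    ``overrides`` supplies per-simulation parameter arrays (keys 'a1', 'b1',
    'a2', 'b2', 'c2:<covariate>', 'S0', 'b3', 'b4', 'F5') for batched
    calibration.  Returns a dict with 'spawners' and 'smolts'
    (n_sims, n_years) plus an 'implausible' per-sim flag for parameter sets
    that imply first-winter ocean survival above one.
    """
    years = np.asarray(years, dtype=int)
    n_years = years.size
    names = tuple(cov_names)
    env3 = {}
    for stage in STAGES:
        arr = np.asarray(env[stage], dtype=float)
        if arr.ndim == 2:
            arr = np.broadcast_to(arr, (n_sims,) + arr.shape)
        if arr.shape != (n_sims, n_years, len(names)):
            raise ValueError(f"env[{stage!r}] has shape {arr.shape}; expected "
                             f"({n_sims}, {n_years}, {len(names)})")
        env3[stage] = arr

    ov = dict(overrides or {})

    def par(key, default):
        v = ov.get(key, default)
        return np.asarray(v, dtype=float)

    a1, b1 = par("a1", params.g1.a), par("b1", params.g1.b)
    a2, b2 = par("a2", params.g2.a), par("b2", params.g2.b)
    c2 = {k: par(f"c2:{k}", v) for k, v in params.g2.c.items()}
    c1 = dict(params.g1.c)
    S0 = par("S0", params.maturation.S0)
    b3 = par("b3", params.maturation.b3)
    b4 = par("b4", params.maturation.b4)
    F5 = par("F5", params.maturation.F5)

    # pre-draw every stochastic input in a fixed order so common random
    # numbers hold across scenario cells that share the seed
    if stochastic:
        if rng is None:
            raise ValueError("stochastic mode needs an rng")
        eps1 = rng.normal(0.0, params.g1.sigma_proc, (n_sims, n_years))
        eps2 = rng.normal(0.0, params.g2.sigma_proc, (n_sims, n_years))
        sd_ir = np.hypot(params.sar_in_river.day_sd, params.sar_in_river.dayyear_sd)
        sd_tr = np.hypot(params.sar_transported.day_sd, params.sar_transported.dayyear_sd)
        day_ir = rng.normal(0.0, sd_ir, (n_sims, n_years))
        day_tr = rng.normal(0.0, sd_tr, (n_sims, n_years))
        u_main = rng.random((n_sims, n_years))
    else:
        eps1 = eps2 = day_ir = day_tr = np.zeros((n_sims, n_years))
        u_main = None

    spawners = np.zeros((n_sims, n_years))
    smolts = np.zeros((n_sims, n_years))
    pend3 = np.zeros((n_sims, n_years))
    pend4 = np.zeros((n_sims, n_years))
    pend5 = np.zeros((n_sims, n_years))
    implausible = np.zeros(n_sims, dtype=bool)
    init = np.broadcast_to(np.asarray(init_spawners, dtype=float), (n_sims,))

    for t in range(n_years):
        if t < SPINUP_YEARS:
            E = init.copy()
        else:
            up = upstream_survival(_cov_dict(env3["upstream"], t, names), params.upstream)
            surv = up * params.prespawn
            E = pend4[:, t] * surv + F5 * (pend5[:, t] * surv)
        _check("effective_spawners", E)
        spawners[:, t] = E

        # propagate brood year t forward where the window allows
        if t + 2 >= n_years:
            continue
        trib1 = _cov_dict(env3["tributary"], t + 1, names)
        parr = _gompertz_vec(E, a1, b1, c1, trib1, eps1[:, t + 1])
        _check("spawner_to_parr", parr)
        trib2 = _cov_dict(env3["tributary"], t + 2, names)
        smolt_trib = _gompertz_vec(parr, a2, b2, c2, trib2, eps2[:, t + 2])
        _check("parr_to_smolt", smolt_trib)
        smolts[:, t + 2] = smolt_trib

        stemp = env3["mainstem"][:, t + 2, names.index(params.spring_temp_cov)]
        sflow = env3["mainstem"][:, t + 2, names.index(params.spring_flow_cov)]
        if stochastic:
            surv_m, _shift, p_tr = _table_sample_u(params.mainstem, stemp, sflow,
                                                   u_main[:, t + 2])
        else:
            surv_m, _shift, p_tr = params.mainstem.bin_means(stemp, sflow)
        N2 = smolt_trib * surv_m
        _check("mainstem", N2)

        sar_covs = _cov_dict(env3["sar"], t + 2, names)
        z_ir = params.sar_in_river.intercept + day_ir[:, t + 2]
        for name, coef in params.sar_in_river.betas.items():
            z_ir = z_ir + coef * sar_covs[name]
        z_tr = params.sar_transported.intercept + day_tr[:, t + 2]
        for name, coef in params.sar_transported.betas.items():
            z_tr = z_tr + coef * sar_covs[name]
        S_sar = p_tr / (1.0 + np.exp(-z_tr)) + (1.0 - p_tr) / (1.0 + np.exp(-z_ir))
        _check("sar", S_sar)

        S3 = S_sar / sar_denominator(S0, b3, b4)
        implausible |= np.broadcast_to(S3 > 1.0, (n_sims,))
        N3 = S3 * N2
        N4 = (1.0 - b3) * N3 * S0
        N5 = (1.0 - b4) * N4 * S0
        _check("ocean", N3, N4, N5)
        if t + 3 < n_years:
            pend3[:, t + 3] += b3 * N3
        if t + 4 < n_years:
            pend4[:, t + 4] += b4 * N4
        if t + 5 < n_years:
            pend5[:, t + 5] += N5

    return {"years": years, "spawners": spawners, "smolts": smolts,
            "implausible": implausible}


def _table_sample_u(table: MainstemTable, temp, flow, u):
    """Record draw per element using externally supplied uniforms (CRN-safe)."""
    temp = np.asarray(temp, float)
    want = table._bin_of(temp, np.asarray(flow, float))
    occupied = np.unique(table._bin_index)
    idx = np.empty(want.size, dtype=int)
    flat_u = np.asarray(u, float).ravel()
    for b in np.unique(want):
        mask = want == b
        use = b if b in occupied else occupied[np.argmin(np.abs(occupied - b))]
        pool = np.nonzero(table._bin_index == use)[0]
        idx[mask] = pool[(flat_u[mask] * pool.size).astype(int).clip(0, pool.size - 1)]
    shape = temp.shape
    return (table.survival[idx].reshape(shape),
            table.arrival_shift[idx].reshape(shape),
            table.p_transport[idx].reshape(shape))


# ---------------------------------------------------------------------------
# scalar reference implementation


def step_year(
    state: PopulationState,
    params: LifecycleParams,
    env: Mapping[str, Mapping[str, float]],
    rng: np.random.Generator | None = None,
) -> PopulationState:
    """Advance one population one calendar year (scalar reference path).

    ``env`` maps each stage to that year's covariate values (the year being
    entered).  With ``rng=None`` the step is fully deterministic (process
    noise off, mainstem bin means).
    """
    year = state.year + 1
    F5 = params.maturation.F5
    E_prev = state_effective_spawners(state, F5)

    if rng is not None:
        eps1 = rng.normal(0.0, params.g1.sigma_proc)
        eps2 = rng.normal(0.0, params.g2.sigma_proc)
        day_ir = rng.normal(0.0, np.hypot(params.sar_in_river.day_sd,
                                          params.sar_in_river.dayyear_sd))
        day_tr = rng.normal(0.0, np.hypot(params.sar_transported.day_sd,
                                          params.sar_transported.dayyear_sd))
        u_main = rng.random()
    else:
        eps1 = eps2 = day_ir = day_tr = 0.0
        u_main = None

    trib = env["tributary"]
    parr = float(_gompertz_vec(E_prev, params.g1.a, params.g1.b, params.g1.c,
                               trib, eps1))
    _check("spawner_to_parr", parr)
    smolt_trib = float(_gompertz_vec(state.parr, params.g2.a, params.g2.b,
                                     params.g2.c, trib, eps2))
    _check("parr_to_smolt", smolt_trib)

    stemp = env["mainstem"][params.spring_temp_cov]
    sflow = env["mainstem"][params.spring_flow_cov]
    if rng is not None:
        surv_m, _shift, p_tr = _table_sample_u(
            params.mainstem, np.atleast_1d(stemp), np.atleast_1d(sflow),
            np.atleast_1d(u_main))
        surv_m, p_tr = float(surv_m[0]), float(p_tr[0])
    else:
        s, _a, p = params.mainstem.bin_means(np.atleast_1d(stemp), np.atleast_1d(sflow))
        surv_m, p_tr = float(s[0]), float(p[0])
    N2 = smolt_trib * surv_m
    _check("mainstem", N2)

    sar_covs = env["sar"]
    z_ir = params.sar_in_river.intercept + day_ir
    for name, coef in params.sar_in_river.betas.items():
        z_ir += coef * sar_covs[name]
    z_tr = params.sar_transported.intercept + day_tr
    for name, coef in params.sar_transported.betas.items():
        z_tr += coef * sar_covs[name]
    S_sar = p_tr / (1.0 + np.exp(-z_tr)) + (1.0 - p_tr) / (1.0 + np.exp(-z_ir))

    m = params.maturation
    S3 = S_sar / float(sar_denominator(m.S0, m.b3, m.b4))
    N3 = S3 * N2
    N4 = (1.0 - m.b3) * N3 * m.S0
    N5 = (1.0 - m.b4) * N4 * m.S0
    _check("ocean", N3, N4, N5)

    pending = dict(state.pending)
    pending[year + 1] = tuple(np.add(pending.get(year + 1, (0.0, 0.0, 0.0)),
                                     (m.b3 * N3, 0.0, 0.0)))
    pending[year + 2] = tuple(np.add(pending.get(year + 2, (0.0, 0.0, 0.0)),
                                     (0.0, m.b4 * N4, 0.0)))
    pending[year + 3] = tuple(np.add(pending.get(year + 3, (0.0, 0.0, 0.0)),
                                     (0.0, 0.0, N5)))

    arr3, arr4, arr5 = pending.pop(year, (0.0, 0.0, 0.0))
    up = float(upstream_survival(env["upstream"], params.upstream)) * params.prespawn
    spawners_by_age = {3: arr3 * up, 4: arr4 * up, 5: arr5 * up}
    _check("upstream", *spawners_by_age.values())

    return PopulationState(
        year=year,
        spawners_by_age=spawners_by_age,
        parr=parr,
        smolts=N2,
        ocean=(N3, N4, N5),
        pending=pending,
    )


# ---------------------------------------------------------------------------
# drivers


def stage_env_from_scenario(
    scenario: ClimateScenario,
    years: np.ndarray,
    n_sims: int,
    forced_stages: Sequence[str] = STAGES,
) -> tuple[dict, tuple[str, ...]]:
    """Per-stage environment arrays: detrended draws plus offsets on forced stages."""
    years = np.asarray(years, dtype=int)
    if scenario.n_draws < n_sims:
        raise ValueError(
            f"scenario has {scenario.n_draws} detrended draws but {n_sims} "
            "iterations were requested (iteration i uses draw i)"
        )
    for s in forced_stages:
        if s not in STAGES:
            raise ValueError(f"unknown stage {s!r}; valid stages: {STAGES}")
    draw0 = scenario.detrended_draws[0]
    names = draw0.names
    idx0 = np.searchsorted(draw0.years, years)
    if (np.any(idx0 >= draw0.years.size)
            or np.any(draw0.years[np.clip(idx0, 0, draw0.years.size - 1)] != years)):
        raise ValueError("scenario draws do not cover the projection years")
    base = np.stack([scenario.detrended_draws[i].values[idx0]
                     for i in range(n_sims)])
    offsets = np.zeros((years.size, len(names)))
    for name, trend in scenario.trends.items():
        if name not in names:
            raise KeyError(f"trend covariate {name!r} absent from draws")
        offsets[:, names.index(name)] = trend.offsets_for(years)
    forced = base + offsets
    env = {s: (forced if s in forced_stages else base) for s in STAGES}
    return env, names


def run_projection(
    params: LifecycleParams,
    scenario: ClimateScenario,
    n_iter: int,
    seed: int,
    init_spawners: float,
    years: tuple[int, int] = (2015, 2089),
    population: str = "pop",
    stochastic: bool = True,
    forced_stages: Sequence[str] = STAGES,
) -> list[Trajectory]:
    """Project one population under one climate scenario.

    Iteration i pairs with detrended draw i; all randomness flows from the
    seed, so identical seeds give bit-identical trajectory sets.
    """
    year_axis = np.arange(years[0], years[1] + 1)
    env, names = stage_env_from_scenario(scenario, year_axis, n_iter, forced_stages)
    rng = substream(seed, "lifecycle", population)
    res = simulate_ensemble(params, env, names, year_axis, n_iter,
                            init_spawners, rng=rng, stochastic=stochastic)
    return [
        Trajectory(population, i, year_axis, res["spawners"][i], res["smolts"][i])
        for i in range(n_iter)
    ]


def run_historical_ensemble(
    params: LifecycleParams,
    env_matrix: CovariateMatrix,
    n_sims: int,
    seed: int,
    init_spawners,
    overrides: Mapping[str, np.ndarray] | None = None,
    stochastic: bool = True,
) -> dict:
    """Run many simulations against one shared historical covariate record.

    Used by calibration: each simulation may carry its own candidate
    parameter set through ``overrides``.
    """
    env = {s: env_matrix.values for s in STAGES}
    rng = substream(seed, "historical")
    return simulate_ensemble(params, env, env_matrix.names, env_matrix.years,
                             n_sims, init_spawners, rng=rng,
                             overrides=overrides, stochastic=stochastic)


def trajectories_to_frame(trajectories: Sequence[Trajectory]) -> pd.DataFrame:
    rows = []
    for tr in trajectories:
        rows.append(pd.DataFrame({
            "population": tr.population,
            "simulation": tr.simulation,
            "year": tr.years,
            "spawners": tr.spawners,
            "smolts": tr.smolts,
        }))
    return pd.concat(rows, ignore_index=True)
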