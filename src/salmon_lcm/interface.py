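"""Experiment orchestration: config schema, seeding, manifests.

An experiment is described by a small structured config (YAML or dict) and
one master seed.  ``run_experiment`` chains the pipeline end to end —
synthetic world, covariance fit, detrended simulation, trend construction,
ABC calibration, projection, and risk summaries — writing CSV outputs and a
manifest (config hash, seed, package version) so a run can be reproduced
exactly.  All randomness flows from the master seed through named
substreams.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from . import __version__
from ._rng import child_seed
from .calibration import calibrate
from .envsim import ClimateScenario, extract_trend, fit_covariance_model, simulate_detrended
from .lifecycle import run_projection, trajectories_to_frame
from .risk import summarize_risk
from .sensitivity import stage_forcing_factorial, wire_variant
from .stage_models import MaturationParams
from .synthdata import default_world, gen_gcm_ensemble, write_world

__all__ = ["ExperimentConfig", "ConfigError", "run_experiment", "load_config"]

# trend magnitude reached in 2089, in anomaly units, per scenario
DEFAULT_TREND_MAGNITUDES = {
    "rcp85": {"sst_arc": 2.2, "sst_wa": 2.0, "summer_air_temp": 2.2,
              "spring_temp": 1.8, "summer_flow": -1.0, "fall_flow": 0.2,
              "spring_flow": 0.3, "upwelling": 0.4},
    "rcp45": {"sst_arc": 1.2, "sst_wa": 1.1, "summer_air_temp": 1.2,
              "spring_temp": 1.0, "summer_flow": -0.6, "fall_flow": 0.1,
              "spring_flow": 0.2, "upwelling": 0.2},
}

PROFILES = {
    "test": {"n_iter": 50, "n_candidates": 2000, "fraction": 0.05},
    "full": {"n_iter": 1000, "n_candidates": 500_000, "fraction": 0.002},
}


class ConfigError(ValueError):
    """Config failed schema validation; message lists the offending keys."""


_SCHEMA_KEYS = {
    "populations", "model_variant", "scenario", "quantile", "years",
    "n_iter", "n_candidates", "fraction", "profile", "sensitivity",
    "trend_shape",
}


@dataclass(frozen=True)
class ExperimentConfig:
    populations: tuple[str, ...] = ("sulphur_creek",)
    model_variant: int = 1
    scenario: str = "detrended"          # detrended | rcp45 | rcp85
    quantile: int = 50
    years: tuple[int, int] = (2015, 2089)
    n_iter: int = 50
    n_candidates: int = 2000
    fraction: float = 0.05
    profile: str = "test"
    sensitivity: str | None = None       # None | 'stages'
    trend_shape: str = "linear"

    @classmethod
    def from_dict(cls, raw: Mapping) -> "ExperimentConfig":
        unknown = set(raw) - _SCHEMA_KEYS
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        merged = dict(raw)
        profile = merged.get("profile", "test")
        if profile not in PROFILES:
            raise ConfigError(f"unknown profile {profile!r}; choose from {sorted(PROFILES)}")
        for key, val in PROFILES[profile].items():
            merged.setdefault(key, val)
        if "populations" in merged:
            merged["populations"] = tuple(merged["populations"])
        if "years" in merged:
            merged["years"] = tuple(merged["years"])
        cfg = cls(**merged)
        if cfg.scenario not in ("detrended", "rcp45", "rcp85"):
            raise ConfigError(f"unknown scenario {cfg.scenario!r}")
        if cfg.quantile not in (25, 50, 75):
            raise ConfigError("quantile must be one of 25, 50, 75")
        if cfg.sensitivity not in (None, "stages"):
            raise ConfigError("sensitivity must be null or 'stages'")
        return cfg

    def to_dict(self) -> dict:
        return {
            "populations": list(self.populations),
            "model_variant": self.model_variant,
            "scenario": self.scenario,
            "quantile": self.quantile,
            "years": list(self.years),
            "n_iter": self.n_iter,
            "n_candidates": self.n_candidates,
            "fraction": self.fraction,
            "profile": self.profile,
            "sensitivity": self.sensitivity,
            "trend_shape": self.trend_shape,
        }


def load_config(path) -> ExperimentConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return ExperimentConfig.from_dict(raw)


def build_scenario_trends(
    scenario: str,
    quantile: int,
    seed: int,
    covariates: Sequence[str],
    trend_shape: str = "linear",
) -> dict:
    """Per-covariate ClimateTrend dict from synthetic GCM ensembles."""
    if scenario == "detrended":
        return {}
    mags = DEFAULT_TREND_MAGNITUDES[scenario]
    trends = {}
    for cov in covariates:
        if cov not in mags or mags[cov] == 0:
            continue
        ens = gen_gcm_ensemble(cov, scenario, trend_magnitude=mags[cov],
                               trend_shape=trend_shape,
                               seed=child_seed(seed, "gcm", cov, scenario))
        trends[cov] = extract_trend(ens)[quantile]
    return trends


def run_experiment(config, seed: int, out) -> Path:
    """Execute the full pipeline described by ``config``; returns the output dir.

    Writes, per population: calibration results, trajectories, QET risk and
    decadal geometric-mean summaries; plus the synthetic inputs and a
    manifest recording the config hash, seed and package version.
    """
    if isinstance(config, (str, Path)):
        cfg = load_config(config)
    elif isinstance(config, ExperimentConfig):
        cfg = config
    else:
        cfg = ExperimentConfig.from_dict(config)
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)

    world = default_world(child_seed(seed, "world"),
                          populations=cfg.populations)
    write_world(world, out / "inputs")

    model = fit_covariance_model(world.historical_env)
    n_years = cfg.years[1] - cfg.years[0] + 1
    draws = simulate_detrended(model, n_years, cfg.n_iter,
                               seed=child_seed(seed, "detrended"),
                               start_year=cfg.years[0])
    trends = build_scenario_trends(cfg.scenario, cfg.quantile, seed,
                                   model.names, cfg.trend_shape)
    scenario = ClimateScenario(draws, trends, label=cfg.scenario)

    manifest_outputs = []
    for pop in cfg.populations:
        params = wire_variant(world.params[pop], world.variants[cfg.model_variant])
        observed = world.observed[pop]["spawners"].to_numpy()
        abc = calibrate(
            params, world.priors, observed, world.historical_env,
            world.freshwater_draws[pop],
            n_candidates=cfg.n_candidates, fraction=cfg.fraction,
            seed=child_seed(seed, "abc", pop),
            init_spawners=world.init_spawners[pop], population=pop,
        )
        abc_path = out / f"abc_retained_{pop}.csv"
        abc.retained.to_csv(abc_path, index=False)
        manifest_outputs.append(abc_path.name)

        tuned = MaturationParams(
            S0=float(abc.retained["S0"].median()),
            b3=float(abc.retained["b3"].median()),
            b4=float(abc.retained["b4"].median()),
            F5=float(abc.retained["F5"].median()),
        )
        proj_params = wire_variant(
            world.params[pop], world.variants[cfg.model_variant])
        proj_params = _with_maturation(proj_params, tuned)

        trajs = run_projection(
            proj_params, scenario, cfg.n_iter,
            seed=child_seed(seed, "project", pop),
            init_spawners=world.init_spawners[pop],
            years=cfg.years, population=pop,
        )
        tag = f"{pop}_model{cfg.model_variant}_{cfg.scenario}"
        tpath = out / f"trajectories_{tag}.csv"
        trajectories_to_frame(trajs).to_csv(tpath, index=False)
        manifest_outputs.append(tpath.name)

        summary = summarize_risk(trajs)
        risk_df, geo_df = summary.to_frames()
        rpath = out / f"risk_{tag}.csv"
        gpath = out / f"geomean_{tag}.csv"
        risk_df.to_csv(rpath, index=False)
        geo_df.to_csv(gpath, index=False)
        manifest_outputs += [rpath.name, gpath.name]

        if cfg.sensitivity == "stages":
            fact = stage_forcing_factorial(
                proj_params, scenario, cfg.n_iter,
                seed=child_seed(seed, "sensitivity", pop),
                init_spawners=world.init_spawners[pop],
                years=cfg.years, population=pop,
            )
            spath = out / f"stage_sensitivity_{tag}.csv"
            fact.to_csv(spath, index=False)
            manifest_outputs.append(spath.name)

    cfg_json = json.dumps(cfg.to_dict(), sort_keys=True)
    manifest = {
        "config": cfg.to_dict(),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": int(seed),
        "version": __version__,
        "outputs": manifest_outputs,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def _with_maturation(params, maturation: MaturationParams):
    from dataclasses import replace
    return replace(params, maturation=maturation)
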