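"""Approximate Bayesian Computation calibration of the maturation parameters.

The maturation tuning parameters (S0, b3, b4, F5) cannot be estimated
directly from tagging data, so they are calibrated through the whole life
cycle: candidate parameter sets are drawn from priors (beta for the
(0,1)-supported parameters, normal with sd 0.1 for F5), each candidate is
paired intact with one draw from the freshwater (Gompertz) posterior so
within-set correlations survive selection, the life-cycle model is run
against the historical covariate record, and candidates are ranked by the
two-sample Kolmogorov-Smirnov deviance between simulated and observed
annual spawner distributions.  The top fraction (0.2% of 500,000 draws at
full scale, giving 1000 retained sets) is retained; retained sets whose KS
p-value is not above 0.05 are flagged, never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd
from scipy import stats

from ._rng import child_seed, substream
from .lifecycle import LifecycleParams, run_historical_ensemble
from .envsim import CovariateMatrix

__all__ = [
    "BetaPrior",
    "NormalPrior",
    "PriorSpec",
    "AbcResult",
    "draw_candidates",
    "ks_deviance",
    "abc_select",
    "calibrate",
]

TUNING_KEYS = ("S0", "b3", "b4", "F5")


@dataclass(frozen=True)
class BetaPrior:
    """Beta prior parameterized by mean and concentration (alpha + beta)."""

    mean: float
    concentration: float = 10.0

    def __post_init__(self):
        if not 0.0 < self.mean < 1.0:
            raise ValueError("beta prior mean must lie in (0, 1)")
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")

    @property
    def alpha(self) -> float:
        return self.mean * self.concentration

    @property
    def beta(self) -> float:
        return (1.0 - self.mean) * self.concentration

    def rvs(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.beta(self.alpha, self.beta, size=n)

    def iqr(self) -> float:
        d = stats.beta(self.alpha, self.beta)
        return float(d.ppf(0.75) - d.ppf(0.25))


@dataclass(frozen=True)
class NormalPrior:
    mean: float
    sd: float = 0.1

    def __post_init__(self):
        if self.sd <= 0:
            raise ValueError("sd must be positive")

    def rvs(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.normal(self.mean, self.sd, size=n)

    def iqr(self) -> float:
        return float(2.0 * stats.norm.ppf(0.75) * self.sd)


@dataclass(frozen=True)
class PriorSpec:
    """Priors for the four tuning parameters."""

    S0: BetaPrior
    b3: BetaPrior
    b4: BetaPrior
    F5: NormalPrior

    def prior(self, key: str):
        return getattr(self, key)


@dataclass(frozen=True)
class AbcResult:
    """Retained parameter sets with their KS statistics."""

    retained: pd.DataFrame          # sorted by deviance ascending; has D, p, rank
    n_candidates: int
    fraction: float
    candidates: pd.DataFrame | None = None

    def __post_init__(self):
        expected = int(round(self.fraction * self.n_candidates))
        if len(self.retained) != expected:
            raise ValueError(
                f"retained {len(self.retained)} sets; expected "
                f"round({self.fraction} * {self.n_candidates}) = {expected}"
            )
        d = self.retained["D"].to_numpy()
        if np.any(np.diff(d) < 0):
            raise ValueError("retained sets must be sorted by deviance")

    @property
    def n_retained(self) -> int:
        return len(self.retained)

    @property
    def n_flagged(self) -> int:
        """Retained sets whose KS p-value is not above 0.05."""
        return int((self.retained["p"] <= 0.05).sum())


def draw_candidates(
    priors: PriorSpec,
    freshwater_draws: pd.DataFrame,
    n: int,
    seed: int,
) -> pd.DataFrame:
    """Draw ``n`` candidate parameter vectors.

    Each candidate pairs one complete freshwater-posterior row (kept intact,
    preserving its internal correlations) with independent draws of the four
    tuning parameters from their priors.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if len(freshwater_draws) == 0:
        raise ValueError("freshwater posterior draw set is empty")
    rng = substream(seed, "abc-candidates")
    rows = rng.integers(0, len(freshwater_draws), size=n)
    out = freshwater_draws.iloc[rows].reset_index(drop=True).copy()
    for key in TUNING_KEYS:
        out[key] = priors.prior(key).rvs(n, rng)
    # valid-support guards: clip pathological tail draws rather than reject
    out["S0"] = out["S0"].clip(1e-6, 1 - 1e-6)
    out["F5"] = out["F5"].clip(lower=1e-6)
    return out


def ks_deviance(simulated, observed) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov statistic and asymptotic p-value."""
    simulated = np.asarray(simulated, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if simulated.size == 0 or observed.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(simulated, observed, method="asymp")
    return float(res.statistic), float(res.pvalue)


def abc_select(deviances, fraction: float) -> np.ndarray:
    """Indices of the round(fraction * n) smallest deviances.

    Ties are broken by ascending candidate index so selection is
    deterministic.
    """
    deviances = np.asarray(deviances, dtype=float)
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    k = int(round(fraction * deviances.size))
    if k < 1:
        raise ValueError(
            f"fraction {fraction} of {deviances.size} candidates retains none"
        )
    order = np.argsort(deviances, kind="stable")
    return order[:k]


def calibrate(
    params: LifecycleParams,
    priors: PriorSpec,
    observed_spawners: np.ndarray,
    historical_env: CovariateMatrix,
    freshwater_draws: pd.DataFrame,
    n_candidates: int = 500_000,
    fraction: float = 0.002,
    seed: int = 0,
    init_spawners: float | None = None,
    population: str = "pop",
    keep_candidates: bool = False,
    burn_in: int = 5,
) -> AbcResult:
    """ABC calibration of one population.

    Runs the life cycle once per candidate against the historical covariate
    record, computes the KS deviance of simulated vs observed annual spawner
    distributions, and retains the top ``fraction``.  Candidates whose
    implied first-winter ocean survival exceeds one are assigned infinite
    deviance (rejected); retained sets failing the KS p > 0.05 criterion are
    flagged in the result.

    The first ``burn_in`` years are excluded from the comparison on both
    sides: simulated series are pinned to the initial abundance during the
    age-structure spin-up, so those years carry no parameter information.
    """
    observed = np.asarray(observed_spawners, dtype=float)
    if observed.size == 0:
        raise ValueError("observed spawner series is empty")
    if burn_in >= observed.size:
        raise ValueError("burn_in leaves no observed years to compare")
    cand = draw_candidates(priors, freshwater_draws, n_candidates, seed)
    overrides = {
        k: cand[k].to_numpy(float)
        for k in cand.columns
        if k in TUNING_KEYS or k in ("a1", "b1", "a2", "b2")
        or k.startswith("c2:")
    }
    if init_spawners is None:
        init_spawners = float(np.mean(observed[: min(5, observed.size)]))
    res = run_historical_ensemble(
        params, historical_env, n_candidates,
        seed=child_seed(seed, "abc-run", population),
        init_spawners=init_spawners, overrides=overrides,
    )
    spawners = res["spawners"][:, burn_in:]
    observed = observed[burn_in:]
    degenerate = np.all(spawners <= 0, axis=1)
    if np.all(degenerate | res["implausible"]):
        raise RuntimeError(
            "every candidate produced a degenerate (all-zero or implausible) "
            "trajectory; check priors and initial abundance"
        )
    D = np.empty(n_candidates)
    p = np.empty(n_candidates)
    for i in range(n_candidates):
        if degenerate[i] or res["implausible"][i]:
            D[i], p[i] = np.inf, 0.0
        else:
            D[i], p[i] = ks_deviance(spawners[i], observed)
    idx = abc_select(D, fraction)
    retained = cand.iloc[idx].reset_index(drop=True).copy()
    retained["D"] = D[idx]
    retained["p"] = p[idx]
    retained["rank"] = np.arange(1, idx.size + 1)
    retained["candidate_index"] = idx
    return AbcResult(
        retained=retained,
        n_candidates=n_candidates,
        fraction=fraction,
        candidates=cand if keep_candidates else None,
    )
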