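"""Stage-specific survival, timing, and maturation submodels.

Covers the freshwater and marine building blocks chained by the life-cycle
projection:

* two-stage Gompertz stock-recruitment (spawner->parr, parr->smolt) with
  log-linear covariate effects and lognormal process error;
* a juvenile mainstem-passage emulator: a lookup table of (survival,
  arrival-day shift, transported fraction) distributions binned by annual
  spring mean temperature and flow;
* the fixed-calendar barge-transport rule;
* smolt-to-adult return (SAR) as a logistic model with environmental fixed
  effects and AR(1) random effects of ocean-entry day and day-by-year;
* the maturation partition of total SAR into age-specific ocean survival and
  return propensities (jacks at age 3, spawners at ages 4 and 5);
* a logistic adult upstream-survival model and the age-weighted effective
  spawner sum (weights 0 / 1 / F5 for ages 3 / 4 / 5).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GompertzStageParams",
    "SarParams",
    "MaturationParams",
    "UpstreamParams",
    "MainstemTable",
    "gompertz_recruits",
    "fit_gompertz",
    "fit_gompertz_pooled",
    "transport_assign",
    "simulate_ar1_effects",
    "sar_probability",
    "sar_from_ages",
    "partition_sar",
    "effective_spawners",
    "upstream_survival",
]


def _logistic(z):
    return 1.0 / (1.0 + np.exp(-np.asarray(z, dtype=float)))


# ---------------------------------------------------------------------------
# Gompertz stock-recruitment


@dataclass(frozen=True)
class GompertzStageParams:
    """One Gompertz stage:  log R = a + (1+b) log S + sum_i c_i x_i + eps.

    ``a`` is log-productivity, ``b < 0`` gives compensation (carrying
    capacity exp(-a/b)), ``c`` maps covariate names to log-linear effects,
    and ``eps ~ N(0, sigma_proc^2)`` is lognormal process error.
    """

    a: float
    b: float
    c: Mapping[str, float] = field(default_factory=dict)
    sigma_proc: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "c", dict(self.c))
        if self.sigma_proc < 0:
            raise ValueError("sigma_proc must be >= 0")

    @property
    def capacity(self) -> float:
        if self.b >= 0:
            raise ValueError("capacity is defined only for b < 0")
        return float(np.exp(-self.a / self.b))


def _covariate_term(c: Mapping[str, float], covs: Mapping[str, float]):
    term = 0.0
    for name, coef in c.items():
        if name not in covs:
            raise KeyError(
                f"missing covariate {name!r}; expected {sorted(c)}"
            )
        term = term + coef * np.asarray(covs[name], dtype=float)
    return term


def gompertz_recruits(stock, params: GompertzStageParams, covs: Mapping[str, float] | None = None,
                      noise=None):
    """Recruits from stock under the Gompertz law; 0 stock is absorbing.

    ``noise`` is a realized normal deviate (log scale) or None for the
    deterministic expectation. Accepts scalars or arrays.
    """
    stock = np.asarray(stock, dtype=float)
    if np.any(stock < 0):
        raise ValueError("stock must be >= 0")
    cov_term = _covariate_term(params.c, covs or {})
    eps = 0.0 if noise is None else np.asarray(noise, dtype=float)
    with np.errstate(divide="ignore"):
        logR = params.a + (1.0 + params.b) * np.log(stock) + cov_term + eps
    recruits = np.where(stock > 0, np.exp(logR), 0.0)
    if recruits.ndim == 0:
        return float(recruits)
    return recruits


def fit_gompertz(stock, recruits, covs: Mapping[str, Sequence[float]] | None = None,
                 sigma_known: bool = False) -> tuple[GompertzStageParams, dict[str, float]]:
    """Log-linear least-squares fit of one Gompertz stage.

    Returns the fitted parameters and a dict of standard errors keyed
    'a', 'b', and each covariate name.
    """
    stock = np.asarray(stock, dtype=float)
    recruits = np.asarray(recruits, dtype=float)
    if stock.size < 8:
        raise ValueError("need at least 8 stock-recruit pairs")
    if np.any(stock <= 0) or np.any(recruits <= 0):
        raise ValueError("stocks and recruits must be positive for fitting")
    covs = {k: np.asarray(v, dtype=float) for k, v in (covs or {}).items()}
    names = sorted(covs)
    X = np.column_stack([np.ones_like(stock), np.log(stock)]
                        + [covs[n] for n in names])
    cond = np.linalg.cond(X)
    if cond > 1e8:
        raise ValueError(
            f"collinear design (condition number {cond:.3g}); "
            "drop or decorrelate covariates"
        )
    y = np.log(recruits)
    beta, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = max(stock.size - X.shape[1], 1)
    s2 = float(resid @ resid) / dof
    cov_beta = s2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov_beta))
    params = GompertzStageParams(
        a=float(beta[0]), b=float(beta[1] - 1.0),
        c={n: float(beta[2 + i]) for i, n in enumerate(names)},
        sigma_proc=float(np.sqrt(s2)),
    )
    ses = {"a": float(se[0]), "b": float(se[1])}
    ses.update({n: float(se[2 + i]) for i, n in enumerate(names)})
    return params, ses


def fit_gompertz_pooled(
    tables: Mapping[str, tuple],
    pooling: str = "partial",
) -> dict[str, tuple[GompertzStageParams, dict[str, float]]]:
    """Fit one Gompertz stage per population with optional partial pooling.

    ``tables`` maps population id -> (stock, recruits, covs).  Partial
    pooling treats each population's coefficients as draws from a common
    normal distribution: per-population least-squares estimates are shrunk
    toward the precision-weighted grand mean, with the between-population
    variance estimated by the DerSimonian-Laird moment estimator.
    """
    if pooling not in ("none", "partial"):
        raise ValueError("pooling must be 'none' or 'partial'")
    fits = {pop: fit_gompertz(*args) for pop, args in tables.items()}
    if pooling == "none" or len(fits) < 2:
        return fits
    keys = ["a", "b"] + sorted(next(iter(fits.values()))[0].c)
    shrunk_values: dict[str, dict[str, float]] = {pop: {} for pop in fits}
    for key in keys:
        est = np.array([_param_value(fits[pop][0], key) for pop in fits])
        se = np.array([fits[pop][1][key] for pop in fits])
        var = se**2
        w = 1.0 / var
        grand = float(np.sum(w * est) / np.sum(w))
        q = float(np.sum(w * (est - grand) ** 2))
        k = est.size
        tau2 = max(0.0, (q - (k - 1)) / (np.sum(w) - np.sum(w**2) / np.sum(w)))
        lam = var / (var + tau2) if tau2 > 0 else np.ones_like(var)
        shrunk = grand + (1.0 - lam) * (est - grand)
        for pop, val in zip(fits, shrunk):
            shrunk_values[pop][key] = float(val)
    out = {}
    for pop, (params, ses) in fits.items():
        vals = shrunk_values[pop]
        out[pop] = (
            GompertzStageParams(
                a=vals["a"], b=vals["b"],
                c={n: vals[n] for n in params.c},
                sigma_proc=params.sigma_proc,
            ),
            ses,
        )
    return out


def _param_value(p: GompertzStageParams, key: str) -> float:
    if key == "a":
        return p.a
    if key == "b":
        return p.b
    return p.c[key]


# ---------------------------------------------------------------------------
# transport rule


def transport_assign(arrival_day, start: int, stop: int, p_transport_within: float, u):
    """Barge-transport flag: fixed calendar window, probabilistic within it.

    ``u`` is a uniform(0,1) deviate (scalar or array, matched to
    ``arrival_day``).
    """
    if start > stop:
        raise ValueError("transport window start must be <= stop")
    arrival_day = np.asarray(arrival_day)
    u = np.asarray(u, dtype=float)
    inside = (arrival_day >= start) & (arrival_day <= stop)
    flag = inside & (u < p_transport_within)
    if flag.ndim == 0:
        return bool(flag)
    return flag


# ---------------------------------------------------------------------------
# smolt-to-adult return


@dataclass(frozen=True)
class SarParams:
    """Logistic SAR model with AR(1) day and day-by-year random effects."""

    intercept: float
    betas: Mapping[str, float]
    day_sd: float = 0.0
    day_rho: float = 0.0
    dayyear_sd: float = 0.0
    dayyear_rho: float = 0.0
    variant: str = "in_river"

    def __post_init__(self):
        object.__setattr__(self, "betas", dict(self.betas))
        if self.variant not in ("in_river", "transported"):
            raise ValueError("variant must be 'in_river' or 'transported'")
        for r in (self.day_rho, self.dayyear_rho):
            if not -1.0 < r < 1.0:
                raise ValueError("AR coefficients must lie in (-1, 1)")
        if self.day_sd < 0 or self.dayyear_sd < 0:
            raise ValueError("random-effect SDs must be >= 0")


def simulate_ar1_effects(n: int, sd: float, rho: float, rng: np.random.Generator,
                         size: int | tuple = ()) -> np.ndarray:
    """Stationary AR(1) effect series of length n (e.g. over season days)."""
    shape = (size,) if isinstance(size, int) else tuple(size)
    out = np.zeros(shape + (n,))
    if sd == 0 or n == 0:
        return out
    out[..., 0] = rng.normal(0.0, sd, size=shape)
    innov_sd = sd * np.sqrt(1.0 - rho**2)
    for t in range(1, n):
        out[..., t] = rho * out[..., t - 1] + rng.normal(0.0, innov_sd, size=shape)
    return out


def sar_probability(covs: Mapping[str, float], day, params: SarParams,
                    day_effect=0.0, dayyear_effect=0.0):
    """Return probability for a smolt entering the ocean on ``day``.

    ``day_effect`` / ``dayyear_effect`` are realized AR(1) effects for that
    day (and year); pass 0 for the population-mean curve.
    """
    for name in params.betas:
        if name not in covs:
            raise KeyError(f"missing SAR covariate {name!r}")
    z = params.intercept + _covariate_term(params.betas, covs)
    z = z + np.asarray(day_effect, dtype=float) + np.asarray(dayyear_effect, dtype=float)
    return _logistic(z)


# ---------------------------------------------------------------------------
# maturation partition (ages 3/4/5)


@dataclass(frozen=True)
class MaturationParams:
    """Tuning parameters partitioning total SAR into age-specific rates.

    S0: annual ocean survival after the first winter; b3: propensity to
    return at age 3 (jacks); b4: propensity to return at age 4; F5:
    fecundity weight of age-5 spawners.
    """

    S0: float
    b3: float
    b4: float
    F5: float

    def __post_init__(self):
        if not 0.0 < self.S0 < 1.0:
            raise ValueError("S0 must be in (0, 1)")
        for name, v in (("b3", self.b3), ("b4", self.b4)):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.F5 <= 0:
            raise ValueError("F5 must be > 0")


def sar_from_ages(N2, N3, N4, N5, b3, b4):
    """Total smolt-to-adult survival from age-class abundances.

    S_SAR = (b3*N3 + b4*N4 + N5) / N2.
    """
    N2 = np.asarray(N2, dtype=float)
    if np.any(N2 <= 0):
        raise ValueError("S_SAR is undefined for N2 <= 0")
    return (np.asarray(b3) * np.asarray(N3) + np.asarray(b4) * np.asarray(N4)
            + np.asarray(N5)) / N2


def sar_denominator(S0, b3, b4):
    """b3 + (1-b3) S0 (b4 + (1-b4) S0): total SAR per unit first-winter survival."""
    S0, b3, b4 = (np.asarray(v, dtype=float) for v in (S0, b3, b4))
    return b3 + (1.0 - b3) * S0 * (b4 + (1.0 - b4) * S0)


def partition_sar(S_sar, m: MaturationParams | None = None, *, S0=None, b3=None, b4=None):
    """Partition total SAR into first-winter survival and age fractions.

    Returns ``(S3, f3, f4, f5, implausible)`` where f_k = N_k / N2 and
    ``implausible`` flags parameter sets with S3 > 1 (first-winter survival
    above one; calibration uses the flag to reject the candidate). Accepts
    either a MaturationParams or array-valued S0/b3/b4 keywords.
    """
    if m is not None:
        S0, b3, b4 = m.S0, m.b3, m.b4
    S_sar = np.asarray(S_sar, dtype=float)
    if np.any(S_sar <= 0) or np.any(S_sar > 1):
        raise ValueError("S_sar must lie in (0, 1]")
    denom = sar_denominator(S0, b3, b4)
    if np.any(denom == 0):
        raise ZeroDivisionError(
            "maturation denominator is zero (b3 = 0 and S0 = 0); no fish can return"
        )
    S3 = S_sar / denom
    f3 = S3
    f4 = (1.0 - np.asarray(b3)) * f3 * np.asarray(S0)
    f5 = (1.0 - np.asarray(b4)) * f4 * np.asarray(S0)
    implausible = S3 > 1.0
    return S3, f3, f4, f5, implausible


def effective_spawners(N3, N4, N5, F5):
    """Age-weighted spawner sum: 0*N3 + 1*N4 + F5*N5 (jacks weigh nothing)."""
    return 0.0 * np.asarray(N3, dtype=float) + np.asarray(N4, dtype=float) \
        + np.asarray(F5, dtype=float) * np.asarray(N5, dtype=float)


# ---------------------------------------------------------------------------
# mainstem passage emulator


@dataclass(frozen=True)
class MainstemTable:
    """Empirical passage outcomes binned by spring mean temperature x flow.

    Each record carries (survival, arrival-day shift at the downstream dam,
    transported fraction) from a disaggregated daily passage reconstruction;
    sampling draws one record uniformly from the bin containing the year's
    spring conditions, clamping out-of-range inputs to the nearest bin.
    Empty bins fall back to the nearest non-empty bin.
    """

    temp_edges: np.ndarray
    flow_edges: np.ndarray
    temp: np.ndarray
    flow: np.ndarray
    survival: np.ndarray
    arrival_shift: np.ndarray
    p_transport: np.ndarray

    def __post_init__(self):
        for name in ("temp_edges", "flow_edges", "temp", "flow", "survival",
                     "arrival_shift", "p_transport"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.survival.size == 0:
            raise ValueError("mainstem table must contain at least one record")
        if np.any((self.survival < 0) | (self.survival > 1)):
            raise ValueError("mainstem survivals must lie in [0, 1]")
        if np.any((self.p_transport < 0) | (self.p_transport > 1)):
            raise ValueError("transported fractions must lie in [0, 1]")
        ti = np.clip(np.digitize(self.temp, self.temp_edges) - 1, 0,
                     len(self.temp_edges) - 2)
        fi = np.clip(np.digitize(self.flow, self.flow_edges) - 1, 0,
                     len(self.flow_edges) - 2)
        object.__setattr__(self, "_bin_index", ti * (len(self.flow_edges) - 1) + fi)

    @property
    def n_records(self) -> int:
        return self.survival.size

    def _bin_of(self, spring_temp, spring_flow):
        ti = np.clip(np.digitize(spring_temp, self.temp_edges) - 1, 0,
                     len(self.temp_edges) - 2)
        fi = np.clip(np.digitize(spring_flow, self.flow_edges) - 1, 0,
                     len(self.flow_edges) - 2)
        return np.asarray(ti * (len(self.flow_edges) - 1) + fi)

    def sample(self, spring_temp: float, spring_flow: float, rng: np.random.Generator):
        """Draw one (survival, arrival_shift, transported fraction) record."""
        s, a, p = self.sample_many(np.atleast_1d(spring_temp),
                                   np.atleast_1d(spring_flow), rng)
        return float(s[0]), float(a[0]), float(p[0])

    def sample_many(self, spring_temp, spring_flow, rng: np.random.Generator):
        """Vectorized per-element record draws (arrays broadcast together)."""
        spring_temp, spring_flow = np.broadcast_arrays(
            np.asarray(spring_temp, float), np.asarray(spring_flow, float))
        shape = spring_temp.shape
        want = self._bin_of(spring_temp.ravel(), spring_flow.ravel())
        idx = np.empty(want.size, dtype=int)
        occupied = np.unique(self._bin_index)
        for b in np.unique(want):
            mask = want == b
            use = b
            if b not in occupied:  # fallback: nearest occupied bin
                use = occupied[np.argmin(np.abs(occupied - b))]
            pool = np.nonzero(self._bin_index == use)[0]
            idx[mask] = pool[rng.integers(0, pool.size, size=mask.sum())]
        return (self.survival[idx].reshape(shape),
                self.arrival_shift[idx].reshape(shape),
                self.p_transport[idx].reshape(shape))

    def bin_means(self, spring_temp, spring_flow):
        """Deterministic per-bin mean outcomes (no sampling)."""
        spring_temp, spring_flow = np.broadcast_arrays(
            np.asarray(spring_temp, float), np.asarray(spring_flow, float))
        shape = spring_temp.shape
        want = self._bin_of(spring_temp.ravel(), spring_flow.ravel())
        occupied = np.unique(self._bin_index)
        s = np.empty(want.size)
        a = np.empty(want.size)
        p = np.empty(want.size)
        for b in np.unique(want):
            mask = want == b
            use = b if b in occupied else occupied[np.argmin(np.abs(occupied - b))]
            pool = self._bin_index == use
            s[mask] = self.survival[pool].mean()
            a[mask] = self.arrival_shift[pool].mean()
            p[mask] = self.p_transport[pool].mean()
        return s.reshape(shape), a.reshape(shape), p.reshape(shape)

    def to_frame(self) -> pd.DataFrame:
        ti = np.clip(np.digitize(self.temp, self.temp_edges) - 1, 0,
                     len(self.temp_edges) - 2)
        fi = np.clip(np.digitize(self.flow, self.flow_edges) - 1, 0,
                     len(self.flow_edges) - 2)
        return pd.DataFrame({
            "temp_bin_lo": self.temp_edges[ti],
            "temp_bin_hi": self.temp_edges[ti + 1],
            "flow_bin_lo": self.flow_edges[fi],
            "flow_bin_hi": self.flow_edges[fi + 1],
            "temp": self.temp,
            "flow": self.flow,
            "survival": self.survival,
            "arrival_shift": self.arrival_shift,
            "p_transport": self.p_transport,
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MainstemTable":
        temp_edges = np.unique(np.concatenate([df["temp_bin_lo"], df["temp_bin_hi"]]))
        flow_edges = np.unique(np.concatenate([df["flow_bin_lo"], df["flow_bin_hi"]]))
        temp = df["temp"].to_numpy(float) if "temp" in df else \
            0.5 * (df["temp_bin_lo"] + df["temp_bin_hi"]).to_numpy(float)
        flow = df["flow"].to_numpy(float) if "flow" in df else \
            0.5 * (df["flow_bin_lo"] + df["flow_bin_hi"]).to_numpy(float)
        return cls(temp_edges, flow_edges, temp, flow,
                   df["survival"].to_numpy(float),
                   df["arrival_shift"].to_numpy(float),
                   df["p_transport"].to_numpy(float))

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def read_csv(cls, path) -> "MainstemTable":
        return cls.from_frame(pd.read_csv(path, float_precision="round_trip"))


# ---------------------------------------------------------------------------
# adult upstream survival stand-in


@dataclass(frozen=True)
class UpstreamParams:
    """Logistic-linear adult upstream-survival model (monotone in each covariate)."""

    intercept: float
    betas: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "betas", dict(self.betas))


def upstream_survival(covs: Mapping[str, float], params: UpstreamParams):
    """Upstream migration survival probability from covariates."""
    for name in params.betas:
        if name not in covs:
            raise KeyError(f"missing upstream covariate {name!r}")
    return _logistic(params.intercept + _covariate_term(params.betas, covs))
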