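"""Multivariate environmental covariate process and climate-change scenarios.

The environmental state shared by all life stages is a vector of annual
covariates (ocean temperatures, upwelling, air temperature, stream flows)
modelled as a first-order multivariate autoregression around its mean:

    x_t ~ MVN(rho * x_{t-1}, Q),    y_t ~ N(x_t, obs_sd)

with a single scalar autoregression coefficient ``rho``, an unstructured
(free) covariance matrix ``Q``, and a tiny fixed observation noise
(``obs_sd = 0.001``: covariates are treated as measured essentially without
error).  Because the observation noise is negligible at that scale, the
maximum-likelihood fit is computed as the conditional (on the first year)
likelihood of the autoregression with the observations standing in for the
latent states; ``Q`` has a closed form given ``rho`` and the profile
likelihood is optimized over ``rho`` alone.

Climate-change scenarios combine stationary ("detrended") draws from the
fitted process with additive trend offsets extracted from ensembles of
global-climate-model (GCM) series in four steps: per-member baseline mean
over 2005-2025, anomalies from that baseline, a centered multi-year running
mean of the anomalies, and per-year quantiles (25/50/75) across members.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

__all__ = [
    "CovariateMatrix",
    "CovarianceModel",
    "GcmEnsemble",
    "ClimateTrend",
    "ClimateScenario",
    "SingularCovarianceError",
    "FitConvergenceError",
    "count_correlation_params",
    "fit_covariance_model",
    "simulate_detrended",
    "extract_trend",
    "apply_trend",
]

DEFAULT_OBS_SD = 0.001
DEFAULT_BASELINE = (2005, 2025)
DEFAULT_WINDOW = 20
DEFAULT_QUANTILES = (25, 50, 75)


class SingularCovarianceError(ValueError):
    """Raised when the innovation covariance is (near-)singular.

    Typically caused by a constant covariate series or exact collinearity;
    regularize the input (drop or perturb the offending covariate).
    """


class FitConvergenceError(RuntimeError):
    """Raised when the likelihood optimization fails; carries the trace."""

    def __init__(self, message: str, trace: list | None = None):
        super().__init__(message)
        self.trace = trace or []


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class CovariateMatrix:
    """Annual values of named environmental covariates (years x covariates)."""

    years: np.ndarray
    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        years = np.asarray(self.years, dtype=int)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "names", tuple(self.names))
        object.__setattr__(self, "values", values)
        if years.ndim != 1:
            raise ValueError("years must be one-dimensional")
        if np.any(np.diff(years) != 1):
            raise ValueError("years must be consecutive and strictly increasing")
        if len(set(self.names)) != len(self.names):
            raise ValueError("covariate names must be unique")
        if values.shape != (years.size, len(self.names)):
            raise ValueError(
                f"values shape {values.shape} does not match "
                f"({years.size} years, {len(self.names)} covariates)"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("covariate values must be finite (no missing data)")

    @property
    def n_years(self) -> int:
        return self.years.size

    @property
    def n_covariates(self) -> int:
        return len(self.names)

    def column(self, name: str) -> np.ndarray:
        try:
            j = self.names.index(name)
        except ValueError:
            raise KeyError(
                f"unknown covariate {name!r}; available: {list(self.names)}"
            ) from None
        return self.values[:, j]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.names))
        df.insert(0, "year", self.years)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CovariateMatrix":
        if "year" not in df.columns:
            raise ValueError("covariate table must have a 'year' column")
        df = df.sort_values("year")
        names = tuple(c for c in df.columns if c != "year")
        return cls(df["year"].to_numpy(int), names, df[list(names)].to_numpy(float))

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def read_csv(cls, path) -> "CovariateMatrix":
        return cls.from_frame(pd.read_csv(path, float_precision="round_trip"))


@dataclass(frozen=True)
class CovarianceModel:
    """Fitted mean-reverting multivariate AR(1) covariate process."""

    names: tuple[str, ...]
    mu: np.ndarray
    rho: float | np.ndarray
    Q: np.ndarray
    obs_sd: float = DEFAULT_OBS_SD
    log_covariates: tuple[str, ...] = ()
    loglik: float | None = None

    def __post_init__(self):
        mu = np.asarray(self.mu, dtype=float)
        Q = np.asarray(self.Q, dtype=float)
        object.__setattr__(self, "names", tuple(self.names))
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "Q", Q)
        object.__setattr__(self, "log_covariates", tuple(self.log_covariates))
        n = len(self.names)
        if mu.shape != (n,) or Q.shape != (n, n):
            raise ValueError("mu / Q shapes inconsistent with covariate names")
        if not np.allclose(Q, Q.T, atol=1e-10):
            raise ValueError("Q must be symmetric")
        if np.min(np.linalg.eigvalsh(Q)) < -1e-10 * max(1.0, np.trace(Q)):
            raise ValueError("Q must be positive semi-definite")
        rho = np.asarray(self.rho, dtype=float)
        if np.any(np.abs(rho) >= 1):
            raise ValueError("|rho| must be < 1 for stationarity")
        if self.obs_sd <= 0:
            raise ValueError("obs_sd must be positive")

    @property
    def n_covariates(self) -> int:
        return len(self.names)

    @property
    def n_correlation_params(self) -> int:
        return count_correlation_params(self.n_covariates)

    def stationary_cov(self) -> np.ndarray:
        """Solve V = rho V rho' + Q (diagonal/scalar rho closed form)."""
        r = np.broadcast_to(np.atleast_1d(np.asarray(self.rho, float)), (self.n_covariates,))
        denom = 1.0 - np.outer(r, r)
        return self.Q / denom

    def correlations(self) -> np.ndarray:
        sd = np.sqrt(np.diag(self.Q))
        return self.Q / np.outer(sd, sd)


@dataclass(frozen=True)
class GcmEnsemble:
    """One covariate's ensemble of annual GCM projection series."""

    covariate: str
    scenario: str
    years: np.ndarray
    members: np.ndarray  # (n_members, n_years)
    member_names: tuple[str, ...] = ()

    def __post_init__(self):
        years = np.asarray(self.years, dtype=int)
        members = np.atleast_2d(np.asarray(self.members, dtype=float))
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "members", members)
        if members.shape[0] < 1:
            raise ValueError("ensemble needs at least one member")
        if members.shape[1] != years.size:
            raise ValueError("all members must share the ensemble year axis")
        if not self.member_names:
            object.__setattr__(
                self,
                "member_names",
                tuple(f"member_{i + 1}" for i in range(members.shape[0])),
            )

    @property
    def n_members(self) -> int:
        return self.members.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.members.T, columns=list(self.member_names))
        df.insert(0, "year", self.years)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, covariate: str, scenario: str) -> "GcmEnsemble":
        names = tuple(c for c in df.columns if c != "year")
        return cls(covariate, scenario, df["year"].to_numpy(int),
                   df[list(names)].to_numpy(float).T, names)


@dataclass(frozen=True)
class ClimateTrend:
    """Per-year additive anomaly offsets for one covariate at one quantile."""

    covariate: str
    scenario: str
    quantile: int
    years: np.ndarray
    offsets: np.ndarray

    def __post_init__(self):
        years = np.asarray(self.years, dtype=int)
        offsets = np.asarray(self.offsets, dtype=float)
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "offsets", offsets)
        if years.shape != offsets.shape:
            raise ValueError("years and offsets must align")

    def offsets_for(self, years: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.years, years)
        ok = (idx < self.years.size) & (self.years[np.clip(idx, 0, self.years.size - 1)] == years)
        if not np.all(ok):
            missing = np.asarray(years)[~ok]
            raise ValueError(
                f"trend for {self.covariate!r} does not cover years {missing.tolist()}"
            )
        return self.offsets[idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"year": self.years, "offset": self.offsets})


@dataclass(frozen=True)
class ClimateScenario:
    """Detrended covariate draws plus (possibly empty) per-covariate trends."""

    detrended_draws: tuple[CovariateMatrix, ...]
    trends: Mapping[str, ClimateTrend] = field(default_factory=dict)
    label: str = "detrended"

    def __post_init__(self):
        object.__setattr__(self, "detrended_draws", tuple(self.detrended_draws))
        object.__setattr__(self, "trends", dict(self.trends))

    @property
    def n_draws(self) -> int:
        return len(self.detrended_draws)

    def forced_draw(self, i: int) -> CovariateMatrix:
        return apply_trend(self.detrended_draws[i], self.trends)


# ---------------------------------------------------------------------------
# operations


def count_correlation_params(n: int) -> int:
    """Number of free correlation coefficients in an unstructured n x n Q."""
    if not isinstance(n, (int, np.integer)) or isinstance(n, bool):
        raise TypeError("covariate count must be an integer")
    if n < 1:
        raise ValueError("covariate count must be >= 1")
    return (n * (n - 1)) // 2


def _transform(values: np.ndarray, names: Sequence[str],
               log_covariates: Iterable[str]) -> np.ndarray:
    out = values.copy()
    for name in log_covariates:
        j = list(names).index(name)
        if np.any(out[:, j] <= 0):
            raise ValueError(f"covariate {name!r} must be strictly positive to log-transform")
        out[:, j] = np.log(out[:, j])
    return out


def fit_covariance_model(
    data: CovariateMatrix,
    obs_sd: float = DEFAULT_OBS_SD,
    per_covariate_rho: bool = False,
    log_covariates: Iterable[str] = (),
) -> CovarianceModel:
    """Maximum-likelihood fit of the mean-reverting multivariate AR(1).

    Parameters
    ----------
    data
        Annual covariate matrix; at least 10 years.
    obs_sd
        Fixed observation noise scale (default 0.001; treated as negligible,
        so the conditional AR(1) likelihood is maximized with observations
        standing in for the latent states).
    per_covariate_rho
        If True, fit one autoregression coefficient per covariate (diagonal
        rho) instead of the default single scalar.
    log_covariates
        Strictly positive covariates (flows) to fit on the log scale.
    """
    if data.n_years < 10:
        raise ValueError("need at least 10 years to fit the covariance model")
    if obs_sd <= 0:
        raise ValueError("obs_sd must be positive")
    log_covariates = tuple(log_covariates)
    values = _transform(data.values, data.names, log_covariates)
    mu = values.mean(axis=0)
    x = values - mu
    sd = x.std(axis=0)
    if np.any(sd < 1e-12):
        flat = [n for n, s in zip(data.names, sd) if s < 1e-12]
        raise SingularCovarianceError(
            f"covariate(s) {flat} have zero variance; Q would be singular — "
            "drop the constant series or add regularizing noise"
        )
    x0, x1 = x[:-1], x[1:]
    T1 = x1.shape[0]

    def q_given_rho(rho):
        resid = x1 - rho * x0
        return resid.T @ resid / T1

    def nll(rho):
        Q = q_given_rho(rho)
        sign, logdet = np.linalg.slogdet(Q)
        if sign <= 0:
            return np.inf
        return 0.5 * T1 * (logdet + x.shape[1])

    if per_covariate_rho:
        # column-wise least squares, then joint residual covariance
        denom = np.sum(x0 * x0, axis=0)
        rho = np.clip(np.sum(x0 * x1, axis=0) / denom, -0.999, 0.999)
        Q = q_given_rho(rho)
        loglik = -nll(rho)
    else:
        res = minimize_scalar(nll, bounds=(-0.999, 0.999), method="bounded",
                              options={"xatol": 1e-10})
        if not res.success:
            raise FitConvergenceError(
                f"rho optimization did not converge: {res.message}",
                trace=[{"rho": float(res.x), "nll": float(res.fun)}],
            )
        rho = float(res.x)
        Q = q_given_rho(rho)
        loglik = -float(res.fun)

    eigmin = np.min(np.linalg.eigvalsh(Q))
    if eigmin < 1e-12 * max(1.0, float(np.trace(Q))):
        raise SingularCovarianceError(
            "fitted Q is numerically singular; consider dropping collinear "
            "covariates or adding a ridge term"
        )
    return CovarianceModel(data.names, mu, rho, Q, obs_sd=obs_sd,
                           log_covariates=log_covariates, loglik=loglik)


def simulate_detrended(
    model: CovarianceModel,
    n_years: int,
    n_draws: int,
    seed: int | np.random.Generator,
    start_year: int = 2015,
) -> list[CovariateMatrix]:
    """Draw stationary ("detrended") covariate series from the fitted process.

    Each draw follows x_t ~ MVN(rho x_{t-1}, Q) around ``model.mu``,
    initialized from the stationary distribution.  Log-fitted covariates are
    returned on their raw (exponentiated) scale.
    """
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = model.n_covariates
    r = np.broadcast_to(np.atleast_1d(np.asarray(model.rho, float)), (n,))
    # Cholesky-like factors; Q may be exactly zero (degenerate but valid)
    V = model.stationary_cov()
    Lq = _psd_factor(model.Q)
    Lv = _psd_factor(V)
    x = np.empty((n_draws, n_years, n), dtype=float)
    x[:, 0, :] = rng.standard_normal((n_draws, n)) @ Lv.T
    for t in range(1, n_years):
        shocks = rng.standard_normal((n_draws, n)) @ Lq.T
        x[:, t, :] = r * x[:, t - 1, :] + shocks
    x += model.mu
    for name in model.log_covariates:
        j = model.names.index(name)
        x[:, :, j] = np.exp(x[:, :, j])
    years = np.arange(start_year, start_year + n_years)
    return [CovariateMatrix(years, model.names, x[i]) for i in range(n_draws)]


def _psd_factor(M: np.ndarray) -> np.ndarray:
    """Lower-triangular-ish factor L with L L' = M, tolerating PSD rank loss."""
    try:
        return np.linalg.cholesky(M)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(M)
        if np.min(w) < -1e-8 * max(1.0, np.max(np.abs(w))):
            raise ValueError("covariance matrix is not positive semi-definite")
        return v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))


def running_mean(series: np.ndarray, window: int) -> np.ndarray:
    """Centered running mean with half-width window//2, truncated at edges.

    The symmetric (odd-length) window preserves linear trends exactly at
    interior points, which is the property the trend extraction relies on.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    h = window // 2
    series = np.asarray(series, dtype=float)
    n = series.size
    out = np.empty(n)
    csum = np.concatenate([[0.0], np.cumsum(series)])
    lo = np.maximum(np.arange(n) - h, 0)
    hi = np.minimum(np.arange(n) + h + 1, n)
    out = (csum[hi] - csum[lo]) / (hi - lo)
    return out


def extract_trend(
    ensemble: GcmEnsemble,
    baseline: tuple[int, int] = DEFAULT_BASELINE,
    window: int = DEFAULT_WINDOW,
    quantiles: Sequence[int] = DEFAULT_QUANTILES,
) -> dict[int, ClimateTrend]:
    """Extract per-quantile additive climate trends from a GCM ensemble.

    Four steps, per member: (1) mean over the baseline window (2005-2025 by
    default), (2) anomalies from that mean, (3) centered running mean of the
    anomalies, then (4) per-year quantiles across members of the smoothed
    anomalies.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    lo, hi = baseline
    base_mask = (ensemble.years >= lo) & (ensemble.years <= hi)
    expected = hi - lo + 1
    if base_mask.sum() != expected:
        raise ValueError(
            f"ensemble years do not fully cover the baseline window {lo}-{hi}"
        )
    bad = ~np.all(np.isfinite(ensemble.members[:, base_mask]), axis=1)
    if np.any(bad):
        names = [ensemble.member_names[i] for i in np.nonzero(bad)[0]]
        raise ValueError(f"member(s) {names} missing values in baseline window")
    base_means = ensemble.members[:, base_mask].mean(axis=1, keepdims=True)
    anomalies = ensemble.members - base_means
    smoothed = np.vstack([running_mean(row, window) for row in anomalies])
    out: dict[int, ClimateTrend] = {}
    for q in quantiles:
        offs = np.percentile(smoothed, q, axis=0)  # linear interpolation
        out[int(q)] = ClimateTrend(ensemble.covariate, ensemble.scenario,
                                   int(q), ensemble.years.copy(), offs)
    return out


def apply_trend(
    draw: CovariateMatrix,
    trends: Mapping[str, ClimateTrend],
) -> CovariateMatrix:
    """Add per-covariate trend offsets to a detrended draw.

    Covariates without a trend pass through unchanged; the detrended
    component's variance and autocorrelation are untouched.
    """
    if not trends:
        return draw
    values = draw.values.copy()
    for name, trend in trends.items():
        if name not in draw.names:
            raise KeyError(f"trend covariate {name!r} not present in draw")
        j = draw.names.index(name)
        values[:, j] = values[:, j] + trend.offsets_for(draw.years)
    return replace(draw, values=values)
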