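"""Penalized-likelihood fitting of the smolt-to-adult return (SAR) model.

The SAR model is a logistic regression on per-fish return (0/1) with
environmental fixed effects and two random-effect terms: an AR(1) effect of
ocean-entry day (the seasonal survival curve) and a year-level intercept.
The year intercept absorbs the day-by-year interaction at the cohort level:
because the environmental covariates vary only across years, ignoring
year-level excess variation would understate every fixed-effect standard
error.  The day-by-year AR(1) structure itself is simulated from its law in
projection mode; its scale travels through the parameter template.

Fitting maximizes the Laplace-approximate marginal likelihood: for each
candidate variance/correlation vector the fixed and random effects are
jointly maximized by damped Newton steps, and the marginal likelihood is
corrected by the log-determinant of the random-effect Hessian block.  The
AR(1) prior precision is tridiagonal with closed-form log-determinant
-n log(sd^2) - (n-1) log(1 - rho^2).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .stage_models import SarParams

__all__ = ["SarFit", "fit_sar", "SeparationError", "UnidentifiableError"]


class SeparationError(RuntimeError):
    """Complete separation: the outcome is constant (or perfectly predicted)."""


class UnidentifiableError(ValueError):
    """A fixed-effect covariate has no variation; its coefficient is inestimable."""


@dataclass(frozen=True)
class SarFit:
    """Result of one SAR model fit."""

    params: SarParams
    se: Mapping[str, float]
    loglik: float
    null_loglik: float
    day_effects: np.ndarray
    days: np.ndarray
    year_effects: np.ndarray
    year_sd: float
    n_records: int
    converged: bool = True

    def __post_init__(self):
        object.__setattr__(self, "se", dict(self.se))

    def lr_stat_day_effects(self) -> float:
        """Likelihood-ratio statistic of the random effects vs the null GLM."""
        return 2.0 * (self.loglik - self.null_loglik)


def _ar1_precision(n: int, sd: float, rho: float) -> np.ndarray:
    tau = 1.0 / (sd**2 * (1.0 - rho**2))
    P = np.zeros((n, n))
    idx = np.arange(n)
    P[idx, idx] = tau * (1.0 + rho**2)
    P[0, 0] = P[n - 1, n - 1] = tau
    P[idx[:-1], idx[:-1] + 1] = -tau * rho
    P[idx[:-1] + 1, idx[:-1]] = -tau * rho
    return P


def _ar1_logdet_precision(n: int, sd: float, rho: float) -> float:
    return -n * np.log(sd**2) - (n - 1) * np.log(1.0 - rho**2)


def _penalized_loglik(X, y, z_idx, P, beta, u):
    eta = X @ beta + u[z_idx]
    ll = float(y @ eta - np.sum(np.logaddexp(0.0, eta)))
    return ll - 0.5 * float(u @ (P @ u))


def _joint_newton(X, y, z_idx, n_u, P, beta, u, max_iter=60, tol=1e-9):
    """Maximize Bernoulli loglik + Gaussian prior jointly over (beta, u).

    ``z_idx`` is an (n_records, k) integer matrix of random-effect indices
    (each record adds the sum of its k effects)."""
    p_dim = X.shape[1]
    k = z_idx.shape[1]
    flat = z_idx  # column j indexes block offsets already applied

    def eta_of(beta, u):
        e = X @ beta
        for j in range(k):
            e = e + u[flat[:, j]]
        return e

    def pen(beta, u):
        e = eta_of(beta, u)
        return float(y @ e - np.sum(np.logaddexp(0.0, e))) - 0.5 * float(u @ (P @ u))

    for _ in range(max_iter):
        eta = eta_of(beta, u)
        prob = 1.0 / (1.0 + np.exp(-eta))
        w = prob * (1.0 - prob)
        r = y - prob
        g_beta = X.T @ r
        g_u = -P @ u
        for j in range(k):
            g_u += np.bincount(flat[:, j], weights=r, minlength=n_u)
        grad = np.concatenate([g_beta, g_u])
        if np.max(np.abs(grad)) < tol * max(1.0, y.size):
            break
        Xw = X * w[:, None]
        H_bb = X.T @ Xw
        H_bu = np.zeros((p_dim, n_u))
        for j in range(k):
            for q in range(p_dim):
                H_bu[q] += np.bincount(flat[:, j], weights=Xw[:, q], minlength=n_u)
        H_uu = P.copy()
        for j in range(k):
            H_uu[np.arange(n_u), np.arange(n_u)] += np.bincount(
                flat[:, j], weights=w, minlength=n_u)
        if k == 2:
            # cross-block terms between the two effect sets
            pair = flat[:, 0] * n_u + flat[:, 1]
            uniq, inv = np.unique(pair, return_inverse=True)
            wsum = np.bincount(inv, weights=w)
            a, b = np.divmod(uniq, n_u)
            H_uu[a, b] += wsum
            H_uu[b, a] += wsum
        H = np.block([[H_bb, H_bu], [H_bu.T, H_uu]])
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        f0 = pen(beta, u)
        scale = 1.0
        for _ in range(25):
            if pen(beta + scale * step[:p_dim], u + scale * step[p_dim:]) >= f0 - 1e-12:
                break
            scale *= 0.5
        beta = beta + scale * step[:p_dim]
        u = u + scale * step[p_dim:]

    eta = eta_of(beta, u)
    prob = 1.0 / (1.0 + np.exp(-eta))
    w = prob * (1.0 - prob)
    H_uu = P.copy()
    for j in range(k):
        H_uu[np.arange(n_u), np.arange(n_u)] += np.bincount(
            flat[:, j], weights=w, minlength=n_u)
    if k == 2:
        pair = flat[:, 0] * n_u + flat[:, 1]
        uniq, inv = np.unique(pair, return_inverse=True)
        wsum = np.bincount(inv, weights=w)
        a, b = np.divmod(uniq, n_u)
        H_uu[a, b] += wsum
        H_uu[b, a] += wsum
    Xw = X * w[:, None]
    H_bb = X.T @ Xw
    H_bu = np.zeros((p_dim, n_u))
    for j in range(k):
        for q in range(p_dim):
            H_bu[q] += np.bincount(flat[:, j], weights=Xw[:, q], minlength=n_u)
    H_full = np.block([[H_bb, H_bu], [H_bu.T, H_uu]])
    return beta, u, H_uu, w, H_full


def fit_sar(
    records: pd.DataFrame,
    covariates: Sequence[str],
    variant: str = "in_river",
    template: SarParams | None = None,
    day_col: str = "arrival_day",
    min_records: int = 1000,
) -> SarFit:
    """Fit the SAR logistic model for one variant (transported / in-river).

    ``records`` needs columns year, ``day_col``, transported (0/1),
    returned (0/1), and each covariate.  Rows are filtered to the requested
    variant.  Returns fitted parameters, fixed-effect standard errors, and
    posterior-mode day and year effects.
    """
    if variant not in ("in_river", "transported"):
        raise ValueError("variant must be 'in_river' or 'transported'")
    want = 1 if variant == "transported" else 0
    df = records[records["transported"].astype(int) == want]
    if len(df) < min_records:
        raise ValueError(
            f"need at least {min_records} records for variant {variant!r}, got {len(df)}"
        )
    years = np.sort(df["year"].unique())
    if years.size < 3:
        raise ValueError("records must span at least 3 years")
    y = df["returned"].to_numpy(float)
    if y.min() == y.max():
        raise SeparationError("outcome is constant; the model is not estimable")
    covariates = list(covariates)
    for c in covariates:
        if df[c].std(ddof=0) < 1e-12:
            raise UnidentifiableError(
                f"covariate {c!r} has no variation; its coefficient is inestimable"
            )
    X = np.column_stack([np.ones(len(df))] + [df[c].to_numpy(float) for c in covariates])
    day = df[day_col].to_numpy(int)
    day_lo, day_hi = int(day.min()), int(day.max())
    n_days = day_hi - day_lo + 1
    n_years = years.size
    n_u = n_days + n_years
    year_pos = {int(yv): n_days + i for i, yv in enumerate(years)}
    z_idx = np.column_stack([
        day - day_lo,
        np.array([year_pos[int(v)] for v in df["year"]]),
    ])

    import statsmodels.api as sm

    null = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    null_ll = float(null.llf)
    beta0 = np.asarray(null.params, dtype=float)
    cache = {"beta": beta0.copy(), "u": np.zeros(n_u)}

    def build_P(day_sd, day_rho, year_sd):
        P = np.zeros((n_u, n_u))
        P[:n_days, :n_days] = _ar1_precision(n_days, day_sd, day_rho)
        P[n_days:, n_days:] = np.eye(n_years) / year_sd**2
        logdet = (_ar1_logdet_precision(n_days, day_sd, day_rho)
                  - 2.0 * n_years * np.log(year_sd))
        return P, logdet

    def neg_marginal(theta):
        day_sd = float(np.exp(theta[0]))
        day_rho = float(np.tanh(theta[1]))
        year_sd = float(np.exp(theta[2]))
        P, logdet_P = build_P(day_sd, day_rho, year_sd)
        beta, u, H_uu, _, H_full = _joint_newton(
            X, y, z_idx, n_u, P, cache["beta"].copy(), cache["u"].copy())
        cache["beta"], cache["u"] = beta, u
        f = _joint_pen(X, y, z_idx, P, beta, u)
        f += 0.5 * logdet_P
        # REML-type Laplace: integrate the fixed effects out as well, so the
        # variance components are not biased low by the fixed-effect fit
        sign, logdet_H = np.linalg.slogdet(H_full)
        if sign <= 0:
            return np.inf
        return -(f - 0.5 * logdet_H)

    def _joint_pen(X, y, z_idx, P, beta, u):
        e = X @ beta + u[z_idx[:, 0]] + u[z_idx[:, 1]]
        return (float(y @ e - np.sum(np.logaddexp(0.0, e)))
                - 0.5 * float(u @ (P @ u)))

    res = minimize(neg_marginal,
                   x0=np.array([np.log(0.2), np.arctanh(0.5), np.log(0.2)]),
                   method="L-BFGS-B",
                   bounds=[(-6.0, 2.0), (-3.0, 3.0), (-6.0, 2.0)],
                   options={"maxiter": 60, "ftol": 1e-9})
    day_sd = float(np.exp(res.x[0]))
    day_rho = float(np.tanh(res.x[1]))
    year_sd = float(np.exp(res.x[2]))
    P, _ = build_P(day_sd, day_rho, year_sd)
    beta, u, H_uu, w, H_full = _joint_newton(
        X, y, z_idx, n_u, P, cache["beta"].copy(), cache["u"].copy())

    # fixed-effect SEs: beta block of the inverse joint observed information
    p_dim = X.shape[1]
    cov = np.linalg.inv(H_full)[:p_dim, :p_dim]
    se_vals = np.sqrt(np.diag(cov))

    tmpl = template or SarParams(0.0, {}, variant=variant)
    params = SarParams(
        intercept=float(beta[0]),
        betas={c: float(beta[1 + i]) for i, c in enumerate(covariates)},
        day_sd=day_sd,
        day_rho=day_rho,
        dayyear_sd=tmpl.dayyear_sd if template is not None else year_sd,
        dayyear_rho=tmpl.dayyear_rho,
        variant=variant,
    )
    se = {"intercept": float(se_vals[0])}
    se.update({c: float(se_vals[1 + i]) for i, c in enumerate(covariates)})
    return SarFit(
        params=params, se=se, loglik=float(-res.fun), null_loglik=null_ll,
        day_effects=u[:n_days], days=np.arange(day_lo, day_hi + 1),
        year_effects=u[n_days:], year_sd=year_sd,
        n_records=len(df), converged=bool(res.success),
    )
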