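"""Quasi-extinction and abundance summaries over trajectory ensembles.

The quasi-extinction threshold (QET50) is passed the first time the 4-year
running mean of spawners drops strictly below 50; the first-passage year is
reported as the final year of the triggering window (trailing windows by
default, centered behind a flag).  Abundance is tracked as per-decade
geometric means; zero counts are handled by an additive offset (default +1)
inside the log.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .lifecycle import Trajectory

__all__ = [
    "RiskSummary",
    "qet_first_year",
    "prop_below_qet",
    "decadal_geomean",
    "summarize_risk",
]

QET_THRESHOLD = 50.0
QET_WINDOW = 4


@dataclass(frozen=True)
class RiskSummary:
    """Ensemble risk summaries for one population/model/scenario cell."""

    years: np.ndarray
    first_qet_year: np.ndarray        # float array; NaN = never
    prop_below: np.ndarray            # per-year fraction at-or-past QET
    decades: np.ndarray
    geomean_median: np.ndarray
    geomean_q25: np.ndarray
    geomean_q75: np.ndarray

    def __post_init__(self):
        if np.any(np.diff(self.prop_below) < -1e-12):
            raise ValueError("proportion curve must be non-decreasing")
        if np.any((self.prop_below < 0) | (self.prop_below > 1)):
            raise ValueError("proportions must lie in [0, 1]")

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        risk = pd.DataFrame({"year": self.years, "prop_below_qet": self.prop_below})
        geo = pd.DataFrame({
            "decade": self.decades,
            "median": self.geomean_median,
            "q25": self.geomean_q25,
            "q75": self.geomean_q75,
        })
        return risk, geo


def _running_mean(series: np.ndarray, window: int, centered: bool) -> np.ndarray:
    """Windowed means; entry t covers [t-window+1, t] (trailing) and is NaN
    until a full window is available."""
    n = series.size
    csum = np.concatenate([[0.0], np.cumsum(series)])
    out = np.full(n, np.nan)
    if centered:
        h = window // 2
        lo = np.arange(n) - h
        hi = lo + window
        ok = (lo >= 0) & (hi <= n)
        out[ok] = (csum[hi[ok]] - csum[lo[ok]]) / window
    else:
        if n >= window:
            out[window - 1:] = (csum[window:] - csum[:-window]) / window
    return out


def qet_first_year(
    years,
    spawners,
    threshold: float = QET_THRESHOLD,
    window: int = QET_WINDOW,
    centered: bool = False,
):
    """First year ending a window whose mean spawner count is strictly below
    the threshold, or None if never."""
    if window < 1:
        raise ValueError("window must be >= 1")
    years = np.asarray(years, dtype=int)
    spawners = np.asarray(spawners, dtype=float)
    if spawners.size < window:
        raise ValueError("series shorter than the QET window")
    means = _running_mean(spawners, window, centered)
    below = np.nonzero(means < threshold)[0]
    if below.size == 0:
        return None
    t = below[0]
    if centered:
        # report the final year of the triggering window
        t = min(t + (window - 1) - window // 2, years.size - 1)
    return int(years[t])


def prop_below_qet(
    trajectories: Sequence[Trajectory],
    threshold: float = QET_THRESHOLD,
    window: int = QET_WINDOW,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-year fraction of simulations whose first QET year is <= that year."""
    if len(trajectories) == 0:
        raise ValueError("need at least one trajectory")
    years = trajectories[0].years
    firsts = np.array([
        np.nan if (fy := qet_first_year(tr.years, tr.spawners, threshold, window)) is None
        else fy
        for tr in trajectories
    ])
    with np.errstate(invalid="ignore"):
        curve = np.array([np.mean((firsts <= y) & ~np.isnan(firsts)) for y in years])
    return years, curve


def decadal_geomean(
    years,
    spawners,
    decades: Sequence[tuple[int, int]] | None = None,
    offset: float = 1.0,
) -> dict[tuple[int, int], float]:
    """Geometric mean spawners per decade: exp(mean(log(x + offset))) - offset.

    The offset (default +1 on counts) makes zeros finite; pass offset=0 for
    strictly positive series.
    """
    years = np.asarray(years, dtype=int)
    spawners = np.asarray(spawners, dtype=float)
    if decades is None:
        start = (years[0] // 10) * 10
        decades = [(d, d + 9) for d in range(start, years[-1] + 1, 10)]
    out = {}
    for lo, hi in decades:
        mask = (years >= lo) & (years <= hi)
        if not np.any(mask):
            raise ValueError(f"decade {lo}-{hi} lies outside the series")
        vals = spawners[mask] + offset
        if np.any(vals <= 0):
            raise ValueError("non-positive values under the chosen offset")
        out[(lo, hi)] = float(np.exp(np.mean(np.log(vals))) - offset)
    return out


def summarize_risk(
    trajectories: Sequence[Trajectory],
    threshold: float = QET_THRESHOLD,
    window: int = QET_WINDOW,
    offset: float = 1.0,
) -> RiskSummary:
    """Full ensemble summary: first-passage years, QET curve, decadal geomeans."""
    years, curve = prop_below_qet(trajectories, threshold, window)
    firsts = np.array([
        np.nan if (fy := qet_first_year(tr.years, tr.spawners, threshold, window)) is None
        else float(fy)
        for tr in trajectories
    ])
    start = (years[0] // 10) * 10
    decades = [(d, d + 9) for d in range(start, years[-1] + 1, 10)]
    per_sim = np.array([
        [decadal_geomean(tr.years, tr.spawners, [dec], offset)[dec] for dec in decades]
        for tr in trajectories
    ])
    return RiskSummary(
        years=years,
        first_qet_year=firsts,
        prop_below=curve,
        decades=np.array([lo for lo, _ in decades]),
        geomean_median=np.median(per_sim, axis=0),
        geomean_q25=np.percentile(per_sim, 25, axis=0),
        geomean_q75=np.percentile(per_sim, 75, axis=0),
    )
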