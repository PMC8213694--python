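"""Vegetation response time to water availability across SPEI timescales.

A cell's **minimum water-deficit response time** is the smallest SPEI
timescale k in 1..24 months whose index correlates significantly positively
(p < alpha) with the vegetation anomaly — shorter means the vegetation reacts
to shorter water-balance deficits, i.e. is more drought-susceptible. The
**maximum water-surplus period** is the largest k with a significant negative
correlation. Both can coexist in one cell (different signs at different
timescales) and both are reported.

Per-window response times (5-year windows by default) feed a linear trend
test per cell; cells with fewer defined windows than a threshold are left
undefined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import xarray as xr

from .coupling import DEFAULT_MIN_PAIRS, GROWING_SEASON, season_pairs, spearman_maps
from .grid import year_numbers
from .trendkit import linear_trend

__all__ = [
    "TimescaleProfile",
    "ResponseTimeMap",
    "UNDEFINED",
    "timescale_profile",
    "min_deficit_response",
    "max_surplus_period",
    "response_time_map",
    "windowed_response_times",
    "response_time_trend",
]

#: sentinel for "no significant timescale" in integer response-time maps
UNDEFINED = -1

DEFAULT_TIMESCALES = tuple(range(1, 25))
MIN_DEFINED_WINDOWS = 10


@dataclass
class TimescaleProfile:
    """Per-cell Spearman results against SPEI at each timescale k."""

    timescales: np.ndarray  # (nk,)
    rho: np.ndarray  # (nk, ny, nx)
    p: np.ndarray
    n: np.ndarray


@dataclass
class ResponseTimeMap:
    """Per-cell minimum deficit response time and maximum surplus period."""

    min_deficit: np.ndarray  # (ny, nx) int, UNDEFINED where no significant k
    max_surplus: np.ndarray
    alpha: float


def timescale_profile(
    anomaly: xr.DataArray,
    spei_by_k: dict[int, xr.DataArray],
    season=GROWING_SEASON,
    year_range: tuple[int, int] | None = None,
    timescales=DEFAULT_TIMESCALES,
    min_n: int = DEFAULT_MIN_PAIRS,
) -> TimescaleProfile:
    """Correlate the anomaly with SPEI separately at every timescale."""
    missing = [k for k in timescales if k not in spei_by_k]
    if missing:
        raise KeyError(f"missing SPEI cubes for timescales {missing}")
    rhos, ps, ns = [], [], []
    for k in timescales:
        x, y = season_pairs(anomaly, spei_by_k[k], season, year_range)
        rho, p, n = spearman_maps(x, y, min_n=min_n)
        rhos.append(rho)
        ps.append(p)
        ns.append(n)
    return TimescaleProfile(
        timescales=np.asarray(list(timescales)),
        rho=np.stack(rhos),
        p=np.stack(ps),
        n=np.stack(ns),
    )


def _extreme_significant(
    profile: TimescaleProfile, alpha: float, sign: int, which: str
) -> np.ndarray:
    sig = np.isfinite(profile.p) & (profile.p < alpha) & (np.sign(profile.rho) == sign)
    ks = profile.timescales.reshape((-1,) + (1,) * (profile.rho.ndim - 1))
    masked = np.where(sig, ks, UNDEFINED)
    if which == "min":
        big = profile.timescales.max() + 1
        masked = np.where(sig, ks, big)
        out = masked.min(axis=0)
        return np.where(out == big, UNDEFINED, out).astype(int)
    out = masked.max(axis=0)
    return out.astype(int)


def min_deficit_response(profile: TimescaleProfile, alpha: float = 0.05) -> np.ndarray:
    """Smallest k with p < alpha and rho > 0; UNDEFINED where none exists."""
    return _extreme_significant(profile, alpha, sign=1, which="min")


def max_surplus_period(profile: TimescaleProfile, alpha: float = 0.05) -> np.ndarray:
    """Largest k with p < alpha and rho < 0; UNDEFINED where none exists."""
    return _extreme_significant(profile, alpha, sign=-1, which="max")


def response_time_map(profile: TimescaleProfile, alpha: float = 0.05) -> ResponseTimeMap:
    return ResponseTimeMap(
        min_deficit=min_deficit_response(profile, alpha),
        max_surplus=max_surplus_period(profile, alpha),
        alpha=alpha,
    )


def windowed_response_times(
    anomaly: xr.DataArray,
    spei_by_k: dict[int, xr.DataArray],
    window_years: int = 5,
    season=GROWING_SEASON,
    alpha: float = 0.05,
    timescales=DEFAULT_TIMESCALES,
    min_n: int = DEFAULT_MIN_PAIRS,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-window response-time maps.

    Returns (start_years, min_deficit, max_surplus) where the maps are
    (nwin, ny, nx) integer arrays with UNDEFINED sentinels. Significance is
    assessed per window on that window's pairs.
    """
    years = year_numbers(anomaly)
    y0, y1 = int(years.min()), int(years.max())
    starts = np.arange(y0, y1 - window_years + 2)
    mins, maxs = [], []
    for s in starts:
        prof = timescale_profile(
            anomaly,
            spei_by_k,
            season=season,
            year_range=(int(s), int(s + window_years - 1)),
            timescales=timescales,
            min_n=min_n,
        )
        mins.append(min_deficit_response(prof, alpha))
        maxs.append(max_surplus_period(prof, alpha))
    return starts, np.stack(mins), np.stack(maxs)


def response_time_trend(
    window_values: np.ndarray, min_defined: int = MIN_DEFINED_WINDOWS
) -> tuple[np.ndarray, np.ndarray]:
    """Linear trend of per-window response times, cell by cell.

    ``window_values`` is (nwin, ny, nx) with UNDEFINED sentinels; windows
    where the response time is undefined are dropped, and cells with fewer
    than ``min_defined`` defined windows get NaN slope and p.
    """
    nwin = window_values.shape[0]
    cell_shape = window_values.shape[1:]
    slope = np.full(cell_shape, np.nan)
    pval = np.full(cell_shape, np.nan)
    xs = np.arange(nwin, dtype=float)
    defined = window_values != UNDEFINED
    enough = defined.sum(axis=0) >= min_defined
    for idx in np.argwhere(enough):
        sel = defined[(slice(None), *idx)]
        y = window_values[(slice(None), *idx)][sel].astype(float)
        b, _, p = linear_trend(y, x=xs[sel])
        slope[tuple(idx)] = b
        pval[tuple(idx)] = p
    return slope, pval
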