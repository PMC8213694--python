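"""Per-cell vegetation-moisture coupling: Spearman correlation, regime
classification, moving-window coupling series, and class-area fractions.

A grid cell whose growing-season vegetation anomaly correlates significantly
*positively* (p < alpha, default 0.05) with a water-availability index is a
**water deficit** cell (growth limited by water scarcity); a significant
*negative* correlation marks a **water surplus** cell (growth favoured by
drier-than-normal conditions). Non-significant cells are "none"; cells with
too few valid pairs are "invalid".

Samples are monthly growing-season (anomaly, index) pairs pooled across
years — 7 months x 34 years = 238 pairs for a full 1982-2015 record, 35 per
5-year window. An annual-mean layout (one pair per year) is available behind
``layout="annual"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import xarray as xr
from scipy import stats

from .grid import TIME, align_check, select_season_years, year_numbers

__all__ = [
    "CouplingMap",
    "WindowSeries",
    "spearman",
    "spearman_maps",
    "season_pairs",
    "classify",
    "full_period_coupling",
    "moving_windows",
    "area_fraction",
    "CLASS_CODES",
    "GROWING_SEASON",
    "DEFAULT_MIN_PAIRS",
]

GROWING_SEASON = (4, 5, 6, 7, 8, 9, 10)  # April..October
DEFAULT_MIN_PAIRS = 10

#: byte codes used in classification maps and NetCDF output
CLASS_CODES = {"none": 0, "deficit": 1, "surplus": 2, "invalid": 255}


@dataclass
class CouplingMap:
    """Per-cell Spearman rho, p-value, pair count, and regime class code."""

    rho: np.ndarray  # (ny, nx) float
    p: np.ndarray  # (ny, nx) float
    n: np.ndarray  # (ny, nx) int
    cls: np.ndarray  # (ny, nx) uint8, see CLASS_CODES
    alpha: float
    min_n: int


@dataclass
class WindowSeries:
    """Consecutive moving-window results: per-window rho/p/class per cell."""

    start_years: np.ndarray  # (nwin,)
    window_years: int
    rho: np.ndarray  # (nwin, ny, nx)
    p: np.ndarray
    n: np.ndarray
    cls: np.ndarray  # (nwin, ny, nx) uint8


# --------------------------------------------------------------------------
# rank correlation
# --------------------------------------------------------------------------


def spearman(x, y, min_n: int = DEFAULT_MIN_PAIRS) -> tuple[float, float, int]:
    """Spearman rho and two-sided p (t-approximation) on one paired sample.

    Invalid pairs (either member non-finite) are dropped first; fewer than
    ``min_n`` surviving pairs yields ``(nan, nan, n)`` rather than an
    exception.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    n = int(ok.sum())
    if n < max(min_n, 3):
        return np.nan, np.nan, n
    rho, p = stats.spearmanr(x[ok], y[ok])
    return float(rho), float(p), n


def _rank_along0(a: np.ndarray) -> np.ndarray:
    return stats.rankdata(a, axis=0)


def spearman_maps(
    x: np.ndarray, y: np.ndarray, min_n: int = DEFAULT_MIN_PAIRS
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized Spearman over stacked samples: x, y are (nsamples, ...).

    Cells whose sample contains any invalid value fall back to the pairwise-
    deletion scalar path; fully valid cells are ranked and correlated in one
    vectorized pass (average ranks, two-sided t-approximation p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must share a shape")
    m = x.shape[0]
    cell_shape = x.shape[1:]
    rho = np.full(cell_shape, np.nan)
    p = np.full(cell_shape, np.nan)
    n = np.full(cell_shape, 0, dtype=int)
    finite = np.isfinite(x) & np.isfinite(y)
    all_ok = finite.all(axis=0)
    n_ok = finite.sum(axis=0)
    n[...] = n_ok
    if m >= max(min_n, 3) and all_ok.any():
        rx = _rank_along0(x[:, all_ok])
        ry = _rank_along0(y[:, all_ok])
        rx = rx - rx.mean(axis=0)
        ry = ry - ry.mean(axis=0)
        denom = np.sqrt((rx**2).sum(axis=0) * (ry**2).sum(axis=0))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (rx * ry).sum(axis=0) / denom
            r = np.clip(r, -1.0, 1.0)
            t = r * np.sqrt((m - 2) / np.maximum(1.0 - r**2, 1e-300))
        pv = 2.0 * stats.t.sf(np.abs(t), df=m - 2)
        pv = np.where(np.isclose(np.abs(r), 1.0), 0.0, pv)
        rho[all_ok] = r
        p[all_ok] = pv
    # ragged cells: pairwise deletion, one at a time
    ragged = ~all_ok & (n_ok >= max(min_n, 3))
    for idx in np.argwhere(ragged):
        sl = (slice(None), *idx)
        rho[tuple(idx)], p[tuple(idx)], n[tuple(idx)] = spearman(x[sl], y[sl], min_n=min_n)
    return rho, p, n


# --------------------------------------------------------------------------
# pairing and classification
# --------------------------------------------------------------------------


def season_pairs(
    anomaly: xr.DataArray,
    index: xr.DataArray,
    season=GROWING_SEASON,
    year_range: tuple[int, int] | None = None,
    layout: str = "monthly",
) -> tuple[np.ndarray, np.ndarray]:
    """Stack paired (anomaly, index) samples for every cell.

    Returns two arrays of shape (nsamples, ny, nx). ``layout="monthly"``
    pools the individual season months across years; ``layout="annual"``
    first averages each year's season months, giving one pair per year.
    """
    align_check(anomaly, index)
    a = select_season_years(anomaly, season, year_range)
    w = select_season_years(index, season, year_range)
    if layout == "monthly":
        return a.values, w.values
    if layout == "annual":
        ay = a.groupby(f"{TIME}.year").mean(skipna=False)
        wy = w.groupby(f"{TIME}.year").mean(skipna=False)
        return ay.values, wy.values
    raise ValueError(f"unknown sample layout {layout!r}")


def classify(
    rho: np.ndarray,
    p: np.ndarray,
    n: np.ndarray,
    alpha: float = 0.05,
    min_n: int = DEFAULT_MIN_PAIRS,
) -> np.ndarray:
    """Regime class codes from correlation results.

    deficit <=> p < alpha and rho > 0; surplus <=> p < alpha and rho < 0;
    invalid <=> fewer than ``min_n`` pairs (or undefined rho); none otherwise.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    cls = np.full(np.shape(rho), CLASS_CODES["none"], dtype=np.uint8)
    sig = np.isfinite(p) & (p < alpha)
    cls[sig & (rho > 0)] = CLASS_CODES["deficit"]
    cls[sig & (rho < 0)] = CLASS_CODES["surplus"]
    invalid = (np.asarray(n) < min_n) | ~np.isfinite(rho)
    cls[invalid] = CLASS_CODES["invalid"]
    return cls


def full_period_coupling(
    anomaly: xr.DataArray,
    index: xr.DataArray,
    season=GROWING_SEASON,
    year_range: tuple[int, int] | None = None,
    alpha: float = 0.05,
    min_n: int = DEFAULT_MIN_PAIRS,
    layout: str = "monthly",
) -> CouplingMap:
    """Classify every cell from all pooled season pairs in the year range."""
    x, y = season_pairs(anomaly, index, season, year_range, layout)
    rho, p, n = spearman_maps(x, y, min_n=min_n)
    cls = classify(rho, p, n, alpha=alpha, min_n=min_n)
    return CouplingMap(rho=rho, p=p, n=n, cls=cls, alpha=alpha, min_n=min_n)


def moving_windows(
    anomaly: xr.DataArray,
    index: xr.DataArray,
    window_years: int = 5,
    season=GROWING_SEASON,
    alpha: float = 0.05,
    min_n: int = DEFAULT_MIN_PAIRS,
    layout: str = "monthly",
) -> WindowSeries:
    """Per-cell coupling in every consecutive ``window_years``-year window.

    A record of Y years yields Y - w + 1 windows (1982-2015 with w = 5 gives
    30). Each window's rho uses only that window's season pairs; anomalies are
    the full-period-climatology anomalies passed in.
    """
    years = year_numbers(anomaly)
    y0, y1 = int(years.min()), int(years.max())
    n_years = y1 - y0 + 1
    if window_years > n_years:
        raise ValueError(f"window of {window_years} years exceeds the {n_years}-year record")
    starts = np.arange(y0, y1 - window_years + 2)
    rhos, ps, ns, clss = [], [], [], []
    for s in starts:
        cm = full_period_coupling(
            anomaly,
            index,
            season=season,
            year_range=(int(s), int(s + window_years - 1)),
            alpha=alpha,
            min_n=min_n,
            layout=layout,
        )
        rhos.append(cm.rho)
        ps.append(cm.p)
        ns.append(cm.n)
        clss.append(cm.cls)
    return WindowSeries(
        start_years=starts,
        window_years=window_years,
        rho=np.stack(rhos),
        p=np.stack(ps),
        n=np.stack(ns),
        cls=np.stack(clss),
    )


def area_fraction(cls: np.ndarray, regime: str, valid_mask: np.ndarray | None = None):
    """Fraction of valid cells in a regime; denominator fixed by ``valid_mask``.

    ``cls`` is a (ny, nx) class-code map or a (nwin, ny, nx) stack; the
    denominator is the count of valid vegetated cells (constant across
    windows), taken from ``valid_mask`` when given, else from cells not coded
    invalid.
    """
    code = CLASS_CODES[regime]
    cls = np.asarray(cls)
    per_window = cls.ndim == 3
    if valid_mask is None:
        valid = cls != CLASS_CODES["invalid"]
        valid = valid.all(axis=0) if per_window else valid
    else:
        valid = np.asarray(valid_mask, dtype=bool)
    denom = valid.sum()
    if denom == 0:
        raise ValueError("no valid cells in denominator")
    hits = (cls == code) & valid
    frac = hits.sum(axis=(-2, -1)) / denom
    return frac if per_window else float(frac)
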