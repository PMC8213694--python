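"""Climate-driver attribution of moving-window coupling series.

For each cell, the per-window coupling coefficient (vegetation-moisture
Spearman rho across 5-year windows) is regressed on four window-mean drivers:
growing-season precipitation, air temperature, shortwave radiation, and
atmospheric CO2. An overall F-test screens whether the drivers explain the
coupling dynamics at all; among screened cells the driver with the largest
absolute *partial Spearman* correlation (rank-transformed, conditioning on
the other three) is the dominant factor; and an exact
Lindeman-Merenda-Gold (LMG) decomposition splits the model R² into
non-negative per-driver importance shares by averaging each driver's
sequential R² increment over all 4! predictor orderings (computed from the
2^4 subset R² values).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import factorial

import numpy as np
import xarray as xr
from scipy import stats

from .coupling import GROWING_SEASON
from .grid import select_season_years

__all__ = [
    "DRIVERS",
    "AttributionMap",
    "window_driver_means",
    "screen_model",
    "partial_spearman",
    "dominant_factor",
    "lmg_importance",
    "attribute_cells",
    "dominant_area_summary",
]

#: fixed driver order; also the tie-breaking order for dominant_factor
DRIVERS = ("precipitation", "radiation", "temperature", "co2")

#: byte codes for dominant-factor maps (0 = none / not significant)
DRIVER_CODES = {"none": 0, "precipitation": 1, "radiation": 2, "temperature": 3, "co2": 4}


@dataclass
class AttributionMap:
    """Per-cell attribution of the window coupling series to four drivers."""

    model_p: np.ndarray  # (ny, nx)
    partial: np.ndarray  # (4, ny, nx) partial Spearman per driver
    dominant: np.ndarray  # (ny, nx) uint8, DRIVER_CODES
    tie: np.ndarray  # (ny, nx) bool, exact |partial| tie among top drivers
    lmg: np.ndarray  # (4, ny, nx) importance shares
    r2: np.ndarray  # (ny, nx)
    alpha: float


# --------------------------------------------------------------------------
# window driver means
# --------------------------------------------------------------------------


def window_driver_means(
    precip: xr.DataArray,
    temp: xr.DataArray,
    rad: xr.DataArray,
    co2: np.ndarray,
    start_years: np.ndarray,
    window_years: int = 5,
    season=GROWING_SEASON,
) -> np.ndarray:
    """Per-cell driver matrix: (nwin, 4, ny, nx) of window-season means.

    ``co2`` is a scalar monthly series aligned with the cubes' calendar; its
    window mean is broadcast to every cell (column order follows DRIVERS).
    """
    co2 = np.asarray(co2, dtype=float)
    if co2.size != precip.sizes["time"]:
        raise ValueError("CO2 series length does not match the cube calendar")
    co2_da = precip.copy(data=np.broadcast_to(co2[:, None, None], precip.shape))
    ny, nx = precip.sizes["lat"], precip.sizes["lon"]
    out = np.full((len(start_years), 4, ny, nx), np.nan)
    cubes = {"precipitation": precip, "radiation": rad, "temperature": temp, "co2": co2_da}
    for i, s in enumerate(start_years):
        yr = (int(s), int(s + window_years - 1))
        for j, name in enumerate(DRIVERS):
            sel = select_season_years(cubes[name], season, yr)
            out[i, j] = sel.mean(dim="time", skipna=False).values
    return out


# --------------------------------------------------------------------------
# per-series statistics
# --------------------------------------------------------------------------


def _ols_r2(y: np.ndarray, X: np.ndarray) -> float:
    """R² of y on X with intercept (empty X gives 0)."""
    n = y.size
    yc = y - y.mean()
    tss = float(yc @ yc)
    if tss == 0:
        return np.nan
    if X.shape[1] == 0:
        return 0.0
    Xc = X - X.mean(axis=0)
    coef, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
    resid = yc - Xc @ coef
    return float(1.0 - (resid @ resid) / tss)


def screen_model(y, X, min_n: int = 10) -> tuple[float, float]:
    """Overall F-test of the multivariate linear model y ~ X (raw values).

    Returns ``(p, R²)``; a constant y or too-short series gives NaNs.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    ok = np.isfinite(y) & np.isfinite(X).all(axis=1)
    y, X = y[ok], X[ok]
    n, k = X.shape
    if n < max(min_n, k + 2) or np.ptp(y) == 0:
        return np.nan, np.nan
    r2 = _ols_r2(y, X)
    if not np.isfinite(r2):
        return np.nan, np.nan
    df2 = n - k - 1
    if r2 >= 1.0:
        return 0.0, 1.0
    f = (r2 / k) / ((1.0 - r2) / df2)
    return float(stats.f.sf(f, k, df2)), r2


def _rank(a: np.ndarray) -> np.ndarray:
    return stats.rankdata(a, axis=0) if a.ndim > 1 else stats.rankdata(a)


def partial_spearman(y, X, j: int, method: str = "precision") -> float:
    """Partial Spearman correlation of y with X[:, j] given the other columns.

    All variables are rank-transformed (average ranks) first. Two algebraically
    equivalent routes are provided: ``"residual"`` correlates the residuals of
    rank-y and rank-x_j after regressing each on the remaining columns (with
    intercept); ``"precision"`` reads the partial correlation off the inverse
    of the rank correlation matrix. A collinear conditioning set gives NaN.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    ok = np.isfinite(y) & np.isfinite(X).all(axis=1)
    y, X = y[ok], X[ok]
    if y.size < X.shape[1] + 3:
        return np.nan
    ry = _rank(y)
    rX = _rank(X)
    others = [c for c in range(X.shape[1]) if c != j]
    if method == "residual":
        Z = np.column_stack([np.ones(y.size), rX[:, others]])
        beta_y, *_ = np.linalg.lstsq(Z, ry, rcond=None)
        beta_x, *_ = np.linalg.lstsq(Z, rX[:, j], rcond=None)
        ey = ry - Z @ beta_y
        ex = rX[:, j] - Z @ beta_x
        denom = np.sqrt((ey @ ey) * (ex @ ex))
        if denom < 1e-12:
            return np.nan
        return float((ey @ ex) / denom)
    if method == "precision":
        M = np.column_stack([ry, rX[:, j], rX[:, others]])
        C = np.corrcoef(M, rowvar=False)
        if not np.all(np.isfinite(C)):
            return np.nan
        try:
            P = np.linalg.inv(C)
        except np.linalg.LinAlgError:
            return np.nan
        if np.abs(np.linalg.det(C)) < 1e-12:
            return np.nan
        return float(-P[0, 1] / np.sqrt(P[0, 0] * P[1, 1]))
    raise ValueError(f"unknown partial-correlation method {method!r}")


def dominant_factor(partials, model_p: float, alpha: float = 0.05) -> tuple[str, bool]:
    """Dominant driver: argmax |partial r| among screened cells.

    Returns ``(driver_name_or_"none", tie_flag)``. Cells whose model F-test
    p is >= alpha (or undefined) are "none". Exact ties in |partial r| are
    broken by the fixed DRIVERS order and flagged.
    """
    partials = np.asarray(partials, dtype=float)
    if not (np.isfinite(model_p) and model_p < alpha):
        return "none", False
    if not np.isfinite(partials).any():
        return "none", False
    absr = np.where(np.isfinite(partials), np.abs(partials), -np.inf)
    best = int(np.argmax(absr))  # argmax takes the first index on ties
    tie = bool((absr == absr[best]).sum() > 1)
    return DRIVERS[best], tie


def lmg_importance(y, X) -> tuple[np.ndarray, float]:
    """Exact LMG relative-importance shares and the full-model R².

    Each driver's share is the average, over all orderings of the predictors,
    of the R² increment it contributes when entered in that position —
    computed exactly from the 2^k subset R² values. Shares are non-negative
    (sequential R² increments never decrease R²) and sum to the full R².
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    ok = np.isfinite(y) & np.isfinite(X).all(axis=1)
    y, X = y[ok], X[ok]
    n, k = X.shape
    if n <= k + 2 or np.ptp(y) == 0:
        return np.full(k, np.nan), np.nan
    r2 = {}
    for size in range(k + 1):
        for subset in combinations(range(k), size):
            r2[subset] = _ols_r2(y, X[:, list(subset)])
    shares = np.zeros(k)
    for j in range(k):
        rest = [c for c in range(k) if c != j]
        for size in range(k):
            w = factorial(size) * factorial(k - size - 1) / factorial(k)
            for subset in combinations(rest, size):
                with_j = tuple(sorted(subset + (j,)))
                shares[j] += w * (r2[with_j] - r2[subset])
    return shares, r2[tuple(range(k))]


# --------------------------------------------------------------------------
# gridded attribution
# --------------------------------------------------------------------------


def attribute_cells(
    window_rho: np.ndarray,
    driver_matrix: np.ndarray,
    alpha: float = 0.05,
    min_windows: int = 10,
) -> AttributionMap:
    """Run screening, partial correlations, dominance, and LMG per cell.

    ``window_rho`` is (nwin, ny, nx); ``driver_matrix`` is (nwin, 4, ny, nx)
    from :func:`window_driver_means`.
    """
    nwin, ny, nx = window_rho.shape
    model_p = np.full((ny, nx), np.nan)
    partial = np.full((4, ny, nx), np.nan)
    dominant = np.zeros((ny, nx), dtype=np.uint8)
    tie = np.zeros((ny, nx), dtype=bool)
    lmg = np.full((4, ny, nx), np.nan)
    r2map = np.full((ny, nx), np.nan)
    for iy in range(ny):
        for ix in range(nx):
            y = window_rho[:, iy, ix]
            X = driver_matrix[:, :, iy, ix]
            ok = np.isfinite(y) & np.isfinite(X).all(axis=1)
            if ok.sum() < min_windows:
                continue
            p, _ = screen_model(y[ok], X[ok], min_n=min_windows)
            model_p[iy, ix] = p
            for j in range(4):
                partial[j, iy, ix] = partial_spearman(y[ok], X[ok], j)
            name, t = dominant_factor(partial[:, iy, ix], p, alpha=alpha)
            dominant[iy, ix] = DRIVER_CODES[name]
            tie[iy, ix] = t
            shares, r2 = lmg_importance(y[ok], X[ok])
            lmg[:, iy, ix] = shares
            r2map[iy, ix] = r2
    return AttributionMap(
        model_p=model_p, partial=partial, dominant=dominant, tie=tie, lmg=lmg, r2=r2map, alpha=alpha
    )


def dominant_area_summary(attribution: AttributionMap, class_map: np.ndarray) -> dict:
    """Per-regime fractions of attributed cells dominated by each driver.

    Within each coupling regime ("deficit", "surplus"), fractions are over
    cells whose dominant factor is not "none" and sum to 1; an empty regime
    reports None for every driver.
    """
    from .coupling import CLASS_CODES

    out: dict[str, dict[str, float | None]] = {}
    for regime in ("deficit", "surplus"):
        cells = (np.asarray(class_map) == CLASS_CODES[regime]) & (attribution.dominant != 0)
        total = int(cells.sum())
        if total == 0:
            out[regime] = {name: None for name in DRIVERS}
            continue
        out[regime] = {
            name: float(((attribution.dominant == DRIVER_CODES[name]) & cells).sum() / total)
            for name in DRIVERS
        }
    return out
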