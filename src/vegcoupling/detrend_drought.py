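"""Long-term detrending of vegetation series and drought-conditioned anomaly
trends.

Two detrending routes are provided. The linear route removes the OLS slope of
a monthly series only when that slope is significant (p < alpha), either over
the whole record or piecewise over consecutive 5-year blocks; the mean of the
series is preserved. The non-linear route subtracts a centred interannual
moving average (half weights at the window ends for an even span, the
classical seasonal-decomposition trend filter).

``drought_anomaly_trend`` then asks whether vegetation state during drought
months is itself drifting: it averages the detrended growing-season anomalies
over all drought-flagged cell-months of each year and runs the trend tests on
the resulting annual series. A decreasing trend means droughts of fixed
meteorological severity leave vegetation progressively worse off.
"""

from __future__ import annotations

import numpy as np
import xarray as xr

from .grid import align_check, season_mask, year_numbers
from .coupling import GROWING_SEASON
from .trendkit import TrendResult, linear_trend, trend_test

__all__ = [
    "detrend_linear",
    "detrend_linear_blocks",
    "detrend_moving_average",
    "detrend_cube",
    "drought_anomaly_trend",
]


def detrend_linear(series, alpha: float = 0.05):
    """Remove a significant OLS slope from a 1-D series; keep the mean.

    If the slope's two-sided p is >= alpha the input is returned unchanged
    (same object), so insignificant series pass through bit-identical.
    """
    y = np.asarray(series, dtype=float)
    if np.isfinite(y).sum() < 24:
        return series
    slope, _, p = linear_trend(y)
    if not (np.isfinite(p) and p < alpha):
        return series
    x = np.arange(y.size, dtype=float)
    ok = np.isfinite(y)
    out = y.copy()
    out[ok] = y[ok] - slope * (x[ok] - x[ok].mean())
    return out


def detrend_linear_blocks(series, block_months: int = 60, alpha: float = 0.05):
    """Piecewise linear detrending over consecutive blocks (default 5 years).

    Each full block is detrended independently with :func:`detrend_linear`'s
    rule; a trailing remainder shorter than a block is treated as its own
    (short) block. This is the variant used before drought-conditioned
    trend analysis, so that multi-decadal drivers such as CO2 fertilization
    or greening trends are removed locally in time.
    """
    y = np.asarray(series, dtype=float)
    out = y.copy()
    n = y.size
    edges = list(range(0, n, block_months))
    for b0 in edges:
        b1 = min(b0 + block_months, n)
        if n - b1 < block_months:  # absorb short remainder into this block
            b1 = n
        block = y[b0:b1]
        if np.isfinite(block).sum() >= 24:
            slope, _, p = linear_trend(block)
            if np.isfinite(p) and p < alpha:
                x = np.arange(block.size, dtype=float)
                ok = np.isfinite(block)
                det = block.copy()
                det[ok] = block[ok] - slope * (x[ok] - x[ok].mean())
                out[b0:b1] = det
        if b1 == n:
            break
    return out


def detrend_moving_average(series, span: int = 12):
    """Subtract a centred moving-average trend; edges become invalid.

    For an even ``span`` the window covers span+1 points with half weights at
    both ends (the standard symmetric filter that averages exactly one full
    seasonal cycle). Months where the window is incomplete are NaN in the
    output.
    """
    y = np.asarray(series, dtype=float)
    n = y.size
    if n <= span:
        raise ValueError(f"series of length {n} is not longer than span {span}")
    if span % 2 == 0:
        w = np.ones(span + 1)
        w[0] = w[-1] = 0.5
        w /= span
    else:
        w = np.ones(span) / span
    half = len(w) // 2
    trend = np.full(n, np.nan)
    conv = np.convolve(y, w[::-1], mode="valid")  # symmetric w; reversal for clarity
    trend[half : half + conv.size] = conv
    return y - trend


def detrend_cube(
    cube: xr.DataArray,
    method: str = "linear_blocks",
    alpha: float = 0.05,
    span: int = 12,
    block_months: int = 60,
) -> xr.DataArray:
    """Apply a detrending route to every cell of a cube."""
    vals = cube.values
    out = np.empty_like(vals)
    ny, nx = vals.shape[1:]
    for iy in range(ny):
        for ix in range(nx):
            s = vals[:, iy, ix]
            if not np.isfinite(s).any():
                out[:, iy, ix] = s
                continue
            if method == "linear":
                out[:, iy, ix] = detrend_linear(s, alpha=alpha)
            elif method == "linear_blocks":
                out[:, iy, ix] = detrend_linear_blocks(s, block_months=block_months, alpha=alpha)
            elif method == "moving_average":
                out[:, iy, ix] = detrend_moving_average(s, span=span)
            else:
                raise ValueError(f"unknown detrending method {method!r}")
    res = cube.copy(data=out)
    res.attrs = dict(cube.attrs, detrend_method=method)
    return res


def drought_anomaly_trend(
    anomaly: xr.DataArray,
    drought_flags: xr.DataArray | np.ndarray,
    season=GROWING_SEASON,
    alpha: float = 0.05,
) -> tuple[np.ndarray, np.ndarray, TrendResult | None]:
    """Annual mean of drought-flagged growing-season anomalies and its trend.

    ``drought_flags`` is a boolean cube aligned with ``anomaly`` (see
    :func:`vegcoupling.indices.flag_drought`). For each year, the anomaly is
    averaged over every flagged cell-month inside the growing season; years
    without any flagged sample are NaN. Returns ``(years, annual_series,
    trend)``; the trend is None when fewer than 4 years are defined.
    """
    flags = drought_flags.values if isinstance(drought_flags, xr.DataArray) else np.asarray(drought_flags)
    if flags.shape != anomaly.shape:
        raise ValueError("drought flags and anomaly cube have mismatched shapes")
    if isinstance(drought_flags, xr.DataArray):
        align_check(anomaly, drought_flags)
    in_season = season_mask(anomaly, season)
    years = year_numbers(anomaly)
    uniq = np.unique(years)
    vals = anomaly.values
    use = flags & in_season[:, None, None] & np.isfinite(vals)
    annual = np.full(uniq.size, np.nan)
    for i, yr in enumerate(uniq):
        sel = use & (years == yr)[:, None, None]
        if sel.any():
            annual[i] = vals[sel].mean()
    if np.isfinite(annual).sum() < 4:
        return uniq, annual, None
    return uniq, annual, trend_test(annual, alpha=alpha, mode="linear")
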