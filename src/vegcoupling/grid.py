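"""Gridded monthly cube helpers.

The universal carrier for all inputs and intermediates is an
:class:`xarray.DataArray` with dims ``(time, lat, lon)``, a monthly
``datetime64`` time coordinate, and NaN marking invalid samples. The helpers
here construct, validate, and slice such cubes; everything downstream assumes
their conventions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import xarray as xr

TIME, LAT, LON = "time", "lat", "lon"
CUBE_DIMS = (TIME, LAT, LON)


class CalendarError(ValueError):
    """Raised when a time coordinate is not a supported monthly calendar."""


def monthly_index(start_year: int, end_year: int) -> pd.DatetimeIndex:
    """Month-start timestamps covering January ``start_year`` .. December ``end_year``."""
    if end_year < start_year:
        raise ValueError(f"end_year {end_year} < start_year {start_year}")
    return pd.date_range(f"{start_year}-01-01", f"{end_year}-12-01", freq="MS")


def default_coords(ny: int, nx: int) -> tuple[np.ndarray, np.ndarray]:
    """0.5-degree grid centres, lat ascending, lon in [-180, 180)."""
    lat = 30.25 + 0.5 * np.arange(ny)
    lon = -10.25 + 0.5 * np.arange(nx)
    return lat, lon


def make_cube(
    values: np.ndarray,
    times: pd.DatetimeIndex,
    lat: np.ndarray | None = None,
    lon: np.ndarray | None = None,
    name: str | None = None,
    attrs: dict | None = None,
) -> xr.DataArray:
    """Wrap a (time, y, x) array into the canonical cube form."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 3:
        raise ValueError(f"cube values must be 3-D (time, lat, lon), got {values.shape}")
    nt, ny, nx = values.shape
    if len(times) != nt:
        raise ValueError(f"time coordinate length {len(times)} != values {nt}")
    if lat is None or lon is None:
        dlat, dlon = default_coords(ny, nx)
        lat = dlat if lat is None else lat
        lon = dlon if lon is None else lon
    return xr.DataArray(
        values,
        dims=CUBE_DIMS,
        coords={TIME: times, LAT: np.asarray(lat, float), LON: np.asarray(lon, float)},
        name=name,
        attrs=attrs or {},
    )


def check_monthly(times) -> None:
    """Validate a monthly time coordinate; name the offending interval otherwise."""
    t = pd.DatetimeIndex(np.asarray(times))
    if len(t) < 2:
        return
    per = t.to_period("M")
    steps = per[1:].astype("int64") - per[:-1].astype("int64")
    bad = np.nonzero(steps != 1)[0]
    if bad.size:
        i = int(bad[0])
        raise CalendarError(
            f"time step between {t[i].date()} and {t[i + 1].date()} is not one month"
        )


def align_check(*cubes: xr.DataArray) -> None:
    """Require identical calendars and grids across cubes."""
    ref = cubes[0]
    for c in cubes[1:]:
        if not ref[TIME].equals(c[TIME]):
            raise CalendarError("cubes have mismatched time coordinates")
        if ref.sizes[LAT] != c.sizes[LAT] or ref.sizes[LON] != c.sizes[LON]:
            raise ValueError("cubes have mismatched grids")


def month_numbers(cube: xr.DataArray) -> np.ndarray:
    return cube[TIME].dt.month.values


def year_numbers(cube: xr.DataArray) -> np.ndarray:
    return cube[TIME].dt.year.values


def season_mask(cube: xr.DataArray, season: tuple[int, ...]) -> np.ndarray:
    """Boolean along-time mask for the given calendar months."""
    months = set(int(m) for m in season)
    if not months or not months <= set(range(1, 13)):
        raise ValueError(f"season months must be within 1..12, got {sorted(months)}")
    return np.isin(month_numbers(cube), sorted(months))


def select_season_years(
    cube: xr.DataArray,
    season: tuple[int, ...],
    year_range: tuple[int, int] | None = None,
) -> xr.DataArray:
    """Slice a cube down to the season months inside an inclusive year range."""
    keep = season_mask(cube, season)
    if year_range is not None:
        years = year_numbers(cube)
        keep &= (years >= year_range[0]) & (years <= year_range[1])
    return cube.isel({TIME: np.nonzero(keep)[0]})
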