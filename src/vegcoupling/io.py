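"""NetCDF and sidecar I/O for gridded monthly cubes.

Cubes are written as classic NetCDF (scipy backend) with CF-style time
encoding ("days since 1850-01-01", standard calendar) and NaN fill for
invalid samples; a write -> read round trip preserves values, mask, and
calendar exactly. Only standard/gregorian monthly calendars are supported —
files with e.g. a 360-day calendar are rejected with an explicit error.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import xarray as xr

from .grid import CalendarError, TIME, check_monthly

__all__ = ["read_cube", "write_cube", "write_truth", "read_truth"]

_SUPPORTED_CALENDARS = {None, "standard", "gregorian", "proleptic_gregorian"}


def write_cube(cube: xr.DataArray, path, variable: str | None = None) -> Path:
    """Write one cube to a classic NetCDF file."""
    path = Path(path)
    name = variable or cube.name or "data"
    ds = cube.to_dataset(name=name)
    enc = {
        name: {"_FillValue": np.nan},
        TIME: {"units": "days since 1850-01-01", "calendar": "standard"},
    }
    ds.to_netcdf(path, engine="scipy", encoding=enc)
    return path


def read_cube(path, variable: str | None = None) -> xr.DataArray:
    """Read one cube, validating the calendar before decoding it.

    Raises :class:`~vegcoupling.grid.CalendarError` for non-monthly time
    steps or unsupported (e.g. 360-day) calendars, and ``KeyError`` naming
    the variable when it is absent.
    """
    path = Path(path)
    with xr.open_dataset(path, engine="scipy", decode_times=False) as raw:
        cal = raw[TIME].attrs.get("calendar") if TIME in raw else None
        if cal is not None and cal.lower() not in _SUPPORTED_CALENDARS:
            raise CalendarError(f"unsupported calendar {cal!r} in {path.name}")
        raw.load()
    ds = xr.decode_cf(raw)
    if variable is None:
        candidates = [v for v in ds.data_vars if TIME in ds[v].dims]
        if len(candidates) != 1:
            raise KeyError(f"specify a variable; {path.name} holds {sorted(ds.data_vars)}")
        variable = candidates[0]
    if variable not in ds:
        raise KeyError(f"variable {variable!r} not found in {path.name}")
    cube = ds[variable]
    check_monthly(cube[TIME].values)
    return cube.load()


def write_truth(truth, path) -> Path:
    path = Path(path)
    path.write_text(truth.to_json())
    return path


def read_truth(path):
    from .synthetic import SyntheticTruth

    return SyntheticTruth.from_json(Path(path).read_text())


def write_manifest(manifest: dict, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return path
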