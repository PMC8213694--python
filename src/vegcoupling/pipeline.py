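"""End-to-end orchestration: config validation, stage sequencing, output
manifest.

A run executes the analysis sequence indices -> coupling -> trends ->
response time -> drought trend -> attribution on either synthetic inputs
(generated from the config's ``synth`` section) or user-supplied NetCDF
cubes, writing NetCDF maps, CSV series, and a JSON manifest into the output
directory. Given one config + seed, every output file is reproducible
byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from . import attribution as attr_mod
from . import coupling as cpl
from . import detrend_drought as dd
from . import indices as idx
from . import io as vio
from . import response_time as rt
from . import synthetic as syn
from .trendkit import trend_test

__all__ = ["RunConfig", "run_pipeline", "load_config"]

FLOAT_FMT = "%.10g"

_STAGES = ("indices", "coupling", "response_time", "drought_trend", "attribution")


class ConfigError(ValueError):
    pass


@dataclasses.dataclass
class RunConfig:
    """Validated run configuration; unknown keys are rejected up front."""

    out_dir: str = "vegcoupling_run"
    seed: int = 0
    synth: dict = dataclasses.field(default_factory=dict)
    season: tuple = cpl.GROWING_SEASON
    window_years: int = 5
    alpha: float = 0.05
    timescale_min: int = 1
    timescale_max: int = 24
    calibration: tuple | None = None  # (start_year, end_year) or None = full record
    drought_threshold_spei: float = idx.DROUGHT_SPEI03
    drought_threshold_scpdsi: float = idx.DROUGHT_SCPDSI
    detrend_method: str = "linear_blocks"
    min_pairs: int = cpl.DEFAULT_MIN_PAIRS
    sample_layout: str = "monthly"
    stages: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha must be in (0,1), got {self.alpha}")
        if not 1 <= self.timescale_min <= self.timescale_max <= 24:
            raise ConfigError("timescale range must satisfy 1 <= min <= max <= 24")
        if self.window_years < 2:
            raise ConfigError("window_years must be >= 2")
        unknown = set(self.stages) - set(_STAGES)
        if unknown:
            raise ConfigError(f"unknown stage toggles: {sorted(unknown)}")
        self.season = tuple(int(m) for m in self.season)

    def stage_enabled(self, name: str) -> bool:
        return bool(self.stages.get(name, True))

    @property
    def timescales(self) -> range:
        return range(self.timescale_min, self.timescale_max + 1)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError("config file must hold a mapping")
    return RunConfig.from_dict(data)


# --------------------------------------------------------------------------
# stage helpers (shared by `run` and the per-stage CLI commands)
# --------------------------------------------------------------------------


def _map_dataset(arrays: dict, like: xr.DataArray) -> xr.Dataset:
    coords = {"lat": like["lat"].values, "lon": like["lon"].values}
    data = {}
    for name, arr in arrays.items():
        arr = np.asarray(arr)
        dims = ("lat", "lon") if arr.ndim == 2 else ("layer", "lat", "lon")
        data[name] = (dims, arr)
    return xr.Dataset(data, coords=coords)


def _write_map(arrays: dict, like: xr.DataArray, path: Path) -> Path:
    ds = _map_dataset(arrays, like)
    ds.to_netcdf(path, engine="scipy")
    return path


def coupling_stage(
    anomaly: xr.DataArray,
    index_cube: xr.DataArray,
    cfg: RunConfig,
    label: str,
    out: Path,
    valid_mask: np.ndarray,
) -> dict:
    """Full-period classification, window series, area fractions and trends."""
    full = cpl.full_period_coupling(
        anomaly, index_cube, season=cfg.season, alpha=cfg.alpha,
        min_n=cfg.min_pairs, layout=cfg.sample_layout,
    )
    win = cpl.moving_windows(
        anomaly, index_cube, window_years=cfg.window_years, season=cfg.season,
        alpha=cfg.alpha, min_n=cfg.min_pairs, layout=cfg.sample_layout,
    )
    frames = {"window_start": win.start_years}
    for regime in ("deficit", "surplus", "none"):
        frames[regime] = cpl.area_fraction(win.cls, regime, valid_mask)
    areas = pd.DataFrame(frames)
    area_csv = out / f"area_fractions_{label}.csv"
    areas.to_csv(area_csv, index=False, float_format=FLOAT_FMT)

    rows = []
    for regime in ("deficit", "surplus"):
        tr = trend_test(areas[regime].values, alpha=cfg.alpha, mode="both")
        rows.append(
            {
                "regime": regime,
                "slope_per_window": tr.slope,
                "p_linear": tr.p_linear,
                "mk_s": tr.s,
                "mk_z": tr.z,
                "p_mk": tr.p_mk,
                "direction": tr.direction,
            }
        )
    trend_csv = out / f"area_trends_{label}.csv"
    pd.DataFrame(rows).to_csv(trend_csv, index=False, float_format=FLOAT_FMT)

    map_nc = _write_map(
        {"rho": full.rho, "p": full.p, "n": full.n.astype(float), "regime": full.cls.astype(float)},
        anomaly,
        out / f"coupling_{label}.nc",
    )
    rho_nc = _write_map(
        {"rho": win.rho, "p": win.p, "regime": win.cls.astype(float)},
        anomaly,
        out / f"coupling_windows_{label}.nc",
    )
    return {
        "full": full,
        "windows": win,
        "files": [p.name for p in (area_csv, trend_csv, map_nc, rho_nc)],
    }


def response_time_stage(
    anomaly: xr.DataArray,
    spei: dict,
    cfg: RunConfig,
    out: Path,
) -> dict:
    timescales = [k for k in cfg.timescales if k in spei]
    prof = rt.timescale_profile(
        anomaly, spei, season=cfg.season, timescales=timescales, min_n=cfg.min_pairs
    )
    rtm = rt.response_time_map(prof, alpha=cfg.alpha)
    starts, mins, maxs = rt.windowed_response_times(
        anomaly, spei, window_years=cfg.window_years, season=cfg.season,
        alpha=cfg.alpha, timescales=timescales, min_n=cfg.min_pairs,
    )
    sl_min, p_min = rt.response_time_trend(mins)
    sl_max, p_max = rt.response_time_trend(maxs)
    nc = _write_map(
        {
            "min_deficit_response": rtm.min_deficit.astype(float),
            "max_surplus_period": rtm.max_surplus.astype(float),
            "min_deficit_trend_slope": sl_min,
            "min_deficit_trend_p": p_min,
            "max_surplus_trend_slope": sl_max,
            "max_surplus_trend_p": p_max,
        },
        anomaly,
        out / "response_time.nc",
    )
    defined = rtm.min_deficit != rt.UNDEFINED
    n_def = int(defined.sum())
    rows = []
    for name, sl, p in (("min_deficit", sl_min, p_min), ("max_surplus", sl_max, p_max)):
        sig = np.isfinite(p) & (p < cfg.alpha)
        tested = int(np.isfinite(p).sum())
        rows.append(
            {
                "metric": name,
                "cells_tested": tested,
                "frac_significant_decreasing": float((sig & (sl < 0)).sum() / tested) if tested else np.nan,
                "frac_significant_increasing": float((sig & (sl > 0)).sum() / tested) if tested else np.nan,
            }
        )
    csv = out / "response_time_summary.csv"
    pd.DataFrame(rows).to_csv(csv, index=False, float_format=FLOAT_FMT)
    return {
        "profile": prof,
        "map": rtm,
        "n_deficit_defined": n_def,
        "files": [nc.name, csv.name],
    }


def drought_trend_stage(
    vegetation: xr.DataArray,
    spei03: xr.DataArray,
    scpdsi: xr.DataArray | None,
    cfg: RunConfig,
    out: Path,
) -> dict:
    veg_det = dd.detrend_cube(vegetation, method=cfg.detrend_method, alpha=cfg.alpha)
    anom_det = idx.monthly_zscore(veg_det)
    results = {}
    frames = []
    flags_spei = spei03.values < cfg.drought_threshold_spei
    index_flags = {"spei03": np.isfinite(spei03.values) & flags_spei}
    if scpdsi is not None:
        index_flags["scpdsi"] = np.isfinite(scpdsi.values) & (
            scpdsi.values < cfg.drought_threshold_scpdsi
        )
    for label, flags in index_flags.items():
        years, annual, tr = dd.drought_anomaly_trend(anom_det, flags, season=cfg.season, alpha=cfg.alpha)
        results[label] = (years, annual, tr)
        frames.append(
            pd.DataFrame(
                {
                    "year": years,
                    "index": label,
                    "mean_drought_anomaly": annual,
                }
            )
        )
    csv = out / "drought_anomaly_series.csv"
    pd.concat(frames, ignore_index=True).to_csv(csv, index=False, float_format=FLOAT_FMT)
    rows = []
    for label, (_, _, tr) in results.items():
        rows.append(
            {
                "index": label,
                "slope_per_year": tr.slope if tr else np.nan,
                "p_linear": tr.p_linear if tr else np.nan,
                "p_mk": tr.p_mk if tr else np.nan,
                "direction": tr.direction if tr else "undefined",
            }
        )
    csv2 = out / "drought_anomaly_trends.csv"
    pd.DataFrame(rows).to_csv(csv2, index=False, float_format=FLOAT_FMT)
    return {"results": results, "files": [csv.name, csv2.name]}


def attribution_stage(
    windows: cpl.WindowSeries,
    precip: xr.DataArray,
    temp: xr.DataArray,
    rad: xr.DataArray,
    co2: np.ndarray,
    class_map: np.ndarray,
    cfg: RunConfig,
    out: Path,
    label: str,
) -> dict:
    X = attr_mod.window_driver_means(
        precip, temp, rad, co2, windows.start_years, windows.window_years, season=cfg.season
    )
    amap = attr_mod.attribute_cells(windows.rho, X, alpha=cfg.alpha)
    summary = attr_mod.dominant_area_summary(amap, class_map)
    nc = _write_map(
        {
            "model_p": amap.model_p,
            "partial": amap.partial,
            "dominant": amap.dominant.astype(float),
            "lmg": amap.lmg,
            "r2": amap.r2,
        },
        precip,
        out / f"attribution_{label}.nc",
    )
    rows = []
    for regime, fracs in summary.items():
        for driver, frac in fracs.items():
            rows.append({"regime": regime, "driver": driver, "fraction": frac})
    csv = out / f"attribution_summary_{label}.csv"
    pd.DataFrame(rows).to_csv(csv, index=False, float_format=FLOAT_FMT)
    return {"map": amap, "summary": summary, "files": [nc.name, csv.name]}


# --------------------------------------------------------------------------
# full run
# --------------------------------------------------------------------------


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages end-to-end; returns the manifest dict."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(yaml.safe_dump(_config_dict(cfg), sort_keys=True))

    manifest: dict = {"seed": cfg.seed, "stages": {}, "files": {"config": "config.yaml"}}

    synth_cfg = syn.SyntheticConfig(seed=cfg.seed, **cfg.synth)
    ds = syn.generate_dataset(synth_cfg, timescales=cfg.timescales)
    vio.write_truth(ds.truth, out / "truth.json")
    for name, cube in (
        ("vegetation", ds.vegetation),
        ("precip", ds.precip),
        ("pet", ds.pet),
        ("temp", ds.temp),
        ("rad", ds.rad),
        ("scpdsi", ds.scpdsi_like),
    ):
        vio.write_cube(cube, out / f"{name}.nc", variable=name)
    co2_df = pd.DataFrame({"time": [str(t.date()) for t in ds.precip["time"].to_index()], "co2": ds.co2})
    co2_df.to_csv(out / "co2.csv", index=False, float_format=FLOAT_FMT)
    manifest["stages"]["synth"] = {
        "grid": [synth_cfg.ny, synth_cfg.nx],
        "months": synth_cfg.n_months,
        "valid_cells": int(ds.valid.sum()),
    }

    if not cfg.stage_enabled("indices"):
        vio.write_manifest(manifest, out / "manifest.json")
        return manifest

    anomaly = idx.monthly_zscore(ds.vegetation)
    vio.write_cube(anomaly, out / "anomaly.nc", variable="anomaly")
    manifest["stages"]["indices"] = {
        "n_timescales": len(list(cfg.timescales)),
        "timescales": [int(k) for k in cfg.timescales],
    }

    spei03 = ds.spei[3]
    results: dict = {"dataset": ds, "anomaly": anomaly}

    if cfg.stage_enabled("coupling"):
        for label, index_cube in (("spei03", spei03), ("scpdsi", ds.scpdsi_like)):
            st = coupling_stage(anomaly, index_cube, cfg, label, out, ds.valid)
            results[f"coupling_{label}"] = st
            manifest["stages"][f"coupling_{label}"] = {
                "n_windows": int(st["windows"].start_years.size),
                "files": st["files"],
            }

    if cfg.stage_enabled("response_time"):
        st = response_time_stage(anomaly, ds.spei, cfg, out)
        results["response_time"] = st
        manifest["stages"]["response_time"] = {
            "n_deficit_defined": st["n_deficit_defined"],
            "files": st["files"],
        }

    if cfg.stage_enabled("drought_trend"):
        st = drought_trend_stage(ds.vegetation, spei03, ds.scpdsi_like, cfg, out)
        results["drought_trend"] = st
        manifest["stages"]["drought_trend"] = {"files": st["files"]}

    if cfg.stage_enabled("attribution") and cfg.stage_enabled("coupling"):
        st = attribution_stage(
            results["coupling_spei03"]["windows"],
            ds.precip,
            ds.temp,
            ds.rad,
            ds.co2,
            results["coupling_spei03"]["full"].cls,
            cfg,
            out,
            "spei03",
        )
        results["attribution"] = st
        manifest["stages"]["attribution"] = {"files": st["files"]}

    vio.write_manifest(manifest, out / "manifest.json")
    manifest["_results"] = results  # in-memory only; not serialized
    return manifest


def _config_dict(cfg: RunConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["season"] = list(cfg.season)
    if d.get("calibration"):
        d["calibration"] = list(d["calibration"])
    return d
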