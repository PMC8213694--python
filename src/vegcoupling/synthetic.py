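"""Synthetic gridded inputs with planted, recorded ground truth.

Every downstream stage of the pipeline — anomaly standardization, SPEI
construction, coupling classification, moving-window trend detection,
response times, drought-conditioned trends, attribution — gets a
parameter-recovery test against data generated here. The generator emulates
the statistical structure of the real inputs (monthly seasonality,
gamma-like precipitation, standardized cumulative water-balance indices,
vegetation anomalies linearly coupled to one index timescale with a linear
drift of coupling strength, driver covariates with planted dominance) without
attempting physical realism.

Default study conditions: 1982-2015 monthly calendar (408 months, hence 30
five-year moving windows), vegetation anomaly noise sd 0.3, coupling
timescales k in 1..24, growing-season coupling with configurable sign per
cell. Identical config + seed reproduces every cube bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from .grid import make_cube, monthly_index
from . import indices

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "SyntheticDataset",
    "make_domain",
    "simulate_climate",
    "simulate_vegetation",
    "make_independent_index_family",
    "generate_dataset",
    "simulate_attribution_windows",
]

REGIME_CODES = {"none": 0, "deficit": 1, "surplus": 2}
REGIME_NAMES = {v: k for k, v in REGIME_CODES.items()}
DRIVER_NAMES = ("precipitation", "radiation", "temperature", "co2")


class ConfigurationError(ValueError):
    pass


@dataclass
class SyntheticConfig:
    """Study-condition parameters for one synthetic dataset.

    Per-cell plantings (``regime``, ``coupling_k``, ``b_start``, ``b_end``,
    ``dominant_driver``) accept a scalar applied everywhere or a full
    (ny, nx) array. With ``regime="mixed"``, cells are assigned deficit /
    surplus / none at the given fractions, uniformly at random.
    """

    ny: int = 20
    nx: int = 20
    start_year: int = 1982
    end_year: int = 2015
    seed: int = 0

    # vegetation coupling
    noise_sd: float = 0.3  # sd of the anomaly noise around the coupled signal
    regime: object = "mixed"  # "deficit"|"surplus"|"none"|"mixed"| (ny,nx) codes
    deficit_frac: float = 0.45
    surplus_frac: float = 0.35
    coupling_k: object = 3  # planted SPEI timescale, scalar or (ny, nx)
    b_start: object = 0.5  # coupling magnitude at series start, in [0, 1]
    b_end: object = 0.8  # ... at series end (linear drift between them)
    coupling_fluct: float = 0.15  # shared-latent fluctuation of b(t), attribution target
    drought_impact_end: float = 0.0  # planted end-of-record anomaly shift in drought months

    # vegetation climatology (raw = clim_j + anomaly_scale * anomaly)
    clim_base: float = 0.5
    clim_amplitude: float = 0.25
    anomaly_scale: float = 0.1

    # domain
    aridity_mode: str = "gradient"  # or "random"
    aridity_range: tuple = (0.05, 1.2)
    mask_fraction: float = 0.05

    # climate
    precip_mean: float = 60.0  # mm/month annual-mean level
    precip_season_amp: float = 0.5  # relative seasonal amplitude
    precip_shape: float = 2.0  # gamma shape
    pet_mean: float = 70.0
    pet_season_amp: float = 0.6
    pet_noise: float = 0.05  # lognormal sd of PET multiplicative noise
    temp_mean: float = 10.0
    temp_season_amp: float = 10.0
    temp_trend: float = 0.0  # degC per month
    temp_noise: float = 1.0
    rad_mean: float = 180.0
    rad_season_amp: float = 60.0
    rad_trend: float = 0.0  # W m-2 per month
    rad_noise: float = 8.0
    co2_start: float = 341.0
    co2_trend: float = 0.145  # ppm per month
    co2_accel: float = 5e-5  # ppm per month^2

    # planted driver dominance (shared annual latent injected into one driver)
    dominant_driver: object = "precipitation"  # name or (ny, nx) codes
    dominance_strength: float = 0.75

    def __post_init__(self):
        if self.ny < 1 or self.nx < 1:
            raise ConfigurationError(f"grid shape must be >= 1x1, got {self.ny}x{self.nx}")
        if self.end_year < self.start_year + 9:
            raise ConfigurationError(
                "need at least a 10-year span for moving windows "
                f"({self.start_year}-{self.end_year})"
            )
        for name in ("b_start", "b_end"):
            v = np.asarray(getattr(self, name), dtype=float)
            if np.any(np.abs(v) > 1):
                raise ConfigurationError(f"{name} magnitudes must lie in [-1, 1]")
            if v.ndim == 2 and v.shape != (self.ny, self.nx):
                raise ConfigurationError(f"{name} field does not match grid shape")
        for name in ("regime", "coupling_k", "dominant_driver"):
            v = getattr(self, name)
            if isinstance(v, np.ndarray) and v.shape != (self.ny, self.nx):
                raise ConfigurationError(f"{name} field does not match grid shape")
        if not 0.0 <= self.mask_fraction < 1.0:
            raise ConfigurationError("mask_fraction must be in [0, 1)")
        if not 0.0 <= self.deficit_frac + self.surplus_frac <= 1.0:
            raise ConfigurationError("regime fractions must sum to at most 1")

    @property
    def n_years(self) -> int:
        return self.end_year - self.start_year + 1

    @property
    def n_months(self) -> int:
        return 12 * self.n_years

    def times(self) -> pd.DatetimeIndex:
        return monthly_index(self.start_year, self.end_year)


@dataclass
class SyntheticTruth:
    """Planted ground truth, serializable alongside the generated cubes."""

    regime: np.ndarray  # (ny, nx) uint8, REGIME_CODES
    coupling_k: np.ndarray  # (ny, nx) int
    drift_sign: np.ndarray  # (ny, nx) int: sign of |b_end| - |b_start|
    dominant_driver: np.ndarray  # (ny, nx) uint8, index into DRIVER_NAMES
    valid: np.ndarray  # (ny, nx) bool
    seed: int

    def to_json(self) -> str:
        payload = {
            "regime": self.regime.astype(int).tolist(),
            "coupling_k": self.coupling_k.astype(int).tolist(),
            "drift_sign": self.drift_sign.astype(int).tolist(),
            "dominant_driver": self.dominant_driver.astype(int).tolist(),
            "valid": self.valid.astype(int).tolist(),
            "seed": int(self.seed),
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        d = json.loads(text)
        return cls(
            regime=np.asarray(d["regime"], dtype=np.uint8),
            coupling_k=np.asarray(d["coupling_k"], dtype=int),
            drift_sign=np.asarray(d["drift_sign"], dtype=int),
            dominant_driver=np.asarray(d["dominant_driver"], dtype=np.uint8),
            valid=np.asarray(d["valid"], dtype=bool),
            seed=int(d["seed"]),
        )


@dataclass
class SyntheticDataset:
    """Everything one pipeline run consumes, plus the planted truth."""

    config: SyntheticConfig
    truth: SyntheticTruth
    aridity: xr.DataArray  # (lat, lon)
    valid: np.ndarray  # (ny, nx) bool
    precip: xr.DataArray
    pet: xr.DataArray
    temp: xr.DataArray
    rad: xr.DataArray
    co2: np.ndarray  # (nt,)
    spei: dict = field(default_factory=dict)  # k -> cube
    scpdsi_like: xr.DataArray | None = None
    vegetation: xr.DataArray | None = None


def _rngs(cfg: SyntheticConfig, n: int):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(cfg.seed).spawn(n)]


# --------------------------------------------------------------------------
# domain
# --------------------------------------------------------------------------


def make_domain(cfg: SyntheticConfig) -> tuple[xr.DataArray, np.ndarray]:
    """Aridity-index field and validity mask.

    ``aridity_mode="gradient"`` sweeps the configured range west-to-east so a
    wide-enough range covers all four aridity classes; ``"random"`` draws
    uniformly from the range. ``mask_fraction`` of cells are marked invalid
    (unvegetated / ocean analogue).
    """
    rng = _rngs(cfg, 7)[0]
    lo, hi = cfg.aridity_range
    if lo < 0:
        raise ConfigurationError("aridity range must be non-negative")
    if cfg.aridity_mode == "gradient":
        row = np.linspace(lo, hi, cfg.nx)
        ai = np.tile(row, (cfg.ny, 1))
    elif cfg.aridity_mode == "random":
        ai = rng.uniform(lo, hi, size=(cfg.ny, cfg.nx))
    else:
        raise ConfigurationError(f"unknown aridity_mode {cfg.aridity_mode!r}")
    valid = np.ones((cfg.ny, cfg.nx), dtype=bool)
    n_mask = int(round(cfg.mask_fraction * cfg.ny * cfg.nx))
    if n_mask:
        flat = rng.choice(cfg.ny * cfg.nx, size=n_mask, replace=False)
        valid.flat[flat] = False
    da = xr.DataArray(ai, dims=("lat", "lon"), name="aridity_index")
    return da, valid


# --------------------------------------------------------------------------
# truth assignment
# --------------------------------------------------------------------------


def _as_field(value, shape, mapping=None, dtype=float):
    if isinstance(value, np.ndarray):
        return value.astype(dtype)
    if mapping is not None and isinstance(value, str):
        return np.full(shape, mapping[value], dtype=dtype)
    return np.full(shape, value, dtype=dtype)


def plant_truth(cfg: SyntheticConfig, valid: np.ndarray) -> SyntheticTruth:
    """Resolve the config's plantings into explicit per-cell truth fields."""
    rng = _rngs(cfg, 7)[1]
    shape = (cfg.ny, cfg.nx)
    if isinstance(cfg.regime, str) and cfg.regime == "mixed":
        u = rng.uniform(size=shape)
        regime = np.zeros(shape, dtype=np.uint8)
        regime[u < cfg.deficit_frac] = REGIME_CODES["deficit"]
        regime[(u >= cfg.deficit_frac) & (u < cfg.deficit_frac + cfg.surplus_frac)] = REGIME_CODES[
            "surplus"
        ]
    else:
        regime = _as_field(cfg.regime, shape, REGIME_CODES, dtype=np.uint8)
    ks = _as_field(cfg.coupling_k, shape, dtype=int)
    if np.any((ks < 1) | (ks > 24)):
        raise ConfigurationError("coupling timescales must be in 1..24")
    b0 = np.abs(_as_field(cfg.b_start, shape))
    b1 = np.abs(_as_field(cfg.b_end, shape))
    drift = np.sign(b1 - b0).astype(int)
    dom_map = {name: i for i, name in enumerate(DRIVER_NAMES)}
    dom = _as_field(cfg.dominant_driver, shape, dom_map, dtype=np.uint8)
    return SyntheticTruth(
        regime=regime, coupling_k=ks, drift_sign=drift, dominant_driver=dom, valid=valid, seed=cfg.seed
    )


# --------------------------------------------------------------------------
# climate
# --------------------------------------------------------------------------


def _season_cycle(n_months: int, amp: float, phase: float = 0.0) -> np.ndarray:
    m = np.arange(n_months)
    return amp * np.sin(2 * np.pi * ((m % 12) - phase) / 12.0)


def _annual_latent(cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-cell annual latent series repeated to months: the shared component
    linking the coupling drift fluctuation and the dominant driver."""
    a = rng.standard_normal((cfg.n_years, cfg.ny, cfg.nx))
    return np.repeat(a, 12, axis=0)


def simulate_climate(
    cfg: SyntheticConfig, domain: tuple[xr.DataArray, np.ndarray], truth: SyntheticTruth | None = None
) -> tuple[xr.DataArray, xr.DataArray, xr.DataArray, xr.DataArray, np.ndarray, np.ndarray]:
    """Monthly precipitation, PET, temperature, radiation cubes and CO2 series.

    Precipitation is gamma-distributed around a sinusoidal seasonal mean
    (non-negative by construction); PET is a positive seasonal cycle with
    multiplicative noise; temperature and radiation are seasonal cycles with
    configurable linear trends plus Gaussian noise; CO2 is a strictly
    increasing quadratic. When ``truth`` is given, the planted dominant
    driver of each cell additionally carries the shared annual latent
    component (scaled by ``dominance_strength``) that the attribution stage
    is meant to recover. Returns ``(precip, pet, temp, rad, co2, latent)``.
    """
    ai, valid = domain
    rng_p, rng_pet, rng_t, rng_r, rng_l = _rngs(cfg, 7)[2:7]
    nt, ny, nx = cfg.n_months, cfg.ny, cfg.nx
    t = np.arange(nt, dtype=float)
    times = cfg.times()

    # wetter cells where the aridity index is higher
    wet = (ai.values / np.nanmean(ai.values))[None, :, :]
    p_mean = cfg.precip_mean * wet * (1.0 + _season_cycle(nt, cfg.precip_season_amp))[:, None, None]
    p_mean = np.maximum(p_mean, 1e-3)
    precip = rng_p.gamma(cfg.precip_shape, p_mean / cfg.precip_shape, size=(nt, ny, nx))

    pet_base = cfg.pet_mean * (1.0 + _season_cycle(nt, cfg.pet_season_amp, phase=1.0))
    pet = pet_base[:, None, None] * np.exp(
        cfg.pet_noise * rng_pet.standard_normal((nt, ny, nx)) - 0.5 * cfg.pet_noise**2
    )

    latent = _annual_latent(cfg, rng_l)
    temp = (
        cfg.temp_mean
        + _season_cycle(nt, cfg.temp_season_amp)[:, None, None]
        + cfg.temp_trend * t[:, None, None]
        + cfg.temp_noise * rng_t.standard_normal((nt, ny, nx))
    )
    rad = (
        cfg.rad_mean
        + _season_cycle(nt, cfg.rad_season_amp, phase=0.5)[:, None, None]
        + cfg.rad_trend * t[:, None, None]
        + cfg.rad_noise * rng_r.standard_normal((nt, ny, nx))
    )
    co2 = cfg.co2_start + cfg.co2_trend * t + cfg.co2_accel * t**2

    if truth is not None and cfg.dominance_strength != 0.0:
        scales = {  # latent amplitude in each driver's own units
            "precipitation": 0.2 * cfg.precip_mean,
            "temperature": cfg.temp_noise,
            "radiation": cfg.rad_noise,
        }
        arrays = {"precipitation": precip, "temperature": temp, "radiation": rad}
        for name, arr in arrays.items():
            cells = truth.dominant_driver == DRIVER_NAMES.index(name)
            if cells.any():
                bump = cfg.dominance_strength * scales[name] * latent
                arr[:, cells] = arr[:, cells] + bump[:, cells]
        precip = np.maximum(precip, 0.0)

    inv = ~valid
    cubes = []
    for name, arr in (("precip", precip), ("pet", pet), ("temp", temp), ("rad", rad)):
        arr = arr.copy()
        arr[:, inv] = np.nan
        cubes.append(make_cube(arr, times, name=name))
    return (*cubes, co2, latent)


# --------------------------------------------------------------------------
# vegetation
# --------------------------------------------------------------------------


def simulate_vegetation(
    cfg: SyntheticConfig,
    spei_by_k: dict[int, xr.DataArray],
    truth: SyntheticTruth,
    latent: np.ndarray | None = None,
) -> xr.DataArray:
    """Raw vegetation cube with the planted coupling folded onto a seasonal
    climatology.

    Per coupled cell, the anomaly is ``sign * b(t) * SPEI_k + noise_sd * eps``
    with b(t) drifting linearly from |b_start| to |b_end| (plus the shared
    latent fluctuation when ``latent`` is given); regime-"none" cells are pure
    unit noise. Raw values are ``clim_j + anomaly_scale * anomaly``.
    """
    missing = sorted(set(np.unique(truth.coupling_k)) - set(spei_by_k))
    if missing:
        raise ConfigurationError(f"planted timescales {missing} missing from supplied SPEI cubes")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]).generate_state(1)[0])
    nt, ny, nx = cfg.n_months, cfg.ny, cfg.nx
    t = np.arange(nt, dtype=float)
    ramp = t / max(nt - 1, 1)
    b0 = np.abs(_as_field(cfg.b_start, (ny, nx)))
    b1 = np.abs(_as_field(cfg.b_end, (ny, nx)))
    b = b0[None] + (b1 - b0)[None] * ramp[:, None, None]
    if latent is not None and cfg.coupling_fluct != 0.0:
        b = b + cfg.coupling_fluct * latent
    b = np.clip(b, 0.0, 1.0)
    sign = np.zeros((ny, nx))
    sign[truth.regime == REGIME_CODES["deficit"]] = 1.0
    sign[truth.regime == REGIME_CODES["surplus"]] = -1.0

    anom = np.empty((nt, ny, nx))
    noise = rng.standard_normal((nt, ny, nx))
    coupled = truth.regime != REGIME_CODES["none"]
    anom[:, ~coupled] = cfg.noise_sd * noise[:, ~coupled]
    driver = np.zeros((nt, ny, nx))
    for k in np.unique(truth.coupling_k[coupled]):
        cells = coupled & (truth.coupling_k == k)
        driver[:, cells] = spei_by_k[int(k)].values[:, cells]
    anom[:, coupled] = (
        sign[None, coupled] * b[:, coupled] * driver[:, coupled]
        + cfg.noise_sd * noise[:, coupled]
    )
    if cfg.drought_impact_end != 0.0:
        # planted intensification of drought impact: anomalies in drought
        # months (SPEI03 below the conventional threshold) drift linearly
        # from 0 to drought_impact_end over the record
        if 3 not in spei_by_k:
            raise ConfigurationError("drought_impact_end requires the 3-month index cube")
        flags = spei_by_k[3].values < indices.DROUGHT_SPEI03
        anom = anom + cfg.drought_impact_end * ramp[:, None, None] * flags

    j = np.arange(nt) % 12
    clim = cfg.clim_base + cfg.clim_amplitude * np.sin(2 * np.pi * j / 12.0)
    raw = clim[:, None, None] + cfg.anomaly_scale * anom
    raw[:, ~truth.valid] = np.nan
    cube = make_cube(raw, cfg.times(), name="vegetation")
    return cube


def make_independent_index_family(
    cfg: SyntheticConfig, timescales=range(1, 25), seed_offset: int = 11
) -> dict[int, xr.DataArray]:
    """Mutually independent standardized index cubes, one per timescale.

    Genuine cumulative-sum SPEI channels are nested (a k-month sum contains
    every shorter sum), so a cell coupled at timescale k* also correlates with
    every k < k* and the *minimum significant timescale* is uninformative
    about k*. Timescale-recovery experiments therefore use this synthetic
    family of independent standardized channels, where the planted k* is
    identifiable. The end-to-end pipeline keeps true cumulative SPEI.
    """
    times = cfg.times()
    out = {}
    for k in timescales:
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, seed_offset, k]).generate_state(1)[0])
        vals = rng.standard_normal((cfg.n_months, cfg.ny, cfg.nx))
        da = make_cube(vals, times, name=f"index{k:02d}")
        da.attrs["timescale_months"] = int(k)
        out[int(k)] = da
    return out


# --------------------------------------------------------------------------
# full dataset
# --------------------------------------------------------------------------


def generate_dataset(cfg: SyntheticConfig, timescales=range(1, 25)) -> SyntheticDataset:
    """Run the whole generator: domain -> climate -> SPEI -> vegetation.

    The scPDSI-role cube is a fixed-timescale standardized index emulated as
    the 9-month SPEI rescaled to a Palmer-like dynamic range (x2); the
    pipeline treats any such cube as opaque input.
    """
    domain = make_domain(cfg)
    ai, valid = domain
    truth = plant_truth(cfg, valid)
    precip, pet, temp, rad, co2, latent = simulate_climate(cfg, domain, truth)
    ks = sorted(set(timescales) | set(np.unique(truth.coupling_k).tolist()) | {3, 9})
    spei, _params = indices.spei_pipeline(precip, pet, timescales=ks)
    veg = simulate_vegetation(cfg, spei, truth, latent=latent)
    scpdsi_like = (spei[9] * 2.0).rename("scpdsi_like")
    return SyntheticDataset(
        config=cfg,
        truth=truth,
        aridity=ai,
        valid=valid,
        precip=precip,
        pet=pet,
        temp=temp,
        rad=rad,
        co2=co2,
        spei=spei,
        scpdsi_like=scpdsi_like,
        vegetation=veg,
    )


# --------------------------------------------------------------------------
# window-level attribution experiment
# --------------------------------------------------------------------------


def simulate_attribution_windows(
    n_cells: int,
    n_windows: int = 30,
    snr: float = 2.0,
    dominant: int = 0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Window-level response/driver draws with one planted dominant driver.

    The coupling series of each cell is ``y = z + e`` with a shared latent
    ``z ~ N(0,1)`` per window; the planted driver is ``z + e'/snr`` where
    ``snr`` is the latent-to-noise sd ratio; the other three drivers are
    independent noise. Returns ``(y, X)`` with shapes (n_windows, n_cells)
    and (n_windows, 4, n_cells); column ``dominant`` holds the planted
    driver.
    """
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_windows, n_cells))
    y = z + rng.standard_normal((n_windows, n_cells)) / snr
    X = rng.standard_normal((n_windows, 4, n_cells))
    X[:, dominant, :] = z + X[:, dominant, :] / snr
    return y, X
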