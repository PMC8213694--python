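"""Water-availability indices and anomaly standardization.

This module builds the inputs every coupling analysis consumes:

* **Monthly z-score anomalies** of a vegetation indicator,
  ``A_{j,i} = (x_{j,i} - mean_j) / sd_j`` per calendar month ``j`` over a
  reference period, which removes the seasonal cycle.
* **SPEI** at timescales k = 1..24 months: the k-month running sum of the
  climatic water balance D = P - PET is fitted, per grid cell and calendar
  month, with a 3-parameter log-logistic distribution via unbiased
  probability-weighted moments; the fitted CDF is mapped through the inverse
  standard normal, producing a standardized index (negative = drier than the
  local climatology at that time of year).
* **Aridity classes** from the aridity index AI = mean annual P / mean annual
  PET, and **drought flags** at the conventional thresholds SPEI03 < -1.28
  and scPDSI < -1 (strict inequalities).

The log-logistic CDF used throughout is
``F(x) = [1 + (alpha / (x - gamma))**beta]**-1`` on ``(gamma, inf)`` with
scale alpha > 0 and shape beta > 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import xarray as xr
from scipy import stats
from scipy.special import gamma as gamma_fn

from .grid import TIME, align_check, month_numbers, year_numbers

__all__ = [
    "Climatology",
    "SpeiParams",
    "monthly_zscore",
    "water_balance",
    "aggregate_k",
    "fit_loglogistic",
    "fit_loglogistic_slots",
    "loglogistic_cdf",
    "compute_spei",
    "spei_pipeline",
    "classify_aridity",
    "flag_drought",
    "ARIDITY_CLASSES",
    "DROUGHT_SPEI03",
    "DROUGHT_SCPDSI",
]

#: Drought thresholds (strict "<"): 3-month SPEI and scPDSI.
DROUGHT_SPEI03 = -1.28
DROUGHT_SCPDSI = -1.0

ARIDITY_CLASSES = ("arid", "semi-arid", "sub-humid", "humid")
_ARIDITY_EDGES = (0.2, 0.5, 0.65)  # half-open upward; upper class wins at an edge

MIN_FIT_SAMPLES = 20  # below this, fitted slots are flagged low-confidence


class DegenerateFitError(ValueError):
    """All samples equal (or otherwise unfittable) in a distribution fit."""


# --------------------------------------------------------------------------
# anomalies
# --------------------------------------------------------------------------


@dataclass
class Climatology:
    """Per-cell, per-calendar-month mean and sd of an indicator.

    ``ddof=1`` (sample sd) is the recorded convention. Slots with sd = 0 make
    downstream anomalies invalid rather than infinite.
    """

    mean: np.ndarray  # (12, ny, nx)
    std: np.ndarray  # (12, ny, nx)
    ref_period: tuple[int, int]
    ddof: int = 1

    @classmethod
    def from_cube(
        cls, cube: xr.DataArray, ref_period: tuple[int, int] | None = None, ddof: int = 1
    ) -> "Climatology":
        years = year_numbers(cube)
        if ref_period is None:
            ref_period = (int(years.min()), int(years.max()))
        sel = (years >= ref_period[0]) & (years <= ref_period[1])
        months = month_numbers(cube)[sel]
        vals = cube.values[sel]
        _, ny, nx = vals.shape
        mean = np.full((12, ny, nx), np.nan)
        std = np.full((12, ny, nx), np.nan)
        for j in range(1, 13):
            rows = vals[months == j]
            if rows.shape[0] < 2:
                raise ValueError(f"calendar month {j} occurs fewer than twice in reference period")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN (masked) cells
                mean[j - 1] = np.nanmean(rows, axis=0)
                std[j - 1] = np.nanstd(rows, axis=0, ddof=ddof)
        return cls(mean=mean, std=std, ref_period=ref_period, ddof=ddof)


def monthly_zscore(cube: xr.DataArray, climatology: Climatology | None = None) -> xr.DataArray:
    """Standardize a cube per calendar month: ``(x - mean_j) / sd_j``.

    Cells/months whose climatological sd is zero come out NaN (invalid), not
    infinite. When no climatology is given, one is computed from the cube's
    own full record.
    """
    if climatology is None:
        climatology = Climatology.from_cube(cube)
    if climatology.mean.shape[1:] != (cube.sizes["lat"], cube.sizes["lon"]):
        raise ValueError("climatology grid does not match cube grid")
    months = month_numbers(cube)
    mean = climatology.mean[months - 1]
    std = climatology.std[months - 1].copy()
    std[std == 0] = np.nan
    out = (cube - mean) / std
    out.name = "anomaly"
    out.attrs["ref_period"] = list(climatology.ref_period)
    return out


# --------------------------------------------------------------------------
# water balance and aggregation
# --------------------------------------------------------------------------


def water_balance(precip: xr.DataArray, pet: xr.DataArray) -> xr.DataArray:
    """Climatic water balance D = P - PET; invalid wherever either input is."""
    align_check(precip, pet)
    d = precip - pet
    d.name = "water_balance"
    return d


def aggregate_k(d: xr.DataArray, k: int) -> xr.DataArray:
    """k-month backward-looking running sum; the first k-1 months are invalid."""
    if not 1 <= int(k) <= 24:
        raise ValueError(f"timescale k must be in 1..24, got {k}")
    k = int(k)
    if k == 1:
        out = d.copy()
    else:
        out = d.rolling({TIME: k}, min_periods=k).sum()
    out.name = f"water_balance_{k:02d}"
    out.attrs["timescale_months"] = k
    return out


# --------------------------------------------------------------------------
# log-logistic fit (unbiased probability-weighted moments)
# --------------------------------------------------------------------------


def _pwm_ascending(x_sorted: np.ndarray, n) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unbiased PWMs a_s = E[X (1-F)^s], s = 0,1,2, from ascending order stats.

    ``x_sorted`` has samples ascending along axis 0 with NaN padding at the
    end; ``n`` is the per-slot finite count (broadcastable to the slot shape).
    """
    m = x_sorted.shape[0]
    i = np.arange(1, m + 1, dtype=float).reshape((m,) + (1,) * (x_sorted.ndim - 1))
    n = np.asarray(n, dtype=float)
    w0 = np.where(i <= n, 1.0, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        w1 = np.where(i <= n, (n - i) / (n - 1), 0.0)
        w2 = np.where(i <= n, (n - i) * (n - i - 1) / ((n - 1) * (n - 2)), 0.0)
    xz = np.where(np.isfinite(x_sorted), x_sorted, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        a0 = (xz * w0).sum(axis=0) / n
        a1 = (xz * w1).sum(axis=0) / n
        a2 = (xz * w2).sum(axis=0) / n
    return a0, a1, a2


def _loglogistic_from_pwm(a0, a1, a2):
    """Map PWMs to (alpha, beta, gamma); invalid slots come out NaN.

    beta equals the reciprocal sample L-skewness, so right-skewed samples give
    the usual lower-bounded branch (alpha, beta > 0, support (gamma, inf)) and
    left-skewed samples the mirrored upper-bounded branch (alpha, beta < 0,
    support (-inf, gamma)); |beta| <= 1 leaves the moment equations without a
    valid solution.
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = (2.0 * a1 - a0) / (6.0 * a1 - a0 - 6.0 * a2)
        ok = np.isfinite(beta) & (np.abs(beta) > 1.0)
        beta = np.where(ok, beta, np.nan)
        g = gamma_fn(1.0 + 1.0 / beta) * gamma_fn(1.0 - 1.0 / beta)
        alpha = (a0 - 2.0 * a1) * beta / g
        gamma = a0 - alpha * g
        alpha = np.where(alpha * np.sign(beta) > 0, alpha, np.nan)
    return alpha, beta, gamma


def fit_loglogistic(samples) -> tuple[float, float, float]:
    """Fit a 3-parameter log-logistic to one sample by unbiased PWM.

    Returns ``(alpha, beta, gamma)`` with alpha, beta > 0. Raises
    :class:`DegenerateFitError` when the sample is constant or the moment
    equations have no valid solution (e.g. beta <= 1).
    """
    x = np.asarray(samples, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 4:
        raise DegenerateFitError(f"need at least 4 finite samples, got {x.size}")
    if np.ptp(x) == 0.0:
        raise DegenerateFitError("all samples equal; log-logistic fit is degenerate")
    xs = np.sort(x)
    a0, a1, a2 = _pwm_ascending(xs[:, None], np.array([x.size]))
    alpha, beta, gamma = _loglogistic_from_pwm(a0, a1, a2)
    if not (np.isfinite(alpha[0]) and np.isfinite(beta[0]) and np.isfinite(gamma[0])):
        raise DegenerateFitError("probability-weighted moments admit no valid log-logistic")
    return float(alpha[0]), float(beta[0]), float(gamma[0])


@dataclass
class SpeiParams:
    """Per-cell, per-calendar-month log-logistic parameters for one timescale."""

    alpha: np.ndarray  # (12, ny, nx)
    beta: np.ndarray
    gamma: np.ndarray
    k: int
    calibration: tuple[int, int]
    low_confidence: np.ndarray = field(default=None)  # (12, ny, nx) bool


def fit_loglogistic_slots(
    dk: xr.DataArray, calibration: tuple[int, int] | None = None
) -> SpeiParams:
    """Fit log-logistic parameters for every (cell, calendar month) slot of a Dk cube.

    Vectorized across cells: samples are the calibration-period values of one
    calendar month in one cell. Slots with fewer than 4 finite samples, or
    whose moment equations are invalid, get NaN parameters; slots with fewer
    than ``MIN_FIT_SAMPLES`` are flagged low-confidence.
    """
    years = year_numbers(dk)
    if calibration is None:
        calibration = (int(years.min()), int(years.max()))
    sel = (years >= calibration[0]) & (years <= calibration[1])
    months = month_numbers(dk)[sel]
    vals = dk.values[sel]
    _, ny, nx = vals.shape
    shape = (12, ny, nx)
    alpha = np.full(shape, np.nan)
    beta = np.full(shape, np.nan)
    gam = np.full(shape, np.nan)
    lowc = np.zeros(shape, dtype=bool)
    for j in range(1, 13):
        rows = vals[months == j]  # (nyears, ny, nx)
        n = np.isfinite(rows).sum(axis=0)
        xs = np.sort(rows, axis=0)  # NaN sort last
        a0, a1, a2 = _pwm_ascending(xs, n)
        a, b, g = _loglogistic_from_pwm(a0, a1, a2)
        enough = n >= 4
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN (masked) slots
            constant = np.nanmax(rows, axis=0) == np.nanmin(rows, axis=0)
        bad = ~enough | constant
        a = np.where(bad, np.nan, a)
        alpha[j - 1], beta[j - 1], gam[j - 1] = a, np.where(bad, np.nan, b), np.where(bad, np.nan, g)
        lowc[j - 1] = enough & (n < MIN_FIT_SAMPLES)
    k = int(dk.attrs.get("timescale_months", 1))
    return SpeiParams(alpha=alpha, beta=beta, gamma=gam, k=k, calibration=calibration, low_confidence=lowc)


def loglogistic_cdf(x, alpha, beta, gamma):
    """Log-logistic CDF for either branch.

    With alpha, beta > 0 the support is (gamma, inf) and F is 0 at and below
    gamma; with alpha, beta < 0 (the mirrored, upper-bounded branch fitted to
    left-skewed samples) the support is (-inf, gamma) and F is 1 at and above
    gamma.
    """
    x = np.asarray(x, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = x - gamma
        inside = t * np.sign(alpha) > 0  # x on the supported side of gamma
        ratio = np.where(inside, alpha / t, np.nan)  # > 0 inside
        f = 1.0 / (1.0 + ratio**beta)
    boundary = np.where(np.asarray(beta) > 0, 0.0, 1.0)
    defined = np.isfinite(x) & np.isfinite(np.asarray(alpha, float))
    return np.where(inside, f, np.where(defined, boundary, np.nan))


def compute_spei(dk: xr.DataArray, params: SpeiParams, clip: float = 3.5) -> xr.DataArray:
    """Standardize a Dk cube: ``SPEI = Phi^-1(F(Dk))`` per cell and calendar month.

    Values are clipped to ``+-clip`` (probabilities at the support boundary
    would otherwise map to infinity). Slots without fitted parameters are
    invalid in the output.
    """
    months = month_numbers(dk)
    a = params.alpha[months - 1]
    b = params.beta[months - 1]
    g = params.gamma[months - 1]
    f = loglogistic_cdf(dk.values, a, b, g)
    eps = 1e-12
    with np.errstate(invalid="ignore"):
        z = stats.norm.ppf(np.clip(f, eps, 1.0 - eps))
        z = np.clip(z, -clip, clip)
    out = dk.copy(data=z)
    out.name = f"spei{params.k:02d}"
    out.attrs = {"timescale_months": params.k, "calibration": list(params.calibration)}
    return out


def spei_pipeline(
    precip: xr.DataArray,
    pet: xr.DataArray,
    timescales=range(1, 25),
    calibration: tuple[int, int] | None = None,
    clip: float = 3.5,
) -> tuple[dict[int, xr.DataArray], dict[int, SpeiParams]]:
    """Water balance -> k-month aggregation -> log-logistic fit -> SPEI, for each k."""
    d = water_balance(precip, pet)
    speis: dict[int, xr.DataArray] = {}
    params: dict[int, SpeiParams] = {}
    for k in timescales:
        dk = aggregate_k(d, k)
        p = fit_loglogistic_slots(dk, calibration=calibration)
        speis[k] = compute_spei(dk, p, clip=clip)
        params[k] = p
    return speis, params


# --------------------------------------------------------------------------
# aridity and drought
# --------------------------------------------------------------------------


def classify_aridity(ai):
    """Aridity class from AI = mean annual P / mean annual PET.

    Half-open intervals, upper class winning at a shared boundary:
    arid [0, 0.2), semi-arid [0.2, 0.5), sub-humid [0.5, 0.65),
    humid [0.65, inf). Drylands are every class but humid.
    """
    ai_arr = np.asarray(ai, dtype=float)
    if np.any(ai_arr[np.isfinite(ai_arr)] < 0):
        raise ValueError("aridity index must be >= 0")
    idx = np.digitize(ai_arr, _ARIDITY_EDGES, right=False)
    if np.ndim(ai) == 0:
        return ARIDITY_CLASSES[int(idx)]
    out = np.array(ARIDITY_CLASSES, dtype=object)[idx]
    out[~np.isfinite(ai_arr)] = None
    return out


def flag_drought(spei03, scpdsi=None):
    """Drought flags at the conventional thresholds (strict inequalities).

    Returns ``(drought_by_spei, drought_by_scpdsi)``; the second is None when
    no scPDSI-style index is supplied. Non-finite inputs are never flagged.
    """
    s = np.asarray(spei03, dtype=float)
    by_spei = np.isfinite(s) & (s < DROUGHT_SPEI03)
    by_pdsi = None
    if scpdsi is not None:
        p = np.asarray(scpdsi, dtype=float)
        by_pdsi = np.isfinite(p) & (p < DROUGHT_SCPDSI)
    if np.ndim(spei03) == 0:
        by_spei = bool(by_spei)
        by_pdsi = bool(by_pdsi) if by_pdsi is not None else None
    return by_spei, by_pdsi
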