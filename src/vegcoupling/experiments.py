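"""Calibration and parameter-recovery experiments.

Each function runs one self-contained study on synthetic data with planted
ground truth and returns the measured quantities: exhaustive oracles for the
rank statistics, null calibration of classification and trend tests,
recovery of planted coupling drifts, response-time declines, drought-impact
trends, and driver dominance, plus an end-to-end determinism check. The
experiment conditions (sample sizes, noise levels, drifts) are the package's
study conditions; seeds are explicit so every number is reproducible.
"""

from __future__ import annotations

import itertools
import time
from pathlib import Path

import numpy as np

from . import indices as idx
from .coupling import full_period_coupling, moving_windows, spearman, spearman_maps
from .detrend_drought import detrend_cube, drought_anomaly_trend
from .grid import make_cube
from .response_time import (
    min_deficit_response,
    response_time_trend,
    timescale_profile,
    windowed_response_times,
)
from .synthetic import (
    SyntheticConfig,
    generate_dataset,
    make_domain,
    make_independent_index_family,
    plant_truth,
    simulate_attribution_windows,
    simulate_climate,
    simulate_vegetation,
)
from .trendkit import linear_trend, mann_kendall

__all__ = [
    "window_count",
    "spei_channel_count",
    "spei_standardization",
    "rank_statistic_oracles",
    "null_calibration",
    "coupling_trend_recovery",
    "response_time_recovery",
    "drought_impact_trend",
    "attribution_checks",
    "end_to_end_determinism",
]


# --------------------------------------------------------------------------
# configuration arithmetic
# --------------------------------------------------------------------------


def window_count(seed: int = 0) -> dict:
    """Number of 5-year moving windows on a 1982-2015 monthly record."""
    cfg = SyntheticConfig(ny=2, nx=2, seed=seed, mask_fraction=0.0)
    ds = generate_dataset(cfg, timescales=[3])
    anom = idx.monthly_zscore(ds.vegetation)
    win = moving_windows(anom, ds.spei[3], window_years=5)
    return {"n_windows": int(win.start_years.size), "n_years": cfg.n_years}


def spei_channel_count(seed: int = 0) -> dict:
    """Number of SPEI channels the multi-timescale stage emits by default."""
    cfg = SyntheticConfig(ny=3, nx=3, seed=seed, mask_fraction=0.0)
    dom = make_domain(cfg)
    truth = plant_truth(cfg, dom[1])
    precip, pet, *_ = simulate_climate(cfg, dom, truth)
    spei, _ = idx.spei_pipeline(precip, pet)
    return {"n_channels": len(spei), "timescales": sorted(spei)}


# --------------------------------------------------------------------------
# SPEI standardization
# --------------------------------------------------------------------------


def spei_standardization(seed: int = 0, n_months: int = 500) -> dict:
    """Per-calendar-month calibration mean/sd of SPEI over a 20x20 grid.

    A cell passes when every calendar month has |mean| < 0.05 and
    |sd - 1| < 0.1 over the calibration period.
    """
    cfg = SyntheticConfig(ny=20, nx=20, start_year=1974, end_year=2015, seed=seed, mask_fraction=0.0)
    dom = make_domain(cfg)
    truth = plant_truth(cfg, dom[1])
    precip, pet, *_ = simulate_climate(cfg, dom, truth)
    d = idx.water_balance(precip, pet).isel(time=slice(0, n_months))
    d.attrs["timescale_months"] = 1
    params = idx.fit_loglogistic_slots(d)
    spei = idx.compute_spei(d, params)
    months = spei["time"].dt.month.values
    vals = spei.values
    ok = np.ones((cfg.ny, cfg.nx), dtype=bool)
    for j in range(1, 13):
        rows = vals[months == j]
        m = rows.mean(axis=0)
        s = rows.std(axis=0, ddof=0)
        ok &= (np.abs(m) < 0.05) & (np.abs(s - 1.0) < 0.1)
    return {"frac_cells_standardized": float(ok.mean()), "n_cells": int(ok.size)}


# --------------------------------------------------------------------------
# exhaustive rank-statistic oracles
# --------------------------------------------------------------------------


def _spearman_oracle(x, y) -> float:
    """Rank-Pearson by hand on distinct values."""
    rx = np.argsort(np.argsort(x)).astype(float)
    ry = np.argsort(np.argsort(y)).astype(float)
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry)))


def _mk_s_oracle(series) -> int:
    s = 0
    n = len(series)
    for i in range(n):
        for j in range(i + 1, n):
            s += int(np.sign(series[j] - series[i]))
    return s


def _mk_var_oracle(series) -> float:
    """Null Var(S) by enumerating every permutation of the multiset."""
    vals = list(series)
    seen = set()
    ss = []
    for perm in itertools.permutations(vals):
        if perm in seen:
            continue
        seen.add(perm)
        ss.append(_mk_s_oracle(perm))
    ss = np.asarray(ss, dtype=float)
    return float((ss**2).mean() - ss.mean() ** 2)


def rank_statistic_oracles() -> dict:
    """Exact agreement checks: Spearman vs brute-force rank-Pearson over all
    120 orderings of n=5, and Mann-Kendall S / tie-corrected Var(S) vs
    enumeration for every length-6 series over {1,2,3}."""
    x = np.arange(5, dtype=float)
    max_rho_err = 0.0
    for perm in itertools.permutations(range(5)):
        y = np.asarray(perm, dtype=float)
        rho, _, _ = spearman(x, y, min_n=3)
        max_rho_err = max(max_rho_err, abs(rho - _spearman_oracle(x, y)))

    max_s_err = 0
    max_var_err = 0.0
    var_cache: dict[tuple, float] = {}
    for series in itertools.product((1, 2, 3), repeat=6):
        s, var_s, _, _ = mann_kendall(series)
        max_s_err = max(max_s_err, abs(s - _mk_s_oracle(series)))
        key = tuple(sorted(series))
        if key not in var_cache:
            var_cache[key] = _mk_var_oracle(key)
        max_var_err = max(max_var_err, abs(var_s - var_cache[key]))
    return {
        "spearman_max_abs_err": max_rho_err,
        "mk_s_max_abs_err": int(max_s_err),
        "mk_var_max_abs_err": max_var_err,
    }


# --------------------------------------------------------------------------
# null calibration
# --------------------------------------------------------------------------


def null_calibration(seed: int = 0, n_trend_reps: int = 10_000, trend_n: int = 30) -> dict:
    """False-positive rates under pure noise.

    Classification: 1,000 uncoupled cells, fraction classified deficit or
    surplus at alpha = 0.05. Trend tests: rejection rates of the linear and
    Mann-Kendall tests on iid normal series of length ``trend_n``.
    """
    cfg = SyntheticConfig(
        ny=25, nx=40, seed=seed, regime="none", mask_fraction=0.0, coupling_fluct=0.0
    )
    ds = generate_dataset(cfg, timescales=[3, 9])
    anom = idx.monthly_zscore(ds.vegetation)
    full = full_period_coupling(anom, ds.spei[3])
    class_rate = float(np.mean((full.cls == 1) | (full.cls == 2)))

    rng = np.random.default_rng(seed + 1)
    data = rng.standard_normal((n_trend_reps, trend_n))
    mk_rate = float(np.mean([mann_kendall(row)[3] < 0.05 for row in data]))
    lin_rate = float(np.mean([linear_trend(row)[2] < 0.05 for row in data]))
    return {
        "classification_rate": class_rate,
        "mk_rejection_rate": mk_rate,
        "linear_rejection_rate": lin_rate,
        "n_cells": int(full.cls.size),
        "n_trend_reps": n_trend_reps,
    }


# --------------------------------------------------------------------------
# coupling-trend recovery
# --------------------------------------------------------------------------


def coupling_trend_recovery(seed: int = 0) -> dict:
    """Detection of a planted coupling drift vs a stationary null.

    Drift: 200 deficit cells with coupling magnitude drifting 0.2 -> 0.8
    (noise sd 0.3); detection = significant positive Mann-Kendall trend of
    the 30-window rho series. Stationary null: 200 cells x 30 *independent*
    windows of 35 pairs at constant coupling — independent windows isolate
    the test's false-positive rate from the serial correlation that
    overlapping windows share by construction (see docs/methods.md).
    """
    cfg = SyntheticConfig(
        ny=10, nx=20, seed=seed, regime="deficit", b_start=0.2, b_end=0.8,
        noise_sd=0.3, mask_fraction=0.0, coupling_fluct=0.0,
    )
    ds = generate_dataset(cfg, timescales=[3, 9])
    anom = idx.monthly_zscore(ds.vegetation)
    win = moving_windows(anom, ds.spei[3], window_years=5)
    hits = 0
    n_cells = cfg.ny * cfg.nx
    for iy in range(cfg.ny):
        for ix in range(cfg.nx):
            s, _, _, p = mann_kendall(win.rho[:, iy, ix])
            if np.isfinite(p) and p < 0.05 and s > 0:
                hits += 1

    rng = np.random.default_rng(seed + 17)
    x = rng.standard_normal((35, 30, 200))
    y = 0.5 * x + 0.3 * rng.standard_normal((35, 30, 200))
    rho, _, _ = spearman_maps(x, y)
    false_pos = 0
    for c in range(200):
        _, _, _, p = mann_kendall(rho[:, c])
        if np.isfinite(p) and p < 0.05:
            false_pos += 1
    return {
        "drift_detection_rate": hits / n_cells,
        "stationary_trend_rate": false_pos / 200,
        "n_windows": int(win.start_years.size),
    }


# --------------------------------------------------------------------------
# response-time recovery
# --------------------------------------------------------------------------

RECOVERY_TIMESCALES = (1, 3, 6, 12)


def response_time_recovery(seed: int = 0) -> dict:
    """Exact recovery of planted response timescales and of their decline.

    Exact recovery: 2,000 deficit cells, 500 per planted k* in {1,3,6,12},
    coupling 0.8 with noise sd 0.3, full-record (238-pair) profiles over the
    planted timescale set of independent index channels; recovery = the
    minimum-significant-timescale statistic equals k*. Decline: 200 cells
    whose active timescale falls 12 -> 3 across the record; detection =
    significant negative linear trend of the per-window minimum.
    """
    ny, nx = 20, 100
    ks = np.repeat(np.asarray(RECOVERY_TIMESCALES), nx // 4)[None, :].repeat(ny, axis=0)
    cfg = SyntheticConfig(
        ny=ny, nx=nx, seed=seed, regime="deficit", coupling_k=ks,
        b_start=0.8, b_end=0.8, noise_sd=0.3, mask_fraction=0.0, coupling_fluct=0.0,
    )
    dom = make_domain(cfg)
    truth = plant_truth(cfg, dom[1])
    family = make_independent_index_family(cfg, timescales=RECOVERY_TIMESCALES)
    veg = simulate_vegetation(cfg, family, truth)
    anom = idx.monthly_zscore(veg)
    prof = timescale_profile(anom, family, timescales=RECOVERY_TIMESCALES)
    recovered = min_deficit_response(prof)
    exact = float(np.mean(recovered == ks))

    cfg2 = SyntheticConfig(
        ny=10, nx=20, seed=seed + 23, regime="deficit", coupling_k=12,
        b_start=0.8, b_end=0.8, noise_sd=0.3, mask_fraction=0.0, coupling_fluct=0.0,
    )
    family2 = make_independent_index_family(cfg2)
    nt = cfg2.n_months
    tt = np.arange(nt)
    k_sched = np.rint(12 + (3 - 12) * tt / (nt - 1)).astype(int)
    rng = np.random.default_rng(seed + 29)
    driver = np.empty((nt, cfg2.ny, cfg2.nx))
    for m in range(nt):
        driver[m] = family2[int(k_sched[m])].values[m]
    anom2 = make_cube(
        0.8 * driver + 0.3 * rng.standard_normal((nt, cfg2.ny, cfg2.nx)), cfg2.times()
    )
    _, mins, _ = windowed_response_times(anom2, family2, window_years=5)
    slope, p = response_time_trend(mins)
    decline = float(np.mean(np.isfinite(p) & (p < 0.05) & (slope < 0)))
    return {
        "exact_recovery_rate": exact,
        "decline_detection_rate": decline,
        "n_recovery_cells": int(ks.size),
    }


# --------------------------------------------------------------------------
# drought-impact trend
# --------------------------------------------------------------------------


def _drought_replicate(seed: int, impact: float):
    cfg = SyntheticConfig(
        ny=8, nx=8, seed=seed, regime="none", noise_sd=0.3, mask_fraction=0.0,
        coupling_fluct=0.0, drought_impact_end=impact,
    )
    ds = generate_dataset(cfg, timescales=[3, 9])
    veg_det = detrend_cube(ds.vegetation, method="linear_blocks")
    anom = idx.monthly_zscore(veg_det)
    flags = np.isfinite(ds.spei[3].values) & (ds.spei[3].values < idx.DROUGHT_SPEI03)
    _, _, tr = drought_anomaly_trend(anom, flags)
    return tr


def drought_impact_trend(seed: int = 0, n_reps: int = 100) -> dict:
    """Detection of a planted drift of drought-month anomalies (0 -> -0.5
    over 34 years, noise sd 0.3) in the annual drought-conditioned series,
    against a stationary null."""
    detected = 0
    for r in range(n_reps):
        tr = _drought_replicate(seed * 100_000 + r, impact=-0.5)
        if tr is not None and tr.p_linear < 0.05 and tr.slope < 0:
            detected += 1
    false_pos = 0
    for r in range(n_reps):
        tr = _drought_replicate(seed * 100_000 + 50_000 + r, impact=0.0)
        if tr is not None and tr.p_linear < 0.05:
            false_pos += 1
    return {
        "impact_detection_rate": detected / n_reps,
        "stationary_rejection_rate": false_pos / n_reps,
        "n_reps": n_reps,
    }


# --------------------------------------------------------------------------
# attribution
# --------------------------------------------------------------------------


def attribution_checks(seed: int = 0) -> dict:
    """Identity checks and planted-dominance recovery for the attribution
    stage: LMG shares sum to R² and match squared simple correlations under
    orthogonal predictors; the two partial-Spearman algorithms agree; and the
    planted dominant driver is recovered among screened cells at SNR 2."""
    from .attribution import attribute_cells, lmg_importance, partial_spearman

    rng = np.random.default_rng(seed)
    lmg_sum_err = 0.0
    dual_err = 0.0
    for _ in range(50):
        y = rng.standard_normal(30)
        X = rng.standard_normal((30, 4))
        shares, r2 = lmg_importance(y, X)
        lmg_sum_err = max(lmg_sum_err, abs(shares.sum() - r2))
        for j in range(4):
            a = partial_spearman(y, X, j, method="residual")
            b = partial_spearman(y, X, j, method="precision")
            dual_err = max(dual_err, abs(a - b))

    # orthogonal predictors: LMG share = squared simple correlation
    Z = rng.standard_normal((64, 4))
    Q, _ = np.linalg.qr(Z - Z.mean(axis=0))
    Xo = Q[:, :4]
    y = Xo @ np.array([0.9, 0.5, -0.3, 0.1]) + 0.2 * rng.standard_normal(64)
    shares, r2 = lmg_importance(y, Xo)
    simple = np.array([np.corrcoef(y, Xo[:, j])[0, 1] ** 2 for j in range(4)])
    ortho_err = float(np.max(np.abs(shares - simple)))

    yw, Xw = simulate_attribution_windows(n_cells=200, n_windows=30, snr=2.0, dominant=0, seed=seed + 3)
    amap = attribute_cells(yw.reshape(30, 10, 20), Xw.reshape(30, 4, 10, 20), alpha=0.05)
    sig = np.isfinite(amap.model_p) & (amap.model_p < 0.05)
    n_sig = int(sig.sum())
    recovery = float(((amap.dominant == 1) & sig).sum() / n_sig) if n_sig else np.nan
    return {
        "lmg_sum_max_err": lmg_sum_err,
        "partial_dual_max_err": dual_err,
        "lmg_orthogonal_max_err": ortho_err,
        "dominance_recovery_rate": recovery,
        "n_significant_cells": n_sig,
    }


# --------------------------------------------------------------------------
# end-to-end determinism
# --------------------------------------------------------------------------


def end_to_end_determinism(seed: int = 0, base_dir=None) -> dict:
    """Run the full default 20x20 pipeline twice with one seed and compare
    every output file byte for byte."""
    import tempfile

    from .pipeline import RunConfig, run_pipeline

    ctx = tempfile.TemporaryDirectory() if base_dir is None else None
    base = Path(ctx.name) if ctx else Path(base_dir)
    out = base / "run"
    t0 = time.time()
    cfg = RunConfig(out_dir=str(out), seed=seed, synth={"ny": 20, "nx": 20})
    run_pipeline(cfg)
    first = {p.name: p.read_bytes() for p in out.iterdir()}
    run_pipeline(cfg)
    elapsed = time.time() - t0
    second = {p.name: p.read_bytes() for p in out.iterdir()}
    identical = first.keys() == second.keys() and all(
        first[name] == second[name] for name in first
    )
    n_files = len(second)
    if ctx:
        ctx.cleanup()
    return {
        "byte_identical": bool(identical),
        "n_output_files": n_files,
        "elapsed_seconds_both_runs": elapsed,
    }
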