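"""Scalar-series trend inference: OLS linear trend test and Mann-Kendall test.

Every stage of the pipeline that asks "is this series going up or down" comes
through here: per-window coupling series, class-area fractions, response-time
series, drought-conditioned anomaly series. Two tests are provided because the
area/coupling trend analyses require agreement of a parametric (least-squares
t-test on the slope) and a non-parametric (Mann-Kendall) test.

The Mann-Kendall statistic is ``S = sum_{i<j} sign(x_j - x_i)``; its null
variance uses the standard tie correction

    Var(S) = [n(n-1)(2n+5) - sum_t t(t-1)(2t+5)] / 18

summed over tie groups of extent ``t``, and the normal approximation applies a
continuity correction (S shifted one unit toward zero). Overlapping moving
windows induce serial correlation that neither test corrects for; the tests
are applied to such series as-is (a documented limitation, see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["TrendResult", "linear_trend", "mann_kendall", "trend_test"]


@dataclass(frozen=True)
class TrendResult:
    """Joint result of the linear and Mann-Kendall trend tests on one series."""

    slope: float
    intercept: float
    p_linear: float
    s: int
    var_s: float
    z: float
    p_mk: float
    direction: str  # "increasing" | "decreasing" | "none"
    n: int

    def significant(self, alpha: float = 0.05, mode: str = "both") -> bool:
        """Whether the series shows a trend at level ``alpha``.

        mode="both" requires both tests below alpha (the convention used for
        the area-trend series); "linear"/"mk" use a single test; "either"
        accepts either.
        """
        lin = np.isfinite(self.p_linear) and self.p_linear < alpha
        mk = np.isfinite(self.p_mk) and self.p_mk < alpha
        if mode == "both":
            return lin and mk
        if mode == "linear":
            return lin
        if mode == "mk":
            return mk
        if mode == "either":
            return lin or mk
        raise ValueError(f"unknown significance mode {mode!r}")


def linear_trend(series, x=None) -> tuple[float, float, float]:
    """OLS slope, intercept and two-sided t-test p-value against index.

    ``x`` defaults to 0..n-1. A constant series has slope 0 and is reported
    as no-trend (p = 1) rather than undefined.
    """
    y = np.asarray(series, dtype=float)
    if x is None:
        x = np.arange(y.size, dtype=float)
    else:
        x = np.asarray(x, dtype=float)
    ok = np.isfinite(y) & np.isfinite(x)
    y, x = y[ok], x[ok]
    if y.size < 3:
        return np.nan, np.nan, np.nan
    if np.ptp(y) == 0.0:
        return 0.0, float(y[0]), 1.0
    res = stats.linregress(x, y)
    p = res.pvalue
    if not np.isfinite(p):  # perfect fit: slope exact, evidence overwhelming
        p = 0.0
    return float(res.slope), float(res.intercept), float(p)


def mann_kendall(series) -> tuple[int, float, float, float]:
    """Mann-Kendall S, tie-corrected Var(S), continuity-corrected Z, two-sided p."""
    y = np.asarray(series, dtype=float)
    y = y[np.isfinite(y)]
    n = y.size
    if n < 4:
        return 0, np.nan, np.nan, np.nan
    s = int(np.sign(y[None, :] - y[:, None])[np.triu_indices(n, k=1)].sum())
    _, counts = np.unique(y, return_counts=True)
    ties = counts[counts > 1]
    var_s = (n * (n - 1) * (2 * n + 5) - np.sum(ties * (ties - 1) * (2 * ties + 5))) / 18.0
    if var_s <= 0:  # all values tied
        return s, 0.0, 0.0, 1.0
    if s > 0:
        z = (s - 1) / np.sqrt(var_s)
    elif s < 0:
        z = (s + 1) / np.sqrt(var_s)
    else:
        z = 0.0
    p = 2.0 * stats.norm.sf(abs(z))
    return s, float(var_s), float(z), float(p)


def trend_test(series, x=None, alpha: float = 0.05, mode: str = "both") -> TrendResult:
    """Run both tests on one series and classify its direction.

    Direction is "increasing"/"decreasing" only when the tests required by
    ``mode`` are significant at ``alpha`` and agree in sign with the slope.
    """
    slope, intercept, p_lin = linear_trend(series, x=x)
    s, var_s, z, p_mk = mann_kendall(series)
    y = np.asarray(series, dtype=float)
    n = int(np.isfinite(y).sum())
    res = TrendResult(slope, intercept, p_lin, s, var_s, z, p_mk, "none", n)
    if res.significant(alpha, mode):
        # sign carried by slope for the linear test, S for MK; prefer agreement
        sgn = np.sign(slope) if mode == "linear" else np.sign(s) if mode == "mk" else None
        if sgn is None:
            sgn = np.sign(slope) if np.sign(slope) == np.sign(s) else 0.0
        if sgn > 0:
            res = TrendResult(slope, intercept, p_lin, s, var_s, z, p_mk, "increasing", n)
        elif sgn < 0:
            res = TrendResult(slope, intercept, p_lin, s, var_s, z, p_mk, "decreasing", n)
    return res
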