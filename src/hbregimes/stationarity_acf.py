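"""Analysis-window selection from the heart-rate autocorrelation function.

The statistical unit of the regime analysis is a sliding window whose width
is the lag beyond which heart-rate samples are no longer significantly
autocorrelated.  The series is detrended (low-order polynomial), checked
for stationarity with the augmented Dickey-Fuller test, and its sample ACF
compared against Bartlett large-lag confidence bands; the first downward
crossing of the upper band (located by linear interpolation between integer
lags) is the cutoff lag t_cut.  Aggregating t_cut over a set of calibration
sessions gives the window width used everywhere downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm
from statsmodels.tsa.stattools import acf as _sm_acf
from statsmodels.tsa.stattools import adfuller

from .io_sessions import UniformSeries

__all__ = [
    "ACFResult",
    "ADFReport",
    "WindowWidthEstimate",
    "detrend_poly",
    "adf_test",
    "acf_bartlett",
    "cutoff_lag",
    "estimate_window_width",
]


@dataclass
class ACFResult:
    """Sample ACF with Bartlett confidence bands (centered on zero)."""

    dt: float
    lags: np.ndarray  # seconds
    acf: np.ndarray
    ci_upper: np.ndarray
    ci_lower: np.ndarray
    alpha: float = 0.05
    t_cut: float | None = None


@dataclass
class ADFReport:
    statistic: float
    pvalue: float
    stationary: bool


@dataclass
class WindowWidthEstimate:
    per_session_tcut: list
    mean: float
    sd: float
    chosen_width: float
    overridden: bool = False


def detrend_poly(series: UniformSeries, order: int = 1) -> UniformSeries:
    """Subtract a least-squares polynomial of the given order."""
    n = len(series)
    if n <= order + 1:
        raise ValueError(f"series of length {n} too short for order-{order} detrend")
    t = np.arange(n, dtype=float)
    coeffs = np.polyfit(t, series.values, order)
    resid = series.values - np.polyval(coeffs, t)
    return UniformSeries(series.t0, series.dt, resid)


def adf_test(series: UniformSeries) -> ADFReport:
    """Augmented Dickey-Fuller unit-root test; stationary when p < 0.05.

    A constant series has no unit root by construction; it is reported as
    stationary with a degenerate (-inf) statistic rather than an error.
    """
    x = series.values
    if len(x) < 20:
        raise ValueError("need at least 20 samples for the ADF test")
    if np.ptp(x) == 0:
        return ADFReport(statistic=-np.inf, pvalue=0.0, stationary=True)
    stat, pvalue = adfuller(x, autolag="AIC")[:2]
    return ADFReport(statistic=float(stat), pvalue=float(pvalue),
                     stationary=bool(pvalue < 0.05))


def acf_bartlett(
    series: UniformSeries, max_lag_s: float, alpha: float = 0.05
) -> ACFResult:
    """Sample ACF with Bartlett large-lag confidence bands.

    The band at lag k is ``+-z_{1-alpha/2} * sqrt((1 + 2*sum_{j<k} r_j^2)/n)``,
    the standard error of a sample autocorrelation when the true ACF vanishes
    from lag k on.  Bands are centered about zero.
    """
    n = len(series)
    max_lag = int(round(max_lag_s / series.dt))
    if max_lag < 1 or max_lag >= n:
        raise ValueError(f"max_lag_s={max_lag_s} out of range for series of {n} samples")
    r = _sm_acf(series.values, nlags=max_lag, fft=True)
    se = np.zeros(max_lag + 1)
    se[1] = 1.0 / np.sqrt(n)
    if max_lag >= 2:
        cum = np.cumsum(r[1:] ** 2)
        se[2:] = np.sqrt((1.0 + 2.0 * cum[:-1]) / n)
    z = norm.ppf(1 - alpha / 2)
    upper = z * se
    lags = series.dt * np.arange(max_lag + 1)
    return ACFResult(dt=series.dt, lags=lags, acf=r, ci_upper=upper,
                     ci_lower=-upper, alpha=alpha)


def cutoff_lag(acf_result: ACFResult) -> float:
    """First downward crossing of the ACF through the upper Bartlett band.

    The crossing is located by intersecting the straight line through the
    two bracketing ACF points with the line through the corresponding band
    values.  If the ACF is already below the band at lag 1, the cutoff is
    one grid step.  Never crossing within the computed lags is an error:
    recompute with a larger ``max_lag_s``.
    """
    r, u, dt = acf_result.acf, acf_result.ci_upper, acf_result.dt
    for k in range(1, len(r)):
        if r[k] <= u[k]:
            if k == 1:
                t_cut = dt
            else:
                a0, a1 = r[k - 1], r[k]
                u0, u1 = u[k - 1], u[k]
                frac = (u0 - a0) / ((a1 - a0) - (u1 - u0))
                t_cut = (k - 1 + frac) * dt
            acf_result.t_cut = float(t_cut)
            return float(t_cut)
    raise ValueError(
        "ACF never crosses the upper confidence band within "
        f"{acf_result.lags[-1]:.0f} s; increase max_lag_s"
    )


def _session_tcut(hr: UniformSeries, detrend_order: int, max_lag_s: float,
                  alpha: float) -> float | None:
    """t_cut of one HR series, with the deterministic detrend escalation."""
    for order in (detrend_order, detrend_order + 1):
        resid = detrend_poly(hr, order)
        if adf_test(resid).stationary:
            return cutoff_lag(acf_bartlett(resid, max_lag_s, alpha))
    warnings.warn("session failed the stationarity gate; excluded", stacklevel=2)
    return None


def estimate_window_width(
    hr_series: list,
    detrend_order: int = 1,
    max_lag_s: float = 300.0,
    alpha: float = 0.05,
    round_to_s: float = 10.0,
    reference_width_s: float = 90.0,
    override_s: float | None = None,
) -> WindowWidthEstimate:
    """Aggregate per-session cutoff lags into one analysis-window width.

    Each series is detrended (order escalated once if the ADF gate fails,
    then the session is excluded).  The chosen width is the mean t_cut
    rounded to ``round_to_s``; when the reference width of 90 s lies within
    one SD of the mean it is preferred, so the canonical window is stable
    against calibration noise.  ``override_s`` forces the width.
    """
    tcuts = []
    for hr in hr_series:
        tc = _session_tcut(hr, detrend_order, max_lag_s, alpha)
        if tc is not None:
            tcuts.append(tc)
    if not tcuts:
        raise ValueError("all sessions failed the stationarity gate")
    arr = np.asarray(tcuts)
    mean = float(arr.mean())
    sd = float(arr.std())
    if override_s is not None:
        return WindowWidthEstimate(tcuts, mean, sd, float(override_s), overridden=True)
    if abs(mean - reference_width_s) <= sd:
        chosen = float(reference_width_s)
    else:
        chosen = float(round(mean / round_to_s) * round_to_s)
    return WindowWidthEstimate(tcuts, mean, sd, chosen)
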