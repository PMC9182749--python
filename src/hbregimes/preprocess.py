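"""Session cleaning: effort-zone restriction, outlier repair, speed filtering.

The analysis domain is maximal cardiac effort: only stretches where heart
rate exceeds a fraction (default 90%) of the age-predicted maximum
(Tanaka formula, HRmax = 208 - 0.7*age) are analysed.  Optical-sensor
glitches are repaired by a global z-score rule, GPS speed is smoothed with
a zero-phase Butterworth low-pass, and altitude is rebased to the session
start so sessions run at different elevations are comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .io_sessions import UniformSeries

__all__ = [
    "CleaningConfig",
    "hr_max_tanaka",
    "restrict_to_intense_zone",
    "remove_outliers_zscore",
    "remove_outliers_zscore_raw",
    "lowpass_speed",
    "rebase_altitude",
]


@dataclass
class CleaningConfig:
    """Cleaning parameters.

    hr_zone_fraction : fraction of HRmax defining the intense zone.
    zscore_threshold : |z| above which a sample is treated as a sensor glitch.
    butter_cutoff    : Butterworth cutoff as a fraction of Nyquist (at the
                       1 Hz grid, 0.01 of Nyquist = 0.005 Hz).
    butter_order     : filter order before the forward-backward pass.
    min_segment_s    : retained intense-zone segments shorter than this are
                       dropped (shorter stretches cannot hold one window).
    max_gap_s        : observation gaps longer than this split the session.
    """

    hr_zone_fraction: float = 0.9
    zscore_threshold: float = 3.0
    butter_cutoff: float = 0.01
    butter_order: int = 2
    min_segment_s: float = 90.0
    max_gap_s: float = 30.0

    def __post_init__(self) -> None:
        if not 0 < self.hr_zone_fraction <= 1:
            raise ValueError("hr_zone_fraction must be in (0, 1]")
        if self.zscore_threshold <= 0:
            raise ValueError("zscore_threshold must be positive")
        if not 0 < self.butter_cutoff < 1:
            raise ValueError("butter_cutoff must be a normalized frequency in (0, 1)")
        if self.butter_order < 1:
            raise ValueError("butter_order must be >= 1")


def hr_max_tanaka(age: float) -> float:
    """Age-predicted maximum heart rate: 208 - 0.7*age (bpm)."""
    if not 0 < age < 130:
        raise ValueError(f"implausible age {age!r}")
    return 208.0 - 0.7 * age


def restrict_to_intense_zone(
    hr: UniformSeries,
    hrmax: float,
    fraction: float = 0.9,
    min_segment_s: float = 90.0,
):
    """Mask of maximal-effort samples and the contiguous runs they form.

    Returns ``(mask, segments)`` where ``mask[i]`` is True when
    ``hr[i] >= fraction*hrmax`` and ``segments`` is a list of index ranges
    ``(start, stop)`` (half-open) of retained runs spanning more than
    ``min_segment_s``.  An empty result is a warning, not an error: a
    session may simply never reach the zone.
    """
    if hrmax <= 0:
        raise ValueError("hrmax must be positive")
    values = hr.values
    mask = values >= fraction * hrmax
    segments = []
    n = values.size
    edges = np.flatnonzero(np.diff(mask.astype(int)))
    bounds = np.concatenate(([0], edges + 1, [n]))
    for a, b in zip(bounds[:-1], bounds[1:]):
        if mask[a] and (b - a) * hr.dt > min_segment_s:
            segments.append((int(a), int(b)))
    if not segments:
        warnings.warn("no samples in the intense zone", stacklevel=2)
    return mask, segments


def remove_outliers_zscore(series: UniformSeries, threshold: float = 3.0) -> UniformSeries:
    """Replace |z| > threshold samples by linear interpolation.

    The z-score uses the global mean and SD of the series.  Interpolated
    replacement (rather than deletion) preserves the uniform grid needed by
    the autocorrelation and recurrence analyses.  A zero-SD (constant)
    series is returned unchanged.
    """
    if len(series) < 3:
        raise ValueError("need at least 3 samples")
    x = series.values
    sd = x.std()
    if sd == 0:
        return UniformSeries(series.t0, series.dt, x.copy())
    z = np.abs(x - x.mean()) / sd
    bad = z > threshold
    if not bad.any():
        return UniformSeries(series.t0, series.dt, x.copy())
    out = x.copy()
    idx = np.arange(x.size)
    good = ~bad
    if good.sum() < 2:
        raise ValueError("too few inliers to interpolate over")
    out[bad] = np.interp(idx[bad], idx[good], x[good])
    return UniformSeries(series.t0, series.dt, out)


def remove_outliers_zscore_raw(channel, threshold: float = 3.0):
    """Z-score outlier repair on a raw (irregularly sampled) channel.

    Same rule as :func:`remove_outliers_zscore` but applied to the sensor
    samples before any gridding, so a single spiked reading is repaired in
    place and never smeared across the interpolation grid.  Replacement
    interpolates linearly over the timestamps of the surrounding inliers.
    """
    from .io_sessions import RawChannel

    x = channel.values
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    sd = x.std()
    if sd == 0:
        return channel
    bad = np.abs(x - x.mean()) / sd > threshold
    if not bad.any():
        return channel
    good = ~bad
    if good.sum() < 2:
        raise ValueError("too few inliers to interpolate over")
    out = x.copy()
    out[bad] = np.interp(channel.timestamps[bad], channel.timestamps[good], x[good])
    return RawChannel(channel.name, channel.timestamps.copy(), out)


def lowpass_speed(
    speed: UniformSeries, cutoff: float = 0.01, order: int = 2
) -> UniformSeries:
    """Zero-phase Butterworth low-pass for GPS speed.

    ``cutoff`` is a normalized digital frequency (fraction of Nyquist).
    Forward-backward filtering (filtfilt) gives zero phase so speed is not
    time-shifted against heart rate; the effective magnitude response is the
    squared Butterworth response.  DC gain is exactly 1.
    """
    b, a = signal.butter(order, cutoff)
    padlen = 3 * (max(len(a), len(b)) - 1)
    if len(speed) <= padlen:
        raise ValueError(
            f"series of length {len(speed)} shorter than filter warm-up ({padlen + 1})"
        )
    y = signal.filtfilt(b, a, speed.values)
    return UniformSeries(speed.t0, speed.dt, y)


def rebase_altitude(z: UniformSeries) -> UniformSeries:
    """Subtract the starting altitude so every session starts at z = 0."""
    if len(z) == 0:
        raise ValueError("empty altitude series")
    return UniformSeries(z.t0, z.dt, z.values - z.values[0])
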