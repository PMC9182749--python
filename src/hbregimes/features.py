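"""Energy proxy and sliding-window trend features.

External energy demand is summarized by e = v_norm + k_norm, the sum of a
potential term V = g*(z - z0) and a kinetic term K = v^2/2, each min-max
normalized to [0, 1] over the whole cleaned session so that both contribute
comparable weight (e ranges over [0, 2]).

Each sliding window (width = the ACF-derived cutoff, stepped point by
point) yields two features per channel x in {E, HR}:

    gamma0(x) = (mean(x) - x[0]) / sd(x)      -- standardized mean-vs-start
    gamma1(x) = mean(((x - mean(x)) / sd(x))^3) -- skewness
    Delta(x)  = gamma0(x) + gamma1(x)

with population SDs throughout.  Delta(E) and Delta(HR) are dimensionless,
invariant under positive affine rescaling of the channel, and their sign
pair defines the heartbeat-dynamics regime of the window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_sessions import AlignedSegment, UniformSeries

__all__ = [
    "STANDARD_GRAVITY",
    "EnergySeries",
    "compute_energy",
    "compute_energy_segments",
    "gamma0",
    "gamma1",
    "window_features",
    "FEATURE_COLUMNS",
]

STANDARD_GRAVITY = 9.80665  # m/s^2

FEATURE_COLUMNS = [
    "window_start_s",
    "width_s",
    "delta_e",
    "delta_hr",
    "gamma0_e",
    "gamma1_e",
    "gamma0_hr",
    "gamma1_hr",
]


@dataclass
class EnergySeries:
    """Dimensionless energy-demand proxy on a uniform grid."""

    t0: float
    dt: float
    v_norm: np.ndarray  # normalized potential term, [0, 1]
    k_norm: np.ndarray  # normalized kinetic term, [0, 1]
    g: float = STANDARD_GRAVITY

    @property
    def e(self) -> np.ndarray:
        return self.v_norm + self.k_norm

    def __len__(self) -> int:
        return int(self.v_norm.size)


def _minmax(x: np.ndarray, label: str) -> np.ndarray:
    lo, hi = x.min(), x.max()
    if hi == lo:
        warnings.warn(f"degenerate {label} channel (constant); term set to 0",
                      stacklevel=3)
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def compute_energy(z: UniformSeries, v: UniformSeries,
                   g: float = STANDARD_GRAVITY) -> EnergySeries:
    """Energy proxy from rebased altitude and cleaned speed.

    Normalization is over the full session (the series passed in), not per
    window: windows sample a session-level demand curve.  A constant channel
    contributes identically zero with a warning.
    """
    if len(z) != len(v) or z.t0 != v.t0 or z.dt != v.dt:
        raise ValueError("altitude and speed must share the same grid")
    pot = g * z.values
    kin = 0.5 * v.values**2
    return EnergySeries(t0=z.t0, dt=z.dt,
                        v_norm=_minmax(pot, "potential"),
                        k_norm=_minmax(kin, "kinetic"), g=g)


def compute_energy_segments(
    segments: list, g: float = STANDARD_GRAVITY
) -> list:
    """Energy proxy for several gap-split segments of one session.

    The min-max normalization constants of the potential and kinetic terms
    are shared across all segments (session-level normalization), so the
    energy proxy of a split session is identical to that of the unsplit
    one.  Returns one :class:`EnergySeries` per segment.
    """
    if not segments:
        return []
    for seg in segments:
        if seg.speed is None or seg.altitude is None:
            raise ValueError("energy needs both speed and altitude channels")
    pots = [g * seg.altitude for seg in segments]
    kins = [0.5 * seg.speed**2 for seg in segments]
    out = []
    for which, series_list in (("potential", pots), ("kinetic", kins)):
        lo = min(s.min() for s in series_list)
        hi = max(s.max() for s in series_list)
        if hi == lo:
            warnings.warn(
                f"degenerate {which} channel (constant); term set to 0",
                stacklevel=2,
            )
            out.append([np.zeros_like(s) for s in series_list])
        else:
            out.append([(s - lo) / (hi - lo) for s in series_list])
    return [
        EnergySeries(t0=seg.t0, dt=seg.dt, v_norm=vn, k_norm=kn, g=g)
        for seg, vn, kn in zip(segments, out[0], out[1])
    ]


def gamma0(segment: np.ndarray) -> float:
    """Standardized displacement of the window mean from its first value.

    Population SD; a zero-SD (constant) window returns 0.
    """
    x = np.asarray(segment, dtype=float)
    if x.size < 3:
        raise ValueError("window needs at least 3 samples")
    sd = x.std()
    if sd == 0:
        return 0.0
    return float((x.mean() - x[0]) / sd)


def gamma1(segment: np.ndarray) -> float:
    """Fisher-Pearson skewness, (1/n) * sum(((x - mean)/sd)^3).

    Population SD; a zero-SD window returns 0.
    """
    x = np.asarray(segment, dtype=float)
    if x.size < 3:
        raise ValueError("window needs at least 3 samples")
    sd = x.std()
    if sd == 0:
        return 0.0
    return float(np.mean(((x - x.mean()) / sd) ** 3))


def _sliding_gammas(x: np.ndarray, w: int):
    """Vectorized gamma0/gamma1 over all length-w windows of x."""
    win = np.lib.stride_tricks.sliding_window_view(x, w)
    mean = win.mean(axis=1)
    sd = win.std(axis=1)
    ok = sd > 0
    g0 = np.zeros(win.shape[0])
    g1 = np.zeros(win.shape[0])
    g0[ok] = (mean[ok] - win[ok, 0]) / sd[ok]
    centered = win[ok] - mean[ok, None]
    g1[ok] = np.mean((centered / sd[ok, None]) ** 3, axis=1)
    return g0, g1


def window_features(
    segments: list,
    energies: list,
    width_s: float = 90.0,
) -> pd.DataFrame:
    """Delta-E / Delta-HR features for every admissible sliding window.

    ``segments`` are the retained intense-zone :class:`AlignedSegment`
    stretches and ``energies`` the matching :class:`EnergySeries` (same
    order, same grids).  Windows are half-open ``[start, start + width)``
    stepped one grid point at a time and must lie entirely inside a single
    segment; a segment shorter than the width contributes no windows (with
    a warning).  Returns one row per window with the Delta features and
    their gamma components (``delta_x = gamma0_x + gamma1_x`` exactly).
    """
    if len(segments) != len(energies):
        raise ValueError("segments and energies must pair up")
    rows = []
    for seg, en in zip(segments, energies):
        if seg.n != len(en) or seg.t0 != en.t0 or seg.dt != en.dt:
            raise ValueError("segment and energy series on different grids")
        w = int(round(width_s / seg.dt))
        if w < 3:
            raise ValueError("window width below 3 samples")
        if seg.n < w:
            warnings.warn(
                f"segment at t0={seg.t0:.0f}s shorter than the window; skipped",
                stacklevel=2,
            )
            continue
        g0_hr, g1_hr = _sliding_gammas(seg.hr, w)
        g0_e, g1_e = _sliding_gammas(en.e, w)
        starts = seg.t0 + seg.dt * np.arange(seg.n - w + 1)
        rows.append(
            pd.DataFrame(
                {
                    "window_start_s": starts,
                    "width_s": width_s,
                    "delta_e": g0_e + g1_e,
                    "delta_hr": g0_hr + g1_hr,
                    "gamma0_e": g0_e,
                    "gamma1_e": g1_e,
                    "gamma0_hr": g0_hr,
                    "gamma1_hr": g1_hr,
                }
            )
        )
    if not rows:
        return pd.DataFrame(columns=FEATURE_COLUMNS)
    return pd.concat(rows, ignore_index=True)[FEATURE_COLUMNS]
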