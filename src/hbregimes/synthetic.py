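"""Synthetic wearable running sessions with known ground truth.

The generator emulates what a wrist-worn device records during a city run:
heart rate, speed and altitude sampled at irregular intervals (HR about
5.1 +- 2.6 s, speed 2.6 +- 1.4 s, altitude 2.0 +- 1.8 s), optical-sensor
outlier spikes, white GPS speed noise, and a heart-rate response that
switches between planted dynamic regimes.

A session is a sequence of contiguous :class:`RegimeSegment` stretches.
Within a segment, an abstract energy-demand curve and the heart-rate level
ramp linearly with slopes whose signs realize the segment's regime (sign
of Delta-E / sign of Delta-HR).  Demand is rendered into altitude and
speed ramps (split between the potential and kinetic term by a
configurable share), and heart rate adds stationary AR(1) physiological
variability whose correlation time sets the expected ACF cutoff lag
(default 85 s, so the window-width estimation path lands near the 90 s
canonical window) plus white sensor noise at the observation times.

Ground truth is recorded per admissible analysis window, so recovered
regime labels, cohort frequency trends and fatigue-driven determinism can
all be scored against what was planted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io_sessions import RawChannel, Session, UniformSeries

__all__ = [
    "RegimeSegment",
    "SyntheticPlan",
    "DEFAULT_SAMPLING",
    "make_balanced_plan",
    "make_steady_plan",
    "make_share_plan",
    "generate_session",
    "generate_cohort",
    "generate_fatigue_series",
    "window_ground_truth",
    "expected_frequencies",
]

#: (mean, sd) of the sampling interval per channel, seconds.
DEFAULT_SAMPLING = {"hr": (5.1, 2.6), "speed": (2.6, 1.4), "altitude": (2.0, 1.8)}

_CYCLE_ORDER = ("+/+", "-/+", "-/-", "+/-")  # level-neutral regime cycle

#: correlation time (s) of the AR(1) heart-rate noise
DEFAULT_AR1_TAU = 85.0


@dataclass
class RegimeSegment:
    """One planted regime stretch: linear demand and HR ramps."""

    start: float
    duration: float
    regime: str  # sign(Delta-E)/sign(Delta-HR), e.g. "-/+"
    e_slope: float  # demand units / s
    hr_slope: float  # bpm / s

    def __post_init__(self) -> None:
        if self.regime not in ("+/+", "+/-", "-/+", "-/-"):
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.duration <= 0:
            raise ValueError("segment duration must be positive")
        se, sh = self.regime.split("/")
        if self.e_slope * (1 if se == "+" else -1) < 0:
            raise ValueError(f"e_slope sign contradicts regime {self.regime}")
        if self.hr_slope * (1 if sh == "+" else -1) < 0:
            raise ValueError(f"hr_slope sign contradicts regime {self.regime}")

    @property
    def end(self) -> float:
        return self.start + self.duration


@dataclass
class SyntheticPlan:
    """Full recipe for one synthetic session."""

    segments: list
    hr_baseline: float = 160.0  # mean HR level, bpm (inside the intense zone)
    hr_noise_sd: float = 2.5  # stationary SD of the AR(1) component, bpm
    ar1_phi: float = float(np.exp(-1.0 / DEFAULT_AR1_TAU))
    hr_obs_noise_sd: float = 1.5  # white optical-sensor noise, bpm
    speed_noise_sd: float = 0.3  # white GPS speed noise, m/s
    altitude_noise_sd: float = 0.5  # barometric noise, m
    sampling: dict = field(default_factory=lambda: dict(DEFAULT_SAMPLING))
    outlier_rate: float = 0.002  # per-HR-sample spike probability
    fatigue_gain: float = 0.0
    seed: int = 0
    pot_share: float = 0.5  # demand split between potential and kinetic term
    z_scale: float = 25.0  # altitude excursion per demand unit at full share, m
    k_base: float = 2.42  # kinetic floor, (m/s)^2 / 2 units (v_min ~ 2.2 m/s)
    k_scale: float = 2.1  # kinetic excursion per demand unit at full share
    age: float = 57.0
    vo2max: float | None = None
    session_id: str = "synthetic"
    date: str = "2021-06-18"

    def __post_init__(self) -> None:
        segs = sorted(self.segments, key=lambda s: s.start)
        for prev, cur in zip(segs[:-1], segs[1:]):
            if abs(prev.end - cur.start) > 1e-9:
                raise ValueError("segments must be contiguous and non-overlapping")
        self.segments = segs
        if not 0 <= self.pot_share <= 1:
            raise ValueError("pot_share must lie in [0, 1]")

    @property
    def duration(self) -> float:
        return self.segments[-1].end if self.segments else 0.0


def make_balanced_plan(
    duration: float = 3600.0,
    segment_s: float = 300.0,
    hr_step: float = 12.0,
    demand_step: float = 0.8,
    seed: int = 0,
    **plan_kwargs,
) -> SyntheticPlan:
    """Plan cycling through all four regimes with equal segment lengths.

    The cycle +/+, -/+, -/-, +/- raises and lowers both the HR level and
    the demand level symmetrically, so levels return to baseline after
    every cycle and stay bounded for arbitrarily long sessions.
    """
    shares = {r: 0.25 for r in _CYCLE_ORDER}
    return make_share_plan(shares, duration=duration, cycle_s=4 * segment_s,
                           hr_step=hr_step, demand_step=demand_step, seed=seed,
                           **plan_kwargs)


def make_steady_plan(duration: float = 3600.0, seed: int = 0,
                     **plan_kwargs) -> SyntheticPlan:
    """Steady-state run: flat demand and HR level, physiological AR(1)
    variability plus sensor noise only.

    This is the calibration condition for the window-width estimation
    path: after detrending, the heart-rate series is dominated by the
    AR(1) component whose correlation time sets the ACF cutoff lag.
    """
    seg = RegimeSegment(0.0, duration, "+/+", 0.0, 0.0)
    return SyntheticPlan(segments=[seg], seed=seed, **plan_kwargs)


def make_share_plan(
    shares: dict,
    duration: float = 3600.0,
    cycle_s: float = 1200.0,
    hr_step: float = 12.0,
    demand_step: float = 0.8,
    seed: int = 0,
    **plan_kwargs,
) -> SyntheticPlan:
    """Plan whose regime time shares follow ``shares`` (must sum to 1).

    Each cycle allocates its duration across the four regimes in
    proportion to the shares; every segment changes the HR level by a
    fixed +-``hr_step`` and demand by +-``demand_step`` (slope = step /
    duration), so the level path is share-independent and bounded.

    Regime plans default to *well-separated* noise settings: the planted
    HR ramp across one 90 s window (hr_step * 90 / segment duration)
    exceeds three times the physiological AR(1) SD, so window labels are
    recoverable.  The baseline sits high enough that the whole level path
    stays inside the intense zone.  Pass explicit ``hr_noise_sd`` /
    ``hr_obs_noise_sd`` / ``hr_baseline`` to override.
    """
    plan_kwargs.setdefault("hr_noise_sd", 0.7)
    plan_kwargs.setdefault("hr_obs_noise_sd", 0.7)
    plan_kwargs.setdefault("hr_baseline", 166.0)
    total = sum(shares.get(r, 0.0) for r in _CYCLE_ORDER)
    if abs(total - 1.0) > 1e-9:
        raise ValueError("regime shares must sum to 1")
    if any(shares.get(r, 0.0) < 0 for r in _CYCLE_ORDER):
        raise ValueError("negative regime share")
    n_cycles = max(1, int(round(duration / cycle_s)))
    segments = []
    t = 0.0
    for _ in range(n_cycles):
        for regime in _CYCLE_ORDER:
            dur = shares.get(regime, 0.0) * cycle_s
            if dur <= 0:
                continue
            se, sh = regime.split("/")
            e_slope = (demand_step / dur) * (1 if se == "+" else -1)
            hr_slope = (hr_step / dur) * (1 if sh == "+" else -1)
            segments.append(RegimeSegment(t, dur, regime, e_slope, hr_slope))
            t += dur
    return SyntheticPlan(segments=segments, seed=seed, **plan_kwargs)


# ---------------------------------------------------------------------------
# deterministic truth curves


def _truth_curves(plan: SyntheticPlan, dt: float = 1.0):
    """Piecewise-linear HR level and demand curves on a uniform grid."""
    n = int(np.floor(plan.duration / dt)) + 1
    t = dt * np.arange(n)
    hr = np.empty(n)
    demand = np.empty(n)
    hr_level = plan.hr_baseline
    d_level = 1.0
    for seg in plan.segments:
        sel = (t >= seg.start - 1e-9) & (t <= seg.end + 1e-9)
        rel = t[sel] - seg.start
        hr[sel] = hr_level + seg.hr_slope * rel
        demand[sel] = d_level + seg.e_slope * rel
        hr_level += seg.hr_slope * seg.duration
        d_level += seg.e_slope * seg.duration
    # center HR levels on the requested baseline
    hr += plan.hr_baseline - hr.mean()
    return t, hr, demand


def _ar1(n: int, phi: float, sd: float, rng: np.random.Generator,
         burn: int = 500) -> np.ndarray:
    if sd == 0:
        return np.zeros(n)
    innov_sd = sd * np.sqrt(max(1.0 - phi**2, 0.0))
    e = rng.normal(scale=innov_sd, size=n + burn)
    x = np.empty(n + burn)
    x[0] = rng.normal(scale=sd)
    for i in range(1, n + burn):
        x[i] = phi * x[i - 1] + e[i]
    return x[burn:]


def _clipped_normal_params(target_mean: float, target_sd: float,
                           floor: float = 0.5):
    """Pre-clipping (mu, sigma) so max(floor, N(mu, sigma)) has the target
    mean and SD.  Solved from the closed-form moments of the clipped
    normal; falls back to the naive parameters when the solver fails."""

    def moments(p):
        mu, sig = p
        a = (floor - mu) / sig
        cdf, pdf = stats.norm.cdf(a), stats.norm.pdf(a)
        m1 = floor * cdf + mu * (1 - cdf) + sig * pdf
        m2 = floor**2 * cdf + (mu**2 + sig**2) * (1 - cdf) + sig * (mu + floor) * pdf
        return m1, np.sqrt(max(m2 - m1**2, 1e-12))

    def resid(p):
        m, s = moments(p)
        return [m - target_mean, s - target_sd]

    sol, info, ok, _ = optimize.fsolve(resid, [target_mean, target_sd],
                                       full_output=True)
    if ok != 1 or sol[1] <= 0:
        return target_mean, target_sd
    return float(sol[0]), float(sol[1])


def _sample_times(duration: float, mean: float, sd: float,
                  rng: np.random.Generator, floor: float = 0.5) -> np.ndarray:
    mu, sig = _clipped_normal_params(mean, sd, floor)
    # draw enough intervals to exceed the duration, then trim
    n_guess = int(duration / max(mean - sd, floor)) + 10
    ts = [0.0]
    while ts[-1] < duration:
        incr = np.maximum(floor, rng.normal(mu, sig, size=n_guess))
        ts.extend(ts[-1] + np.cumsum(incr))
    arr = np.asarray(ts)
    return arr[arr <= duration]


def window_ground_truth(plan: SyntheticPlan, width_s: float = 90.0,
                        dt: float = 1.0) -> pd.DataFrame:
    """Planted regime label for every window inside a single segment.

    Windows are half-open ``[start, start + width_s)`` on the uniform grid;
    a window is admissible when its span lies entirely within one segment.
    """
    rows = []
    for seg in plan.segments:
        first = int(np.ceil(seg.start / dt - 1e-9))
        last = int(np.floor((seg.end - width_s) / dt + 1e-9))
        for i in range(first, last + 1):
            rows.append((i * dt, seg.regime))
    return pd.DataFrame(rows, columns=["window_start_s", "regime"])


def expected_frequencies(plan: SyntheticPlan, width_s: float = 90.0) -> dict:
    """Regime shares among the plan's admissible windows."""
    truth = window_ground_truth(plan, width_s)
    return truth["regime"].value_counts(normalize=True).to_dict()


def generate_session(plan: SyntheticPlan):
    """Render a plan into a wearable-style :class:`Session`.

    Returns ``(session, ground_truth)`` where the ground truth holds the
    planted regime per admissible 90 s window.  The same plan (same seed)
    always produces the identical session.
    """
    rng = np.random.default_rng(plan.seed)
    t, hr_level, demand = _truth_curves(plan)

    span = np.ptp(demand)
    dnorm = (demand - demand.min()) / span if span > 0 else np.zeros_like(demand)
    z_true = 2.0 * plan.pot_share * plan.z_scale * dnorm
    kin = plan.k_base + 2.0 * (1.0 - plan.pot_share) * plan.k_scale * dnorm
    if np.any(kin < 0):
        raise ValueError("infeasible plan: negative kinetic energy (speed)")
    v_true = np.sqrt(2.0 * kin)

    hr_true = hr_level + _ar1(t.size, plan.ar1_phi, plan.hr_noise_sd, rng)
    if hr_true.min() < 30 or hr_true.max() > 220:
        raise ValueError("infeasible plan: heart rate outside 30-220 bpm")

    channels = {}
    for name, truth, noise_sd in (
        ("hr", hr_true, plan.hr_obs_noise_sd),
        ("speed", v_true, plan.speed_noise_sd),
        ("altitude", z_true, plan.altitude_noise_sd),
    ):
        mean, sd = plan.sampling[name]
        ts = _sample_times(plan.duration, mean, sd, rng)
        obs = np.interp(ts, t, truth)
        if noise_sd > 0:
            obs = obs + rng.normal(scale=noise_sd, size=ts.size)
        if name == "hr" and plan.outlier_rate > 0:
            spikes = rng.random(ts.size) < plan.outlier_rate
            if spikes.any():
                base_sd = obs.std() if obs.std() > 0 else 1.0
                mags = rng.uniform(5.0, 10.0, size=int(spikes.sum())) * base_sd
                signs = rng.choice([-1.0, 1.0], size=int(spikes.sum()))
                obs[spikes] = obs[spikes] + signs * mags
        if name == "speed":
            obs = np.maximum(obs, 0.0)
        channels[name] = RawChannel(name, ts, obs)

    session = Session(
        session_id=plan.session_id,
        date=plan.date,
        age=plan.age,
        vo2max=plan.vo2max,
        channels=channels,
        duration=plan.duration,
    )
    return session, window_ground_truth(plan)


def generate_cohort(
    n_sessions: int,
    vo2max_start: float = 32.0,
    vo2max_end: float = 38.2,
    regime_trend: tuple = (0.16, 0.32),
    duration: float = 3600.0,
    seed: int = 0,
):
    """Cohort with a planted -/+ share rising alongside VO2max.

    The -/+ time share moves linearly between ``regime_trend`` endpoints
    while the -/- share falls by the same amount; +/+ and +/- stay fixed.
    Returns ``(sessions, plans, expected)`` where ``expected`` is a
    DataFrame of the per-session planted window frequencies and VO2max.
    """
    if n_sessions < 3:
        raise ValueError("need at least 3 sessions")
    mp_lo, mp_hi = regime_trend
    other = 0.54  # fixed share of +/+ and +/- combined
    rows, sessions, plans = [], [], []
    master = np.random.default_rng(seed)
    for i in range(n_sessions):
        frac = i / (n_sessions - 1)
        mp = mp_lo + (mp_hi - mp_lo) * frac
        mm = (1.0 - other) - mp
        if mm < 0 or mp < 0:
            raise ValueError("regime trend produces negative shares")
        shares = {"+/+": other / 2, "+/-": other / 2, "-/+": mp, "-/-": mm}
        vo2 = vo2max_start + (vo2max_end - vo2max_start) * frac
        plan = make_share_plan(
            shares,
            duration=duration,
            seed=int(master.integers(2**31 - 1)),
            vo2max=float(vo2),
            session_id=f"synthetic-{i:02d}",
            date=(pd.Timestamp("2021-01-01") + pd.Timedelta(days=30 * i)).date().isoformat(),
        )
        session, _ = generate_session(plan)
        sessions.append(session)
        plans.append(plan)
        exp = expected_frequencies(plan)
        rows.append({"session_id": plan.session_id, "vo2max": vo2,
                     **{f"freq_{k}": exp.get(k, 0.0) for k in _CYCLE_ORDER}})
    return sessions, plans, pd.DataFrame(rows)


def generate_fatigue_series(
    duration: float = 900.0,
    fatigue_gain: float = 0.6,
    seed: int = 0,
    baseline: float = 160.0,
    total_sd: float = 3.0,
    period_s: float = 20.0,
    base_regularity: float = 0.25,
    dt: float = 1.0,
) -> UniformSeries:
    """HR-like series whose regular (oscillatory) variance share rises.

    The share of variance carried by a deterministic oscillation grows
    linearly with normalized time at rate ``fatigue_gain`` from
    ``base_regularity``, the white-noise share shrinking to match — the
    signature that recurrence determinism picks up as fatigue emerges.
    ``fatigue_gain = 0`` gives a statistically flat series.
    """
    if not 0 <= base_regularity <= 1:
        raise ValueError("base_regularity must be in [0, 1]")
    if fatigue_gain < 0 or base_regularity + fatigue_gain > 1:
        raise ValueError("fatigue_gain must satisfy 0 <= gain <= 1 - base_regularity")
    if duration < 3 * period_s:
        raise ValueError("duration too short for the oscillatory component")
    rng = np.random.default_rng(seed)
    n = int(np.floor(duration / dt)) + 1
    t = dt * np.arange(n)
    w = np.clip(base_regularity + fatigue_gain * (t / t[-1]), 0.0, 1.0)
    osc = np.sqrt(2.0) * np.sin(2 * np.pi * t / period_s)
    noise = rng.normal(size=n)
    x = baseline + total_sd * (np.sqrt(w) * osc + np.sqrt(1.0 - w) * noise)
    return UniformSeries(t0=0.0, dt=dt, values=x)
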