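"""Session data model and I/O.

A running session is a set of irregularly sampled channels (heart rate in
bpm, speed in m/s, altitude in m) plus subject metadata.  The canonical
on-disk form is a long-format CSV with a ``# key=value`` metadata header,
chosen so that fixtures are plain text and diff-able.  A thin GPX importer
builds the same :class:`Session` from GPS track points.

All downstream analysis runs on a uniform 1 Hz grid; :func:`resample_uniform`
and :func:`align_channels` perform the interpolation.  Long observation gaps
are never interpolated across: they split the session into segments.
"""

from __future__ import annotations

import math
import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass

import numpy as np

__all__ = [
    "CHANNEL_NAMES",
    "CHANNEL_UNITS",
    "RawChannel",
    "Session",
    "UniformSeries",
    "AlignedSegment",
    "read_session_csv",
    "write_session_csv",
    "read_session_gpx",
    "resample_uniform",
    "split_on_gaps",
    "align_channels",
]

CHANNEL_NAMES = ("hr", "speed", "altitude")
CHANNEL_UNITS = {"hr": "bpm", "speed": "m/s", "altitude": "m"}


@dataclass
class RawChannel:
    """One irregularly sampled channel of a session.

    Timestamps are seconds since session start, strictly increasing.
    """

    name: str
    timestamps: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.name not in CHANNEL_NAMES:
            raise ValueError(
                f"unknown channel {self.name!r}; expected one of {CHANNEL_NAMES}"
            )
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.timestamps.ndim != 1 or self.timestamps.shape != self.values.shape:
            raise ValueError(f"channel {self.name!r}: timestamps/values shape mismatch")
        if self.timestamps.size and self.timestamps[0] < 0:
            raise ValueError(f"channel {self.name!r}: negative timestamp")
        diffs = np.diff(self.timestamps)
        if np.any(diffs <= 0):
            row = int(np.argmax(diffs <= 0)) + 1
            raise ValueError(
                f"non-monotonic timestamps in channel {self.name!r} at row {row}"
            )
        if self.name == "speed" and np.any(self.values < 0):
            raise ValueError("negative speed value")

    def __len__(self) -> int:
        return int(self.timestamps.size)

    def __eq__(self, other) -> bool:  # value semantics for round-trip tests
        return (
            isinstance(other, RawChannel)
            and self.name == other.name
            and np.array_equal(self.timestamps, other.timestamps)
            and np.array_equal(self.values, other.values)
        )


@dataclass
class Session:
    """A running session: per-channel raw series plus subject metadata."""

    session_id: str
    date: str
    age: float
    channels: dict
    vo2max: float | None = None
    duration: float | None = None

    def __post_init__(self) -> None:
        if "hr" not in self.channels:
            raise ValueError("missing required channel 'hr'")
        for name in self.channels:
            if name not in CHANNEL_NAMES:
                raise ValueError(f"unknown channel {name!r}")
        if self.age is not None and not 0 < self.age < 130:
            raise ValueError(f"implausible age {self.age}")
        max_t = max(
            (ch.timestamps[-1] for ch in self.channels.values() if len(ch)), default=0.0
        )
        if self.duration is None:
            self.duration = float(max_t)
        elif self.duration < max_t:
            raise ValueError("duration shorter than last sample timestamp")

    def __eq__(self, other) -> bool:
        if not isinstance(other, Session):
            return NotImplemented
        same_meta = (
            self.session_id == other.session_id
            and self.date == other.date
            and self.age == other.age
            and self.duration == other.duration
            and (
                (self.vo2max is None and other.vo2max is None)
                or (
                    self.vo2max is not None
                    and other.vo2max is not None
                    and self.vo2max == other.vo2max
                )
            )
        )
        return same_meta and self.channels == other.channels


@dataclass
class UniformSeries:
    """Equally spaced series: timestamps are ``t0 + i*dt``."""

    t0: float
    dt: float
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        self.values = np.asarray(self.values, dtype=float)

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.values.size)

    def __len__(self) -> int:
        return int(self.values.size)


@dataclass
class AlignedSegment:
    """All channels on one shared uniform grid (a gap-free stretch)."""

    t0: float
    dt: float
    hr: np.ndarray
    speed: np.ndarray | None = None
    altitude: np.ndarray | None = None

    @property
    def n(self) -> int:
        return int(self.hr.size)

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n)


# ---------------------------------------------------------------------------
# CSV dialect


def _format_meta(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return repr(float(value))
    return str(value)


def write_session_csv(session: Session, path) -> None:
    """Serialize a session to the canonical long-format CSV.

    Floats are written with :func:`repr` (shortest exact form), so reading
    the file back yields a bit-identical session and equal sessions produce
    byte-identical files.
    """
    lines = [
        f"# session_id={session.session_id}",
        f"# date={session.date}",
        f"# age={_format_meta(session.age)}",
        f"# vo2max={_format_meta(session.vo2max)}",
        f"# duration_s={_format_meta(session.duration)}",
        "channel,t_s,value",
    ]
    for name in CHANNEL_NAMES:
        ch = session.channels.get(name)
        if ch is None:
            continue
        for t, v in zip(ch.timestamps, ch.values):
            lines.append(f"{name},{float(t)!r},{float(v)!r}")
    text = "\n".join(lines) + "\n"
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(text)


def read_session_csv(path) -> Session:
    """Parse the canonical CSV back into a :class:`Session`.

    Raises ``ValueError`` for unknown channels, non-monotonic timestamps
    (naming channel and row) and negative speeds; the hr channel is required.
    """
    meta: dict = {}
    data: dict = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line.lstrip("# ").partition("=")
                meta[key.strip()] = value.strip()
                continue
            if line.startswith("channel,"):
                continue
            parts = line.split(",")
            if len(parts) != 3:
                raise ValueError(f"{path}: malformed row {lineno}: {line!r}")
            name, t_s, value = parts
            if name not in CHANNEL_NAMES:
                raise ValueError(f"{path}: unknown channel {name!r} at row {lineno}")
            data.setdefault(name, ([], []))
            data[name][0].append(float(t_s))
            data[name][1].append(float(value))
    channels = {
        name: RawChannel(name, np.array(ts), np.array(vs))
        for name, (ts, vs) in data.items()
    }
    vo2 = meta.get("vo2max", "")
    dur = meta.get("duration_s", "")
    return Session(
        session_id=meta.get("session_id", ""),
        date=meta.get("date", ""),
        age=float(meta["age"]) if meta.get("age") else None,
        vo2max=float(vo2) if vo2 else None,
        duration=float(dur) if dur else None,
        channels=channels,
    )


# ---------------------------------------------------------------------------
# GPX import (optional adapter; same Session out)

_GPX_NS = {
    "gpx": "http://www.topografix.com/GPX/1/1",
    "tpx": "http://www.garmin.com/xmlschemas/TrackPointExtension/v1",
}

_EARTH_R = 6371008.8  # mean Earth radius, m


def _haversine(lat1, lon1, lat2, lon2) -> float:
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dp, dl = p2 - p1, math.radians(lon2 - lon1)
    a = math.sin(dp / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2) ** 2
    return 2 * _EARTH_R * math.asin(math.sqrt(a))


def read_session_gpx(path, session_id: str = "", age: float | None = None,
                     vo2max: float | None = None) -> Session:
    """Import a GPX 1.1 track as a Session.

    Heart rate is read from the Garmin track-point extension when present;
    speed is derived from consecutive haversine distances.  Timestamps are
    rebased so the first track point is t = 0.
    """
    from datetime import datetime

    tree = ET.parse(path)
    pts = tree.getroot().findall(".//gpx:trkpt", _GPX_NS)
    if len(pts) < 2:
        raise ValueError("GPX track needs at least 2 points")
    times, lats, lons, eles, hrs = [], [], [], [], []
    for pt in pts:
        t_el = pt.find("gpx:time", _GPX_NS)
        if t_el is None:
            raise ValueError("GPX track point without <time>")
        times.append(datetime.fromisoformat(t_el.text.replace("Z", "+00:00")))
        lats.append(float(pt.get("lat")))
        lons.append(float(pt.get("lon")))
        ele = pt.find("gpx:ele", _GPX_NS)
        eles.append(float(ele.text) if ele is not None else np.nan)
        hr = pt.find(".//tpx:hr", _GPX_NS)
        hrs.append(float(hr.text) if hr is not None else np.nan)
    t0 = times[0]
    t = np.array([(ti - t0).total_seconds() for ti in times])
    date = t0.date().isoformat()
    channels = {}
    hr_arr = np.array(hrs)
    ok = ~np.isnan(hr_arr)
    if not ok.any():
        raise ValueError("GPX track has no heart-rate extension data")
    channels["hr"] = RawChannel("hr", t[ok], hr_arr[ok])
    ele_arr = np.array(eles)
    ok = ~np.isnan(ele_arr)
    if ok.any():
        channels["altitude"] = RawChannel("altitude", t[ok], ele_arr[ok])
    dist = np.array(
        [_haversine(lats[i - 1], lons[i - 1], lats[i], lons[i]) for i in range(1, len(pts))]
    )
    dt = np.diff(t)
    good = dt > 0
    speed = dist[good] / dt[good]
    channels["speed"] = RawChannel("speed", t[1:][good], speed)
    return Session(session_id=session_id or date, date=date, age=age,
                   vo2max=vo2max, channels=channels)


# ---------------------------------------------------------------------------
# Resampling / alignment


def resample_uniform(channel: RawChannel, dt: float) -> UniformSeries:
    """Linearly interpolate a channel onto a uniform grid.

    The grid runs from the first to the last observed timestamp; no
    extrapolation beyond the observed range is performed.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if len(channel) < 2:
        raise ValueError(f"channel {channel.name!r} needs >= 2 samples to resample")
    t0, t_end = channel.timestamps[0], channel.timestamps[-1]
    n = int(np.floor((t_end - t0) / dt + 1e-9)) + 1
    grid = t0 + dt * np.arange(n)
    values = np.interp(grid, channel.timestamps, channel.values)
    return UniformSeries(t0=float(t0), dt=float(dt), values=values)


def split_on_gaps(channel: RawChannel, max_gap_s: float = 30.0) -> list:
    """Split a channel at observation gaps longer than ``max_gap_s``."""
    if len(channel) == 0:
        return []
    cuts = np.flatnonzero(np.diff(channel.timestamps) > max_gap_s) + 1
    pieces = []
    for idx in np.split(np.arange(len(channel)), cuts):
        pieces.append(
            RawChannel(channel.name, channel.timestamps[idx], channel.values[idx])
        )
    return pieces


def align_channels(session: Session, dt: float = 1.0,
                   max_gap_s: float = 30.0) -> list:
    """Put all channels of a session onto shared uniform grids.

    The common grid spans the overlap of all channels' observed ranges.
    Grid points falling inside an observation gap longer than ``max_gap_s``
    in any channel are dropped, and the remaining valid runs become
    :class:`AlignedSegment` objects — gaps split the session instead of
    being bridged by interpolation.
    """
    names = [n for n in CHANNEL_NAMES if n in session.channels]
    chans = {n: session.channels[n] for n in names}
    for n, ch in chans.items():
        if len(ch) < 2:
            raise ValueError(f"channel {n!r} too short to align")
    start = max(ch.timestamps[0] for ch in chans.values())
    stop = min(ch.timestamps[-1] for ch in chans.values())
    if stop - start < dt:
        raise ValueError("channels do not overlap in time")
    n_pts = int(np.floor((stop - start) / dt + 1e-9)) + 1
    grid = start + dt * np.arange(n_pts)
    valid = np.ones(n_pts, dtype=bool)
    interp = {}
    for n, ch in chans.items():
        interp[n] = np.interp(grid, ch.timestamps, ch.values)
        gaps = np.diff(ch.timestamps)
        for j in np.flatnonzero(gaps > max_gap_s):
            lo, hi = ch.timestamps[j], ch.timestamps[j + 1]
            valid &= ~((grid > lo) & (grid < hi))
    segments = []
    cuts = np.flatnonzero(np.diff(valid.astype(int)))
    bounds = np.concatenate(([0], cuts + 1, [n_pts]))
    for a, b in zip(bounds[:-1], bounds[1:]):
        if not valid[a] or b - a < 2:
            continue
        segments.append(
            AlignedSegment(
                t0=float(grid[a]),
                dt=float(dt),
                hr=interp["hr"][a:b].copy(),
                speed=interp["speed"][a:b].copy() if "speed" in interp else None,
                altitude=interp["altitude"][a:b].copy() if "altitude" in interp else None,
            )
        )
    if not segments:
        warnings.warn("no gap-free aligned segments found", stacklevel=2)
    return segments
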