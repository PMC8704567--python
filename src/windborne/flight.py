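"""Nocturnal flight-behavior rules for the migrating moth.

Every behavioral constant lives in :class:`FlightParams`: the downwind
self-powered airspeed, the low-temperature flight gate, the dusk-to-dawn night
window, the 12 h over-land / 36 h over-sea duration caps, the two-leg
(stepping-stone) limit and the eight standard launch altitudes.  The default
values parameterize a noctuid moth such as the fall armyworm.

Clock times are local mean solar time: UTC = local - lon/15 h.  Trap sites and
candidate source regions span several civil time zones, so solar time is the
only convention that keeps "takeoff at 19:00" meaningful everywhere.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, replace
from typing import Literal

import numpy as np

CALM_WIND_MS = 0.1   # below this, downwind heading is undefined

DEFAULT_ALTITUDES_M = (500.0, 750.0, 1000.0, 1200.0, 1500.0, 1750.0, 2000.0, 2250.0)


@dataclass(frozen=True)
class FlightParams:
    """Behavioral constants of the trajectory model.

    airspeed
        Self-powered flight speed added along the wind unit vector, m/s.
    t_min
        Minimum air temperature (degC) permitting flight; at or above flies.
    nightly_max_h / max_nights
        Over-land nightly flight cap (h) and maximum consecutive nights.
    oversea_max_h
        A single over-sea flight extends past dawn up to this many hours.
    max_legs
        Maximum flights chained in the stepping-stone reconstruction.
    takeoff_local / dusk_local / dawn_local
        Local solar clock times: nominal takeoff, first and last nocturnal
        release hour.
    altitudes_m
        Candidate launch altitudes, meters AGL, strictly increasing.
    step_s
        Integration step of the trajectory engine, seconds.
    takeoff_tolerance_h
        Half-width of the window around takeoff_local accepted as a
        plausible departure time.
    """

    airspeed: float = 3.0
    t_min: float = 13.8
    nightly_max_h: float = 12.0
    max_nights: int = 3
    oversea_max_h: float = 36.0
    max_legs: int = 2
    takeoff_local: dt.time = dt.time(19, 0)
    dusk_local: dt.time = dt.time(20, 0)
    dawn_local: dt.time = dt.time(5, 0)
    altitudes_m: tuple[float, ...] = DEFAULT_ALTITUDES_M
    step_s: float = 300.0
    takeoff_tolerance_h: float = 1.0
    host_strict: bool = False

    def __post_init__(self):
        if self.airspeed < 0:
            raise ValueError("airspeed must be >= 0")
        if not (0 < self.nightly_max_h <= self.oversea_max_h):
            raise ValueError("need 0 < nightly_max_h <= oversea_max_h")
        alts = tuple(float(a) for a in self.altitudes_m)
        if any(b <= a for a, b in zip(alts, alts[1:])) or not alts:
            raise ValueError("altitudes_m must be non-empty and strictly increasing")
        object.__setattr__(self, "altitudes_m", alts)
        if self.max_legs < 1:
            raise ValueError("max_legs must be >= 1")
        if self.step_s <= 0:
            raise ValueError("step_s must be positive")

    def with_overrides(self, **kwargs) -> "FlightParams":
        for key in ("takeoff_local", "dusk_local", "dawn_local"):
            if key in kwargs and isinstance(kwargs[key], str):
                kwargs[key] = dt.time.fromisoformat(kwargs[key])
        return replace(self, **kwargs)


def ground_velocity(u: float, v: float, airspeed: float) -> tuple[float, float]:
    """Ground velocity of a downwind-flying moth: wind plus airspeed along it.

    In calm air (|wind| < 0.1 m/s) the downwind heading is undefined and the
    self-powered vector is suppressed, returning the wind unchanged.
    """
    speed = float(np.hypot(u, v))
    if speed < CALM_WIND_MS:
        return float(u), float(v)
    scale = 1.0 + airspeed / speed
    return float(u) * scale, float(v) * scale


def flight_permitted(temperature: float, params: FlightParams) -> bool:
    """True iff the air temperature permits flight (gate is inclusive at t_min)."""
    return bool(temperature >= params.t_min)


# -- local solar time ---------------------------------------------------------

def lon_offset(lon: float) -> np.timedelta64:
    """Solar-time offset of longitude `lon`: positive east, lon/15 hours."""
    return np.timedelta64(int(round(lon / 15.0 * 3600.0)), "s")


def to_local(t_utc, lon: float) -> np.datetime64:
    return np.datetime64(t_utc, "s") + lon_offset(lon)


def to_utc(t_local, lon: float) -> np.datetime64:
    return np.datetime64(t_local, "s") - lon_offset(lon)


def local_clock_hours(t_utc, lon: float) -> float:
    """Local solar clock time in fractional hours [0, 24)."""
    loc = to_local(t_utc, lon)
    day = loc.astype("datetime64[D]")
    return float((loc - day) / np.timedelta64(1, "h"))


def _clock_to_td(clock: dt.time) -> np.timedelta64:
    return np.timedelta64(clock.hour * 3600 + clock.minute * 60 + clock.second, "s")


def prev_local_clock(t_utc, lon: float, clock: dt.time) -> np.datetime64:
    """Latest UTC instant strictly before `t_utc` whose local clock equals `clock`."""
    t = np.datetime64(t_utc, "s")
    loc = to_local(t, lon)
    cand = loc.astype("datetime64[D]") + _clock_to_td(clock)
    if cand >= loc:
        cand -= np.timedelta64(1, "D")
    return to_utc(cand, lon)


def next_local_clock(t_utc, lon: float, clock: dt.time) -> np.datetime64:
    """Earliest UTC instant strictly after `t_utc` whose local clock equals `clock`."""
    t = np.datetime64(t_utc, "s")
    loc = to_local(t, lon)
    cand = loc.astype("datetime64[D]") + _clock_to_td(clock)
    if cand <= loc:
        cand += np.timedelta64(1, "D")
    return to_utc(cand, lon)


def night_window(date, lon: float, params: FlightParams | None = None
                 ) -> tuple[np.datetime64, np.datetime64]:
    """UTC (takeoff, dawn) instants of the night beginning on `date` at `lon`.

    Takeoff is takeoff_local (default 19:00) on `date`; dawn is dawn_local
    (default 05:00) the following morning.  Local mean solar time convention.
    """
    params = params or FlightParams()
    day = np.datetime64(str(date), "D")
    takeoff_local = day.astype("datetime64[s]") + _clock_to_td(params.takeoff_local)
    dawn_local = (day + np.timedelta64(1, "D")).astype("datetime64[s]") + _clock_to_td(params.dawn_local)
    return to_utc(takeoff_local, lon), to_utc(dawn_local, lon)


def release_hours(arrival_night, lon: float, params: FlightParams | None = None
                  ) -> list[np.datetime64]:
    """Hourly UTC release times from dusk to dawn of `arrival_night` at `lon`.

    Defaults (20:00 ... 05:00) give ten hourly instants.
    """
    params = params or FlightParams()
    day = np.datetime64(str(arrival_night), "D")
    dusk = to_utc(day.astype("datetime64[s]") + _clock_to_td(params.dusk_local), lon)
    dawn = to_utc((day + np.timedelta64(1, "D")).astype("datetime64[s]")
                  + _clock_to_td(params.dawn_local), lon)
    out, t = [], dusk
    while t <= dawn:
        out.append(t)
        t = t + np.timedelta64(3600, "s")
    return out


Direction = Literal["forward", "backward"]
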