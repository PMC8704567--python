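"""Forward and backward trajectory integration under the nocturnal flight rules.

A trajectory leg starts at a release point (dusk takeoff when forward, a
nocturnal landing hour when backward) and is integrated with a midpoint (RK2)
scheme at a constant altitude AGL until the first applicable stop:

========================  =====================================================
``cold``                  air temperature at the current position fell below
                          the flight gate
``dawn_landfall``         forward: dawn reached over land, or first land cell
                          after dawn when the over-sea extension applies;
                          backward: the nominal takeoff time reached over land,
                          or first land cell earlier when extending over sea
``nightly_cap``           over land with the nightly flight budget exhausted
``oversea_cap``           a single flight reached the over-sea duration cap
``domain_exit``           the position left the meteorological grid
========================  =====================================================

Backward integration negates the full ground velocity (wind plus the
self-powered downwind vector), assuming the moth also flew downwind in the
past.  The stepping-stone reconstruction chains a second backward leg from any
first-leg endpoint that looks like a dusk takeoff from land.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .flight import (FlightParams, Direction, ground_velocity, local_clock_hours,
                     next_local_clock, prev_local_clock, release_hours)
from .geography import LandMask
from .met_field import MetField, OutOfDomainError, EARTH_RADIUS_M

TERMINATION_REASONS = ("dawn_landfall", "nightly_cap", "oversea_cap", "cold", "domain_exit")

_DEG_PER_M = 180.0 / (np.pi * EARTH_RADIUS_M)


@dataclass(frozen=True)
class ReleaseSpec:
    """Where, when, at which altitude and in which time direction to launch."""

    lon: float
    lat: float
    time: np.datetime64
    altitude_m: float
    direction: Direction = "forward"

    def __post_init__(self):
        object.__setattr__(self, "time", np.datetime64(self.time, "s"))
        if self.direction not in ("forward", "backward"):
            raise ValueError(f"direction must be forward or backward, got {self.direction!r}")


@dataclass(frozen=True)
class TrajectoryPoint:
    time: np.datetime64
    lon: float
    lat: float
    altitude_m: float
    u: float
    v: float
    temperature: float
    surface: str        # "land" | "sea"


@dataclass
class Trajectory:
    """One simulated flight leg (points in simulation order)."""

    points: list[TrajectoryPoint]
    direction: Direction
    termination_reason: str
    release: ReleaseSpec
    leg_index: int = 1

    def __post_init__(self):
        if self.termination_reason not in TERMINATION_REASONS:
            raise ValueError(f"unknown termination reason {self.termination_reason!r}")

    @property
    def flight_duration_h(self) -> float:
        if len(self.points) < 2:
            return 0.0
        dt = abs((self.points[-1].time - self.points[0].time) / np.timedelta64(1, "h"))
        return float(dt)

    @property
    def endpoint(self) -> TrajectoryPoint:
        return self.points[-1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": [p.time for p in self.points],
            "lon": [p.lon for p in self.points],
            "lat": [p.lat for p in self.points],
            "altitude_m": [p.altitude_m for p in self.points],
            "u": [p.u for p in self.points],
            "v": [p.v for p in self.points],
            "temperature": [p.temperature for p in self.points],
            "surface": [p.surface for p in self.points],
        })


@dataclass
class Stopover:
    lon: float
    lat: float
    landing_time: np.datetime64   # when the earlier flight landed
    takeoff_time: np.datetime64   # when the later flight departed


@dataclass
class MultiLegPath:
    """Chained backward legs: legs[0] is the flight nearest arrival."""

    legs: list[Trajectory]
    stopovers: list[Stopover] = dc_field(default_factory=list)
    valid: bool | None = None

    def __post_init__(self):
        for i, leg in enumerate(self.legs, start=1):
            leg.leg_index = i

    @property
    def final_endpoint(self) -> TrajectoryPoint:
        return self.legs[-1].endpoint


# -- integration --------------------------------------------------------------

def _step_position(lon, lat, u, v, dt_s):
    """Spherical position update: dlon = dx/(R cos lat), dlat = dy/R."""
    new_lat = lat + v * dt_s * _DEG_PER_M
    new_lon = lon + u * dt_s * _DEG_PER_M / np.cos(np.radians(lat))
    return new_lon, new_lat


def advance(time, lon, lat, alt, fld: MetField, params: FlightParams,
            direction: Direction):
    """One midpoint (RK2) step of length params.step_s; returns (time, lon, lat).

    Raises OutOfDomainError if the midpoint or start sample leaves the grid.
    """
    sign = 1.0 if direction == "forward" else -1.0
    dt_s = params.step_s
    s1 = fld.sample(time, lon, lat, alt)
    u1, v1 = ground_velocity(s1.u, s1.v, params.airspeed)
    mid_t = time + np.timedelta64(int(round(sign * dt_s / 2)), "s")
    mid_lon, mid_lat = _step_position(lon, lat, sign * u1, sign * v1, dt_s / 2)
    s2 = fld.sample(mid_t, mid_lon, mid_lat, alt)
    u2, v2 = ground_velocity(s2.u, s2.v, params.airspeed)
    new_lon, new_lat = _step_position(lon, lat, sign * u2, sign * v2, dt_s)
    new_t = time + np.timedelta64(int(round(sign * dt_s)), "s")
    return new_t, new_lon, new_lat


def integrate_fixed(release: ReleaseSpec, fld: MetField, params: FlightParams,
                    duration_h: float) -> Trajectory:
    """Rule-free advection for a fixed duration (used for inversion checks)."""
    n_steps = int(round(duration_h * 3600.0 / params.step_s))
    t, lon, lat, alt = release.time, release.lon, release.lat, release.altitude_m
    points = []
    for _ in range(n_steps + 1):
        s = fld.sample(t, lon, lat, alt)
        points.append(TrajectoryPoint(t, lon, lat, alt, s.u, s.v, s.temperature,
                                      "sea"))
        if len(points) == n_steps + 1:
            break
        t, lon, lat = advance(t, lon, lat, alt, fld, params, release.direction)
    return Trajectory(points, release.direction, "domain_exit", release)


def run_leg(release: ReleaseSpec, fld: MetField, mask: LandMask,
            params: FlightParams | None = None) -> Trajectory:
    """Integrate one flight leg until the first applicable stopping rule."""
    params = params or FlightParams()
    if not fld.contains_time(release.time):
        raise ValueError(
            f"release time {release.time} outside field span {fld.time_span}")

    forward = release.direction == "forward"
    if forward:
        dawn = next_local_clock(release.time, release.lon, params.dawn_local)
        window_h = min(params.nightly_max_h,
                       float((dawn - release.time) / np.timedelta64(1, "h")))
    else:
        nominal_takeoff = prev_local_clock(release.time, release.lon, params.takeoff_local)

    t, lon, lat, alt = release.time, release.lon, release.lat, release.altitude_m
    points: list[TrajectoryPoint] = []
    reason = None
    while True:
        try:
            s = fld.sample(t, lon, lat, alt)
        except OutOfDomainError:
            reason = "domain_exit"
            break
        on_land = mask.is_land(lon, lat)
        points.append(TrajectoryPoint(t, float(lon), float(lat), float(alt),
                                      s.u, s.v, s.temperature,
                                      "land" if on_land else "sea"))
        elapsed_h = abs((t - release.time) / np.timedelta64(1, "h"))
        if s.temperature < params.t_min:
            reason = "cold"
            break
        if forward:
            if t >= dawn and on_land:
                reason = "dawn_landfall"
                break
            if elapsed_h >= params.oversea_max_h:
                reason = "oversea_cap"
                break
            if on_land and elapsed_h >= window_h and t >= dawn:
                reason = "nightly_cap"
                break
        else:
            if t <= nominal_takeoff and on_land:
                reason = "dawn_landfall"
                break
            if elapsed_h >= params.oversea_max_h:
                reason = "oversea_cap"
                break
            if on_land and elapsed_h >= params.nightly_max_h:
                reason = "nightly_cap"
                break
        try:
            t, lon, lat = advance(t, lon, lat, alt, fld, params, release.direction)
        except OutOfDomainError:
            reason = "domain_exit"
            break
    if not points:  # release itself outside the spatial grid
        raise ValueError("release point outside the meteorological grid")
    return Trajectory(points, release.direction, reason, release)


# -- fans and stepping-stone chaining ------------------------------------------

def run_backward_fan(arrival_lon: float, arrival_lat: float, arrival_night,
                     fld: MetField, mask: LandMask,
                     params: FlightParams | None = None) -> list[Trajectory]:
    """Backward legs for every (hourly nocturnal release time, launch altitude).

    With default parameters this is 10 release hours x 8 altitudes = 80
    candidate trajectories for one arrival night.
    """
    params = params or FlightParams()
    out = []
    for t0 in release_hours(arrival_night, arrival_lon, params):
        for alt in params.altitudes_m:
            rel = ReleaseSpec(arrival_lon, arrival_lat, t0, alt, "backward")
            out.append(run_leg(rel, fld, mask, params))
    return out


def plausible_takeoff(traj: Trajectory, mask: LandMask,
                      params: FlightParams | None = None,
                      require_host: bool = False) -> bool:
    """Does this backward leg end like a dusk takeoff from land?

    True iff the endpoint is on land (in the host raster when
    ``require_host``), its local solar clock time is within
    ``takeoff_tolerance_h`` of the nominal takeoff, and the leg did not
    terminate by cold or domain exit.
    """
    params = params or FlightParams()
    if traj.termination_reason in ("cold", "domain_exit"):
        return False
    end = traj.endpoint
    on_target = (mask.in_host(end.lon, end.lat) if require_host
                 else mask.is_land(end.lon, end.lat))
    if not on_target:
        return False
    clock = local_clock_hours(end.time, end.lon)
    takeoff_h = (params.takeoff_local.hour + params.takeoff_local.minute / 60.0)
    diff = abs(clock - takeoff_h)
    diff = min(diff, 24.0 - diff)
    return diff <= params.takeoff_tolerance_h


def run_multileg_backward(arrival_lon: float, arrival_lat: float, arrival_night,
                          fld: MetField, mask: LandMask,
                          params: FlightParams | None = None) -> list[MultiLegPath]:
    """Stepping-stone reconstruction: chain up to max_legs backward flights.

    Every first-leg trajectory yields a one-leg path.  A first leg whose
    endpoint looks like a dusk takeoff from land is treated as the landing
    site of an earlier flight, and a second backward fan is launched from it
    across the preceding night's hourly landing times (one fan per distinct
    stopover cell and takeoff evening).
    """
    params = params or FlightParams()
    fan1 = run_backward_fan(arrival_lon, arrival_lat, arrival_night, fld, mask, params)
    paths = [MultiLegPath(legs=[t]) for t in fan1]
    if params.max_legs < 2:
        return paths

    fans2: dict[tuple, list[Trajectory]] = {}
    for leg1 in fan1:
        if not plausible_takeoff(leg1, mask, params):
            continue
        end = leg1.endpoint
        # takeoff evening (local date of the endpoint's dusk)
        takeoff_day = (end.time + np.timedelta64(int(round(end.lon / 15 * 3600)), "s")
                       ).astype("datetime64[D]")
        iy, ix = mask._nearest(end.lon, end.lat)
        key = (int(iy), int(ix), str(takeoff_day))
        if key not in fans2:
            landing_night = takeoff_day - np.timedelta64(1, "D")
            legs2 = []
            for t0 in release_hours(landing_night, end.lon, params):
                for alt in params.altitudes_m:
                    rel = ReleaseSpec(end.lon, end.lat, t0, alt, "backward")
                    legs2.append(run_leg(rel, fld, mask, params))
            fans2[key] = legs2
        for leg2 in fans2[key]:
            stop = Stopover(end.lon, end.lat,
                            landing_time=leg2.release.time,
                            takeoff_time=end.time)
            paths.append(MultiLegPath(legs=[leg1, leg2], stopovers=[stop]))
    return paths


# -- export -------------------------------------------------------------------

def trajectories_to_frame(trajs: Iterable[Trajectory]) -> pd.DataFrame:
    """Long-form table (one row per point) for CSV export."""
    frames = []
    for i, tr in enumerate(trajs):
        f = tr.to_frame()
        f.insert(0, "trajectory", i)
        f.insert(1, "leg_index", tr.leg_index)
        frames.append(f)
    if not frames:
        return pd.DataFrame(columns=["trajectory", "leg_index", "time", "lon", "lat",
                                     "altitude_m", "u", "v", "temperature", "surface"])
    return pd.concat(frames, ignore_index=True)


def legs_to_geojson(trajs: Sequence[Trajectory]) -> dict:
    """GeoJSON FeatureCollection: one LineString per leg."""
    features = []
    for tr in trajs:
        features.append({
            "type": "Feature",
            "geometry": {
                "type": "LineString",
                "coordinates": [[round(p.lon, 6), round(p.lat, 6)] for p in tr.points],
            },
            "properties": {
                "leg_index": tr.leg_index,
                "direction": tr.direction,
                "termination_reason": tr.termination_reason,
                "duration_h": round(tr.flight_duration_h, 4),
                "release_time": str(tr.release.time),
                "altitude_m": tr.release.altitude_m,
            },
        })
    return {"type": "FeatureCollection", "features": features}


def write_geojson(trajs: Sequence[Trajectory], path) -> None:
    with open(path, "w") as fh:
        json.dump(legs_to_geojson(trajs), fh)
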