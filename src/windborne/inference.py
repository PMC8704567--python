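"""Endpoint-validity filtering and source-region summaries.

A backward leg is accepted as evidence of a departure only when its endpoint
looks like a dusk takeoff: terrestrial (preferably inside the host-crop
raster), at a local clock time near the nominal takeoff, and not produced by a
cold stop or a grid exit.  Counting accepted (release hour, altitude) pairs per
migration leg, and summarising their flight durations and endpoints, yields
the source-region report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field

import numpy as np
from shapely.geometry import MultiPoint

from .flight import FlightParams
from .geography import LandMask
from .trajectory import MultiLegPath, Trajectory, plausible_takeoff

# LandMask lives in geography; re-exported here because endpoint validity is
# its principal consumer.
__all__ = ["LandMask", "ValidityReport", "endpoint_valid", "filter_and_count",
           "summarize_durations", "source_region_summary", "NoValidLegsError"]


class NoValidLegsError(ValueError):
    """Summary requested for a leg index with no valid trajectories."""


def endpoint_valid(traj: Trajectory, mask: LandMask,
                   params: FlightParams | None = None) -> bool:
    """Is this backward leg's endpoint a plausible departure?

    True iff the endpoint (a) is on land — inside the host raster when
    ``params.host_strict`` — (b) falls within ``takeoff_tolerance_h`` of the
    local nominal takeoff time, and (c) the leg did not end by cold or
    domain exit.
    """
    params = params or FlightParams()
    if traj.direction != "backward":
        raise ValueError("endpoint validity applies to backward legs only")
    return plausible_takeoff(traj, mask, params, require_host=params.host_strict)


@dataclass
class LegSummary:
    migration: str              # chronological name ("first migration", ...)
    count: int
    duration_mean_h: float | None
    duration_sd_h: float | None          # sample (n-1) SD; 0 with flag when n=1
    duration_se_h: float | None
    degenerate_sd: bool
    endpoints: list[tuple[float, float]]  # lon, lat of valid endpoints


@dataclass
class ValidityReport:
    """Per-leg counts, duration statistics and endpoints of valid trajectories."""

    legs: dict[int, LegSummary] = dc_field(default_factory=dict)
    n_paths: int = 0
    n_valid_paths: int = 0

    def to_dict(self) -> dict:
        return {
            "n_paths": self.n_paths,
            "n_valid_paths": self.n_valid_paths,
            "legs": {
                str(k): {
                    "migration": s.migration,
                    "valid_count": s.count,
                    "duration_mean_h": s.duration_mean_h,
                    "duration_sd_h": s.duration_sd_h,
                    "duration_se_h": s.duration_se_h,
                    "degenerate_sd": s.degenerate_sd,
                    "endpoints": [[round(lo, 6), round(la, 6)] for lo, la in s.endpoints],
                } for k, s in sorted(self.legs.items())
            },
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


_ORDINALS = {1: "first", 2: "second", 3: "third", 4: "fourth"}


def _leg_valid(path: MultiLegPath, i: int, mask: LandMask, params: FlightParams) -> bool:
    """Validity of leg i of a path: host tier applies to the deepest leg only."""
    leg = path.legs[i]
    require_host = params.host_strict and (i == len(path.legs) - 1)
    return plausible_takeoff(leg, mask, params, require_host=require_host)


def filter_and_count(paths: list[MultiLegPath], mask: LandMask,
                     params: FlightParams | None = None) -> ValidityReport:
    """Mark paths valid/invalid and count valid trajectories per migration leg.

    A path is valid when every leg endpoint passes the departure filter.  A
    candidate trajectory is identified by its (release time, altitude) pair,
    so the same flight reached through different chains is counted once.
    Migration names are chronological: the earliest flight (deepest backward
    leg) is the "first migration".
    """
    params = params or FlightParams()
    report = ValidityReport(n_paths=len(paths))
    if not paths:
        return report
    max_legs_seen = max(len(p.legs) for p in paths)

    seen: dict[int, set] = {}
    per_leg: dict[int, list[Trajectory]] = {}
    for path in paths:
        leg_ok = [_leg_valid(path, i, mask, params) for i in range(len(path.legs))]
        path.valid = all(leg_ok)
        for i, leg in enumerate(path.legs):
            if not leg_ok[i]:
                continue
            key = (str(leg.release.time), float(leg.release.altitude_m))
            if key in seen.setdefault(leg.leg_index, set()):
                continue
            seen[leg.leg_index].add(key)
            per_leg.setdefault(leg.leg_index, []).append(leg)

    report.n_valid_paths = sum(1 for p in paths if p.valid)
    for leg_index in range(1, max_legs_seen + 1):
        legs = per_leg.get(leg_index, [])
        chrono = max_legs_seen - leg_index + 1
        name = f"{_ORDINALS.get(chrono, str(chrono) + 'th')} migration"
        if legs:
            durations = np.array([t.flight_duration_h for t in legs])
            mean = float(durations.mean())
            degenerate = durations.size == 1
            sd = 0.0 if degenerate else float(durations.std(ddof=1))
            se = sd / np.sqrt(durations.size)
            summary = LegSummary(name, len(legs), mean, sd, float(se), degenerate,
                                 [(t.endpoint.lon, t.endpoint.lat) for t in legs])
        else:
            summary = LegSummary(name, 0, None, None, None, False, [])
        report.legs[leg_index] = summary
    return report


def summarize_durations(paths: list[MultiLegPath], leg_index: int,
                        mask: LandMask, params: FlightParams | None = None
                        ) -> tuple[float, float]:
    """Mean and sample (n-1) SD of flight duration over valid legs of one index.

    A single valid leg returns SD 0 by convention (the report carries a
    degenerate flag).  Raises :class:`NoValidLegsError` when none qualify.
    """
    report = filter_and_count(paths, mask, params)
    summary = report.legs.get(leg_index)
    if summary is None or summary.count == 0:
        raise NoValidLegsError(f"no valid trajectories with leg index {leg_index}")
    return summary.duration_mean_h, summary.duration_sd_h


def source_region_summary(paths: list[MultiLegPath], mask: LandMask,
                          params: FlightParams | None = None,
                          leg_index: int | None = None):
    """Centroid and convex hull of inferred departure points.

    By default the deepest available reconstruction is used: endpoints of the
    earliest flight of the valid paths with the most legs (two-leg chains
    dominate one-leg ones when both exist).  Returns
    ``(centroid_lonlat, hull_geometry, degenerate_flag)``; with fewer than
    three distinct endpoints the hull degenerates to a point or segment and
    the flag is set.
    """
    params = params or FlightParams()
    valid = [p for p in paths if (p.valid if p.valid is not None
                                  else all(_leg_valid(p, i, mask, params)
                                           for i in range(len(p.legs))))]
    if not valid:
        raise NoValidLegsError("no valid paths to summarise")
    if leg_index is None:
        depth = max(len(p.legs) for p in valid)
        endpoints = [p.final_endpoint for p in valid if len(p.legs) == depth]
    else:
        endpoints = [p.legs[leg_index - 1].endpoint for p in valid
                     if len(p.legs) >= leg_index]
        if not endpoints:
            raise NoValidLegsError(f"no valid paths reach leg index {leg_index}")
    pts = [(e.lon, e.lat) for e in endpoints]
    centroid = (float(np.mean([p[0] for p in pts])), float(np.mean([p[1] for p in pts])))
    hull = MultiPoint(pts).convex_hull
    degenerate = hull.geom_type != "Polygon"
    return centroid, hull, degenerate
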