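"""Nocturnal wind climatology and vertical-velocity diagnostics.

Reproduces the synoptic analyses that frame the trajectory study: 16-sector
circular histograms of nocturnal monthly-mean winds at the 800-900 hPa rose
levels, sector-group frequencies and mean speeds (the monsoon risk window),
and time-height omega profiles with downdraft-event detection against the
0.3 Pa/s threshold.

Wind direction uses the meteorological "blowing from" convention (a westerly
blows from 270 degrees).  One rose sample is the monthly mean wind vector for
one (site, pressure level, nocturnal hour, year) stratum; with 3 sites, 5
levels, 10 hourly bins (20:00-05:00 local) and 10 years this gives 1500
samples per monthly histogram.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .met_field import MetField, OutOfDomainError, height_from_pressure, omega_to_vertical_ms

SECTOR_WIDTH = 22.5
SECTOR_NAMES = ("N", "NNE", "NE", "ENE", "E", "ESE", "SE", "SSE",
                "S", "SSW", "SW", "WSW", "W", "WNW", "NW", "NNW")
DEFAULT_ROSE_LEVELS_HPA = (800.0, 825.0, 850.0, 875.0, 900.0)
DEFAULT_PROFILE_LEVELS_HPA = tuple(float(p) for p in range(800, 951, 25))
DEFAULT_NIGHT_HOURS = (20, 21, 22, 23, 0, 1, 2, 3, 4, 5)

# the three trap locations whose decade climatology frames the analysis
CLIMATOLOGY_SITES = {
    "Saibai": (142.6075, -9.382222),
    "Erub": (143.75698, -9.590167),
    "Bamaga": (142.38442, -10.89583),
}

# surveillance trap placements (site name -> lon, lat)
TRAP_SITES = {
    "FAW-Erub001": (143.75698, -9.590167),
    "FAW-Erub002": (143.77208, -9.5915),
    "FAW-Saibai001": (142.6075, -9.382222),
    "FAW-Saibai002": (142.62528, -9.381111),
    "FAW-Bamaga001": (142.38442, -10.89583),
    "FAW-Bamaga002": (142.36731, -10.84815),
    "FAW-Badu001": (142.1682, -10.15776),
    "FAW-Badu002": (142.16694, -10.16836),
}


class CalmWindError(ValueError):
    """Direction undefined: both wind components are (near) zero."""


class EmptyRoseError(ValueError):
    """No samples available for the requested month."""


class CoverageError(ValueError):
    """The field does not cover part of the requested sampling grid."""


def met_direction(u: float, v: float, calm_threshold: float = 1e-9):
    """Meteorological wind direction: degrees FROM which the wind blows.

    0 = from north, 90 = from east, 270 = from west.  Raises
    :class:`CalmWindError` for a (near-)zero vector, which rose builders
    exclude.  Vectorised over array input (calm entries become NaN).
    """
    u_arr = np.asarray(u, dtype=float)
    v_arr = np.asarray(v, dtype=float)
    calm = np.hypot(u_arr, v_arr) < calm_threshold
    if u_arr.ndim == 0:
        if calm:
            raise CalmWindError("wind direction undefined in calm air")
        return float(np.degrees(np.arctan2(-u_arr, -v_arr)) % 360.0)
    out = np.degrees(np.arctan2(-u_arr, -v_arr)) % 360.0
    out[calm] = np.nan
    return out


def sector_of(direction):
    """16-sector index of a direction; bins are centered on the compass points.

    Sector k covers [k*22.5 - 11.25, k*22.5 + 11.25) so a boundary direction
    belongs to the higher sector; sector 0 (N) wraps around 360.
    """
    d = np.asarray(direction, dtype=float)
    idx = (np.floor(((d + SECTOR_WIDTH / 2) % 360.0) / SECTOR_WIDTH)).astype(int)
    return int(idx) if idx.ndim == 0 else idx


@dataclass(frozen=True)
class WindSample:
    """One rose sample: the monthly mean nocturnal wind for one stratum."""

    site: str
    time: np.datetime64        # first instant of the stratum (UTC)
    level_hpa: float
    month: int
    year: int
    hour_local: int
    u: float
    v: float

    @property
    def speed(self) -> float:
        return float(np.hypot(self.u, self.v))

    @property
    def direction_from(self) -> float:
        return met_direction(self.u, self.v)


@dataclass
class WindRose:
    """16-sector circular histogram of wind directions with per-sector speeds."""

    month: int
    counts: np.ndarray            # (16,) int
    frequencies: np.ndarray       # (16,) float, sums to 1
    mean_speed: np.ndarray        # (16,) float, NaN where count = 0
    total: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "month": self.month,
            "sector": SECTOR_NAMES,
            "center_deg": np.arange(16) * SECTOR_WIDTH,
            "count": self.counts,
            "frequency": self.frequencies,
            "mean_speed_ms": self.mean_speed,
        })


def _days_of_month(year: int, month: int) -> np.ndarray:
    first = np.datetime64(f"{year}-{month:02d}", "M")
    return np.arange(first, first + np.timedelta64(1, "M"), dtype="datetime64[D]")


def nightly_level_samples(field: MetField, sites: dict[str, tuple[float, float]],
                          levels_hpa=DEFAULT_ROSE_LEVELS_HPA,
                          hours_local=DEFAULT_NIGHT_HOURS,
                          years=range(2010, 2020), months=range(1, 13),
                          mean_temperature: float = 288.0,
                          monthly_mean: bool = True) -> list[WindSample]:
    """Build rose samples: one per (site, level, nocturnal hour, year, month).

    Each sample is the mean wind vector over every night of that month at the
    given local solar hour, site and pressure level (heights via the
    hypsometric conversion).  ``monthly_mean=False`` instead emits one sample
    per individual night.  A field that does not cover part of the request
    raises :class:`CoverageError` naming the first missing stratum.
    """
    heights = {p: float(height_from_pressure(p, mean_temperature=mean_temperature))
               for p in levels_hpa}
    samples: list[WindSample] = []
    for site, (lon, lat) in sites.items():
        for year in years:
            for month in months:
                days = _days_of_month(year, month)
                for hour in hours_local:
                    # morning hours belong to the night that began the evening before
                    day_shift = np.timedelta64(1 if hour < 12 else 0, "D")
                    locals_ = ((days + day_shift).astype("datetime64[s]")
                               + np.timedelta64(hour * 3600, "s"))
                    utcs = locals_ - np.timedelta64(int(round(lon / 15 * 3600)), "s")
                    for p, z in heights.items():
                        try:
                            vals = field.sample_many(utcs, lon, lat, z)
                        except OutOfDomainError as err:
                            raise CoverageError(
                                f"field does not cover site={site} year={year} "
                                f"month={month} hour={hour:02d} level={p} hPa: {err}"
                            ) from err
                        if monthly_mean:
                            samples.append(WindSample(
                                site, utcs[0], p, month, year, hour,
                                float(vals["u"].mean()), float(vals["v"].mean())))
                        else:
                            samples.extend(
                                WindSample(site, t, p, month, year, hour,
                                           float(u), float(v))
                                for t, u, v in zip(utcs, vals["u"], vals["v"]))
    return samples


def monthly_wind_rose(samples: list[WindSample], month: int) -> WindRose:
    """Tally one month's samples into a 16-sector rose (calm samples excluded)."""
    sel = [s for s in samples if s.month == month]
    if not sel:
        raise EmptyRoseError(f"no samples for month {month}")
    counts = np.zeros(16, dtype=int)
    speed_sum = np.zeros(16)
    for s in sel:
        try:
            k = sector_of(s.direction_from)
        except CalmWindError:
            continue
        counts[k] += 1
        speed_sum[k] += s.speed
    total = int(counts.sum())
    if total == 0:
        raise EmptyRoseError(f"all samples for month {month} are calm")
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_speed = np.where(counts > 0, speed_sum / np.maximum(counts, 1), np.nan)
    return WindRose(month, counts, counts / total, mean_speed, total)


WESTERLY_SECTORS = frozenset({sector_of(270.0)})
WESTERLY_POOLED_SECTORS = frozenset({sector_of(247.5), sector_of(270.0), sector_of(292.5)})
NORTHWEST_SECTORS = frozenset({sector_of(315.0)})


def sector_group_stats(samples: list[WindSample], months, group) -> tuple[float, float]:
    """Frequency (%) and mean speed (m/s) of winds from a sector group.

    ``group`` is a set of sector indices (see WESTERLY_SECTORS and friends);
    frequency is the share of the months' non-calm samples whose direction
    falls in the group, and the mean speed is taken over those samples.
    """
    if not group:
        raise ValueError("sector group must be non-empty")
    months = {months} if isinstance(months, int) else set(months)
    n_tot = 0
    hits: list[float] = []
    for s in samples:
        if s.month not in months:
            continue
        try:
            k = sector_of(s.direction_from)
        except CalmWindError:
            continue
        n_tot += 1
        if k in group:
            hits.append(s.speed)
    if n_tot == 0:
        return 0.0, float("nan")
    freq = 100.0 * len(hits) / n_tot
    return freq, (float(np.mean(hits)) if hits else float("nan"))


# -- vertical velocity ----------------------------------------------------------


@dataclass
class VVProfile:
    """Time-height grid of vertical pressure velocity at one site."""

    site: str
    times: np.ndarray             # datetime64[s]
    levels_hpa: np.ndarray
    omega: np.ndarray             # (time, level) Pa/s, positive descending

    def to_dataset(self) -> xr.Dataset:
        return xr.Dataset(
            {"omega": (("time", "level_hpa"), self.omega)},
            coords={"time": self.times, "level_hpa": self.levels_hpa},
            attrs={"site": self.site})


def vertical_velocity_profile(field: MetField, site: str, lon: float, lat: float,
                              levels_hpa=DEFAULT_PROFILE_LEVELS_HPA,
                              window=None, mean_temperature: float = 288.0) -> VVProfile:
    """Sample omega at a site over a time x pressure-level grid.

    ``window`` is an optional (start, end) UTC pair; defaults to the full
    field span.  Level heights come from the hypsometric conversion.
    """
    if window is None:
        times = field.times
    else:
        a, b = (np.datetime64(t, "s") for t in window)
        times = field.times[(field.times >= a) & (field.times <= b)]
    if times.size == 0:
        raise CoverageError("requested window contains no field time steps")
    levels_hpa = np.asarray(levels_hpa, float)
    heights = height_from_pressure(levels_hpa, mean_temperature=mean_temperature)
    tt, zz = np.meshgrid(times, heights, indexing="ij")
    try:
        vals = field.sample_many(tt.ravel(), lon, lat, zz.ravel().astype(float))
    except OutOfDomainError as err:
        raise CoverageError(f"field does not cover site {site}: {err}") from err
    omega = vals["omega"].reshape(times.size, levels_hpa.size)
    return VVProfile(site, times, levels_hpa, omega)


@dataclass(frozen=True)
class DowndraftEvent:
    start: np.datetime64
    end: np.datetime64
    max_omega: float             # Pa/s
    max_downdraft_ms: float      # |w| of the peak, hydrostatic conversion
    exceeds_airspeed: bool       # could the downdraft overwhelm the moth?

    def to_dict(self) -> dict:
        return {"start": str(self.start), "end": str(self.end),
                "max_omega_pa_s": round(self.max_omega, 6),
                "max_downdraft_ms": round(self.max_downdraft_ms, 6),
                "exceeds_airspeed": self.exceeds_airspeed}


def downdraft_events(profile: VVProfile, threshold: float = 0.3,
                     inclusive: bool = True, airspeed: float = 3.0,
                     mean_temperature: float = 288.0) -> list[DowndraftEvent]:
    """Maximal time intervals where any level's omega reaches the threshold.

    The boundary is inclusive by default ("downward flow above 0.3 Pa/s" read
    as >= for robustness).  Each event carries the peak omega, its hydrostatic
    vertical-speed equivalent at the peak's pressure level, and whether that
    sink rate exceeds the moth's self-powered airspeed — the "strong enough to
    overwhelm" test.
    """
    series = profile.omega.max(axis=1)
    exceed = series >= threshold if inclusive else series > threshold
    events: list[DowndraftEvent] = []
    i = 0
    n = exceed.size
    while i < n:
        if not exceed[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and exceed[j + 1]:
            j += 1
        block = profile.omega[i:j + 1]
        flat = int(np.argmax(block))
        ti, li = divmod(flat, block.shape[1])
        peak = float(block[ti, li])
        w = omega_to_vertical_ms(peak, float(profile.levels_hpa[li]) * 100.0,
                                 mean_temperature)
        events.append(DowndraftEvent(profile.times[i], profile.times[j], peak,
                                     abs(float(w)), abs(float(w)) > airspeed))
        i = j + 1
    return events


def events_to_json(events: list[DowndraftEvent], **kwargs) -> str:
    return json.dumps([e.to_dict() for e in events], **kwargs)
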