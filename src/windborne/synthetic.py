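"""Synthetic meteorological fields and ground-truth migration scenarios.

Real applications of this package consume mesoscale-model output (multi-GB
reanalysis downloads); every generator here builds a small in-memory analogue
with the structural features the analysis relies on — monsoon-like westerly
jets, vertical shear, cold layers aloft, downdraft episodes — plus, for the
monsoon scenario, a known forward-migration ground truth against which the
backward source inference can be scored.

Scenario wind fields are deliberately smooth (uniform jet on the corridor
latitude, low-order meridional curvature, a monsoon-onset temporal ramp that
finishes before any simulated flight) so that closed-form time-of-flight
arithmetic predicts the simulated trajectories exactly.  Islands are
rectangles snapped to grid cells: nearest-cell mask lookup then has exact,
quantisation-free land boundaries.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np

from .flight import FlightParams, to_utc, _clock_to_td
from .geography import LandMask, KM_PER_DEG
from .met_field import MetField


class ScenarioInfeasibleError(ValueError):
    """Requested geometry cannot be connected under the flight rules."""


@dataclass(frozen=True)
class ScenarioTruth:
    """Ground truth of a synthetic migration used to score the inference."""

    source_centroid: tuple[float, float]      # lon, lat degrees
    source_radius_km: float
    takeoff_time: np.datetime64               # UTC, truth departure
    expected_arrival_site: tuple[float, float]
    expected_arrival_night: np.datetime64     # date of the arrival night
    leg_count: int
    stopover: tuple[float, float] | None = None

    def __post_init__(self):
        if self.leg_count < 1:
            raise ValueError("leg_count must be >= 1")
        if self.source_radius_km <= 0:
            raise ValueError("source_radius_km must be positive")


DEFAULT_LEVELS_M = tuple(float(z) for z in range(250, 2501, 250))
_DEF_START = "2021-01-10T00:00:00"


def _grid(extent, spacing=0.25):
    lon_min, lon_max, lat_min, lat_max = extent
    if lon_max <= lon_min or lat_max <= lat_min:
        raise ValueError(f"degenerate lon/lat box {extent}")
    lons = np.arange(lon_min, lon_max + spacing / 2, spacing)
    lats = np.arange(lat_min, lat_max + spacing / 2, spacing)
    return lats, lons


def _times(duration_h, start=_DEF_START, step_h=1):
    if duration_h < 2:
        raise ValueError("duration must be at least 2 h")
    n = int(round(duration_h / step_h)) + 1
    t0 = np.datetime64(start, "s")
    return t0 + np.arange(n) * np.timedelta64(int(step_h * 3600), "s")


def make_uniform_field(u0: float, v0: float, t0_c: float, omega0: float,
                       extent=(140.0, 146.0, -12.0, -8.0), duration_h: float = 48.0,
                       start=_DEF_START, levels=DEFAULT_LEVELS_M) -> MetField:
    """Spatially and temporally constant atmosphere — the oracle substrate."""
    lats, lons = _grid(extent)
    times = _times(duration_h, start)
    shape = (times.size, len(levels), lats.size, lons.size)
    return MetField(times, np.asarray(levels, float), lats, lons,
                    np.full(shape, float(u0)), np.full(shape, float(v0)),
                    np.full(shape, float(t0_c)), np.full(shape, float(omega0)))


def make_layered_field(speed_by_level: dict[float, tuple[float, float]],
                       cold_above: float | None = None,
                       extent=(140.0, 146.0, -12.0, -8.0), duration_h: float = 48.0,
                       start=_DEF_START, warm_c: float = 25.0,
                       cold_c: float = 2.0) -> MetField:
    """Horizontally uniform field with per-level wind (a sheared low-level jet).

    Wind is constant within each listed level and blends linearly between
    levels on interpolation.  With ``cold_above`` set, air strictly above that
    altitude is colder than the 13.8 degC flight gate (the transition is
    compressed into a 10 m layer at ``cold_above``).
    """
    if len(speed_by_level) < 2:
        raise ValueError("need at least two levels")
    levels = sorted(float(z) for z in speed_by_level)
    if cold_above is not None:
        for z in (float(cold_above), float(cold_above) + 10.0):
            if z not in levels:
                levels.append(z)
        levels = sorted(levels)
    lats, lons = _grid(extent)
    times = _times(duration_h, start)
    key_levels = sorted(speed_by_level)
    u_prof = np.interp(levels, key_levels, [speed_by_level[z][0] for z in key_levels])
    v_prof = np.interp(levels, key_levels, [speed_by_level[z][1] for z in key_levels])
    if cold_above is None:
        t_prof = np.full(len(levels), warm_c)
    else:
        t_prof = np.where(np.asarray(levels) <= cold_above + 1e-9, warm_c, cold_c)
    shape = (times.size, len(levels), lats.size, lons.size)
    broadcast = lambda prof: np.broadcast_to(  # noqa: E731
        prof[None, :, None, None], shape).copy()
    return MetField(times, np.asarray(levels, float), lats, lons,
                    broadcast(u_prof), broadcast(v_prof), broadcast(t_prof),
                    np.zeros(shape))


def make_downdraft_field(event_window: tuple, peak_omega: float,
                         extent=(140.0, 146.0, -12.0, -8.0), duration_h: float = 72.0,
                         start=_DEF_START, levels=DEFAULT_LEVELS_M) -> MetField:
    """Quiescent field with one descending-air episode.

    Omega equals ``peak_omega`` at mid-levels (600-2000 m, tapering to zero at
    the grid top and bottom) for every hourly frame inside ``event_window``
    (inclusive), and is exactly zero outside it.
    """
    t_a, t_b = (np.datetime64(t, "s") for t in event_window)
    times = _times(duration_h, start)
    if not (times[0] <= t_a <= t_b <= times[-1]):
        raise ValueError("event window must lie within the field duration")
    lats, lons = _grid(extent)
    levels = np.asarray(levels, float)
    in_window = (times >= t_a) & (times <= t_b)
    z = levels
    lev_prof = np.ones_like(z)
    lev_prof[z < 600] = np.clip((z[z < 600] - z[0]) / max(600 - z[0], 1.0), 0, 1)
    lev_prof[z > 2000] = np.clip((z[-1] - z[z > 2000]) / max(z[-1] - 2000, 1.0), 0, 1)
    omega = (float(peak_omega) * in_window[:, None, None, None]
             * lev_prof[None, :, None, None]
             * np.ones((1, 1, lats.size, lons.size)))
    shape = omega.shape
    return MetField(times, levels, lats, lons,
                    np.full(shape, 5.0), np.zeros(shape), np.full(shape, 25.0),
                    omega)


def make_smooth_field(seed: int, extent=(140.0, 150.0, -12.0, -6.0),
                      duration_h: float = 48.0, start=_DEF_START,
                      base_u: float = 8.0, base_v: float = 1.0,
                      amplitude: float = 3.0, levels=DEFAULT_LEVELS_M) -> MetField:
    """Smooth space-time varying wind (low-order trig modes), warm everywhere.

    Used for forward/backward inversion and step-refinement checks, where the
    flow must be non-trivial but well resolved by the grid.
    """
    rng = np.random.default_rng(seed)
    lats, lons = _grid(extent)
    times = _times(duration_h, start)
    levels = np.asarray(levels, float)
    th = (times - times[0]) / np.timedelta64(1, "h")
    T, L, Y, X = np.meshgrid(th, levels / levels.max(),
                             (lats - lats.mean()) / np.ptp(lats),
                             (lons - lons.mean()) / np.ptp(lons), indexing="ij")
    def mode():
        p = rng.uniform(0, 2 * np.pi, 4)
        a = rng.uniform(0.3, 1.0, 4)
        return (a[0] * np.sin(2 * np.pi * X + p[0]) + a[1] * np.sin(2 * np.pi * Y + p[1])
                + a[2] * np.sin(2 * np.pi * T / max(th[-1], 1) + p[2])
                + a[3] * np.sin(np.pi * L + p[3])) / 4.0
    u = base_u + amplitude * mode()
    v = base_v + amplitude * mode()
    temp = np.full(u.shape, 25.0) - 3.0 * L
    omega = 0.05 * mode()
    return MetField(times, levels, lats, lons, u, v, temp, omega)


# -- monsoon migration scenario -------------------------------------------------


def make_monsoon_scenario(seed: int, source_centroid=(120.0, -8.0),
                          arrival_site=None, leg_count: int = 1,
                          stopover=None, jet_speed: float = 12.0,
                          takeoff_date="2021-01-14",
                          params: FlightParams | None = None,
                          spacing: float = 0.25,
                          ) -> tuple[MetField, ScenarioTruth, LandMask]:
    """Monsoon-corridor scenario with a known forward-migration ground truth.

    A uniform westerly jet of ``jet_speed`` m/s blows along the corridor
    latitude from a small source island, past an optional stopover island
    (``leg_count=2``), to an arrival landmass holding the trap site.  Geometry
    is solved so that a moth taking off from the source at the nominal dusk
    lands (via the dawn-landfall and over-sea extension rules) within 50 km of
    the arrival site during the expected arrival night.  Returns the field,
    the scenario truth and the land mask (source island doubles as the host
    raster).

    Deterministic: identical arguments (seed included) give bit-identical
    output.  Raises :class:`ScenarioInfeasibleError` when the requested
    geometry cannot be connected under the flight caps.
    """
    params = params or FlightParams()
    if jet_speed <= 0:
        raise ScenarioInfeasibleError("jet_speed must be positive")
    if leg_count not in (1, 2):
        raise ScenarioInfeasibleError("leg_count must be 1 or 2")
    rng = np.random.default_rng(seed)

    src_lon, lat0 = (float(x) for x in source_centroid)
    speed_kmh = (jet_speed + params.airspeed) * 3.6
    km_per_deg_lon = KM_PER_DEG * np.cos(np.radians(lat0))
    cell_km = spacing * km_per_deg_lon
    half_cell = cell_km / 2.0

    window_h = (24 + params.dawn_local.hour - params.takeoff_local.hour) % 24  # 10 h
    x_dawn = speed_kmh * window_h  # over-land dawn position of a dusk takeoff

    # longitude grid offset so that a grid point sits exactly at x_dawn
    def x_of(lon):
        return (lon - src_lon) * km_per_deg_lon

    def lon_of(x_km):
        return src_lon + x_km / km_per_deg_lon

    offset = (x_dawn / km_per_deg_lon) % spacing
    # eastward travel-time + solar-clock shift per km (used to solve schedules)
    per_km = 1.0 / speed_kmh + 1.0 / (km_per_deg_lon * 15.0)

    if arrival_site is None:
        if leg_count == 1:
            x_trap = x_dawn - 40.0  # dawn landing ~40 km past the trap
        else:
            # second leg lands ~23:40 local: solve takeoff->landing = 28.5 h
            d2 = 28.5 / per_km
            x_trap = x_dawn + d2 + half_cell
        arr_lat = lat0
    else:
        arr_lon, arr_lat = (float(x) for x in arrival_site)
        if abs(arr_lat - lat0) > 0.5:
            raise ScenarioInfeasibleError(
                "source and arrival must share the corridor latitude (|dlat| <= 0.5 deg)")
        x_trap = x_of(arr_lon)
    # snap the trap to the grid
    x_trap = offset * km_per_deg_lon + round(
        (x_trap - offset * km_per_deg_lon) / cell_km) * cell_km

    # feasibility of the schedule
    if leg_count == 1:
        if not (0 < x_trap and abs(x_dawn - x_trap) <= 45.0):
            raise ScenarioInfeasibleError(
                f"one-leg arrival at {x_trap:.0f} km cannot be reached by a dusk "
                f"takeoff landing at dawn near {x_dawn:.0f} km")
        arrival_night_day = np.datetime64(str(takeoff_date), "D")
    else:
        t2_total = (x_trap - half_cell - x_dawn) * per_km
        if not (24.0 + 2.0 <= t2_total <= params.oversea_max_h - 1.0):
            raise ScenarioInfeasibleError(
                f"second-leg crossing of {t2_total:.1f} h is outside the "
                f"over-sea window (26-{params.oversea_max_h - 1:.0f} h)")
        arrival_night_day = np.datetime64(str(takeoff_date), "D") + np.timedelta64(2, "D")

    # grid extent
    lon_lo = lon_of(-cell_km) - 1.0
    lon_hi = lon_of(x_trap + 4 * cell_km) + 1.0
    lons = lon_of(offset * km_per_deg_lon) + spacing * np.arange(
        int(np.floor((lon_lo - lon_of(offset * km_per_deg_lon)) / spacing)),
        int(np.ceil((lon_hi - lon_of(offset * km_per_deg_lon)) / spacing)) + 1)
    lats = lat0 + spacing * np.arange(-8, 9)
    levels = np.asarray(DEFAULT_LEVELS_M)

    day_n = np.datetime64(str(takeoff_date), "D")
    t_start = (day_n - np.timedelta64(2, "D")).astype("datetime64[s]")
    n_hours = 24 * (3 + (2 if leg_count == 2 else 0)) + 1
    times = t_start + np.arange(n_hours) * np.timedelta64(3600, "s")

    # wind: westerly jet, meridional curvature (zero on the corridor), onset ramp
    curv = rng.uniform(0.05, 0.15)
    ramp_floor = rng.uniform(0.5, 0.7)
    t0_c = rng.uniform(24.0, 27.0)
    th = (times - times[0]) / np.timedelta64(1, "h")
    ramp_end_h = float((to_utc(day_n.astype("datetime64[s]")
                               + np.timedelta64(12 * 3600, "s"), src_lon)
                        - times[0]) / np.timedelta64(1, "h"))
    ramp = np.clip(ramp_floor + (1 - ramp_floor) * th / max(ramp_end_h, 1.0),
                   ramp_floor, 1.0)
    lat_shape = 1.0 - curv * ((lats - lat0) / 2.0) ** 2
    u = (jet_speed * ramp[:, None, None, None]
         * np.ones((1, levels.size, 1, 1))
         * lat_shape[None, None, :, None]
         * np.ones((1, 1, 1, lons.size)))
    shape = u.shape
    v = np.zeros(shape)
    temp = np.full(shape, t0_c) - 1.5 * (levels / 1000.0)[None, :, None, None]
    omega = np.zeros(shape)
    fld = MetField(times, levels, lats, lons, u, v, temp, omega)

    # land mask: grid-aligned islands (nearest-cell boundaries are exact)
    land = np.zeros((lats.size, lons.size), dtype=bool)
    host = np.zeros_like(land)
    iy0 = int(np.argmin(np.abs(lats - lat0)))

    def cell_index(x_km):
        return int(np.argmin(np.abs(np.array([x_of(l) for l in lons]) - x_km)))

    ix_src = cell_index(0.0)
    land[iy0 - 1:iy0 + 2, ix_src] = True            # source: 1 lon-cell island
    host[iy0 - 1:iy0 + 2, ix_src] = True
    stop_lonlat = None
    if leg_count == 2:
        if stopover is not None:
            x_stop = x_of(float(stopover[0]))
            if not (cell_km < x_stop < x_trap - cell_km):
                raise ScenarioInfeasibleError("stopover must lie between source and arrival")
            ix_stop = cell_index(x_stop)
        else:
            ix_stop = cell_index(x_dawn)
        land[iy0 - 1:iy0 + 2, ix_stop] = True       # stopover: 1 lon-cell island
        stop_lonlat = (float(lons[ix_stop]), lat0)
    ix_trap = cell_index(x_trap)
    land[iy0 - 2:iy0 + 3, ix_trap:ix_trap + 4] = True   # arrival landmass
    mask = LandMask(lats, lons, land, host)

    takeoff_utc = to_utc(day_n.astype("datetime64[s]")
                         + _clock_to_td(params.takeoff_local), float(lons[ix_src]))
    truth = ScenarioTruth(
        source_centroid=(float(lons[ix_src]), lat0),
        source_radius_km=half_cell,
        takeoff_time=takeoff_utc,
        expected_arrival_site=(float(lons[ix_trap]), lat0),
        expected_arrival_night=arrival_night_day,
        leg_count=leg_count,
        stopover=stop_lonlat,
    )
    return fld, truth, mask


# -- decade-scale climatology substrate ----------------------------------------


def make_climatology_field(seed: int = 0, years=range(2010, 2020),
                           extent=(141.5, 144.5, -11.5, -8.5),
                           levels_m=(400.0, 2100.0)) -> MetField:
    """Hourly multi-year field with a monsoon seasonal cycle at rose levels.

    Emulates the synoptic regime of the Torres Strait region: strong
    westerlies in January-February, weak westerly/northwesterly flow in
    March and December, easterly trades from April to November.  Wind
    direction wobbles deterministically around the monthly mean so that
    sector histograms have realistic spread.  The vertical span covers the
    800-950 hPa rose and profile levels once converted to heights.
    """
    rng = np.random.default_rng(seed)
    years = list(years)
    t0 = np.datetime64(f"{years[0]}-01-01T00:00:00", "s")
    t1 = np.datetime64(f"{years[-1] + 1}-01-01T00:00:00", "s")
    n = int((t1 - t0) / np.timedelta64(3600, "s")) + 1
    times = t0 + np.arange(n) * np.timedelta64(3600, "s")
    months = times.astype("datetime64[M]").astype(int) % 12 + 1

    # monthly regime: (mean u, mean v, speed) -- westerly +u, easterly -u
    mean_u = np.select(
        [np.isin(months, (1, 2)), np.isin(months, (3, 12))],
        [np.where(months == 1, 5.35, 4.37), 2.5], default=-5.0)
    mean_v = np.select(
        [np.isin(months, (1, 2)), np.isin(months, (3, 12))],
        [-0.8, -1.5], default=-1.0)
    th = (times - t0) / np.timedelta64(1, "h")
    wobble = (0.25 * np.sin(2 * np.pi * th / 263.0 + rng.uniform(0, 6.28))
              + 0.15 * np.sin(2 * np.pi * th / 41.0 + rng.uniform(0, 6.28)))
    ang = wobble * np.pi / 4.0   # up to ~+-18 deg direction wobble
    u_t = mean_u * np.cos(ang) - mean_v * np.sin(ang)
    v_t = mean_u * np.sin(ang) + mean_v * np.cos(ang)

    lats, lons = _grid(extent, spacing=np.ptp(extent[:2]))
    levels = np.asarray(levels_m, float)
    shape = (times.size, levels.size, lats.size, lons.size)
    u = np.broadcast_to(u_t[:, None, None, None], shape).copy()
    v = np.broadcast_to(v_t[:, None, None, None], shape).copy()
    temp = np.full(shape, 24.0)
    omega = np.zeros(shape)
    return MetField(times, levels, lats, lons, u, v, temp, omega)
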