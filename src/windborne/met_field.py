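"""Gridded meteorological fields: data model, NetCDF I/O, and interpolation.

A :class:`MetField` is the carrier medium for every downstream stage: a 4-D
(time x level x lat x lon) grid of horizontal wind, air temperature and
vertical pressure velocity (omega).  The canonical in-memory conventions are

* vertical coordinate in **meters above ground level** (pressure-level input
  is converted once at load time via the hypsometric relation),
* temperature in **degrees Celsius** (the nocturnal flight gate is stated
  in Celsius),
* omega in **Pa/s**, positive for descending air.

Sampling is quadrilinear: trilinear in (level, lat, lon) and linear in time,
with no extrapolation — queries outside any coordinate span raise
:class:`OutOfDomainError`, which the trajectory engine records as a domain
exit rather than silently clamping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import xarray as xr

R_DRY = 287.05          # specific gas constant of dry air, J/(kg K)
G0 = 9.80665            # standard gravity, m/s^2
EARTH_RADIUS_M = 6_371_000.0
KELVIN_OFFSET = 273.15
STANDARD_SURFACE_HPA = 1013.25


class MetFieldError(ValueError):
    """Invalid meteorological field or malformed input file."""


class MissingVariableError(MetFieldError):
    """A required variable is absent from the input file."""

    def __init__(self, name: str, available: Sequence[str]):
        self.variable = name
        super().__init__(
            f"variable {name!r} not found in file (available: {sorted(available)})"
        )


class OutOfDomainError(ValueError):
    """Sample query outside the field's space-time domain."""


def omega_to_vertical_ms(omega, pressure, temperature):
    """Convert vertical pressure velocity to vertical speed.

    Uses the hydrostatic relation ``w = -omega / (rho * g)`` with the ideal-gas
    density ``rho = p / (R_d * T)``.  Positive omega (descending air) maps to
    negative w.

    Parameters
    ----------
    omega : Pa/s
    pressure : Pa (must be > 0)
    temperature : K (must be > 0)
    """
    pressure = np.asarray(pressure, dtype=float)
    temperature = np.asarray(temperature, dtype=float)
    if np.any(pressure <= 0) or np.any(temperature <= 0):
        raise ValueError("pressure and temperature must be positive")
    rho = pressure / (R_DRY * temperature)
    w = -np.asarray(omega, dtype=float) / (rho * G0)
    return float(w) if w.ndim == 0 else w


def height_from_pressure(pressure_hpa, reference_pressure_hpa: float = STANDARD_SURFACE_HPA,
                         mean_temperature: float = 288.0):
    """Hypsometric height of a pressure level above the reference pressure.

    ``z = (R_d * Tbar / g) * ln(p0 / p)`` — e.g. 850 hPa maps to roughly
    1.5 km for a 288 K column mean temperature.
    """
    p = np.asarray(pressure_hpa, dtype=float)
    if np.any(p <= 0) or np.any(p > reference_pressure_hpa):
        raise ValueError(
            f"pressure must lie in (0, {reference_pressure_hpa}] hPa, got {pressure_hpa}"
        )
    z = (R_DRY * mean_temperature / G0) * np.log(reference_pressure_hpa / p)
    return float(z) if z.ndim == 0 else z


@dataclass(frozen=True)
class AtmoSample:
    """Pointwise atmospheric state: wind (m/s), temperature (degC), omega (Pa/s)."""

    u: float
    v: float
    temperature: float
    omega: float


@dataclass
class MetField:
    """4-D gridded atmosphere on a regular lon/lat/level/time grid.

    ``times`` must be strictly increasing with a regular step; ``levels`` is in
    meters AGL (``level_kind == "height_agl"``) after any load-time conversion.
    All variable arrays share the shape (time, level, lat, lon).
    """

    times: np.ndarray          # datetime64[s], strictly increasing, regular
    levels: np.ndarray         # meters AGL (or hPa before conversion)
    lats: np.ndarray           # degrees, strictly monotone
    lons: np.ndarray           # degrees, strictly monotone
    u: np.ndarray              # m/s
    v: np.ndarray              # m/s
    temperature: np.ndarray    # degC
    omega: np.ndarray          # Pa/s, positive = descending
    level_kind: str = "height_agl"
    rain: np.ndarray | None = None   # mm/h, (time, lat, lon); carried, unused
    _tsec: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype="datetime64[s]")
        self.levels = np.asarray(self.levels, dtype=float)
        self.lats = np.asarray(self.lats, dtype=float)
        self.lons = np.asarray(self.lons, dtype=float)
        for name in ("u", "v", "temperature", "omega"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self._validate()
        # flip descending coordinate axes so every axis is ascending
        for axis, coord in ((1, "levels"), (2, "lats"), (3, "lons")):
            arr = getattr(self, coord)
            if arr[0] > arr[-1]:
                setattr(self, coord, arr[::-1].copy())
                for name in ("u", "v", "temperature", "omega"):
                    setattr(self, name, np.flip(getattr(self, name), axis=axis).copy())
                if self.rain is not None and axis >= 2:
                    self.rain = np.flip(self.rain, axis=axis - 1).copy()
        self._tsec = self.times.astype("int64").astype(float)

    def _validate(self) -> None:
        if self.level_kind not in ("height_agl", "pressure"):
            raise MetFieldError(f"unknown level_kind {self.level_kind!r}")
        if self.times.size < 2:
            raise MetFieldError("need at least two time steps")
        steps = np.diff(self.times.astype("int64"))
        if not np.all(steps > 0):
            raise MetFieldError("times must be strictly increasing")
        if not np.all(steps == steps[0]):
            raise MetFieldError("times must have a regular step")
        for name, arr in (("levels", self.levels), ("lats", self.lats), ("lons", self.lons)):
            d = np.diff(arr)
            if arr.size < 2 or not (np.all(d > 0) or np.all(d < 0)):
                raise MetFieldError(f"{name} must be strictly monotone with >=2 values")
        shape = (self.times.size, self.levels.size, self.lats.size, self.lons.size)
        for name in ("u", "v", "temperature", "omega"):
            got = getattr(self, name).shape
            if got != shape:
                raise MetFieldError(f"{name} has shape {got}, expected {shape}")
        if self.rain is not None:
            want = (self.times.size, self.lats.size, self.lons.size)
            if np.asarray(self.rain).shape != want:
                raise MetFieldError(f"rain has shape {np.asarray(self.rain).shape}, expected {want}")

    # -- domain helpers -------------------------------------------------------

    @property
    def time_span(self) -> tuple[np.datetime64, np.datetime64]:
        return self.times[0], self.times[-1]

    def contains_time(self, t) -> bool:
        t = np.datetime64(t, "s")
        return self.times[0] <= t <= self.times[-1]

    def to_height_agl(self, mean_temperature: float = 288.0) -> "MetField":
        """Convert pressure levels (hPa) to meters AGL; no-op if already heights."""
        if self.level_kind == "height_agl":
            return self
        heights = height_from_pressure(self.levels, mean_temperature=mean_temperature)
        return MetField(self.times, heights, self.lats, self.lons,
                        self.u, self.v, self.temperature, self.omega,
                        level_kind="height_agl", rain=self.rain)

    # -- sampling -------------------------------------------------------------

    def _axis_weights(self, coord: np.ndarray, q: np.ndarray, name: str):
        lo, hi = coord[0], coord[-1]
        bad = (q < lo) | (q > hi) | ~np.isfinite(q)
        if np.any(bad):
            raise OutOfDomainError(
                f"{name} query outside [{lo}, {hi}]: {np.asarray(q)[bad][:3]}"
            )
        idx = np.clip(np.searchsorted(coord, q, side="right") - 1, 0, coord.size - 2)
        frac = (q - coord[idx]) / (coord[idx + 1] - coord[idx])
        return idx, frac

    def sample_many(self, times, lons, lats, alts) -> dict[str, np.ndarray]:
        """Vectorised quadrilinear sample; arrays broadcast to a common shape.

        Returns a dict of arrays for u, v, temperature, omega.  Raises
        :class:`OutOfDomainError` if any query leaves the grid.
        """
        if self.level_kind != "height_agl":
            raise MetFieldError("convert pressure levels with to_height_agl() before sampling")
        tq = np.atleast_1d(np.asarray(times, dtype="datetime64[s]")).astype("int64").astype(float)
        lonq = np.atleast_1d(np.asarray(lons, dtype=float))
        latq = np.atleast_1d(np.asarray(lats, dtype=float))
        altq = np.atleast_1d(np.asarray(alts, dtype=float))
        tq, lonq, latq, altq = np.broadcast_arrays(tq, lonq, latq, altq)

        it, ft = self._axis_weights(self._tsec, tq, "time")
        il, fl = self._axis_weights(self.levels, altq, "altitude")
        iy, fy = self._axis_weights(self.lats, latq, "latitude")
        ix, fx = self._axis_weights(self.lons, lonq, "longitude")

        out = {}
        for name in ("u", "v", "temperature", "omega"):
            arr = getattr(self, name)
            acc = np.zeros(tq.shape, dtype=float)
            for dt in (0, 1):
                wt = (1 - ft) if dt == 0 else ft
                for dl in (0, 1):
                    wl = (1 - fl) if dl == 0 else fl
                    for dy in (0, 1):
                        wy = (1 - fy) if dy == 0 else fy
                        for dx in (0, 1):
                            wx = (1 - fx) if dx == 0 else fx
                            acc += (wt * wl * wy * wx) * arr[it + dt, il + dl, iy + dy, ix + dx]
            out[name] = acc
        return out

    @staticmethod
    def _scalar_axis(coord: np.ndarray, q: float, name: str) -> tuple[int, float]:
        if not (coord[0] <= q <= coord[-1]):
            raise OutOfDomainError(f"{name} query {q} outside [{coord[0]}, {coord[-1]}]")
        i = int(np.searchsorted(coord, q, side="right")) - 1
        if i > coord.size - 2:
            i = coord.size - 2
        if i < 0:
            i = 0
        return i, (q - coord[i]) / (coord[i + 1] - coord[i])

    def sample(self, t, lon: float, lat: float, alt: float) -> AtmoSample:
        """Single-point quadrilinear interpolation at (t, lon, lat, alt m AGL).

        Scalar fast path of :meth:`sample_many` (the trajectory engine calls
        this twice per integration step).
        """
        if self.level_kind != "height_agl":
            raise MetFieldError("convert pressure levels with to_height_agl() before sampling")
        tsec = float(np.datetime64(t, "s").astype("int64"))
        it, ft = self._scalar_axis(self._tsec, tsec, "time")
        il, fl = self._scalar_axis(self.levels, float(alt), "altitude")
        iy, fy = self._scalar_axis(self.lats, float(lat), "latitude")
        ix, fx = self._scalar_axis(self.lons, float(lon), "longitude")
        out = []
        for arr in (self.u, self.v, self.temperature, self.omega):
            cube = arr[it:it + 2, il:il + 2, iy:iy + 2, ix:ix + 2]
            c = (cube[0] * (1 - ft) + cube[1] * ft)
            c = (c[0] * (1 - fl) + c[1] * fl)
            c = (c[0] * (1 - fy) + c[1] * fy)
            out.append(float(c[0] * (1 - fx) + c[1] * fx))
        return AtmoSample(*out)

    # -- I/O ------------------------------------------------------------------

    def to_dataset(self) -> xr.Dataset:
        coords = {"time": self.times, "level": self.levels,
                  "lat": self.lats, "lon": self.lons}
        data = {
            "u": (("time", "level", "lat", "lon"), self.u),
            "v": (("time", "level", "lat", "lon"), self.v),
            "temperature": (("time", "level", "lat", "lon"), self.temperature),
            "omega": (("time", "level", "lat", "lon"), self.omega),
        }
        if self.rain is not None:
            data["rain"] = (("time", "lat", "lon"), self.rain)
        ds = xr.Dataset(data, coords=coords)
        ds.level.attrs["kind"] = self.level_kind
        ds.temperature.attrs["units"] = "degC"
        ds.u.attrs["units"] = ds.v.attrs["units"] = "m s-1"
        ds.omega.attrs["units"] = "Pa s-1"
        return ds

    def save(self, path) -> None:
        """Write the field as NETCDF3 (CF-style 1-D coordinates + 4-D variables)."""
        self.to_dataset().to_netcdf(path, engine="scipy")


DEFAULT_VARIABLE_MAP = {
    "u": "u", "v": "v", "temperature": "temperature", "omega": "omega",
    "time": "time", "level": "level", "lat": "lat", "lon": "lon",
}


def load_gridded_field(path, variable_map: Mapping[str, str] | None = None,
                       mean_temperature: float = 288.0) -> MetField:
    """Load a WRF/reanalysis-style post-processed NetCDF file into a MetField.

    ``variable_map`` maps the canonical names (u, v, temperature, omega, time,
    level, lat, lon, optionally rain) to the names used in the file.
    Temperatures in Kelvin (values or units attribute) are converted to degC;
    pressure levels (hPa) are converted to meters AGL hypsometrically with
    ``mean_temperature`` as the column mean.
    """
    vmap = dict(DEFAULT_VARIABLE_MAP)
    if variable_map:
        vmap.update(variable_map)
    path = Path(path)
    with xr.open_dataset(path, engine="scipy") as ds:
        ds = ds.load()

    def pick(canonical, from_coords=False):
        name = vmap[canonical]
        pool = ds.coords if from_coords else ds
        if name not in pool:
            raise MissingVariableError(name, list(ds.variables))
        return pool[name]

    time = pick("time", from_coords=True).values
    level = pick("level", from_coords=True)
    lat = pick("lat", from_coords=True).values.astype(float)
    lon = pick("lon", from_coords=True).values.astype(float)

    arrays = {}
    for canonical in ("u", "v", "temperature", "omega"):
        da = pick(canonical)
        if da.ndim != 4:
            raise MetFieldError(f"{vmap[canonical]!r} must be 4-D, got {da.ndim}-D")
        arrays[canonical] = np.asarray(da.transpose(
            vmap["time"], vmap["level"], vmap["lat"], vmap["lon"]).values, dtype=float)

    temp = arrays["temperature"]
    t_units = str(ds[vmap["temperature"]].attrs.get("units", "")).lower()
    if t_units in ("k", "kelvin") or (not t_units and np.nanmin(temp) > 150.0):
        temp = temp - KELVIN_OFFSET

    level_kind = str(level.attrs.get("kind", "")) or (
        "pressure" if str(level.attrs.get("units", "")).lower() in ("hpa", "millibar", "mb")
        else "height_agl")
    rain = None
    if "rain" in vmap and vmap["rain"] in ds:
        rain = np.asarray(ds[vmap["rain"]].values, dtype=float)

    fld = MetField(time, level.values.astype(float), lat, lon,
                   arrays["u"], arrays["v"], temp, arrays["omega"],
                   level_kind=level_kind, rain=rain)
    return fld.to_height_agl(mean_temperature=mean_temperature)
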