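"""Land/sea masks and spherical-geometry helpers.

The trajectory engine looks up the surface type under the moth at every
integration step with a nearest-cell query; the endpoint-validity filter also
uses the optional host-crop raster.  Distances use the great-circle formula on
a 6371 km sphere, consistent with the engine's position-update metric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import xarray as xr

from .met_field import EARTH_RADIUS_M

KM_PER_DEG = EARTH_RADIUS_M / 1000.0 * np.pi / 180.0  # ~111.195 km per degree


def haversine_km(lon1, lat1, lon2, lat2) -> float | np.ndarray:
    """Great-circle distance in kilometers on the R=6371 km sphere."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lon1, lat1, lon2, lat2))
    a = (np.sin((lat2 - lat1) / 2) ** 2
         + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2) ** 2)
    d = 2 * (EARTH_RADIUS_M / 1000.0) * np.arcsin(np.sqrt(a))
    return float(d) if np.ndim(d) == 0 else d


def km_east_to_lon(x_km, lat: float) -> float | np.ndarray:
    """Longitude offset (degrees) of an eastward displacement at latitude `lat`."""
    return np.asarray(x_km, dtype=float) / (KM_PER_DEG * np.cos(np.radians(lat)))


@dataclass
class LandMask:
    """Boolean land/sea raster with an optional host-crop raster.

    The query is total over the mask domain; nearest-cell semantics mean each
    grid cell owns the half-cell band around its center.  Queries outside the
    raster clamp to the edge cell (the met-field domain check fires first in
    the trajectory engine).
    """

    lats: np.ndarray
    lons: np.ndarray
    land: np.ndarray                  # bool, (lat, lon)
    host: np.ndarray | None = None    # bool, (lat, lon); subset of land

    def __post_init__(self):
        self.lats = np.asarray(self.lats, dtype=float)
        self.lons = np.asarray(self.lons, dtype=float)
        self.land = np.asarray(self.land, dtype=bool)
        if self.land.shape != (self.lats.size, self.lons.size):
            raise ValueError(f"land grid shape {self.land.shape} does not match "
                             f"({self.lats.size}, {self.lons.size})")
        if self.host is not None:
            self.host = np.asarray(self.host, dtype=bool)
            if self.host.shape != self.land.shape:
                raise ValueError("host raster must match the land raster shape")

    def _nearest(self, lon, lat):
        iy = np.clip(np.searchsorted(self.lats, np.asarray(lat, dtype=float)), 1, self.lats.size - 1)
        iy = np.where(np.abs(self.lats[iy - 1] - lat) <= np.abs(self.lats[iy] - lat), iy - 1, iy)
        ix = np.clip(np.searchsorted(self.lons, np.asarray(lon, dtype=float)), 1, self.lons.size - 1)
        ix = np.where(np.abs(self.lons[ix - 1] - lon) <= np.abs(self.lons[ix] - lon), ix - 1, ix)
        return iy, ix

    def is_land(self, lon, lat):
        iy, ix = self._nearest(lon, lat)
        out = self.land[iy, ix]
        return bool(out) if np.ndim(out) == 0 else out

    def in_host(self, lon, lat):
        if self.host is None:
            return self.is_land(lon, lat)
        iy, ix = self._nearest(lon, lat)
        out = self.host[iy, ix]
        return bool(out) if np.ndim(out) == 0 else out

    def save(self, path) -> None:
        """Write the mask as a NETCDF3 byte raster."""
        data = {"land": (("lat", "lon"), self.land.astype("i1"))}
        if self.host is not None:
            data["host"] = (("lat", "lon"), self.host.astype("i1"))
        xr.Dataset(data, coords={"lat": self.lats, "lon": self.lons}).to_netcdf(
            path, engine="scipy")

    @classmethod
    def load(cls, path) -> "LandMask":
        with xr.open_dataset(path, engine="scipy") as ds:
            ds = ds.load()
        host = ds["host"].values.astype(bool) if "host" in ds else None
        return cls(ds["lat"].values, ds["lon"].values,
                   ds["land"].values.astype(bool), host)

    @classmethod
    def all_land(cls, lats, lons) -> "LandMask":
        return cls(lats, lons, np.ones((len(lats), len(lons)), dtype=bool))

    @classmethod
    def all_sea(cls, lats, lons) -> "LandMask":
        return cls(lats, lons, np.zeros((len(lats), len(lons)), dtype=bool))
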