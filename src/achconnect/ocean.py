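"""Synthetic coastal domains and daily surface-velocity fields.

The Lagrangian stage needs two ingredients that real studies take from a
hydrodynamic product and a coastline database: a gridded daily (u, v) surface
current series and a set of source/sink points spaced evenly along the shore.
This module generates both synthetically.  The flow recipe is purely
kinematic — a steady alongshore jet, a divergence-free travelling eddy field,
optional cross-shore "barrier" jets and white noise — chosen for statistical
structure (meanders, eddies, retention zones), not for hydrodynamic realism.

Coordinates are decimal degrees on a spherical Earth; local distances use the
equirectangular approximation, which is adequate at the sub-100-km scales of
along-shore point spacing.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
import shapely
import xarray as xr
from shapely.geometry import Polygon

EARTH_RADIUS_KM = 6371.0
KM_PER_DEG = EARTH_RADIUS_KM * math.pi / 180.0  # ~111.19 km per degree of latitude


def local_km_factors(ref_lat: float) -> tuple[float, float]:
    """(km per degree of longitude, km per degree of latitude) at ``ref_lat``."""
    return KM_PER_DEG * math.cos(math.radians(ref_lat)), KM_PER_DEG


class DomainError(ValueError):
    """Raised for invalid coastal-domain geometry or parameters."""


@dataclass
class CoastalDomain:
    """A coastline polygon with a regular lat/lon grid and coastal points.

    Attributes
    ----------
    polygon : shapely.Polygon
        The landmass, in decimal degrees (lon, lat vertex order).
    lats, lons : ndarray
        Grid-cell centre coordinates (ascending, regular spacing).
    grid_spacing_deg : float
        Grid spacing in degrees.
    land_mask : ndarray of bool, shape (nlat, nlon)
        True where the cell centre lies inside the land polygon.
    points : pandas.DataFrame
        Coastal source/sink points: columns ``point_id``, ``lat``, ``lon``,
        ``alongshore_km`` (arc-length position along the seaward boundary).
    point_spacing_km : float
        Nominal along-shore spacing of the points.
    ref_lat : float
        Latitude used for local km/degree conversion.
    """

    polygon: Polygon
    lats: np.ndarray
    lons: np.ndarray
    grid_spacing_deg: float
    land_mask: np.ndarray
    points: pd.DataFrame
    point_spacing_km: float
    ref_lat: float

    @property
    def n_points(self) -> int:
        return len(self.points)

    def point_xy_km(self) -> np.ndarray:
        """Coastal point coordinates projected to local km (x east, y north)."""
        kx, ky = local_km_factors(self.ref_lat)
        x = (self.points["lon"].to_numpy() - self.lons[0]) * kx
        y = (self.points["lat"].to_numpy() - self.lats[0]) * ky
        return np.column_stack([x, y])

    def to_files(self, out_dir) -> None:
        """Write the polygon as GeoJSON and the coastal points as CSV."""
        import pathlib

        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "coastline.geojson").write_text(
            json.dumps(shapely.geometry.mapping(self.polygon))
        )
        self.points.to_csv(out / "coastal_points.csv", index=False)


def _ring_cumlen_km(coords: np.ndarray) -> np.ndarray:
    """Cumulative arc length (km) along a (lon, lat) polyline."""
    lon, lat = coords[:, 0], coords[:, 1]
    mid_lat = 0.5 * (lat[1:] + lat[:-1])
    dx = (lon[1:] - lon[:-1]) * KM_PER_DEG * np.cos(np.radians(mid_lat))
    dy = (lat[1:] - lat[:-1]) * KM_PER_DEG
    seg = np.hypot(dx, dy)
    return np.concatenate([[0.0], np.cumsum(seg)])


def _resample_polyline(
    coords: np.ndarray, spacing_km: float, closed: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Arc-length resample a (lon, lat) polyline at ~spacing_km intervals.

    The actual spacing is L / round(L / spacing) so points divide the boundary
    exactly; a closed ring gets N = round(L/spacing) points (no duplicate),
    an open segment N + 1 points including both ends.
    """
    cum = _ring_cumlen_km(coords)
    total = float(cum[-1])
    if spacing_km <= 0:
        raise DomainError("point spacing must be positive")
    if spacing_km > total:
        raise DomainError(
            f"point spacing {spacing_km} km exceeds boundary length {total:.2f} km"
        )
    n = max(1, round(total / spacing_km))
    s = np.arange(n if closed else n + 1) * (total / n)
    lon = np.interp(s, cum, coords[:, 0])
    lat = np.interp(s, cum, coords[:, 1])
    return np.column_stack([lon, lat]), s


def build_coastal_domain(
    polygon,
    grid_spacing_deg: float = 0.08,
    point_spacing_km: float = 1.0,
    coast_vertices: tuple[int, int] | None = None,
    margin_deg: float = 0.5,
) -> CoastalDomain:
    """Build a :class:`CoastalDomain` from a land polygon.

    Parameters
    ----------
    polygon
        A shapely Polygon or a sequence of (lon, lat) vertices describing the
        landmass.  Must be simple (non-self-intersecting).
    grid_spacing_deg
        Lat/lon grid spacing in degrees (0.08° mirrors an eddy-resolving
        ocean-model product, ~6–9 km).
    point_spacing_km
        Along-shore spacing of source/sink points (1 km nominal).
    coast_vertices
        Declares which stretch of the polygon exterior is the seaward side:
        a pair of exterior-ring vertex indices ``(i0, i1)`` delimiting the
        coast (walked forward from i0 to i1).  ``None`` means the whole ring
        is coast (an island).
    margin_deg
        Ocean margin added around the polygon's bounding box for the grid.

    Returns
    -------
    CoastalDomain
    """
    if not isinstance(polygon, Polygon):
        polygon = Polygon(polygon)
    if not polygon.is_valid:
        raise DomainError("polygon is invalid (self-intersecting or degenerate)")
    if grid_spacing_deg <= 0:
        raise DomainError("grid spacing must be positive")

    ring = np.asarray(polygon.exterior.coords)  # closed: first == last
    if coast_vertices is None:
        coast_coords = ring
        closed = True
    else:
        i0, i1 = coast_vertices
        if not (0 <= i0 < i1 < len(ring)):
            raise DomainError("coast_vertices must index exterior ring vertices, i0 < i1")
        coast_coords = ring[i0 : i1 + 1]
        closed = False

    pts, s = _resample_polyline(coast_coords, point_spacing_km, closed)
    points = pd.DataFrame(
        {
            "point_id": np.arange(len(pts)),
            "lat": pts[:, 1],
            "lon": pts[:, 0],
            "alongshore_km": s[: len(pts)],
        }
    )

    minx, miny, maxx, maxy = polygon.bounds
    lons = np.arange(minx - margin_deg, maxx + margin_deg + 1e-9, grid_spacing_deg)
    lats = np.arange(miny - margin_deg, maxy + margin_deg + 1e-9, grid_spacing_deg)
    glon, glat = np.meshgrid(lons, lats)
    land_mask = shapely.contains_xy(polygon, glon.ravel(), glat.ravel()).reshape(
        glat.shape
    )

    return CoastalDomain(
        polygon=polygon,
        lats=lats,
        lons=lons,
        grid_spacing_deg=float(grid_spacing_deg),
        land_mask=land_mask,
        points=points,
        point_spacing_km=float(point_spacing_km),
        ref_lat=float(points["lat"].mean()),
    )


def straight_coast_domain(
    length_km: float = 300.0,
    coast_lat: float = -34.0,
    lon0: float = 18.0,
    land_depth_km: float = 15.0,
    grid_spacing_deg: float = 0.02,
    point_spacing_km: float = 5.0,
    margin_deg: float = 1.0,
) -> CoastalDomain:
    """An east-west straight coastline with land to the south, ocean north.

    Convenience constructor for scaled-down experiments: the seaward side is
    the northern edge of a land rectangle running east from ``(lon0,
    coast_lat)`` for ``length_km``.
    """
    dlon = length_km / (KM_PER_DEG * math.cos(math.radians(coast_lat)))
    lat_s = coast_lat - land_depth_km / KM_PER_DEG
    ring = [
        (lon0, coast_lat),
        (lon0 + dlon, coast_lat),
        (lon0 + dlon, lat_s),
        (lon0, lat_s),
    ]
    return build_coastal_domain(
        ring,
        grid_spacing_deg=grid_spacing_deg,
        point_spacing_km=point_spacing_km,
        coast_vertices=(0, 1),
        margin_deg=margin_deg,
    )


@dataclass(frozen=True)
class FlowRecipe:
    """Named, versioned parameters of the synthetic flow.

    The flow is u = jet + eddies + barriers + noise, with all speeds in m/s:

    * a steady alongshore jet of speed ``jet_speed`` toward
      ``jet_direction_deg`` (math convention: 0° = east, 90° = north);
    * a divergence-free travelling eddy field of amplitude ``eddy_amplitude``,
      wavelength ``eddy_wavelength_km`` and period ``eddy_period_days``;
    * optional barriers: Gaussian cross-shore jets ``(lon_centre, width_deg,
      speed)`` toward ``offshore_direction_deg`` that also locally damp the
      alongshore jet — these create flow discontinuities that partition the
      coast into weakly connected regions;
    * seeded white noise of standard deviation ``noise_sd`` per component.
    """

    name: str = "alongshore-v1"
    jet_speed: float = 0.2
    jet_direction_deg: float = 0.0
    eddy_amplitude: float = 0.05
    eddy_wavelength_km: float = 60.0
    eddy_period_days: float = 10.0
    noise_sd: float = 0.02
    barriers: tuple[tuple[float, float, float], ...] = ()
    offshore_direction_deg: float = 90.0

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class VelocityFieldSeries:
    """Daily surface-velocity fields on a regular lat/lon grid.

    ``u`` and ``v`` have shape (time, nlat, nlon) in m/s; land cells are
    exactly zero.  The series is reproducible bit-for-bit from (seed, recipe).
    """

    times: pd.DatetimeIndex
    lats: np.ndarray
    lons: np.ndarray
    u: np.ndarray
    v: np.ndarray
    seed: int
    recipe: FlowRecipe

    @property
    def n_days(self) -> int:
        return len(self.times)

    def to_xarray(self) -> xr.Dataset:
        ds = xr.Dataset(
            {
                "u": (("time", "lat", "lon"), self.u),
                "v": (("time", "lat", "lon"), self.v),
            },
            coords={"time": self.times, "lat": self.lats, "lon": self.lons},
            attrs={"seed": self.seed, "recipe": json.dumps(self.recipe.to_dict())},
        )
        return ds

    def to_netcdf(self, path) -> None:
        self.to_xarray().to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path) -> "VelocityFieldSeries":
        ds = xr.open_dataset(path, engine="scipy")
        recipe_dict = json.loads(ds.attrs["recipe"])
        recipe_dict["barriers"] = tuple(tuple(b) for b in recipe_dict["barriers"])
        return cls(
            times=pd.DatetimeIndex(ds["time"].values),
            lats=ds["lat"].values,
            lons=ds["lon"].values,
            u=ds["u"].values,
            v=ds["v"].values,
            seed=int(ds.attrs["seed"]),
            recipe=FlowRecipe(**recipe_dict),
        )


def generate_fields(
    domain: CoastalDomain,
    recipe: FlowRecipe,
    years: int = 1,
    seed: int = 0,
    days_per_year: int = 365,
    start: str = "2003-01-01",
) -> VelocityFieldSeries:
    """Generate a daily velocity-field series for ``years`` simulated years.

    One field per day; identical (domain, recipe, seed) always yields
    identical arrays.  ``days_per_year`` is exposed so that scaled-down runs
    can use short synthetic years.
    """
    if years < 1:
        raise ValueError("years must be >= 1")
    if days_per_year < 1:
        raise ValueError("days_per_year must be >= 1")

    n_days = years * days_per_year
    times = pd.date_range(start, periods=n_days, freq="D")
    kx, ky = local_km_factors(domain.ref_lat)
    x_km = (domain.lons - domain.lons[0]) * kx  # (nlon,)
    y_km = (domain.lats - domain.lats[0]) * ky  # (nlat,)
    X = x_km[None, :]  # broadcast over (nlat, nlon)
    Y = y_km[:, None]

    theta = math.radians(recipe.jet_direction_deg)
    jet_u, jet_v = recipe.jet_speed * math.cos(theta), recipe.jet_speed * math.sin(theta)

    # barrier damping factor and cross-shore jet, constant in time
    damp = np.ones((len(domain.lats), len(domain.lons)))
    bar_u = np.zeros_like(damp)
    bar_v = np.zeros_like(damp)
    phi = math.radians(recipe.offshore_direction_deg)
    for lon_c, width_deg, speed in recipe.barriers:
        w = np.exp(-(((domain.lons[None, :] - lon_c) / width_deg) ** 2))
        w = np.broadcast_to(w, damp.shape)
        damp = damp * (1.0 - w)
        bar_u = bar_u + speed * math.cos(phi) * w
        bar_v = bar_v + speed * math.sin(phi) * w

    k = 2 * math.pi / recipe.eddy_wavelength_km
    omega = 2 * math.pi / recipe.eddy_period_days

    rng = np.random.default_rng(seed)
    u = np.empty((n_days, len(domain.lats), len(domain.lons)))
    v = np.empty_like(u)
    for t in range(n_days):
        # divergence-free eddy field from a travelling streamfunction
        eu = recipe.eddy_amplitude * np.sin(k * X - omega * t) * np.cos(k * Y)
        ev = -recipe.eddy_amplitude * np.cos(k * X - omega * t) * np.sin(k * Y)
        u[t] = jet_u * damp + bar_u + eu
        v[t] = jet_v * damp + bar_v + ev
    if recipe.noise_sd > 0:
        u += rng.normal(0.0, recipe.noise_sd, u.shape)
        v += rng.normal(0.0, recipe.noise_sd, v.shape)

    u[:, domain.land_mask] = 0.0
    v[:, domain.land_mask] = 0.0
    return VelocityFieldSeries(
        times=times,
        lats=domain.lats,
        lons=domain.lons,
        u=u,
        v=v,
        seed=int(seed),
        recipe=recipe,
    )
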