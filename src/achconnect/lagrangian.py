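"""Lagrangian simulation of passively drifting larvae.

Particles are released daily from every coastal point, advected with
forward-Euler steps of one hour using bilinear interpolation of the daily
velocity field (piecewise-constant in time within a day), and terminate by
settling — entering the capture zone of a coastal point after an optional
pre-competency period, or beaching on the land polygon — or by being lost:
leaving the domain or exceeding the maximum pelagic larval duration (PLD).

Advection is fully deterministic unless sub-grid diffusion is switched on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy.spatial import cKDTree

from .ocean import KM_PER_DEG, CoastalDomain, VelocityFieldSeries, local_km_factors


class OutOfDomainError(ValueError):
    """Query position lies outside the gridded velocity field."""


def _bilinear_uv(field: VelocityFieldSeries, lat, lon, day):
    """Vectorised bilinear interpolation of (u, v) for per-particle day indices.

    Returns (u, v, inbounds); velocities are NaN where out of bounds.
    """
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    day = np.asarray(day)
    dlat = field.lats[1] - field.lats[0]
    dlon = field.lons[1] - field.lons[0]
    fi = (lat - field.lats[0]) / dlat
    fj = (lon - field.lons[0]) / dlon
    nlat, nlon = len(field.lats), len(field.lons)
    inb = (fi >= 0) & (fi <= nlat - 1) & (fj >= 0) & (fj <= nlon - 1)

    fi_c = np.clip(fi, 0, nlat - 1)
    fj_c = np.clip(fj, 0, nlon - 1)
    i0 = np.minimum(fi_c.astype(int), nlat - 2)
    j0 = np.minimum(fj_c.astype(int), nlon - 2)
    wi = fi_c - i0
    wj = fj_c - j0

    out_u = np.full(lat.shape, np.nan)
    out_v = np.full(lat.shape, np.nan)
    for arr, out in ((field.u, out_u), (field.v, out_v)):
        v00 = arr[day, i0, j0]
        v01 = arr[day, i0, j0 + 1]
        v10 = arr[day, i0 + 1, j0]
        v11 = arr[day, i0 + 1, j0 + 1]
        out[...] = (
            v00 * (1 - wi) * (1 - wj)
            + v01 * (1 - wi) * wj
            + v10 * wi * (1 - wj)
            + v11 * wi * wj
        )
    out_u[~inb] = np.nan
    out_v[~inb] = np.nan
    return out_u, out_v, inb


def interpolate_velocity(field: VelocityFieldSeries, lat: float, lon: float, time):
    """(u, v) at a position and time by bilinear spatial interpolation.

    ``time`` may be a day index (int) or anything convertible to a timestamp;
    the field is piecewise-constant within each day.  Raises
    :class:`OutOfDomainError` outside the grid bounds.
    """
    if isinstance(time, (int, np.integer)):
        day = int(time)
    else:
        day = int(field.times.get_indexer([pd.Timestamp(time)], method="ffill")[0])
    if day < 0 or day >= field.n_days:
        raise OutOfDomainError(f"time {time!r} outside the field's span")
    u, v, inb = _bilinear_uv(field, [lat], [lon], [day])
    if not inb[0]:
        raise OutOfDomainError(f"position ({lat}, {lon}) outside grid bounds")
    return float(u[0]), float(v[0])


def advect(lat, lon, u, v, dt_seconds: float = 3600.0):
    """One forward-Euler step: displacement u·dt, v·dt converted to degrees.

    The metre-to-degree conversion uses the particle's current latitude
    (equirectangular approximation).
    """
    if dt_seconds <= 0:
        raise ValueError("dt must be positive")
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    dy_km = np.asarray(v) * dt_seconds / 1000.0
    dx_km = np.asarray(u) * dt_seconds / 1000.0
    new_lat = lat + dy_km / KM_PER_DEG
    new_lon = lon + dx_km / (KM_PER_DEG * np.cos(np.radians(lat)))
    return new_lat, new_lon


def _step_km(lat0, lon0, lat1, lon1):
    mid = np.radians(0.5 * (lat0 + lat1))
    dx = (lon1 - lon0) * KM_PER_DEG * np.cos(mid)
    dy = (lat1 - lat0) * KM_PER_DEG
    return np.hypot(dx, dy)


SETTLED, LOST = "settled", "lost"


@dataclass
class TrajectorySet:
    """Outcome of one release experiment.

    ``particles`` is a DataFrame with one row per particle: ``particle_id``,
    ``origin_id``, ``release_day``, ``fate`` ('settled'|'lost'), ``settle_id``
    (nullable), ``drift_days``, ``drift_km``.  ``released`` counts releases
    per origin point.  Hourly tracks are kept only when requested.
    """

    particles: pd.DataFrame
    released: pd.Series
    year: str = ""
    tracks: dict[int, np.ndarray] = field(default_factory=dict)

    @property
    def n_particles(self) -> int:
        return len(self.particles)

    def fate_counts(self) -> pd.Series:
        return self.particles["fate"].value_counts()

    def to_csv(self, path) -> None:
        self.particles.to_csv(path, index=False)


def run_release(
    domain: CoastalDomain,
    field: VelocityFieldSeries,
    release_days=None,
    particles_per_point_per_day: int = 1,
    pld_days: float = 30.0,
    capture_radius_km: float = 2.0,
    min_competency_days: float = 0.0,
    beaching: str = "nearest-point",
    diffusion_km_sqrt_day: float = 0.0,
    seed: int = 0,
    record_tracks: bool = False,
    year: str = "",
) -> TrajectorySet:
    """Release and track particles from every coastal point.

    Parameters
    ----------
    release_days
        Iterable of day indices into ``field.times``; default is every day
        that leaves room for a full PLD.  Must be non-empty and within the
        field's span.
    particles_per_point_per_day
        Particles released from each coastal point on each release day.
    pld_days
        Maximum pelagic larval duration; particles still adrift afterwards
        are lost.
    capture_radius_km
        Radius of the disc-shaped capture zone around each coastal point.
    min_competency_days
        Pre-competency period during which capture-zone settlement is
        disabled (beaching still settles).  With the default of 0 a particle
        can settle at its own origin immediately (full retention under zero
        flow).
    beaching
        'nearest-point' converts a land crossing into settlement at the
        nearest coastal point; 'lost' removes the particle instead.
    diffusion_km_sqrt_day
        Standard deviation of an optional random walk, km per sqrt(day);
        0 keeps the advection fully deterministic.
    """
    n_steps = int(round(pld_days * 24))
    if release_days is None:
        last = field.n_days - 1 - int(math.ceil(pld_days))
        release_days = list(range(0, max(last, 0) + 1))
    release_days = [int(d) for d in release_days]
    if len(release_days) == 0:
        raise ValueError("release schedule is empty")
    for d in release_days:
        if d < 0 or d + int(math.ceil(pld_days)) > field.n_days:
            raise ValueError(
                f"release day {d} (+PLD {pld_days} d) is outside the field's span"
            )
    if beaching not in ("nearest-point", "lost"):
        raise ValueError("beaching must be 'nearest-point' or 'lost'")
    if particles_per_point_per_day < 1:
        raise ValueError("particles_per_point_per_day must be >= 1")

    pts = domain.points
    n_pts = len(pts)
    ppd = particles_per_point_per_day
    origin = np.tile(np.repeat(pts["point_id"].to_numpy(), ppd), len(release_days))
    rel_day = np.repeat(np.asarray(release_days), n_pts * ppd)
    n = len(origin)

    lat = pts["lat"].to_numpy()[origin % n_pts].astype(float).copy()
    lon = pts["lon"].to_numpy()[origin % n_pts].astype(float).copy()

    kx, ky = local_km_factors(domain.ref_lat)
    tree = cKDTree(domain.point_xy_km())

    def to_xy(la, lo):
        return np.column_stack(
            [(lo - domain.lons[0]) * kx, (la - domain.lats[0]) * ky]
        )

    shapely.prepare(domain.polygon)
    land = domain.polygon

    def on_land(la, lo):
        # exact polygon test keeps recorded tracks strictly out of land
        return shapely.contains_xy(land, lo, la)

    rng = np.random.default_rng(seed)
    active = np.ones(n, dtype=bool)
    fate = np.array([""] * n, dtype=object)
    settle_id = np.full(n, -1)
    end_hours = np.zeros(n)
    drift_km = np.zeros(n)
    comp_hours = min_competency_days * 24.0
    tracks: dict[int, list] = {i: [(lat[i], lon[i])] for i in range(n)} if record_tracks else {}

    def settle(mask, ids, hour):
        fate[mask] = SETTLED
        settle_id[mask] = ids
        end_hours[mask] = hour
        active[mask] = False

    # settlement check at release (hour 0): a capture radius > 0 with zero
    # pre-competency retains particles at their origin instantly
    if comp_hours <= 0:
        d0, i0 = tree.query(to_xy(lat, lon))
        hit = d0 <= capture_radius_km
        if hit.any():
            settle(hit, pts["point_id"].to_numpy()[i0[hit]], 0)

    for h in range(1, n_steps + 1):
        if not active.any():
            break
        idx = np.flatnonzero(active)
        day = rel_day[idx] + (h - 1) // 24
        u, v, inb = _bilinear_uv(field, lat[idx], lon[idx], day)

        # out of grid bounds -> lost where interpolation failed
        lost_now = idx[~inb]
        if len(lost_now):
            fate[lost_now] = LOST
            end_hours[lost_now] = h - 1
            active[lost_now] = False
        idx = idx[inb]
        if len(idx) == 0:
            continue
        u, v = u[inb], v[inb]

        new_lat, new_lon = advect(lat[idx], lon[idx], u, v, 3600.0)
        if diffusion_km_sqrt_day > 0:
            sd_km = diffusion_km_sqrt_day * math.sqrt(1.0 / 24.0)
            new_lat = new_lat + rng.normal(0, sd_km, len(idx)) / KM_PER_DEG
            new_lon = new_lon + rng.normal(0, sd_km, len(idx)) / (
                KM_PER_DEG * np.cos(np.radians(new_lat))
            )
        step = _step_km(lat[idx], lon[idx], new_lat, new_lon)

        beached = on_land(new_lat, new_lon)
        water = ~beached
        wsel = idx[water]
        drift_km[idx] += step  # beached particles travelled the step to shore
        lat[wsel] = new_lat[water]
        lon[wsel] = new_lon[water]
        if record_tracks:
            for k, i in enumerate(wsel):
                tracks[i].append((lat[i], lon[i]))

        if beached.any():
            bsel = idx[beached]
            if beaching == "nearest-point":
                _, bi = tree.query(to_xy(new_lat[beached], new_lon[beached]))
                settle(bsel, pts["point_id"].to_numpy()[bi], h)
            else:
                fate[bsel] = LOST
                end_hours[bsel] = h
                active[bsel] = False

        if h >= comp_hours and len(wsel):
            d, pi = tree.query(to_xy(lat[wsel], lon[wsel]))
            hit = d <= capture_radius_km
            if hit.any():
                settle(wsel[hit], pts["point_id"].to_numpy()[pi[hit]], h)

    still = np.flatnonzero(active)
    fate[still] = LOST
    end_hours[still] = n_steps
    active[still] = False

    particles = pd.DataFrame(
        {
            "particle_id": np.arange(n),
            "origin_id": origin,
            "release_day": rel_day,
            "fate": fate,
            "settle_id": pd.array(
                np.where(settle_id >= 0, settle_id, pd.NA), dtype="Int64"
            ),
            "drift_days": end_hours / 24.0,
            "drift_km": drift_km,
        }
    )
    released = particles.groupby("origin_id").size()
    released = released.reindex(pts["point_id"], fill_value=0)
    return TrajectorySet(
        particles=particles,
        released=released,
        year=year,
        tracks={k: np.asarray(v) for k, v in tracks.items()},
    )


@dataclass
class DispersalSummary:
    """Mean ± sample SD and maximum of drift distance and duration."""

    n_settled: int
    n_lost: int
    mean_km: float
    sd_km: float
    max_km: float
    mean_days: float
    sd_days: float
    max_days: float

    def as_dict(self) -> dict:
        return self.__dict__.copy()


def summarize_dispersal(ts: TrajectorySet) -> DispersalSummary:
    """Distance/duration summary over settled particles (sample SD, ddof=1)."""
    if ts.n_particles == 0:
        raise ValueError("empty trajectory set")
    settled = ts.particles[ts.particles["fate"] == SETTLED]
    if len(settled) == 0:
        raise ValueError("no settled particles to summarise")
    km = settled["drift_km"].to_numpy()
    days = settled["drift_days"].to_numpy()
    sd = lambda x: float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
    return DispersalSummary(
        n_settled=len(settled),
        n_lost=int((ts.particles["fate"] == LOST).sum()),
        mean_km=float(km.mean()),
        sd_km=sd(km),
        max_km=float(km.max()),
        mean_days=float(days.mean()),
        sd_days=sd(days),
        max_days=float(days.max()),
    )
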