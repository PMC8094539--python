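"""GPS track processing for central-place foragers.

Builds foraging trips from raw fix tables, quality-filters fixes,
interpolates positions to arbitrary times (e.g. dive start times) and
computes great-circle distances to the colony.

Conventions
-----------
* Fix tables are pandas DataFrames with columns ``bird_id``, ``t``
  (timezone-naive UTC timestamps), ``lat``, ``lon``.
* Distances are haversine on a sphere of radius 6371 km.  At the
  sub-100-km scales of colony-based foraging the difference from an
  ellipsoidal geodesic is < 0.5 %.
* Latitude and longitude are interpolated independently in degrees,
  which is adequate away from the antimeridian and the poles.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy.interpolate import PchipInterpolator
from shapely.geometry import Polygon

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0

__all__ = [
    "EARTH_RADIUS_KM",
    "Colony",
    "Trip",
    "haversine_km",
    "dist_to_colony",
    "flag_on_land",
    "compute_speeds",
    "speed_filter",
    "jump_outlier_filter",
    "segment_trips",
    "interpolate_positions",
    "julian_day",
]


@dataclass
class Colony:
    """A breeding colony: the central place of all trips."""

    name: str
    lat: float
    lon: float
    near_radius_km: float | None = None  # set by models.near_colony_radius


@dataclass
class Trip:
    bird_id: str
    trip_id: str
    t_start: pd.Timestamp
    t_end: pd.Timestamp
    duration_h: float
    fixes: pd.DataFrame = field(repr=False)
    max_distance_km: float = np.nan
    stage: str | None = None
    start_julian: int | None = None
    bracketed: bool = True  # False when no land fix existed on one side


# ---------------------------------------------------------------------------
# distances


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km between coordinate arrays (degrees)."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(a, dtype=float)) for a in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def dist_to_colony(lat, lon, colony: Colony | tuple[float, float]) -> np.ndarray:
    """Distance (km) from positions to the colony."""
    if isinstance(colony, Colony):
        clat, clon = colony.lat, colony.lon
    else:
        clat, clon = colony
    return haversine_km(lat, lon, clat, clon)


# ---------------------------------------------------------------------------
# land masking and fix quality


def flag_on_land(fixes: pd.DataFrame, coastline: Polygon) -> pd.DataFrame:
    """Add an ``on_land`` column: point-in-polygon, boundary counts as land.

    The coastline polygon is in lon/lat vertex order (GeoJSON convention).
    """
    if not coastline.is_valid:
        raise ValueError("coastline polygon is invalid (self-intersecting?)")
    pts = shapely.points(fixes["lon"].to_numpy(), fixes["lat"].to_numpy())
    out = fixes.copy()
    out["on_land"] = shapely.covers(coastline, pts)
    return out


def compute_speeds(fixes: pd.DataFrame) -> pd.DataFrame:
    """Add ``speed_prev`` / ``speed_next`` (m/s) per bird from consecutive fixes."""
    out = fixes.copy()
    out["speed_prev"] = np.nan
    out["speed_next"] = np.nan
    for _, idx in out.groupby("bird_id", sort=False).groups.items():
        sub = out.loc[idx]
        lat = sub["lat"].to_numpy()
        lon = sub["lon"].to_numpy()
        t = sub["t"].astype("int64").to_numpy() / 1e9
        if len(sub) < 2:
            continue
        d_m = haversine_km(lat[:-1], lon[:-1], lat[1:], lon[1:]) * 1000.0
        dt = np.diff(t)
        v = np.where(dt > 0, d_m / np.where(dt > 0, dt, 1.0), np.inf)
        out.loc[idx[1:], "speed_prev"] = v
        out.loc[idx[:-1], "speed_next"] = v
    return out


def speed_filter(fixes: pd.DataFrame, vmax: float = 10.0) -> tuple[pd.DataFrame, int]:
    """Drop fixes whose speeds to BOTH neighbours exceed ``vmax`` (m/s).

    Single pass: offending fixes are identified once, removed together,
    and speeds recomputed once on the survivors.
    """
    fixes = compute_speeds(fixes)
    bad = (fixes["speed_prev"] > vmax) & (fixes["speed_next"] > vmax)
    removed = int(bad.sum())
    kept = compute_speeds(fixes.loc[~bad].copy())
    if removed:
        logger.info("speed_filter removed %d of %d fixes (%.2f%%)", removed, len(fixes), 100 * removed / len(fixes))
    return kept, removed


def jump_outlier_filter(fixes: pd.DataFrame, max_jump_km: float) -> tuple[pd.DataFrame, int]:
    """Drop single fixes far (> max_jump_km) from BOTH neighbours while the
    neighbours are near each other.  Deterministic stand-in for manual
    inspection of isolated implausible points; off by default in the pipeline.
    Two consecutive displaced fixes are deliberately kept (rule targets
    single points) — a warning is logged when that pattern is seen.
    """
    drop: list[int] = []
    for _, idx in fixes.groupby("bird_id", sort=False).groups.items():
        sub = fixes.loc[idx]
        lat = sub["lat"].to_numpy()
        lon = sub["lon"].to_numpy()
        n = len(sub)
        for i in range(1, n - 1):
            d_prev = haversine_km(lat[i], lon[i], lat[i - 1], lon[i - 1])
            d_next = haversine_km(lat[i], lon[i], lat[i + 1], lon[i + 1])
            d_span = haversine_km(lat[i - 1], lon[i - 1], lat[i + 1], lon[i + 1])
            if d_prev > max_jump_km and d_next > max_jump_km and d_span <= max_jump_km:
                drop.append(idx[i])
            elif (d_prev > max_jump_km) != (d_next > max_jump_km):
                # one long leg only: start or end of a displaced run of >= 2
                # fixes, which the single-point rule deliberately keeps
                logger.warning("consecutive displaced fixes near index %s kept (single-point rule)", idx[i])
    kept = fixes.drop(index=drop)
    return kept, len(drop)


# ---------------------------------------------------------------------------
# trips


def segment_trips(
    fixes: pd.DataFrame,
    min_fixes: int = 10,
    min_span_s: float = 3600.0,
) -> list[Trip]:
    """Cut each bird's fix sequence into foraging trips.

    A trip is a maximal run of consecutive at-sea fixes with at least
    ``min_fixes`` fixes spanning at least ``min_span_s`` seconds.  Trip
    start/end use the bracketing land fixes when they exist; otherwise the
    first/last at-sea fix is used and the trip flagged unbracketed.
    """
    if "on_land" not in fixes.columns:
        raise ValueError("fixes need an on_land column (run flag_on_land first)")
    trips: list[Trip] = []
    for bird, sub in fixes.groupby("bird_id", sort=False):
        sub = sub.sort_values("t").reset_index(drop=True)
        at_sea = ~sub["on_land"].to_numpy()
        # run boundaries of at-sea stretches
        padded = np.concatenate([[False], at_sea, [False]])
        starts = np.flatnonzero(padded[1:] & ~padded[:-1])
        ends = np.flatnonzero(~padded[1:] & padded[:-1])  # exclusive
        k = 0
        for s, e in zip(starts, ends):
            run = sub.iloc[s:e]
            span = (run["t"].iloc[-1] - run["t"].iloc[0]).total_seconds()
            if len(run) < min_fixes or span < min_span_s:
                continue
            bracketed = True
            if s > 0:
                t0 = sub["t"].iloc[s - 1]
            else:
                t0 = run["t"].iloc[0]
                bracketed = False
            if e < len(sub):
                t1 = sub["t"].iloc[e]
            else:
                t1 = run["t"].iloc[-1]
                bracketed = False
            if not bracketed:
                logger.info("trip of bird %s lacks a bracketing land fix; using at-sea endpoints", bird)
            k += 1
            trips.append(
                Trip(
                    bird_id=str(bird),
                    trip_id=f"{bird}_T{k:02d}",
                    t_start=t0,
                    t_end=t1,
                    duration_h=(t1 - t0).total_seconds() / 3600.0,
                    fixes=run,
                    bracketed=bracketed,
                )
            )
    return trips


# ---------------------------------------------------------------------------
# interpolation


def interpolate_positions(
    fixes: pd.DataFrame,
    query_times: pd.Series | np.ndarray,
    max_gap_s: float = 3600.0,
) -> pd.DataFrame:
    """Interpolate lat/lon to ``query_times`` by monotone (shape-preserving)
    piecewise cubic Hermite interpolation on time.

    Queries outside the fix span, or falling inside an inter-fix gap longer
    than ``max_gap_s``, come back as NaN with a reason string.
    """
    sub = fixes.sort_values("t")
    if len(sub) < 2:
        raise ValueError("need at least 2 fixes to interpolate")
    t = sub["t"].astype("int64").to_numpy() / 1e9
    if np.any(np.diff(t) <= 0):
        keep = np.concatenate([[True], np.diff(t) > 0])
        sub = sub.loc[keep]
        t = t[keep]
    f_lat = PchipInterpolator(t, sub["lat"].to_numpy())
    f_lon = PchipInterpolator(t, sub["lon"].to_numpy())
    q = pd.to_datetime(pd.Series(np.asarray(query_times))).astype("int64").to_numpy() / 1e9

    lat = np.full(q.shape, np.nan)
    lon = np.full(q.shape, np.nan)
    reason = np.full(q.shape, "", dtype=object)
    inside = (q >= t[0]) & (q <= t[-1])
    reason[~inside] = "outside_fix_span"
    # gap test: the fix interval containing each query
    left = np.searchsorted(t, q[inside], side="right") - 1
    left = np.clip(left, 0, len(t) - 2)
    gap = t[left + 1] - t[left]
    ok = gap <= max_gap_s
    idx_in = np.flatnonzero(inside)
    reason[idx_in[~ok]] = "gps_gap"
    good = idx_in[ok]
    lat[good] = f_lat(q[good])
    lon[good] = f_lon(q[good])
    return pd.DataFrame({"lat": lat, "lon": lon, "reason": reason})


# ---------------------------------------------------------------------------
# dates


def julian_day(date: _dt.date | pd.Timestamp) -> int:
    """Day-of-year, with +365 added in January/February so the austral
    breeding season (Dec-Feb) is a continuous axis.
    """
    ts = pd.Timestamp(date)
    if ts.month not in (12, 1, 2):
        raise ValueError(f"{ts.date()} outside the Dec-Feb season window")
    doy = ts.timetuple().tm_yday
    if ts.month in (1, 2):
        doy += 365
    return int(doy)
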