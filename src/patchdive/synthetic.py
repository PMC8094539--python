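"""Synthetic GPS + TDR data with known ground truth.

Emulates a colony of central-place foraging divers: out-and-back trips
from an island colony, three dive types (travel / explore / forage) with
the measured population mean structure, bouts of foraging dives separated
by short surface pauses, surface pauses growing exponentially with dive
duration (s = b*exp(c*u)), and a patch-quality field that increases with
distance from the colony (a depletion "halo") and with date near the
colony.  Forage dive durations follow from optimal time allocation: given
a patch quality x and transit time tau, the dive duration maximizes the
long-run gain rate (u - tau)^x / (u + b*exp(c*u)), so the downstream
inverse-optimality index can be validated by parameter recovery.

Instrument artefacts are included: linear TDR pressure drift per trip,
GPS dropouts (satellite gaps) and isolated large position outliers.

The patch-quality field is parameterized on the sqrt-IPQ scale, because
the hypothesis battery models sqrt-transformed IPQ; its slopes are then
directly comparable with the generator's.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from shapely.geometry import Polygon, mapping

from .tracks import haversine_km

logger = logging.getLogger(__name__)

__all__ = [
    "DiveTypeParams",
    "World",
    "GeneratorConfig",
    "default_world",
    "forward_optimal_duration",
    "sample_dive_metrics",
    "simulate_dive_trace",
    "simulate_trip",
    "simulate_dataset",
]

KM_PER_DEG_LAT = 111.19492664455873  # 2*pi*R/360 with R = 6371 km

DIVE_TYPES = ("travel", "explore", "forage")


@dataclass(frozen=True)
class DiveTypeParams:
    """Mean/SD structure of one dive type (durations s, depths m)."""

    duration_mean: float
    duration_sd: float
    depth_mean: float
    depth_sd: float
    bottom_mean: float
    bottom_sd: float


#: Population mean structure of the three dive types.  Means are the
#: measured cluster means for chinstrap penguins; SDs are generator
#: choices (the field data report standard errors only) giving realistic
#: within-type spread while keeping the types distinct.
DEFAULT_TYPE_PARAMS: dict[str, DiveTypeParams] = {
    "travel": DiveTypeParams(23.9, 4.5, 5.6, 1.3, 2.3, 0.8),
    "explore": DiveTypeParams(69.8, 9.0, 22.3, 4.5, 9.3, 2.5),
    "forage": DiveTypeParams(112.4, 13.0, 61.6, 8.5, 16.0, 4.0),
}

DEFAULT_WEIGHTS: dict[str, float] = {"travel": 0.40, "explore": 0.39, "forage": 0.21}


@dataclass(frozen=True)
class World:
    """The environment: island, colonies, and the patch-quality field.

    ``halo_slope`` and ``seasonal_slope`` are in sqrt-IPQ units per km and
    per day; ``halo_intercept`` is sqrt-IPQ at the colony at season start.
    """

    colonies: dict[str, tuple[float, float]]  # name -> (lat, lon)
    coastline: tuple[tuple[float, float], ...]  # (lat, lon) vertices, closed ring
    halo_slope: float = 0.0015
    halo_intercept: float = 0.32
    seasonal_slope: float = 0.0041
    season_start: pd.Timestamp = pd.Timestamp("2015-12-01")

    def __post_init__(self):
        if self.halo_intercept <= 0:
            raise ValueError("halo_intercept must be > 0")
        poly = self.polygon()
        if not poly.is_valid:
            raise ValueError("coastline polygon is not simple")
        for name, (lat, lon) in self.colonies.items():
            if not poly.covers(_point(lon, lat)):
                raise ValueError(f"colony {name} lies outside the coastline")

    @property
    def colony_position(self) -> tuple[float, float]:
        return next(iter(self.colonies.values()))

    def polygon(self) -> Polygon:
        return Polygon([(lon, lat) for lat, lon in self.coastline])

    def sqrt_x_field(self, dist_km, day, rng=None, noise_sd: float = 0.0):
        """sqrt(patch quality) at a distance from the colony on a season day."""
        v = self.halo_intercept + self.halo_slope * np.asarray(dist_km) + self.seasonal_slope * np.asarray(day)
        if rng is not None and noise_sd > 0:
            v = v + rng.normal(0.0, noise_sd, size=np.shape(v))
        return np.maximum(v, 0.15)


def _point(lon, lat):
    from shapely.geometry import Point

    return Point(lon, lat)


def default_world() -> World:
    """A convex island ~5 km across with two colonies, at 60.7 S, 45.6 W."""
    clat, clon = -60.70, -45.60
    r_km = 2.5
    ang = np.linspace(0, 2 * np.pi, 25)[:-1]
    lat = clat + (r_km * np.cos(ang)) / KM_PER_DEG_LAT
    lon = clon + (r_km * np.sin(ang)) / (KM_PER_DEG_LAT * math.cos(math.radians(clat)))
    ring = tuple(zip(lat.tolist(), lon.tolist()))
    colonies = {
        "North": (clat + 1.9 / KM_PER_DEG_LAT, clon),
        "South": (clat - 1.9 / KM_PER_DEG_LAT, clon),
    }
    return World(colonies=colonies, coastline=ring)


@dataclass(frozen=True)
class GeneratorConfig:
    n_birds: int = 12
    trips_per_bird: int = 2
    stage_fractions: tuple[float, float, float] = (0.30, 0.58, 0.12)  # incubation, brood, transition
    weights: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))
    type_params: dict[str, DiveTypeParams] = field(default_factory=lambda: dict(DEFAULT_TYPE_PARAMS))
    b_true: float = 20.0  # s
    c_true: float = 0.01  # 1/s
    pause_noise_sd: float = 0.10  # lognormal sigma on forage pauses; 0 => exact pause law
    gps_interval_s: float = 240.0
    tdr_interval_s: float = 1.0
    tdr_noise_sd: float = 0.05  # m
    drift_per_trip_m: float = 3.0  # linear pressure drift across a trip
    outlier_rate: float = 0.005  # per retained fix
    gap_rate: float = 0.008  # chance a fix starts a dropout block
    gps_noise_m: float = 25.0
    vertical_rate_ms: float = 1.0  # effective transit rate to/from the bottom phase
    entry_depth_m: float = 1.2
    travel_speed_ms: float = 2.0
    max_range_incubation_km: float = 30.0
    max_range_brood_km: float = 12.0
    field_noise_sd: float = 0.06  # sqrt-IPQ units, patch-to-patch
    dive_noise_sd: float = 0.03  # sqrt-IPQ units, dive-to-dive within a patch
    bout_size_per_x: float = 24.0  # mean extra dives per unit patch quality
    wiggle_per_x_m: float = 4.0
    stage_depth_shift_m: dict[str, float] = field(
        default_factory=lambda: {"incubation": -6.0, "brood": 5.0, "transition": 0.0}
    )
    deploy_day_window: tuple[float, float] = (3.0, 60.0)  # days after season start, all stages
    seed: int | None = None

    def __post_init__(self):
        w = sum(self.weights.values())
        if abs(w - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if self.gps_interval_s <= 0 or self.tdr_interval_s <= 0:
            raise ValueError("sampling intervals must be positive")
        for name, p in self.type_params.items():
            if min(p.duration_sd, p.depth_sd, p.bottom_sd) <= 0:
                raise ValueError(f"SDs for {name} must be positive")


# ---------------------------------------------------------------------------
# optimal diving forward model


def forward_optimal_duration(
    x: float, tau: float, b: float, c: float, u_max: float = 3600.0
) -> float:
    """Rate-maximizing dive duration for patch quality x and transit tau.

    Maximizes (u - tau)^x / (u + b*exp(c*u)) over u in (tau, u_max] by
    bounded 1-D optimization of the log rate.  Raises when no interior
    maximum exists on the interval (x too large for the given b, c).
    """
    if x <= 0:
        raise ValueError("x must be positive")
    if tau < 0 or b <= 0 or c <= 0:
        raise ValueError("require tau >= 0, b > 0, c > 0")

    logb = math.log(b)

    def neg_log_rate(u):
        return -(x * math.log(u - tau) - np.logaddexp(math.log(u), logb + c * u))

    res = minimize_scalar(
        neg_log_rate, bounds=(tau + 1e-9, u_max), method="bounded", options={"xatol": 1e-8}
    )
    u_star = float(res.x)
    if u_max - u_star < 1e-2:
        raise RuntimeError(
            f"no interior optimum below {u_max} s for x={x}, tau={tau}, b={b}, c={c}"
        )
    return u_star


# ---------------------------------------------------------------------------
# dive metric sampling (the population mixture)


def _truncated_normal(rng, mean, sd, lo, hi, size):
    out = rng.normal(mean, sd, size=size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def sample_dive_metrics(n: int, config: GeneratorConfig | None = None, seed: int = 0) -> pd.DataFrame:
    """Draw n dives (duration, max depth, bottom time) from the three-type
    mixture; ``true_type`` records the generating component."""
    config = config or GeneratorConfig()
    rng = np.random.default_rng(seed)
    names = list(config.weights)
    counts = rng.multinomial(n, [config.weights[k] for k in names])
    frames = []
    for name, m in zip(names, counts):
        p = config.type_params[name]
        u = _truncated_normal(rng, p.duration_mean, p.duration_sd, 6.0, np.inf, m)
        d = _truncated_normal(rng, p.depth_mean, p.depth_sd, 1.2, np.inf, m)
        bt = _truncated_normal(rng, p.bottom_mean, p.bottom_sd, 0.5, np.inf, m)
        bt = np.minimum(bt, 0.6 * u)
        frames.append(pd.DataFrame({"u": u, "max_depth": d, "bottom_time": bt, "true_type": name}))
    out = pd.concat(frames, ignore_index=True)
    return out.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(drop=True)


# ---------------------------------------------------------------------------
# dive traces


@dataclass
class TruthDive:
    """Generator-side truth for one dive."""

    dive_type: str
    t_offset_s: float  # start, seconds from trip start
    u_true: float
    tau_true: float
    s_true: float  # post-dive surface interval actually placed
    depth_m: float
    bottom_true: float
    true_x: float = np.nan  # forage dives only
    lat: float = np.nan
    lon: float = np.nan
    dist_km: float = np.nan
    in_bout_true: bool = False
    bout_id_true: int = -1
    wiggle_amp_m: float = 0.0

    def __post_init__(self):
        if self.dive_type == "forage":
            if not self.u_true > self.tau_true:
                raise ValueError("forage dive must have positive bottom time")
            if not self.true_x >= 0:
                raise ValueError("forage dive needs a non-negative patch quality")
        if self.s_true is not None and not np.isnan(self.s_true) and self.s_true <= 0:
            raise ValueError("surface interval must be positive")


def simulate_dive_trace(
    truth: TruthDive,
    tdr_interval_s: float = 1.0,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    entry_depth_m: float = 1.2,
) -> np.ndarray:
    """Depth samples for one dive (length round(u/dt), all >= entry depth).

    The profile enters at ``entry_depth_m`` immediately (so detection at a
    ~1 m threshold recovers the full duration), transits to 80 % of max
    depth over tau/2 on each side, and spends u - tau in the bottom phase
    (a slow final descent/ascent plus a wiggling segment whose amplitude
    encodes patch quality for forage dives).  Max depth, duration and the
    0.8-fraction bottom time therefore match the truth within one sample.
    """
    dt = tdr_interval_s
    u, d, tau = truth.u_true, truth.depth_m, truth.tau_true
    if u < 3 * dt:
        raise ValueError("dive too short for the sampling interval")
    n = max(int(round(u / dt)), 3)
    t = np.arange(n) * dt
    entry = min(entry_depth_m, 0.5 * d)
    d08 = 0.8 * d
    rem = max(u - tau, 2 * dt)
    a1 = tau / 2.0
    a2 = 0.25 * rem
    m_flat = rem - 2 * a2
    w = min(truth.wiggle_amp_m, 0.15 * d)
    k_wig = max(1, int(round(m_flat / 6.0))) if w > 0 else 0

    depth = np.empty(n)
    t1, t2, t3, t4 = a1, a1 + a2, a1 + a2 + m_flat, a1 + 2 * a2 + m_flat
    for i, ti in enumerate(t):
        if ti < t1:
            depth[i] = entry + (d08 - entry) * ti / max(a1, dt)
        elif ti < t2:
            depth[i] = d08 + (d - d08) * (ti - t1) / a2
        elif ti < t3:
            s = (ti - t2) / max(m_flat, dt)
            depth[i] = d - (0.5 * w) * (1 - math.cos(2 * math.pi * k_wig * s)) if w > 0 else d
        elif ti < t4:
            depth[i] = d - (d - d08) * (ti - t3) / a2
        else:
            depth[i] = max(d08 - (d08 - entry) * (ti - t4) / max(a1, dt), entry)
    depth[np.argmax(depth)] = d
    if noise_sd > 0 and rng is not None:
        depth = depth + rng.normal(0.0, noise_sd, n)
        depth = np.maximum(depth, entry)
    return depth


# ---------------------------------------------------------------------------
# trips


def _local_to_latlon(colony: tuple[float, float], east_km, north_km):
    lat0, lon0 = colony
    lat = lat0 + np.asarray(north_km) / KM_PER_DEG_LAT
    lon = lon0 + np.asarray(east_km) / (KM_PER_DEG_LAT * math.cos(math.radians(lat0)))
    return lat, lon


def _draw_type_dive(rng, p: DiveTypeParams):
    u = float(_truncated_normal(rng, p.duration_mean, p.duration_sd, 6.0, np.inf, 1)[0])
    d = float(_truncated_normal(rng, p.depth_mean, p.depth_sd, 1.5, np.inf, 1)[0])
    bt = float(_truncated_normal(rng, p.bottom_mean, p.bottom_sd, 0.5, np.inf, 1)[0])
    bt = min(bt, 0.6 * u)
    return u, d, bt


def _pause(rng, config: GeneratorConfig, u: float, extra_noise: float = 0.0) -> float:
    s = config.b_true * math.exp(config.c_true * u)
    sd = config.pause_noise_sd + extra_noise
    if sd > 0:
        s *= math.exp(rng.normal(0.0, sd))
    return s


def simulate_trip(
    world: World,
    config: GeneratorConfig,
    stage: str,
    date: pd.Timestamp,
    rng: np.random.Generator,
    colony_name: str | None = None,
    max_attempts: int = 5,
    include_tdr: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame, list[TruthDive], dict]:
    """One out-and-back foraging trip.

    Returns (gps fixes, tdr series, truth dives, trip truth dict).  Fix and
    depth tables carry no bird id (the dataset assembler adds it).  With
    ``include_tdr=False`` the depth trace is skipped (empty frame) — handy
    for studies that work from the truth tables directly.
    """
    for attempt in range(max_attempts):
        try:
            return _simulate_trip_once(world, config, stage, date, rng, colony_name, include_tdr)
        except RuntimeError as err:  # trip left the simulation bounding box
            logger.warning("trip rejected (%s); regenerating (attempt %d)", err, attempt + 1)
    raise RuntimeError("failed to generate an in-bounds trip")


def _simulate_trip_once(world, config, stage, date, rng, colony_name, include_tdr=True):
    colony_name = colony_name or next(iter(world.colonies))
    colony = world.colonies[colony_name]
    day0 = (date - world.season_start).total_seconds() / 86400.0

    if stage == "incubation":
        base = config.max_range_incubation_km
    else:  # brood and transition birds make short trips
        base = config.max_range_brood_km
    # constructive bound: destination + patch meander (< 2.2 km) + GPS noise
    # always stay inside the configured maximum range
    D = base * rng.uniform(0.35, 0.88)
    if D > 200.0:
        raise RuntimeError(f"destination {D:.0f} km outside bounding box")
    bearing = rng.uniform(0, 2 * math.pi)

    v = config.travel_speed_ms
    t_out = D * 1000.0 / v

    # --- event sequence -----------------------------------------------------
    travel_p = config.type_params["travel"]
    explore_p = config.type_params["explore"]
    forage_p = config.type_params["forage"]
    dshift = config.stage_depth_shift_m.get(stage, 0.0)

    dives: list[TruthDive] = []

    def emit_travel(t, until):
        while t < until:
            u, d, bt = _draw_type_dive(rng, travel_p)
            s = _pause(rng, config, u, extra_noise=0.1)
            dives.append(TruthDive("travel", t, u, u - bt, s, d, bt))
            t += u + s
        return t

    t = emit_travel(0.0, t_out)
    n_travel_out = len(dives)
    n_travel = 2 * n_travel_out
    n_forage = max(int(round(n_travel * config.weights["forage"] / config.weights["travel"])), 4)
    n_explore = max(int(round(n_travel * config.weights["explore"] / config.weights["travel"])), 4)

    t_forage_start = t
    bout_counter = 0
    f_left, e_left = n_forage, n_explore

    def emit_patch(t, bout_id):
        """A visit to one prey patch: the better the patch, the more dives.

        Patch quality comes from the halo/seasonal field at the patch
        position; the number of dives is 1 + Poisson(bout_size_per_x * x),
        so runs of length 1 (non-bout single dives) arise naturally in
        poor patches and bout size grows with patch quality.
        """
        nonlocal f_left
        dist = math.hypot(*_meander_offset(rng)) + D  # patch near the destination
        day = day0 + t / 86400.0
        sx_patch = float(world.sqrt_x_field(dist, day, rng=rng, noise_sd=config.field_noise_sd))
        size = 1 + int(rng.poisson(config.bout_size_per_x * sx_patch**2))
        size = min(size, f_left)  # may truncate the last patch of the trip
        in_bout = size >= 2
        for j in range(size):
            d = float(_truncated_normal(rng, forage_p.depth_mean + dshift, forage_p.depth_sd, 10.0, np.inf, 1)[0])
            tau = 2.0 * (0.8 * d - config.entry_depth_m) / config.vertical_rate_ms
            sx = sx_patch + (rng.normal(0.0, config.dive_noise_sd) if config.dive_noise_sd > 0 else 0.0)
            x = max(sx, 0.15) ** 2
            u = forward_optimal_duration(x, tau, config.b_true, config.c_true)
            s = _pause(rng, config, u)
            if in_bout and j < size - 1:
                s = min(s, 320.0)  # keep within-bout pauses under the threshold
            dives.append(
                TruthDive(
                    "forage", t, u, tau, s, d, u - tau, true_x=x,
                    in_bout_true=in_bout, bout_id_true=bout_id if in_bout else -1,
                    wiggle_amp_m=config.wiggle_per_x_m * x,
                )
            )
            f_left -= 1
            t += u + s
            if f_left == 0:
                break
        return t

    def emit_explore(t, n_in_run):
        nonlocal e_left
        for _ in range(n_in_run):
            u, d, bt = _draw_type_dive(rng, explore_p)
            s = _pause(rng, config, u, extra_noise=0.1)
            dives.append(TruthDive("explore", t, u, u - bt, s, d, bt))
            e_left -= 1
            t += u + s
            if e_left == 0:
                break
        return t

    while f_left > 0 or e_left > 0:
        if f_left > 0:
            t = emit_patch(t, bout_counter)
            bout_counter += 1
            t += rng.uniform(360.0, 900.0)  # inter-patch surface interval (> threshold)
        if e_left > 0:
            t = emit_explore(t, min(3 + rng.poisson(5.0), e_left))
            t += rng.uniform(60.0, 240.0)

    t_forage_end = t
    t = emit_travel(t, t + t_out)
    trip_T = t

    # --- positions -----------------------------------------------------------
    # meander path around the destination at 60-s knots
    T_f = t_forage_end - t_forage_start
    n_knots = max(int(T_f / 60.0) + 2, 2)
    steps = rng.normal(0.0, 0.05, size=(n_knots, 2)).cumsum(axis=0)
    steps -= steps.mean(axis=0)
    steps = np.clip(steps, -1.5, 1.5)
    dest = np.array([D * math.sin(bearing), D * math.cos(bearing)])

    def pos_at(ts):
        ts = np.asarray(ts, dtype=float)
        e = np.empty_like(ts)
        nn = np.empty_like(ts)
        out_m = ts < t_forage_start
        f_m = (ts >= t_forage_start) & (ts < t_forage_end)
        back_m = ts >= t_forage_end
        frac_out = np.clip(ts[out_m] / t_out, 0, 1)
        e[out_m] = dest[0] * frac_out
        nn[out_m] = dest[1] * frac_out
        ki = np.clip(((ts[f_m] - t_forage_start) / 60.0).astype(int), 0, n_knots - 1)
        e[f_m] = dest[0] + steps[ki, 0]
        nn[f_m] = dest[1] + steps[ki, 1]
        frac_back = np.clip((ts[back_m] - t_forage_end) / t_out, 0, 1)
        e[back_m] = dest[0] * (1 - frac_back)
        nn[back_m] = dest[1] * (1 - frac_back)
        return e, nn

    # dive positions
    dive_t = np.array([dv.t_offset_s for dv in dives])
    de, dn = pos_at(dive_t)
    dlat, dlon = _local_to_latlon(colony, de, dn)
    ddist = haversine_km(dlat, dlon, colony[0], colony[1])
    for dv, la, lo, di in zip(dives, dlat, dlon, ddist):
        dv.lat, dv.lon, dv.dist_km = float(la), float(lo), float(di)

    # GPS fixes
    fix_times = [-2 * config.gps_interval_s, -config.gps_interval_s]
    ti = 0.0
    while ti <= trip_T:
        fix_times.append(ti + rng.normal(0, 5.0))
        if rng.uniform() < config.gap_rate:
            ti += config.gps_interval_s * rng.integers(9, 25)  # dropout block
        else:
            ti += config.gps_interval_s
    fix_times += [trip_T + config.gps_interval_s, trip_T + 2 * config.gps_interval_s]
    fix_times = np.array(sorted(fix_times))
    at_sea = (fix_times >= 0) & (fix_times <= trip_T)
    fe = np.zeros_like(fix_times)
    fn = np.zeros_like(fix_times)
    fe[at_sea], fn[at_sea] = pos_at(fix_times[at_sea])
    noise = rng.normal(0.0, config.gps_noise_m / 1000.0, size=(len(fix_times), 2))
    fe += noise[:, 0]
    fn += noise[:, 1]
    outlier = (rng.uniform(size=len(fix_times)) < config.outlier_rate) & at_sea
    if outlier.any():
        r = rng.uniform(15.0, 60.0, size=int(outlier.sum()))
        a = rng.uniform(0, 2 * math.pi, size=int(outlier.sum()))
        fe[outlier] += r * np.sin(a)
        fn[outlier] += r * np.cos(a)
    flat, flon = _local_to_latlon(colony, fe, fn)
    fixes = pd.DataFrame(
        {
            "t": date + pd.to_timedelta(fix_times, unit="s"),
            "lat": flat,
            "lon": flon,
            "outlier_true": outlier,
        }
    )

    # TDR series
    if include_tdr:
        dt = config.tdr_interval_s
        n_samp = int(trip_T / dt) + 1
        depth = np.abs(rng.normal(0.0, 0.02, n_samp))
        for dv in dives:
            i0 = int(round(dv.t_offset_s / dt))
            trace = simulate_dive_trace(dv, dt, noise_sd=config.tdr_noise_sd, rng=rng, entry_depth_m=config.entry_depth_m)
            i1 = min(i0 + len(trace), n_samp)
            depth[i0:i1] = trace[: i1 - i0]
        drift = np.linspace(0.0, config.drift_per_trip_m, n_samp)
        tdr = pd.DataFrame(
            {
                "t": date + pd.to_timedelta(np.arange(n_samp) * dt, unit="s"),
                "depth": depth + drift,
            }
        )
    else:
        tdr = pd.DataFrame({"t": pd.Series([], dtype="datetime64[ns]"), "depth": pd.Series([], dtype=float)})

    trip_truth = {
        "colony": colony_name,
        "stage": stage,
        "t_start": date,
        "t_end": date + pd.to_timedelta(trip_T, unit="s"),
        "duration_h": trip_T / 3600.0,
        "max_dist_true_km": float(ddist.max()),
        "n_dives": len(dives),
    }
    return fixes, tdr, dives, trip_truth


def _meander_offset(rng):
    off = np.clip(rng.normal(0.0, 1.0, 2), -1.5, 1.5)
    return float(off[0]), float(off[1])


# ---------------------------------------------------------------------------
# dataset assembly


def _assign_stages(n_birds: int, fractions: tuple[float, float, float]) -> list[str]:
    n_inc = int(round(fractions[0] * n_birds))
    n_trans = int(round(fractions[2] * n_birds))
    n_brood = n_birds - n_inc - n_trans
    return ["incubation"] * n_inc + ["brood"] * n_brood + ["transition"] * n_trans


def simulate_dataset(
    config: GeneratorConfig,
    world: World | None = None,
    seed: int = 0,
    outdir: str | Path | None = None,
    include_tdr: bool = True,
) -> dict[str, pd.DataFrame]:
    """Simulate a whole deployment season; optionally write it to disk.

    Returns a dict of tables: gps, tdr, metadata, truth_dives, truth_trips
    (plus the world, under key ``"world"``).  Deterministic given seed.
    """
    world = world or default_world()
    rng = np.random.default_rng(seed)
    stages = _assign_stages(config.n_birds, config.stage_fractions)
    colony_names = list(world.colonies)

    gps_parts, tdr_parts, dive_rows, trip_rows, meta_rows = [], [], [], [], []
    for i in range(config.n_birds):
        bird = f"B{i + 1:03d}"
        stage = stages[i]
        colony = colony_names[i % len(colony_names)]
        # a common deployment window for all stages keeps date, stage and
        # distance effects separately identifiable (see docs/methods.md)
        day = rng.uniform(*config.deploy_day_window)
        t_next = world.season_start + pd.to_timedelta(day * 86400 + rng.uniform(0, 3600 * 6), unit="s")
        trip_stage = {"transition": "brood"}.get(stage, stage)  # transition birds behave brood-like at sea
        for j in range(config.trips_per_bird):
            fixes, tdr, dives, trip_truth = simulate_trip(
                world, config, trip_stage, t_next, rng, colony, include_tdr=include_tdr
            )
            trip_id = f"{bird}_T{j + 1:02d}"
            fixes.insert(0, "bird_id", bird)
            tdr.insert(0, "bird_id", bird)
            gps_parts.append(fixes)
            tdr_parts.append(tdr)
            trip_truth.update({"bird_id": bird, "trip_id": trip_id, "stage": stage})
            trip_rows.append(trip_truth)
            for k, dv in enumerate(dives):
                dive_rows.append(
                    {
                        "bird_id": bird,
                        "trip_id": trip_id,
                        "dive_idx": k,
                        "t_start": trip_truth["t_start"] + pd.to_timedelta(dv.t_offset_s, unit="s"),
                        "dive_type": dv.dive_type,
                        "u_true": dv.u_true,
                        "tau_true": dv.tau_true,
                        "s_true": dv.s_true,
                        "depth_true": dv.depth_m,
                        "bottom_true": dv.bottom_true,
                        "true_x": dv.true_x,
                        "lat": dv.lat,
                        "lon": dv.lon,
                        "dist_km": dv.dist_km,
                        "in_bout_true": dv.in_bout_true,
                        "bout_id_true": dv.bout_id_true,
                    }
                )
            t_next = trip_truth["t_end"] + pd.to_timedelta(rng.uniform(4, 18) * 3600, unit="s")
        meta_rows.append(
            {
                "bird_id": bird,
                "colony": colony,
                "stage_deploy": "incubation" if stage in ("incubation", "transition") else "brood",
                "stage_retrieve": "brood" if stage in ("brood", "transition") else "incubation",
                "stage": stage,
            }
        )

    data = {
        "gps": pd.concat(gps_parts, ignore_index=True),
        "tdr": pd.concat(tdr_parts, ignore_index=True),
        "metadata": pd.DataFrame(meta_rows),
        "truth_dives": pd.DataFrame(dive_rows),
        "truth_trips": pd.DataFrame(trip_rows),
        "world": world,
    }
    if outdir is not None:
        write_dataset(data, outdir)
    return data


def truth_dive_table(data: dict) -> pd.DataFrame:
    """Recast the generator's truth dives as a pipeline-style dive table.

    Lets the IPQ and modelling stages run on exact dive quantities (no
    detection error), which is how parameter-recovery studies isolate
    those stages.
    """
    td = data["truth_dives"]
    meta = data["metadata"].set_index("bird_id")
    out = pd.DataFrame(
        {
            "bird_id": td["bird_id"],
            "trip_id": td["trip_id"],
            "start_time": td["t_start"],
            "u": td["u_true"],
            "tau": td["tau_true"],
            "s_post": td["s_true"],
            "max_depth": td["depth_true"],
            "bottom_time": td["bottom_true"],
            "dive_type": td["dive_type"],
            "dist_to_colony": td["dist_km"],
            "true_x": td["true_x"],
        }
    )
    out["colony"] = out["bird_id"].map(meta["colony"])
    out["stage"] = out["bird_id"].map(meta["stage"])
    return out


_DATE_FMT = "%Y-%m-%dT%H:%M:%S.%f"


def write_dataset(data: dict, outdir: str | Path) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    data["gps"][["bird_id", "t", "lat", "lon"]].to_csv(out / "gps.csv", index=False, date_format=_DATE_FMT)
    data["tdr"].rename(columns={"depth": "depth_m"}).to_csv(out / "tdr.csv", index=False, date_format=_DATE_FMT)
    data["metadata"].to_csv(out / "metadata.csv", index=False)
    data["truth_dives"].to_csv(out / "truth_dives.csv", index=False, date_format=_DATE_FMT)
    data["truth_trips"].to_csv(out / "truth_trips.csv", index=False, date_format=_DATE_FMT)
    world: World = data["world"]
    gj = {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature", "properties": {"name": "island"}, "geometry": mapping(world.polygon())}
        ],
    }
    (out / "coastline.geojson").write_text(json.dumps(gj, sort_keys=True))
    colonies = pd.DataFrame(
        [{"colony": k, "lat": v[0], "lon": v[1]} for k, v in world.colonies.items()]
    )
    colonies.to_csv(out / "colonies.csv", index=False)
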