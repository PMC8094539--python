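"""Dive extraction from time-depth-recorder (TDR) traces.

A depth series is a DataFrame with columns ``t`` (UTC timestamps, strictly
increasing) and ``depth`` (metres, positive down), typically at 1 Hz.
Pressure sensors drift with temperature, so traces are zero-offset
corrected before dives are detected as excursions below a depth threshold.

Per-dive metrics follow the usual biologging conventions: the bottom phase
is the contiguous span from the first to the last sample at or below
``bottom_fraction`` of the maximum depth; descent and ascent are the
transit to and from that span; bottom vertical distance is the summed
absolute depth change within it (a "wiggle" proxy for prey pursuit).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "zero_offset_correct",
    "detect_dives",
    "dive_metrics",
    "filter_impossible",
]

#: defaults for dive detection; the travel-dive mode (~5.6 m, ~24 s) must
#: remain detectable, so the floor sits well below it.
DEPTH_THRESHOLD_M = 1.0
MIN_DURATION_S = 5.0
BOTTOM_FRACTION = 0.8
ZOC_WINDOW_S = 900.0
SURFACE_QUANTILE = 0.05
#: offsets are only trusted where the window's low quantile is near-surface
_NEAR_SURFACE_CAP_M = 10.0
MAX_DEPTH_CAP_M = 200.0
MAX_DURATION_CAP_S = 360.0


def _times_seconds(series: pd.DataFrame) -> np.ndarray:
    return series["t"].astype("int64").to_numpy() / 1e9


def zero_offset_correct(
    series: pd.DataFrame,
    window_s: float = ZOC_WINDOW_S,
    surface_quantile: float = SURFACE_QUANTILE,
) -> pd.DataFrame:
    """Remove slow pressure drift so surface intervals read ~0 m.

    Per window of ``window_s`` seconds, the surface offset is the
    ``surface_quantile`` quantile of depth; windows whose estimate is not
    near-surface (all-submerged windows) are discarded and bridged by
    linear interpolation between neighbouring windows.  The offset curve is
    evaluated at every sample time and subtracted.  Corrected depths may be
    slightly negative; flooring at zero is left to dive detection.
    """
    if series.empty:
        raise ValueError("empty depth series")
    if window_s < 60:
        raise ValueError("ZOC window must be >= 60 s")
    t = _times_seconds(series)
    depth = series["depth"].to_numpy(dtype=float)
    span = t[-1] - t[0]
    if span <= window_s:
        logger.warning("ZOC window (%.0f s) exceeds series span (%.0f s); using one global offset", window_s, span)
        offset = np.quantile(depth, surface_quantile)
        out = series.copy()
        out["depth"] = depth - offset
        return out

    edges = np.arange(t[0], t[-1] + window_s, window_s)
    knots_t, offsets = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        m = (t >= lo) & (t < hi)
        if not m.any():
            continue
        q = np.quantile(depth[m], surface_quantile)
        if q <= _NEAR_SURFACE_CAP_M:
            # anchor the offset at the median time of the samples near the
            # quantile, so a drifting baseline is tracked without lag
            near = m & (depth <= q + 0.15)
            knots_t.append(float(np.median(t[near])))
            offsets.append(q)
    if not knots_t:
        raise ValueError("no near-surface windows found; cannot estimate offsets")
    knots_t = np.asarray(knots_t)
    offsets = np.asarray(offsets)
    if len(knots_t) >= 2:  # linear extrapolation beyond the outer knots
        s0 = (offsets[1] - offsets[0]) / (knots_t[1] - knots_t[0])
        s1 = (offsets[-1] - offsets[-2]) / (knots_t[-1] - knots_t[-2])
        knots_t = np.concatenate([[t[0] - 1.0], knots_t, [t[-1] + 1.0]])
        offsets = np.concatenate(
            [[offsets[0] + s0 * (t[0] - 1.0 - knots_t[1])], offsets, [offsets[-1] + s1 * (t[-1] + 1.0 - knots_t[-2])]]
        )
    offset_at = np.interp(t, knots_t, offsets)
    out = series.copy()
    out["depth"] = depth - offset_at
    return out


def detect_dives(
    series: pd.DataFrame,
    depth_threshold_m: float = DEPTH_THRESHOLD_M,
    min_duration_s: float = MIN_DURATION_S,
    bird_id: str | None = None,
) -> pd.DataFrame:
    """Segment a (corrected) depth series into dives.

    A dive is a maximal run of samples with depth >= ``depth_threshold_m``
    lasting at least ``min_duration_s``.  Duration counts one sampling
    interval per submerged sample; the post-dive surface interval
    ``s_post`` is the gap to the next dive's start (NaN for the last dive).

    Returns a dive table with start_time, u (s), max_depth (m), s_post (s)
    and the sample index range of each dive (for metric computation).
    """
    if series.empty:
        return _empty_dive_table()
    t = _times_seconds(series)
    depth = np.maximum(series["depth"].to_numpy(dtype=float), 0.0)
    dt = float(np.median(np.diff(t))) if len(t) > 1 else 1.0
    wet = depth >= depth_threshold_m
    padded = np.concatenate([[False], wet, [False]])
    starts = np.flatnonzero(padded[1:] & ~padded[:-1])
    ends = np.flatnonzero(~padded[1:] & padded[:-1])  # exclusive

    rows = []
    for s, e in zip(starts, ends):
        u = (e - s) * dt
        if u < min_duration_s:
            continue
        rows.append(
            {
                "bird_id": bird_id,
                "start_time": series["t"].iloc[s],
                "u": u,
                "max_depth": float(depth[s:e].max()),
                "i_start": int(s),
                "i_end": int(e),
            }
        )
    if not rows:
        return _empty_dive_table()
    dives = pd.DataFrame(rows)
    t_start = t[dives["i_start"].to_numpy()]
    s_post = np.full(len(dives), np.nan)
    s_post[:-1] = t_start[1:] - (t_start[:-1] + dives["u"].to_numpy()[:-1])
    dives["s_post"] = s_post
    return dives


def _empty_dive_table() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["bird_id", "start_time", "u", "max_depth", "i_start", "i_end", "s_post"]
    )


def dive_metrics(
    times: np.ndarray,
    depths: np.ndarray,
    bottom_fraction: float = BOTTOM_FRACTION,
) -> tuple[float, float, float, float]:
    """Phase durations and bottom vertical distance for one dive.

    Returns (descent_time, ascent_time, bottom_time, bottom_vertical_distance).
    The three phases partition the dive: descent + bottom + ascent equals
    the dive duration up to one sampling interval.
    """
    times = np.asarray(times, dtype=float)
    depths = np.asarray(depths, dtype=float)
    if len(times) < 3:
        raise ValueError("dive needs at least 3 samples")
    dt = float(np.median(np.diff(times)))
    maxd = depths.max()
    bottom = np.flatnonzero(depths >= bottom_fraction * maxd)
    f, l = int(bottom[0]), int(bottom[-1])
    descent_time = times[f] - times[0]
    ascent_time = times[-1] - times[l]
    bottom_time = times[l] - times[f] + dt
    bvd = float(np.abs(np.diff(depths[f : l + 1])).sum()) if l > f else 0.0
    return descent_time, ascent_time, bottom_time, bvd


def add_dive_metrics(
    dives: pd.DataFrame,
    series: pd.DataFrame,
    bottom_fraction: float = BOTTOM_FRACTION,
) -> pd.DataFrame:
    """Attach per-dive phase metrics (and tau = descent + ascent) to a dive
    table produced by :func:`detect_dives` on the same series."""
    t = _times_seconds(series)
    depth = np.maximum(series["depth"].to_numpy(dtype=float), 0.0)
    cols = {"descent_time": [], "ascent_time": [], "bottom_time": [], "bottom_vertical_distance": []}
    for s, e in zip(dives["i_start"], dives["i_end"]):
        d, a, b, v = dive_metrics(t[s:e], depth[s:e], bottom_fraction)
        cols["descent_time"].append(d)
        cols["ascent_time"].append(a)
        cols["bottom_time"].append(b)
        cols["bottom_vertical_distance"].append(v)
    out = dives.copy()
    for k, v in cols.items():
        out[k] = v
    out["tau"] = out["descent_time"] + out["ascent_time"]
    return out


def filter_impossible(
    dives: pd.DataFrame,
    max_depth_cap_m: float = MAX_DEPTH_CAP_M,
    max_duration_cap_s: float = MAX_DURATION_CAP_S,
) -> tuple[pd.DataFrame, int]:
    """Drop dives beyond physiological capability (sensor malfunction)."""
    if max_depth_cap_m <= 0 or max_duration_cap_s <= 0:
        raise ValueError("caps must be positive")
    bad = (dives["max_depth"] > max_depth_cap_m) | (dives["u"] > max_duration_cap_s)
    removed = int(bad.sum())
    if removed:
        logger.info("filter_impossible removed %d dive(s) beyond caps (%.0f m / %.0f s)", removed, max_depth_cap_m, max_duration_cap_s)
    return dives.loc[~bad].reset_index(drop=True), removed
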