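"""End-to-end run: simulate (or load) -> dives -> classify -> tracks -> IPQ -> models.

Everything downstream of the generator works from plain tables, so the
same steps apply to real GPS/TDR exports with matching columns.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import divetypes, ipq, models, tdr, tracks
from .synthetic import GeneratorConfig, World, default_world, simulate_dataset

logger = logging.getLogger(__name__)

__all__ = ["process_tdr", "process_gps", "run_pipeline"]


def process_tdr(
    tdr_df: pd.DataFrame,
    zoc_window_s: float = tdr.ZOC_WINDOW_S,
    depth_threshold_m: float = tdr.DEPTH_THRESHOLD_M,
    min_duration_s: float = tdr.MIN_DURATION_S,
    bottom_fraction: float = tdr.BOTTOM_FRACTION,
) -> pd.DataFrame:
    """Per-bird ZOC + dive detection + metrics + impossible-dive filter."""
    parts = []
    removed_total = 0
    for bird, series in tdr_df.groupby("bird_id", sort=False):
        series = series.sort_values("t").reset_index(drop=True)
        corrected = tdr.zero_offset_correct(series, zoc_window_s)
        dives = tdr.detect_dives(corrected, depth_threshold_m, min_duration_s, bird_id=str(bird))
        if len(dives) == 0:
            continue
        dives = tdr.add_dive_metrics(dives, corrected, bottom_fraction)
        dives, removed = tdr.filter_impossible(dives)
        removed_total += removed
        parts.append(dives)
    out = pd.concat(parts, ignore_index=True) if parts else tdr._empty_dive_table()
    logger.info("detected %d dives (%d removed as impossible)", len(out), removed_total)
    return out


def process_gps(
    gps_df: pd.DataFrame,
    coastline,
    vmax_ms: float = 10.0,
    jump_filter_km: float | None = None,
) -> tuple[pd.DataFrame, list[tracks.Trip]]:
    """Land flags, speed filter, optional jump filter, trip segmentation."""
    fixes = tracks.flag_on_land(gps_df, coastline)
    fixes, n_speed = tracks.speed_filter(fixes, vmax_ms)
    if jump_filter_km is not None:
        fixes, n_jump = tracks.jump_outlier_filter(fixes, jump_filter_km)
    trips = tracks.segment_trips(fixes)
    return fixes, trips


def run_pipeline(
    config: GeneratorConfig | None = None,
    world: World | None = None,
    seed: int = 0,
    outdir: str | Path | None = None,
    k: int | None = 3,
    pause_threshold_s: float = ipq.PAUSE_THRESHOLD_S,
    jump_filter_km: float | None = None,
    data: dict | None = None,
) -> dict:
    """Run the whole analysis on a simulated season (or supplied tables).

    Returns a dict with keys dives, bouts, trips, constants, results,
    cluster_model, data.  With ``k=None`` the cluster count is chosen by
    the Calinski-Harabasz criterion; the default fixes k=3.
    """
    config = config or GeneratorConfig()
    world = world or default_world()
    if data is None:
        data = simulate_dataset(config, world, seed=seed)
    meta = data["metadata"].set_index("bird_id")

    # --- tracks ---------------------------------------------------------
    fixes, trip_objs = process_gps(data["gps"], world.polygon(), jump_filter_km=jump_filter_km)
    colony_of = meta["colony"].to_dict()
    stage_of = meta["stage"].to_dict()
    trip_rows = []
    for tr in trip_objs:
        colony = world.colonies[colony_of[tr.bird_id]]
        at_sea = tr.fixes
        d = tracks.dist_to_colony(at_sea["lat"].to_numpy(), at_sea["lon"].to_numpy(), colony)
        tr.max_distance_km = float(d.max())
        tr.stage = stage_of[tr.bird_id]
        tr.start_julian = tracks.julian_day(tr.t_start)
        trip_rows.append(
            {
                "bird_id": tr.bird_id,
                "trip_id": tr.trip_id,
                "colony": colony_of[tr.bird_id],
                "stage": tr.stage,
                "t_start": tr.t_start,
                "t_end": tr.t_end,
                "duration_h": tr.duration_h,
                "max_distance": tr.max_distance_km,
                "start_julian": tr.start_julian,
            }
        )
    trips_df = pd.DataFrame(trip_rows)

    # --- dives ----------------------------------------------------------
    dives = process_tdr(data["tdr"])
    dives["colony"] = dives["bird_id"].map(colony_of)
    dives["stage"] = dives["bird_id"].map(stage_of)

    # assign dives to trips and interpolate positions at dive starts
    dives["trip_id"] = pd.NA
    dives["lat"] = np.nan
    dives["lon"] = np.nan
    n_gap = 0
    for tr in trip_objs:
        m = (
            (dives["bird_id"] == tr.bird_id)
            & (dives["start_time"] >= tr.t_start)
            & (dives["start_time"] <= tr.t_end)
        )
        if not m.any():
            continue
        dives.loc[m, "trip_id"] = tr.trip_id
        pos = tracks.interpolate_positions(tr.fixes, dives.loc[m, "start_time"])
        dives.loc[m, "lat"] = pos["lat"].to_numpy()
        dives.loc[m, "lon"] = pos["lon"].to_numpy()
        n_gap += int(pos["lat"].isna().sum())
    n_no_trip = int(dives["trip_id"].isna().sum())
    dives = dives[dives["trip_id"].notna() & dives["lat"].notna()].reset_index(drop=True)
    logger.info("dropped %d dives outside trips and %d in GPS gaps", n_no_trip, n_gap)

    dist = np.full(len(dives), np.nan)
    for cname, cpos in world.colonies.items():
        m = (dives["colony"] == cname).to_numpy()
        if m.any():
            dist[m] = tracks.dist_to_colony(dives.loc[m, "lat"].to_numpy(), dives.loc[m, "lon"].to_numpy(), cpos)
    dives["dist_to_colony"] = dist

    # --- dive typing ------------------------------------------------------
    dives, cluster_model = divetypes.classify_dives(dives, k=k, seed=seed)

    # --- IPQ and bouts ----------------------------------------------------
    forage = dives[dives["dive_type"] == "forage"]
    usable = forage[(forage["s_post"] > 0) & (forage["s_post"] <= pause_threshold_s)]
    constants = ipq.fit_constants(usable["u"], usable["s_post"])
    dives = ipq.detect_bouts(dives, pause_threshold_s)
    dives = ipq.add_ipq(dives, constants, pause_threshold_s)
    bouts = ipq.summarize_bouts(dives)

    # --- models -----------------------------------------------------------
    results = models.run_battery(dives, bouts, trips_df)

    out = {
        "dives": dives,
        "bouts": bouts,
        "trips": trips_df,
        "constants": constants,
        "results": results,
        "cluster_model": cluster_model,
        "data": data,
    }
    if outdir is not None:
        write_outputs(out, outdir)
    return out


_DATE_FMT = "%Y-%m-%dT%H:%M:%S.%f"


def write_outputs(out: dict, outdir: str | Path) -> None:
    p = Path(outdir)
    p.mkdir(parents=True, exist_ok=True)
    dive_cols = [c for c in out["dives"].columns if c not in ("i_start", "i_end")]
    out["dives"][dive_cols].to_csv(p / "dives.csv", index=False, date_format=_DATE_FMT)
    out["bouts"].to_csv(p / "bouts.csv", index=False, date_format=_DATE_FMT)
    out["trips"].to_csv(p / "trips.csv", index=False, date_format=_DATE_FMT)
    out["results"].to_csv(p / "results.csv", index=False)
    (p / "constants.json").write_text(json.dumps(asdict(out["constants"]), sort_keys=True, indent=1))
    cm = out["cluster_model"]
    summary = {
        "k": cm.k,
        "centroids_raw": cm.centroids_raw.tolist(),
        "features": divetypes.FEATURES,
        "label_map": {str(k): v for k, v in cm.label_map.items()},
        "ch_scores": {str(k): v for k, v in cm.ch_scores.items()},
        "seed": cm.seed,
    }
    (p / "cluster_model.json").write_text(json.dumps(summary, sort_keys=True, indent=1))
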