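"""Readers, writers, and the end-to-end pipeline driver.

CSV dialect: UTF-8, comma-separated, header row, '.' decimal, empty cell =
missing.  Density movies are multi-page 32-bit float grayscale TIFFs with a
JSON sidecar carrying pixel size (µm/px), frame interval (min), and t0 (min).
Run databases are CSVs with a JSON sidecar holding the time-bin edges and
cue-standardization constants.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .aggregates import (AggregateSet, AggregateTrack, DensityMovie,
                         annotate_flags, compute_scaled_threshold,
                         detect_coarsening_start, normalize_frames,
                         segment_and_track)
from .runs import RunDatabase, RunParams, TimeBin, annotate_runs, extract_runs

log = logging.getLogger("myxodisp")

TRAJ_COLUMNS = ["cell_id", "t_min", "x_um", "y_um"]


# --------------------------------------------------------------------------
# trajectories
# --------------------------------------------------------------------------

def write_trajectories(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=TRAJ_COLUMNS)


def read_trajectories(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(TRAJ_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trajectory CSV missing columns: {sorted(missing)}")
    return df


# --------------------------------------------------------------------------
# density movies
# --------------------------------------------------------------------------

def write_movie(movie: DensityMovie, path) -> None:
    path = Path(path)
    tifffile.imwrite(path, movie.frames.astype(np.float32))
    sidecar = {
        "pixel_size_um": movie.pixel_size,
        "frame_interval_min": movie.frame_interval,
        "t0_min": movie.t0,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_movie(path) -> DensityMovie:
    path = Path(path)
    frames = tifffile.imread(path).astype(np.float64)
    if frames.ndim == 2:
        frames = frames[None]
    meta = json.loads(path.with_suffix(".json").read_text())
    return DensityMovie(frames, meta["pixel_size_um"],
                        meta["frame_interval_min"], meta.get("t0_min", 0.0))


# --------------------------------------------------------------------------
# run databases
# --------------------------------------------------------------------------

def write_run_database(db: RunDatabase, path) -> None:
    path = Path(path)
    db.df.to_csv(path, index=False)
    sidecar = {
        "time_bins": [{"t_lo": b.t_lo, "t_hi": b.t_hi, "phase": b.phase}
                      for b in db.time_bins],
        "standardization": {str(k): {c: list(v) for c, v in d.items()}
                            for k, d in db.standardization.items()},
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_run_database(path) -> RunDatabase:
    path = Path(path)
    df = pd.read_csv(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    bins = [TimeBin(b["t_lo"], b["t_hi"], b["phase"])
            for b in meta["time_bins"]]
    return RunDatabase(df, bins)


# --------------------------------------------------------------------------
# aggregates
# --------------------------------------------------------------------------

def write_aggregates(aggset: AggregateSet, path_prefix) -> None:
    prefix = Path(path_prefix)
    aggset.to_frame().to_csv(prefix.with_suffix(".csv"), index=False)
    feats = []
    for trk in aggset:
        for i, poly in enumerate(trk.contours):
            if poly is None:
                continue
            feats.append({
                "type": "Feature",
                "properties": {"agg_id": trk.agg_id, "t_min": float(trk.t[i])},
                "geometry": {
                    "type": "Polygon",
                    "coordinates": [[list(c) for c in
                                     np.asarray(poly.exterior.coords)]],
                },
            })
    prefix.with_suffix(".contours.json").write_text(
        json.dumps({"type": "FeatureCollection", "features": feats}))


def read_aggregates(path_prefix) -> AggregateSet:
    from shapely.geometry import Polygon

    prefix = Path(path_prefix)
    df = pd.read_csv(prefix.with_suffix(".csv"))
    contour_file = prefix.with_suffix(".contours.json")
    polys: dict = {}
    if contour_file.exists():
        fc = json.loads(contour_file.read_text())
        for feat in fc["features"]:
            key = (feat["properties"]["agg_id"], feat["properties"]["t_min"])
            polys[key] = Polygon(feat["geometry"]["coordinates"][0])
    tracks = []
    for aid, g in df.groupby("agg_id"):
        g = g.sort_values("t_min")
        t = g["t_min"].to_numpy(float)
        tracks.append(AggregateTrack(
            agg_id=int(aid), t=t,
            centroid=g[["centroid_x_um", "centroid_y_um"]].to_numpy(float),
            area=g["area_um2"].to_numpy(float),
            contours=[polys.get((int(aid), float(tt))) for tt in t],
            motile=bool(g["motile"].iloc[0]),
            short_lived=bool(g["short_lived"].iloc[0]),
            partial_fov=bool(g["partial_fov"].iloc[0]),
            fate=str(g["fate"].iloc[0]),
        ))
    return AggregateSet(tracks)


# --------------------------------------------------------------------------
# pipeline
# --------------------------------------------------------------------------

def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def validate_pipeline_config(config: dict) -> dict:
    """Shallow schema validation; raises naming the offending field."""
    if not isinstance(config, dict):
        raise ValueError("config must be a mapping")
    if not config.get("synthetic", False):
        if "pixel_size" not in config:
            raise ValueError("config missing required field pixel_size")
        if config["pixel_size"] <= 0:
            raise ValueError("pixel_size must be positive")
        for key in ("trajectories", "movie"):
            if key not in config.get("paths", {}):
                raise ValueError(f"config missing required field paths.{key}")
            p = Path(config["paths"][key])
            if not p.exists():
                raise ValueError(f"input path does not exist: {p}")
    config.setdefault("seed", 0)
    return config


def run_pipeline(config: dict, out_dir) -> dict:
    """aggregates → runs → stats (→ optional abm), with a JSON report.

    With ``synthetic: true`` the pipeline generates its own world from the
    ``synth`` parameter block; otherwise it reads the trajectory CSV and
    density TIFF named under ``paths``.
    """
    from . import abm as abmmod
    from . import stats as statsmod
    from . import synthkit

    config = validate_pipeline_config(dict(config))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    report: dict = {"config_hash": config_hash(config), "seed": seed}
    t_wall = time.time()

    if config.get("synthetic", False):
        synth_kwargs = dict(config.get("synth", {}))
        aggs = [synthkit.AggregateSpec(**a)
                for a in synth_kwargs.pop("aggregates", [])]
        if not aggs:
            aggs = [
                synthkit.AggregateSpec((150.0, 150.0), 40.0),
                synthkit.AggregateSpec((360.0, 260.0), 22.0,
                                       disperse_at=420.0),
            ]
        cfg = synthkit.SyntheticWorldConfig(
            aggregates=aggs, seed=seed,
            p_stop=synthkit.linear_in_density(0.1, 0.4),
            tau_stop=synthkit.linear_in_density(6.0, 14.0),
            **synth_kwargs)
        tracks = synthkit.gen_trajectories(cfg)
        traj = tracks.table
        movie = synthkit.gen_density_movie(cfg)
    else:
        traj = read_trajectories(config["paths"]["trajectories"])
        movie = read_movie(config["paths"]["movie"])
    log.info("stage=input rows=%d frames=%d", len(traj), movie.n_frames)

    # aggregates
    norm = normalize_frames(movie)
    t_ref = config.get("t_ref", float(np.median(norm.times)))
    threshold = compute_scaled_threshold(norm, t_ref)
    aggset = segment_and_track(norm, threshold,
                               min_area=config.get("min_area", 100.0))
    annotate_flags(aggset, norm)
    t_coarsen = detect_coarsening_start(aggset, norm.times)
    if not np.isfinite(t_coarsen):
        t_coarsen = config.get("t_coarsen_fallback", None)
    report["threshold"] = threshold
    report["n_aggregates"] = len(aggset)
    report["t_coarsen"] = t_coarsen
    write_aggregates(aggset, out / "aggregates")

    # runs
    params = RunParams(**config.get("runs", {}))
    runs_df = extract_runs(traj, params)
    fov = (norm.frames.shape[2] * norm.pixel_size,
           norm.frames.shape[1] * norm.pixel_size)
    run_db = annotate_runs(runs_df, norm, aggset, traj, params,
                           t_coarsen=t_coarsen, fov_size=fov)
    write_run_database(run_db, out / "run_db.csv")
    log.info("stage=runs n_runs=%d", len(run_db))

    # stats
    series = statsmod.windowed_bias(run_db, seed=seed)
    report["bias_overall"] = {
        "mean": float(np.nanmean(series["all"].bias)),
        "n_windows": int(len(series["all"].window_centers)),
    }
    jam = statsmod.jam_metrics(run_db, seed=seed)
    report["jam"] = jam.to_dict()
    try:
        fit = statsmod.logistic_from_tracks(
            aggset, t_coarsen if t_coarsen is not None else norm.times[-1])
        report["logistic_threshold_area"] = fit.threshold_area
    except ValueError:
        report["logistic_threshold_area"] = None
    for label, s in series.items():
        s.to_frame().to_csv(out / f"bias_{label}.csv", index=False)

    # optional abm
    if config.get("abm", {}).get("enabled", False):
        abm_cfg = abmmod.SimulationConfig(
            seed=seed, t_coarsen=t_coarsen,
            **{k: v for k, v in config["abm"].items() if k != "enabled"})
        result = abmmod.run_simulation(abm_cfg, run_db)
        summary = abmmod.dispersal_summary(
            result, t_coarsen if t_coarsen is not None else abm_cfg.t_end)
        report["abm"] = {
            "pct_decrease_in_count": summary["pct_decrease_in_count"],
            "count_at_coarsen": summary["count_at_coarsen"],
            "count_at_end": summary["count_at_end"],
        }

    log.info("pipeline finished in %.1f s", time.time() - t_wall)
    (out / "report.json").write_text(json.dumps(report, indent=2,
                                                default=float))
    return report
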