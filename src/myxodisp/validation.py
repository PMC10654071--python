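"""End-to-end validation studies on the canonical synthetic worlds.

Each function runs one self-contained study — generating data with known
ground truth, running the relevant pipeline stages, and returning measured
versus expected quantities.  The test suite asserts on these results and the
reproduction script reports them; both use the same code so the study
conditions are defined exactly once (in :mod:`myxodisp.presets`).
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

from . import presets
from .abm import (DURATION_SEARCH, CueFlags, build_search_index,
                  dispersal_summary, run_simulation, sub_threshold_dispersal,
                  variant_flags)
from .aggregates import (annotate_flags, compute_scaled_threshold,
                         detect_coarsening_start, normalize_frames,
                         segment_and_track)
from .runs import PERSISTENT, annotate_runs, extract_runs
from .stats import jam_metrics, reversal_bias
from .synthkit import (expected_bias, gen_density_movie, gen_run_database,
                       gen_trajectories, ground_truth_aggregates)


def _sub(seed: int, k: int) -> int:
    return int((seed * 1000003 + k * 7919) % (2 ** 31 - 1))


# --------------------------------------------------------------------------
# 1. bias estimator vs closed form
# --------------------------------------------------------------------------

def bias_estimator_study(seed: int = 0, n_runs: int = 10000) -> dict:
    """Reversal-bias estimator on a 6/4-min run set vs the 0.4 oracle."""
    cfg = presets.run_set_world(seed=_sub(seed, 1), n_runs=n_runs)
    df = gen_run_database(cfg).df
    est = reversal_bias(df)
    rng = np.random.default_rng(_sub(seed, 2))
    boot = np.empty(200)
    idx_all = np.arange(len(df))
    for b in range(200):
        boot[b] = reversal_bias(
            df.iloc[rng.choice(idx_all, size=len(df), replace=True)])
    oracle = expected_bias(cfg, 5000.0)
    return {"estimate": float(est), "oracle": float(oracle),
            "se": float(boot.std()), "n": n_runs}


# --------------------------------------------------------------------------
# 2. trajectory-pipeline parameter recovery
# --------------------------------------------------------------------------

def bias_recovery_study(seed: int = 0) -> dict:
    """gen_trajectories → runs → stats on the area-flip world: measured
    bias per area stratum vs the generator's Monte-Carlo truth."""
    cfg = presets.bias_recovery_world(seed=_sub(seed, 3))
    tracks = gen_trajectories(cfg)
    runs_df = extract_runs(tracks.table)
    db = annotate_runs(runs_df, None, ground_truth_aggregates(cfg),
                       tracks.table, fov_size=cfg.fov_size)
    t = tracks.true_runs
    pe = t[(t.state == PERSISTENT) & (t.end_event != "track_end")]
    out = {}
    area_split = cfg.flip_area
    for label in ("small", "large"):
        if label == "small":
            meas_mask = ((db.df.nearest_aggregate_area > 0)
                         & (db.df.nearest_aggregate_area < area_split))
            true_sub = pe[pe.area < area_split]
        else:
            meas_mask = db.df.nearest_aggregate_area >= area_split
            true_sub = pe[pe.area >= area_split]
        truth = ((true_sub[true_sub.toward].duration.mean()
                  - true_sub[~true_sub.toward].duration.mean())
                 / true_sub.duration.mean())
        out[label] = {
            "measured": float(reversal_bias(db.df[meas_mask])),
            "truth": float(truth),
            "oracle": float(expected_bias(
                cfg, 1000.0 if label == "small" else 9000.0)),
            "n": int(meas_mask.sum()),
        }
    return out


def jam_recovery_study(seed: int = 0) -> dict:
    """gen_trajectories → runs → stats on the jam world: stopping
    probability and stop durations inside/outside vs start-conditioned
    generator truth."""
    cfg = presets.jam_world(seed=_sub(seed, 4))
    tracks = gen_trajectories(cfg)
    runs_df = extract_runs(tracks.table)
    db = annotate_runs(runs_df, None, ground_truth_aggregates(cfg),
                       tracks.table, fov_size=cfg.fov_size)
    m = jam_metrics(db, bootstrap_b=50, seed=_sub(seed, 5))
    t = tracks.true_runs
    pe = t[(t.state == PERSISTENT) & (t.end_event != "track_end")]
    npr = t[t.state == "non-persistent"]
    tin = pe[pe.rho_start == 1]
    tout = pe[pe.rho_start == 0]
    return {
        "p_stop_inside": {"measured": float(m.p_stop_inside),
                          "truth": float((tin.end_event == "state_change").mean()),
                          "n": int(len(tin))},
        "p_stop_outside": {"measured": float(m.p_stop_outside),
                           "truth": float((tout.end_event == "state_change").mean()),
                           "n": int(len(tout))},
        "stop_duration_inside": {
            "measured": float(m.stop_duration_inside),
            "truth": float(npr[npr.rho_start == 1].duration.mean()),
            "n": int((npr.rho_start == 1).sum())},
        "stop_duration_outside": {
            "measured": float(m.stop_duration_outside),
            "truth": float(npr[npr.rho_start == 0].duration.mean()),
            "n": int((npr.rho_start == 0).sum())},
    }


# --------------------------------------------------------------------------
# 3. segmentation and coarsening detection
# --------------------------------------------------------------------------

def segmentation_study(seed: int = 0, n_seeds: int = 20) -> dict:
    """Otsu vs exhaustive scan, blob areas vs analytic Gaussian contours,
    and the detected coarsening start vs the 420-min dispersal trigger."""
    cfg = presets.movie_world(seed=_sub(seed, 6))
    raw = gen_density_movie(cfg)
    norm = normalize_frames(raw)
    thr = compute_scaled_threshold(norm, 210.0)

    # exhaustive Otsu oracle on the unit-rescaled reference frame
    f = norm.frames[norm.frame_index(210.0)]
    a_min, a_max = f.min(), f.max()
    scaled = (f - a_min) / (a_max - a_min)
    counts, edges = np.histogram(scaled, bins=256, range=(0, 1))
    centers = 0.5 * (edges[:-1] + edges[1:])
    best_v, best_t = -1.0, 0.0
    for k in range(1, 256):
        w0, w1 = counts[:k].sum(), counts[k:].sum()
        if w0 == 0 or w1 == 0:
            continue
        m0 = (counts[:k] * centers[:k]).sum() / w0
        m1 = (counts[k:] * centers[k:]).sum() / w1
        v = w0 * w1 * (m0 - m1) ** 2
        if v > best_v:
            best_v, best_t = v, centers[k - 1]
    otsu_diff_bins = abs((thr - a_min) / (a_max - a_min) - best_t) * 256

    # blob area vs analytic contour area for the stable blob at t_ref
    aggset = segment_and_track(norm, thr, min_area=100)
    stable_trk = max(aggset, key=lambda a: a.area.max())
    measured_area = stable_trk.area_at(210.0)
    f_raw = raw.frames[raw.frame_index(210.0)]
    g = f_raw - f_raw.mean()
    g = g - g.min()
    s = g.sum()
    bg_n = (cfg.background_intensity - f_raw.mean()
            - (f_raw - f_raw.mean()).min()) / s
    amp_n = cfg.blob_amplitude / s
    stable = cfg.aggregates[0]
    sigma = stable.radius_at(210.0, cfg.dispersal_ramp) / 2.0
    analytic = np.pi * 2 * sigma ** 2 * np.log(amp_n / (thr - bg_n))

    # coarsening start across seeds
    t_detected = []
    for k in range(n_seeds):
        cfg_k = presets.movie_world(seed=_sub(seed, 100 + k))
        norm_k = normalize_frames(gen_density_movie(cfg_k))
        thr_k = compute_scaled_threshold(norm_k, 210.0)
        set_k = segment_and_track(norm_k, thr_k, min_area=100)
        annotate_flags(set_k, norm_k)
        t_detected.append(detect_coarsening_start(set_k, norm_k.times))
    return {
        "otsu_diff_bins": float(otsu_diff_bins),
        "blob_area_ratio": float(measured_area / analytic),
        "t_coarsen": [float(v) for v in t_detected],
        "trigger": 420.0,
        "n_seeds": n_seeds,
    }


# --------------------------------------------------------------------------
# 4. nearest-neighbor sampling fidelity
# --------------------------------------------------------------------------

def nn_fidelity_study(seed: int = 0) -> dict:
    """KD-tree search vs brute force on 500 queries; sampled-duration
    marginal vs the database stratum (KS test at 5,000 draws)."""
    cfg = presets.run_set_world(seed=_sub(seed, 7), n_runs=8000)
    db = gen_run_database(cfg)
    index = build_search_index(db, CueFlags(), knn_k=1)
    st = index.stratum(0, PERSISTENT, DURATION_SEARCH)
    rows = st["rows"]
    X = np.column_stack([
        (np.where(np.isfinite(rows[c].to_numpy(float)),
                  rows[c].to_numpy(float), st["mean"][j])
         - st["mean"][j]) / st["sd"][j]
        for j, c in enumerate(st["cues"])])
    rng = np.random.default_rng(_sub(seed, 8))
    q_std = rng.normal(0, 1, (500, X.shape[1]))
    cues = {c: q_std[:, j] * st["sd"][j] + st["mean"][j]
            for j, c in enumerate(st["cues"])}
    got = index.query(0, PERSISTENT, DURATION_SEARCH, cues,
                      np.random.default_rng(0))
    brute = np.argmin(((X[None, :, :] - q_std[:, None, :]) ** 2).sum(axis=2),
                      axis=1)
    match_frac = float(np.mean(np.isclose(
        got.duration.to_numpy(), rows.duration.to_numpy()[brute])))

    index20 = build_search_index(db, CueFlags(), knn_k=20)
    pick = rng.integers(len(rows), size=5000)
    cues_self = {c: rows[c].to_numpy(float)[pick] for c in st["cues"]}
    sampled = index20.query(0, PERSISTENT, DURATION_SEARCH, cues_self,
                            np.random.default_rng(_sub(seed, 9)))
    ks_p = float(sps.ks_2samp(sampled.duration, rows.duration).pvalue)
    return {"brute_force_match": match_frac, "ks_pvalue": ks_p, "n": 5000}


# --------------------------------------------------------------------------
# 5. agent-model dispersal contrast
# --------------------------------------------------------------------------

def abm_contrast_study(seed: int = 0, n_replicates: int = 3,
                       variants=("bias-only", "no-area", "jam-only")) -> dict:
    """Scaled-down closed-loop simulations: dispersal of sub-A* aggregates
    with the area cue in the duration search vs without area cues vs
    area-dependent jamming only."""
    world = presets.abm_world(seed=_sub(seed, 10))
    db = gen_run_database(world)
    astar = presets.ABM_AREA_STAR
    t_c = presets.ABM_T_COARSEN
    out: dict = {"area_star": astar, "variants": {}}
    counts: dict = {}
    for variant in variants:
        gone = total = 0
        pct, thresholds = [], []
        for rep in range(n_replicates):
            cfg = presets.abm_sim_config(variant,
                                         seed=_sub(seed, 20 + rep))
            res = run_simulation(cfg, db)
            frac, n = sub_threshold_dispersal(res, t_c, astar)
            if n:
                gone += int(round(frac * n))
                total += n
            s = dispersal_summary(res, t_c)
            pct.append(s["pct_decrease_in_count"])
            if s["logistic_fit"] is not None:
                thresholds.append(s["logistic_fit"].threshold_area)
        counts[variant] = (gone, total)
        out["variants"][variant] = {
            "sub_astar_dispersal": float(gone / total) if total else float("nan"),
            "n_sub_astar": total,
            "pct_decrease_mean": float(np.nanmean(pct)),
            "logistic_threshold_mean": (float(np.mean(thresholds))
                                        if thresholds else float("nan")),
        }
    if "jam-only" in counts and "no-area" in counts:
        (g1, n1), (g2, n2) = counts["jam-only"], counts["no-area"]
        table = [[g1, n1 - g1], [g2, n2 - g2]]
        out["jam_vs_noarea_pvalue"] = float(sps.fisher_exact(table)[1])
    return out


# --------------------------------------------------------------------------
# 6. conservation and determinism
# --------------------------------------------------------------------------

def determinism_study(seed: int = 0) -> dict:
    cfg_world = presets.run_set_world(seed=_sub(seed, 11), n_runs=3000)
    db = gen_run_database(cfg_world)
    sim_cfg = presets.abm_sim_config("no-area", seed=_sub(seed, 12),
                                     n_agents=300, t_end=120.0,
                                     kde_bandwidth=7.0)
    sim_cfg.init_duration = 30.0
    r1 = run_simulation(sim_cfg, db)
    r2 = run_simulation(sim_cfg, db)
    tracks_identical = bool(
        np.array_equal(r1.final_positions, r2.final_positions)
        and np.array_equal(r1.field_movie.frames, r2.field_movie.frames))
    field_total_err = float(np.max(np.abs(
        r1.field_movie.frames.sum(axis=(1, 2)) - 1.0)))
    tr_cfg = presets.run_set_world(seed=_sub(seed, 13))
    tr_cfg.n_cells, tr_cfg.duration = 10, 60.0
    t1 = gen_trajectories(tr_cfg).table
    t2 = gen_trajectories(tr_cfg).table
    return {
        "agents_conserved": bool(len(r1.final_positions) == sim_cfg.n_agents),
        "density_total_max_error": field_total_err,
        "simulation_rerun_identical": tracks_identical,
        "trajectories_rerun_identical": bool(t1.equals(t2)),
    }
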