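"""Coarse-graining of cell trajectories into behavioral runs.

A tracked cell's trajectory is reduced to a sequence of *runs*: segments
bounded by transitions between the persistent (steadily gliding) and
non-persistent (stopped / low net displacement) states, or by reversals of the
direction of motion within the persistent state.  Each run records its
kinematics (duration, mean speed, net displacement, orientation) and the cue
covariates used by both the statistics and the data-driven agent model: time,
local density, local nematic alignment, change of orientation, and position /
orientation relative to the nearest aggregate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .aggregates import AggregateSet, DensityMovie

PERSISTENT = "persistent"
NON_PERSISTENT = "non-persistent"

#: boundary-distance value assigned when no aggregate exists (µm)
NO_AGGREGATE_DISTANCE = 500.0
NO_AGGREGATE_ID = -1


@dataclass
class RunParams:
    """Calibration knobs of the coarse-graining step.

    The state classifier labels a frame persistent when, over a centered
    window of ``w_state`` minutes, the windowed mean speed is at least
    ``v_min`` µm/min and the windowed net displacement at least ``d_min`` µm.
    ``theta_rev`` is the minimum turn (radians) between smoothed pre/post
    displacement directions that counts as a reversal.
    """

    v_min: float = 1.0          # µm/min
    d_min: float = 2.0          # µm
    w_state: float = 5.0        # min
    dwell_min_frames: int = 2
    smooth_frames: int = 3
    theta_rev: float = 2.0 * np.pi / 3.0   # 120°
    rev_min_step: float = 0.5              # µm; single-frame step floor for
                                           # the fine-scale reversal detector
    stop_step: float = 0.6                 # µm; frames with both adjacent raw
                                           # steps below this are stopped
    v_fast: float = 1.8                    # µm/min; windowed path speed above
                                           # which a frame is never labeled
                                           # non-persistent (separates fast
                                           # out-and-back turns from arrest)
    alignment_radius: float = 12.0         # µm
    alignment_window: float = 7.0          # min, backward in time
    no_aggregate_distance: float = NO_AGGREGATE_DISTANCE
    toward_split: float = np.pi / 2.0      # rel_angle below ⇒ toward
    fov_margin: float = 40.0               # µm; runs starting this close to
                                           # the field edge are dropped (edge
                                           # effects corrupt run orientation)


@dataclass
class TimeBin:
    t_lo: float
    t_hi: float
    phase: str   # "aggregation" | "coarsening"


class RunDatabase:
    """Indexed table of runs with time bins and cue standardization constants."""

    CUE_COLUMNS = ("local_density", "alignment_gamma", "boundary_distance",
                   "rel_angle", "nearest_aggregate_area")

    def __init__(self, df: pd.DataFrame, time_bins: list[TimeBin]):
        self.df = df.reset_index(drop=True)
        self.time_bins = list(time_bins)
        if "time_bin" not in self.df.columns:
            self.df["time_bin"] = [self.bin_of(t) for t in self.df["t_mid"]]
        self.standardization = self._standardize()

    def bin_of(self, t: float) -> int:
        for i, b in enumerate(self.time_bins):
            if b.t_lo <= t < b.t_hi:
                return i
        if self.time_bins and t >= self.time_bins[-1].t_hi:
            return len(self.time_bins) - 1
        return 0

    def phase_of_bin(self, i: int) -> str:
        return self.time_bins[i].phase

    def _standardize(self) -> dict:
        consts: dict = {}
        for i in range(len(self.time_bins)):
            sub = self.df[self.df["time_bin"] == i]
            consts[i] = {}
            for cue in self.CUE_COLUMNS:
                if cue in sub.columns:
                    v = sub[cue].to_numpy(dtype=float)
                    v = v[np.isfinite(v)]
                    if len(v):
                        consts[i][cue] = (float(v.mean()), float(v.std()))
        return consts

    def __len__(self) -> int:
        return len(self.df)


def make_time_bins(t_lo: float, t_coarsen: float | None, t_hi: float,
                   pre_width: float = 100.0,
                   coarsening_bins: int = 2) -> list[TimeBin]:
    """Partition [t_lo, t_hi] into aggregation-phase bins of ``pre_width``
    minutes and ``coarsening_bins`` equal bins after the coarsening start."""
    bins: list[TimeBin] = []
    if t_coarsen is None or not np.isfinite(t_coarsen) or t_coarsen >= t_hi:
        t_coarsen = t_hi
    t = t_lo
    while t < t_coarsen - 1e-9:
        bins.append(TimeBin(t, min(t + pre_width, t_coarsen), "aggregation"))
        t += pre_width
    if t_coarsen < t_hi - 1e-9:
        width = (t_hi - t_coarsen) / coarsening_bins
        for k in range(coarsening_bins):
            bins.append(TimeBin(t_coarsen + k * width,
                                t_coarsen + (k + 1) * width, "coarsening"))
    if not bins:
        bins.append(TimeBin(t_lo, t_hi, "aggregation"))
    return bins


# --------------------------------------------------------------------------
# per-cell kinematics
# --------------------------------------------------------------------------

def _smooth_positions(xy: np.ndarray, w: int) -> np.ndarray:
    if w <= 1 or len(xy) < w:
        return xy.copy()
    out = np.empty_like(xy)
    half = w // 2
    n = len(xy)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = xy[lo:hi].mean(axis=0)
    return out


def classify_states_arrays(t: np.ndarray, xy: np.ndarray,
                           params: RunParams) -> np.ndarray:
    """Per-frame boolean array: True = persistent."""
    n = len(t)
    if n < 2:
        return np.zeros(n, dtype=bool)
    dt = np.median(np.diff(t))
    half_frames = max(1, int(round(params.w_state / (2 * dt))))
    if n <= 2 * half_frames:
        warnings.warn("track shorter than state window; labeled non-persistent")
        return np.zeros(n, dtype=bool)
    sm = _smooth_positions(xy, params.smooth_frames)
    steps = np.hypot(*np.diff(sm, axis=0).T)
    cum = np.concatenate([[0.0], np.cumsum(steps)])
    persistent = np.zeros(n, dtype=bool)
    for i in range(n):
        lo, hi = max(0, i - half_frames), min(n - 1, i + half_frames)
        span = t[hi] - t[lo]
        if span <= 0:
            continue
        path = cum[hi] - cum[lo]
        net = float(np.hypot(*(sm[hi] - sm[lo])))
        # scale the displacement requirement with the realized window span
        frac = span / params.w_state
        persistent[i] = (path / span >= params.v_fast
                         or (path / span >= params.v_min
                             and net >= params.d_min * min(1.0, frac)))
    # instantaneous criterion: the sliding window cannot resolve stops much
    # shorter than itself, but a truly stopped frame has near-zero raw steps
    # on both sides
    raw_steps = np.hypot(*np.diff(xy, axis=0).T)
    stopped = np.zeros(n, dtype=bool)
    stopped[1:-1] = ((raw_steps[:-1] < params.stop_step)
                     & (raw_steps[1:] < params.stop_step))
    persistent[stopped] = False
    persistent = _merge_short_dwells(persistent, params.dwell_min_frames)
    # a labeled stop whose median raw step is large is not an arrest but a
    # fast direction change (the net-displacement window dips around turns);
    # hand those frames back to the persistent state for reversal analysis
    for i0, i1, val in _segments(persistent):
        if val or i1 <= i0:
            continue
        med = np.median(raw_steps[i0:i1])
        if med > 1.5 * params.stop_step:
            persistent[i0:i1 + 1] = True
    return _merge_short_dwells(persistent, params.dwell_min_frames)


def _merge_short_dwells(labels: np.ndarray, dwell_min: int) -> np.ndarray:
    """Absorb label runs shorter than ``dwell_min`` frames into the flanks."""
    out = labels.copy()
    changed = True
    while changed:
        changed = False
        segs = _segments(out)
        for k, (i0, i1, val) in enumerate(segs):
            if i1 - i0 + 1 < dwell_min and len(segs) > 1:
                out[i0:i1 + 1] = not val
                changed = True
                break
    return out


def _segments(labels: np.ndarray) -> list[tuple[int, int, bool]]:
    segs = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            segs.append((start, i - 1, bool(labels[start])))
            start = i
    return segs


def detect_reversals_arrays(t: np.ndarray, xy: np.ndarray,
                            persistent: np.ndarray,
                            params: RunParams) -> np.ndarray:
    """Frame indices of reversal events within persistent segments."""
    sm = _smooth_positions(xy, params.smooth_frames)
    w = params.smooth_frames

    def _turn(a, b) -> float:
        na, nb = np.hypot(*a), np.hypot(*b)
        if na < 1e-9 or nb < 1e-9:
            return 0.0
        return float(np.arccos(np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0)))

    events = []
    steps = np.diff(xy, axis=0)   # steps[j] = xy[j+1] - xy[j]
    for i0, i1, val in _segments(persistent):
        if not val:
            continue
        # candidate turn angles at every interior frame; a single physical
        # event produces a short contiguous span of candidates, collapsed
        # below to its best frame
        cand: list[tuple[int, float]] = []
        for k in range(i0 + 1, i1):
            # fine scale: raw single-frame steps resolve short runs; a step
            # floor keeps position noise from producing spurious turns, and
            # one sub-floor step may be skipped on either side (an event
            # between frames splits its displacement across the two frames)
            a = steps[k - 1]
            if np.hypot(*a) < params.rev_min_step and k - 2 >= i0:
                a = steps[k - 2]
            b = steps[k]
            if np.hypot(*b) < params.rev_min_step and k + 1 < i1:
                b = steps[k + 1]
            if (np.hypot(*a) >= params.rev_min_step
                    and np.hypot(*b) >= params.rev_min_step):
                ang = _turn(a, b)
            else:
                # coarse fallback: smoothed multi-frame vectors where the
                # raw steps are too small for the fine test (slow or noisy
                # motion); the fine test has strictly better time resolution
                # so it takes precedence whenever defined
                lo = max(i0, k - w)
                hi = min(i1, k + w)
                ang = _turn(sm[k] - sm[lo], sm[hi] - sm[k])
            if ang > params.theta_rev:
                cand.append((k, ang))
        # collapse candidate clusters: one physical turn spreads candidates
        # over a few frames.  The net turn across the cluster tells one
        # reversal (≈180°) apart from an out-and-back pair (≈0°).
        def flush(cluster):
            c0, cN = cluster[0][0], cluster[-1][0]
            a_in = xy[c0] - xy[max(i0, c0 - 2)]
            b_out = xy[min(i1, cN + 2)] - xy[cN]
            net = _turn(a_in, b_out)
            if net > params.theta_rev or len(cluster) == 1:
                events.append(max(cluster, key=lambda c: c[1])[0])
            elif cN - c0 >= params.dwell_min_frames:
                events.append(c0)
                events.append(cN)
            else:
                # direction resumed within the dwell window: an unresolvable
                # out-and-back pair; keep the first candidate
                events.append(c0)

        cluster: list[tuple[int, float]] = []
        for k, ang in cand + [(10 ** 9, 0.0)]:
            if cluster and k - cluster[-1][0] > 2:
                flush(cluster)
                cluster = []
            if k < 10 ** 9:
                cluster.append((k, ang))
    return np.asarray(sorted(set(events)), dtype=int)


def segment_runs_arrays(cell_id, t: np.ndarray, xy: np.ndarray,
                        persistent: np.ndarray,
                        reversal_idx: np.ndarray) -> list[dict]:
    """Tile one track into runs given state labels and reversal frames."""
    n = len(t)
    if n < 2:
        return []
    boundaries = []   # (frame index, event type) at run ends
    segs = _segments(persistent)
    for k, (i0, i1, val) in enumerate(segs[:-1]):
        boundaries.append((i1 + 1, "state_change"))
    for k in reversal_idx:
        boundaries.append((int(k), "reversal"))
    boundaries.sort()
    # deduplicate boundaries at identical frames (state change wins)
    dedup: dict[int, str] = {}
    for idx, ev in boundaries:
        if idx not in dedup or ev == "state_change":
            dedup[idx] = ev
    cuts = sorted(dedup)
    runs = []
    start = 0
    steps = np.hypot(*np.diff(xy, axis=0).T)
    cum = np.concatenate([[0.0], np.cumsum(steps)])
    for idx in cuts + [n - 1]:
        if idx <= start:
            continue
        end = idx
        state = PERSISTENT if persistent[start] else NON_PERSISTENT
        event = dedup.get(idx, "track_end") if idx != n - 1 else dedup.get(idx, "track_end")
        duration = float(t[end] - t[start])
        if duration <= 0:
            start = end
            continue
        net = xy[end] - xy[start]
        distance = float(np.hypot(*net))
        path = float(cum[end] - cum[start])
        runs.append({
            "cell_id": cell_id,
            "state": state,
            "t_start": float(t[start]),
            "t_end": float(t[end]),
            "t_mid": float(0.5 * (t[start] + t[end])),
            "duration": duration,
            "mean_speed": path / duration,
            "distance": distance,
            "orientation": float(np.arctan2(net[1], net[0]))
            if state == PERSISTENT and distance > 0 else np.nan,
            "end_event": event,
        })
        start = end
    return runs


# --------------------------------------------------------------------------
# DataFrame-level API
# --------------------------------------------------------------------------

def _per_cell(traj: pd.DataFrame):
    for cid, g in traj.groupby("cell_id", sort=True):
        g = g.sort_values("t_min")
        yield cid, g["t_min"].to_numpy(float), g[["x_um", "y_um"]].to_numpy(float)


def classify_states(traj: pd.DataFrame,
                    params: RunParams | None = None) -> dict:
    params = params or RunParams()
    return {cid: classify_states_arrays(t, xy, params)
            for cid, t, xy in _per_cell(traj)}


def detect_reversals(traj: pd.DataFrame, states: dict,
                     params: RunParams | None = None) -> dict:
    params = params or RunParams()
    out = {}
    for cid, t, xy in _per_cell(traj):
        out[cid] = t[detect_reversals_arrays(t, xy, states[cid], params)]
    return out


def segment_runs(traj: pd.DataFrame, states: dict, reversals: dict,
                 params: RunParams | None = None) -> pd.DataFrame:
    params = params or RunParams()
    rows = []
    for cid, t, xy in _per_cell(traj):
        rev_idx = np.searchsorted(t, reversals[cid]) if len(reversals[cid]) else np.array([], int)
        rows.extend(segment_runs_arrays(cid, t, xy, states[cid], rev_idx))
    return pd.DataFrame(rows)


def extract_runs(traj: pd.DataFrame,
                 params: RunParams | None = None) -> pd.DataFrame:
    """classify → detect reversals → segment, in one call."""
    params = params or RunParams()
    states = classify_states(traj, params)
    reversals = detect_reversals(traj, states, params)
    return segment_runs(traj, states, reversals, params)


# --------------------------------------------------------------------------
# alignment
# --------------------------------------------------------------------------

def nematic_mean(angles) -> float:
    """Axial (period-π) mean angle 0.5·atan2(Σ sin 2θ, Σ cos 2θ).

    Returns NaN for an empty input or a degenerate (zero-resultant) set.
    """
    angles = np.asarray(angles, dtype=float)
    if angles.size == 0:
        return float("nan")
    s = np.sin(2 * angles).sum()
    c = np.cos(2 * angles).sum()
    if np.hypot(s, c) < 1e-9 * angles.size:
        return float("nan")
    return float(0.5 * np.arctan2(s, c))


def local_alignment(theta_i: float, neighbor_thetas) -> float:
    """Alignment score γ = cos(2(θ_i − θ̄)) against the neighbors' nematic mean.

    NaN when there are no neighbors or their nematic mean is degenerate.
    """
    theta_bar = nematic_mean(neighbor_thetas)
    if not np.isfinite(theta_bar) or not np.isfinite(theta_i):
        return float("nan")
    return float(np.cos(2.0 * (theta_i - theta_bar)))


def frame_orientations(traj: pd.DataFrame,
                       params: RunParams | None = None) -> pd.DataFrame:
    """Per-frame motion orientation (radians) from smoothed displacements."""
    params = params or RunParams()
    parts = []
    for cid, g in traj.groupby("cell_id", sort=True):
        g = g.sort_values("t_min").copy()
        xy = g[["x_um", "y_um"]].to_numpy(float)
        sm = _smooth_positions(xy, params.smooth_frames)
        n = len(sm)
        ori = np.full(n, np.nan)
        if n >= 2:
            d = np.empty_like(sm)
            d[1:-1] = sm[2:] - sm[:-2]
            d[0] = sm[1] - sm[0]
            d[-1] = sm[-1] - sm[-2]
            ori = np.arctan2(d[:, 1], d[:, 0])
        g["orientation"] = ori
        parts.append(g)
    return pd.concat(parts, ignore_index=True)


class _AlignmentLookup:
    """Neighbor search over all tracked points (12 µm radius, 7-min window)."""

    def __init__(self, traj_o: pd.DataFrame, params: RunParams):
        self.params = params
        self.by_frame: dict[float, tuple] = {}
        for tf, g in traj_o.groupby("t_min"):
            self.by_frame[float(tf)] = (
                g[["x_um", "y_um"]].to_numpy(float),
                g["orientation"].to_numpy(float),
                g["cell_id"].to_numpy(),
            )
        self.frame_times = np.array(sorted(self.by_frame), dtype=float)
        self._cache: dict[float, tuple] = {}

    def _window(self, t: float):
        key = float(t)
        if key in self._cache:
            return self._cache[key]
        lo = t - self.params.alignment_window
        sel = self.frame_times[(self.frame_times > lo + 1e-9)
                               & (self.frame_times <= t + 1e-9)]
        if len(sel) == 0:
            out = (None, None, None, None)
        else:
            xs, os_, cs = [], [], []
            for tf in sel:
                x, o, c = self.by_frame[tf]
                xs.append(x)
                os_.append(o)
                cs.append(c)
            pts = np.vstack(xs)
            out = (cKDTree(pts), pts, np.concatenate(os_), np.concatenate(cs))
        self._cache[key] = out
        if len(self._cache) > 64:
            self._cache.pop(next(iter(self._cache)))
        return out

    def gamma(self, cell_id, t: float, x: float, y: float,
              theta_i: float) -> float:
        tree, pts, orients, cids = self._window(t)
        if tree is None:
            return float("nan")
        idx = tree.query_ball_point([x, y], self.params.alignment_radius)
        thetas = [orients[i] for i in idx
                  if cids[i] != cell_id and np.isfinite(orients[i])]
        if not thetas:
            return float("nan")
        return local_alignment(theta_i, thetas)


# --------------------------------------------------------------------------
# annotation
# --------------------------------------------------------------------------

def _wrap_angle(a: float) -> float:
    """Wrap to (−π, π]."""
    return float(np.arctan2(np.sin(a), np.cos(a)))


def annotate_runs(runs_df: pd.DataFrame, movie: DensityMovie | None,
                  aggset: AggregateSet | None, traj: pd.DataFrame,
                  params: RunParams | None = None,
                  t_coarsen: float | None = None,
                  pre_bin_width: float = 100.0,
                  coarsening_bins: int = 2,
                  fov_size: tuple[float, float] | None = None) -> RunDatabase:
    """Attach cue covariates to runs and assemble the run database.

    Adds local density (bilinear sample of the nearest normalized density
    frame at the run midpoint), alignment γ at the run start, the change of
    orientation from the previous run (with π removed after reversal events so
    values are comparable across event types), signed boundary distance and
    relative angle to the nearest aggregate, and the nearest aggregate's
    id/area/fate.  Runs whose nearest aggregate is only partially in the field
    of view are dropped, as are runs starting within ``params.fov_margin`` of
    the field edge when ``fov_size`` is given (edge truncation corrupts run
    orientations).
    """
    params = params or RunParams()
    runs_df = runs_df.sort_values(["cell_id", "t_start"]).reset_index(drop=True)
    traj_o = frame_orientations(traj, params)
    lookup = _AlignmentLookup(traj_o, params)

    n = len(runs_df)
    density = np.full(n, np.nan)
    gamma = np.full(n, np.nan)
    dori = np.full(n, np.nan)
    bdist = np.full(n, np.nan)
    rel = np.full(n, np.nan)
    agg_id = np.full(n, NO_AGGREGATE_ID, dtype=int)
    agg_area = np.zeros(n)
    agg_fate = np.array(["unknown"] * n, dtype=object)
    drop = np.zeros(n, dtype=bool)

    # position interpolators per cell
    pos_by_cell = {}
    for cid, t, xy in _per_cell(traj):
        pos_by_cell[cid] = (t, xy)

    def pos_at(cid, t):
        tt, xy = pos_by_cell[cid]
        x = np.interp(t, tt, xy[:, 0])
        y = np.interp(t, tt, xy[:, 1])
        return float(x), float(y)

    prev_orient: dict = {}
    prev_event: dict = {}

    for i, row in enumerate(runs_df.itertuples(index=False)):
        cid = row.cell_id
        xs, ys = pos_at(cid, row.t_start)
        xm, ym = pos_at(cid, row.t_mid)

        if fov_size is not None:
            mgn = params.fov_margin
            if (xs < mgn or xs > fov_size[0] - mgn
                    or ys < mgn or ys > fov_size[1] - mgn):
                drop[i] = True

        if movie is not None:
            fi = movie.frame_index(row.t_mid)
            if row.t_mid < movie.t0:
                warnings.warn("run precedes first density frame; "
                              "using nearest frame")
            col = xm / movie.pixel_size
            rowpix = ym / movie.pixel_size
            density[i] = float(ndimage.map_coordinates(
                movie.frames[fi], [[rowpix], [col]], order=1,
                mode="nearest")[0])

        theta = row.orientation
        gamma[i] = lookup.gamma(cid, row.t_start, xs, ys, theta)

        po = prev_orient.get(cid)
        if po is not None and np.isfinite(theta):
            base = po + (np.pi if prev_event.get(cid) == "reversal" else 0.0)
            dori[i] = _wrap_angle(theta - base)
        if np.isfinite(theta):
            prev_orient[cid] = theta
        prev_event[cid] = row.end_event

        if aggset is not None and len(aggset):
            trk, d = aggset.nearest(xs, ys, row.t_start)
            if trk is not None:
                if trk.partial_fov:
                    drop[i] = True
                bdist[i] = min(d, params.no_aggregate_distance)
                agg_id[i] = trk.agg_id
                agg_area[i] = trk.area_at(row.t_start)
                agg_fate[i] = trk.fate
                if np.isfinite(theta):
                    ci = trk.frame_index(row.t_start)
                    cx, cy = trk.centroid[ci]
                    to_agg = np.arctan2(cy - ys, cx - xs)
                    rel[i] = abs(_wrap_angle(theta - to_agg))
            else:
                bdist[i] = params.no_aggregate_distance
        else:
            bdist[i] = params.no_aggregate_distance

    out = runs_df.copy()
    out["local_density"] = density
    out["alignment_gamma"] = gamma
    out["delta_orientation"] = dori
    out["boundary_distance"] = bdist
    out["rel_angle"] = rel
    out["nearest_aggregate_id"] = agg_id
    out["nearest_aggregate_area"] = agg_area
    out["nearest_aggregate_fate"] = agg_fate
    out = out[~drop].reset_index(drop=True)

    t_lo = float(out["t_start"].min()) if len(out) else 0.0
    t_hi = float(out["t_end"].max()) if len(out) else 1.0
    bins = make_time_bins(t_lo, t_coarsen, t_hi, pre_bin_width, coarsening_bins)
    return RunDatabase(out, bins)
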