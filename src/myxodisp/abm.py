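"""Closed-loop, data-driven agent-based model of aggregation and dispersal.

Agents move in straight lines between reversals and stops.  When a run
expires, the agent's next state, reorientation, speed and run duration are
*resampled* from a database of experimentally (or synthetically) measured
runs via cue-matched nearest-neighbor searches: the cue vector combines the
current time bin, motile state, local density (from a Gaussian kernel density
estimate of agent positions), local nematic alignment, and the distance,
relative angle and area of the nearest in-simulation aggregate.  Aggregates
are detected on the KDE field with the same thresholding logic as the imaging
pipeline, closing the behavior → density → aggregate → behavior loop.

Three sequential searches determine (1) the state transition (reverse or
stop), (2) the change in orientation, and (3) jointly the speed and duration
of the next run; speed and duration are searched *after* reorienting because
they depend on the agent's new angle relative to the nearest aggregate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from . import aggregates as aggmod
from .aggregates import AggregateSet, DensityMovie
from .runs import (NO_AGGREGATE_DISTANCE, NON_PERSISTENT, PERSISTENT,
                   RunDatabase, nematic_mean)
from .stats import LogisticFit, logistic_from_tracks


@dataclass
class CueFlags:
    """Which optional cues enter which search."""

    area_in_state_search: bool = False
    area_in_duration_search: bool = False
    density_in_aggregation_phase: bool = True
    density_in_coarsening_phase: bool = False


def variant_flags(name: str) -> CueFlags:
    """Named cue configurations: full, bias-only, jam-only, no-area."""
    if name == "full":
        return CueFlags(True, True)
    if name == "bias-only":
        return CueFlags(False, True)
    if name == "jam-only":
        return CueFlags(True, False)
    if name == "no-area":
        return CueFlags(False, False)
    raise ValueError(f"unknown variant {name!r}")


@dataclass
class SimulationConfig:
    fov: tuple[float, float] = (500.0, 400.0)   # µm
    n_agents: int = 2000
    dt: float = 1.0                              # min
    t_start: float = 0.0
    t_end: float = 810.0                         # min
    kde_bandwidth: float = 7.0                   # µm
    pixel_size: float = 2.0                      # µm/px
    agg_threshold: Optional[float] = None        # normalized units; None = 3×uniform
    pinpoint_min_area: float = 300.0             # µm²
    time_bin_pre: float = 100.0                  # min
    coarsening_bins: int = 2
    t_coarsen: Optional[float] = None            # min (from config, not self-detected)
    cue_flags: CueFlags = field(default_factory=CueFlags)
    knn_k: int = 20
    init_duration: float = 90.0                  # min
    init_sample_window: float = 20.0             # min
    density_refresh: float = 15.0                # min
    alignment_radius: float = 12.0               # µm
    no_aggregate_distance: float = NO_AGGREGATE_DISTANCE
    seed: int = 0
    n_replicates: int = 3
    record_tracks: bool = False

    def __post_init__(self) -> None:
        if self.kde_bandwidth <= 0 or self.dt <= 0 or self.coarsening_bins < 1:
            raise ValueError("bandwidth, dt and bin count must be positive")
        if self.agg_threshold is not None and self.agg_threshold <= 0:
            raise ValueError("agg_threshold must be positive")

    @property
    def grid_shape(self) -> tuple[int, int]:
        nx = int(round(self.fov[0] / self.pixel_size))
        ny = int(round(self.fov[1] / self.pixel_size))
        return ny, nx

    def threshold(self) -> float:
        # default: twice the uniform level of the normalized field; explicit
        # values (e.g. the experiment-scale 2.16e-6) override
        if self.agg_threshold is not None:
            return self.agg_threshold
        ny, nx = self.grid_shape
        return 2.0 / (ny * nx)


# --------------------------------------------------------------------------
# nearest-neighbor search index
# --------------------------------------------------------------------------

STATE_SEARCH, ORIENT_SEARCH, DURATION_SEARCH = 0, 1, 2


class SearchIndex:
    """Per-(time bin, state, search) KD-trees over standardized cue vectors.

    Each cue is z-scored within its (bin, state) stratum, which weights all
    cues equally in the Euclidean search metric.  NaN cue values (missing
    alignment, undefined relative angle) are imputed with the stratum mean;
    zero-variance cues are dropped from the metric with a warning.  The
    density cue is active only in phases where the flags allow it and is
    standardized on the *query* side against the simulation's own density
    statistics, reconciling the fluorescence and KDE scales.
    """

    BASE_CUES = ("local_density", "alignment_gamma", "boundary_distance",
                 "rel_angle")

    def __init__(self, run_db: RunDatabase, flags: CueFlags, knn_k: int = 20):
        self.db = run_db
        self.flags = flags
        self.knn_k = knn_k
        self._strata: dict = {}
        self._build()

    def cue_names(self, bin_i: int, search: int) -> list[str]:
        phase = self.db.phase_of_bin(bin_i)
        cues = []
        density_on = (self.flags.density_in_aggregation_phase
                      if phase == "aggregation"
                      else self.flags.density_in_coarsening_phase)
        if density_on:
            cues.append("local_density")
        cues += ["alignment_gamma", "boundary_distance", "rel_angle"]
        if search == STATE_SEARCH and self.flags.area_in_state_search:
            cues.append("nearest_aggregate_area")
        if search == DURATION_SEARCH and self.flags.area_in_duration_search:
            cues.append("nearest_aggregate_area")
        return cues

    def _build(self) -> None:
        df = self.db.df
        for bin_i in range(len(self.db.time_bins)):
            for state in (PERSISTENT, NON_PERSISTENT):
                sub = df[(df["time_bin"] == bin_i) & (df["state"] == state)]
                for search in (STATE_SEARCH, ORIENT_SEARCH, DURATION_SEARCH):
                    s = sub
                    if search == STATE_SEARCH:
                        s = s[s["end_event"].isin(["reversal", "state_change"])]
                    if len(s) == 0:
                        if state == PERSISTENT:
                            raise ValueError(
                                f"empty stratum: bin {bin_i}, state {state}")
                        continue
                    self._strata[(bin_i, state, search)] = self._fit_stratum(
                        s, bin_i, search)

    def _fit_stratum(self, s: pd.DataFrame, bin_i: int, search: int) -> dict:
        cues = self.cue_names(bin_i, search)
        cols, means, sds, kept = [], [], [], []
        for c in cues:
            v = s[c].to_numpy(float)
            finite = np.isfinite(v)
            mu = float(v[finite].mean()) if finite.any() else 0.0
            v = np.where(finite, v, mu)
            sd = float(v.std())
            if sd <= 1e-12 * max(abs(mu), 1.0):
                warnings.warn(f"cue {c!r} has zero variance in bin {bin_i}; "
                              "dropped from the search metric")
                continue
            cols.append((v - mu) / sd)
            means.append(mu)
            sds.append(sd)
            kept.append(c)
        if cols:
            X = np.column_stack(cols)
            tree = cKDTree(X)
        else:
            X, tree = None, None
        return {
            "rows": s.reset_index(drop=True),
            "tree": tree,
            "cues": kept,
            "mean": np.array(means),
            "sd": np.array(sds),
        }

    def stratum(self, bin_i: int, state: str, search: int) -> dict:
        key = (bin_i, state, search)
        if key not in self._strata:
            raise KeyError(f"no rows for bin {bin_i}, state {state}")
        return self._strata[key]

    def query(self, bin_i: int, state: str, search: int,
              cue_values: dict[str, np.ndarray],
              rng: np.random.Generator,
              query_standardization: dict | None = None) -> pd.DataFrame:
        """k-NN search; returns one uniformly drawn matched row per query.

        ``cue_values`` maps cue name -> array over queries.
        ``query_standardization`` optionally overrides (mean, sd) for cues
        whose query-side scale differs from the database's (density).
        """
        st = self.stratum(bin_i, state, search)
        rows = st["rows"]
        n = len(next(iter(cue_values.values())))
        if st["tree"] is None:
            idx = rng.integers(len(rows), size=n)
            return rows.iloc[idx].reset_index(drop=True)
        cols = []
        for j, c in enumerate(st["cues"]):
            v = np.asarray(cue_values[c], dtype=float)
            if query_standardization and c in query_standardization:
                mu, sd = query_standardization[c]
            else:
                mu, sd = st["mean"][j], st["sd"][j]
            v = np.where(np.isfinite(v), v, mu)
            cols.append((v - mu) / max(sd, 1e-12))
        Q = np.column_stack(cols)
        k = min(self.knn_k, len(rows))
        if k < self.knn_k:
            warnings.warn(f"stratum smaller than k={self.knn_k}; using all rows")
        _, nn = st["tree"].query(Q, k=k)
        nn = np.atleast_2d(nn)
        if nn.shape[0] != len(Q):
            nn = nn.reshape(len(Q), -1)
        pick = rng.integers(nn.shape[1], size=len(Q))
        chosen = nn[np.arange(len(Q)), pick]
        return rows.iloc[chosen].reset_index(drop=True)


def build_search_index(run_db: RunDatabase, flags: CueFlags | None = None,
                       knn_k: int = 20) -> SearchIndex:
    return SearchIndex(run_db, flags or CueFlags(), knn_k)


# --------------------------------------------------------------------------
# world state
# --------------------------------------------------------------------------

class WorldState:
    """Agent arrays plus the KDE density field and in-simulation aggregates."""

    def __init__(self, cfg: SimulationConfig, rng: np.random.Generator):
        self.cfg = cfg
        n = cfg.n_agents
        w, h = cfg.fov
        self.x = rng.uniform(0, w, n)
        self.y = rng.uniform(0, h, n)
        self.theta = rng.uniform(-np.pi, np.pi, n)
        self.persistent = np.ones(n, dtype=bool)
        self.speed = np.zeros(n)
        self.time_remaining = rng.uniform(0, 2.0, n)
        self.t = cfg.t_start
        self.field: np.ndarray | None = None
        self.signed_dist: np.ndarray | None = None
        self.nearest_label: np.ndarray | None = None
        self.label_area: dict = {}
        self.label_centroid: dict = {}
        self.density_stats = (0.0, 1.0)
        self.refresh()

    # -- density field and aggregates -------------------------------------
    def refresh(self) -> None:
        cfg = self.cfg
        ny, nx = cfg.grid_shape
        col = np.clip((self.x / cfg.pixel_size).astype(int), 0, nx - 1)
        row = np.clip((self.y / cfg.pixel_size).astype(int), 0, ny - 1)
        hist = np.zeros((ny, nx))
        np.add.at(hist, (row, col), 1.0)
        sigma = cfg.kde_bandwidth / cfg.pixel_size
        f = ndimage.gaussian_filter(hist, sigma, mode="constant")
        total = f.sum()
        self.field = f / total if total > 0 else f
        self._detect_aggregates()
        d = self.density_at(self.x, self.y)
        self.density_stats = (float(d.mean()), float(max(d.std(), 1e-12)))

    def _detect_aggregates(self) -> None:
        cfg = self.cfg
        thr = cfg.threshold()
        mask = self.field > thr
        labels, n_lab = ndimage.label(mask, structure=np.ones((3, 3)))
        px_area = cfg.pixel_size ** 2
        areas = ndimage.sum_labels(mask, labels, index=np.arange(1, n_lab + 1)) * px_area
        keep = np.flatnonzero(areas >= cfg.pinpoint_min_area) + 1
        self.all_label_area = {int(l): float(areas[l - 1])
                               for l in range(1, n_lab + 1)}
        big = np.isin(labels, keep)
        self.labels = np.where(big, labels, 0)
        self.label_area = {int(l): float(areas[l - 1]) for l in keep}
        self.label_centroid = {}
        if len(keep):
            cents = ndimage.center_of_mass(big, labels, index=keep)
            for l, (cy, cx) in zip(keep, cents):
                self.label_centroid[int(l)] = (cx * cfg.pixel_size,
                                               cy * cfg.pixel_size)
            inside = ndimage.distance_transform_edt(big) * cfg.pixel_size
            outside, (ir, ic) = ndimage.distance_transform_edt(
                ~big, return_indices=True)
            outside = outside * cfg.pixel_size
            self.signed_dist = np.where(big, -inside, outside)
            self.nearest_label = self.labels[ir, ic]
        else:
            self.signed_dist = None
            self.nearest_label = None

    # -- per-agent cue evaluation ------------------------------------------
    def _pix(self, x, y):
        ny, nx = self.cfg.grid_shape
        col = np.clip(np.round(x / self.cfg.pixel_size).astype(int), 0, nx - 1)
        row = np.clip(np.round(y / self.cfg.pixel_size).astype(int), 0, ny - 1)
        return row, col

    def density_at(self, x, y) -> np.ndarray:
        col = x / self.cfg.pixel_size
        row = y / self.cfg.pixel_size
        return ndimage.map_coordinates(self.field, [row, col], order=1,
                                       mode="nearest")

    def aggregate_cues(self, x, y, theta):
        """(boundary_distance, rel_angle, area) arrays for given agents."""
        n = len(x)
        cap = self.cfg.no_aggregate_distance
        if self.signed_dist is None:
            return (np.full(n, cap), np.full(n, np.nan), np.zeros(n))
        row, col = self._pix(x, y)
        bd = np.minimum(self.signed_dist[row, col], cap)
        lab = self.nearest_label[row, col]
        area = np.array([self.label_area.get(int(l), 0.0) for l in lab])
        rel = np.full(n, np.nan)
        for i in range(n):
            l = int(lab[i])
            if l in self.label_centroid and np.isfinite(theta[i]):
                cx, cy = self.label_centroid[l]
                to_agg = np.arctan2(cy - y[i], cx - x[i])
                d = np.arctan2(np.sin(theta[i] - to_agg),
                               np.cos(theta[i] - to_agg))
                rel[i] = abs(d)
        return bd, rel, area

    def alignment_at(self, idx: np.ndarray) -> np.ndarray:
        """γ for the agents in ``idx`` from neighbors within 12 µm."""
        tree = cKDTree(np.column_stack([self.x, self.y]))
        out = np.full(len(idx), np.nan)
        pts = np.column_stack([self.x[idx], self.y[idx]])
        neighbor_lists = tree.query_ball_point(pts, self.cfg.alignment_radius)
        for j, (i, nbrs) in enumerate(zip(idx, neighbor_lists)):
            thetas = [self.theta[m] for m in nbrs if m != i]
            if not thetas:
                continue
            tb = nematic_mean(thetas)
            if np.isfinite(tb):
                out[j] = np.cos(2 * (self.theta[i] - tb))
        return out

    def aggregate_count(self) -> int:
        return len(self.label_area)

    def total_aggregate_area(self) -> float:
        return float(sum(self.label_area.values()))


# --------------------------------------------------------------------------
# behavior sampling
# --------------------------------------------------------------------------

def sample_next_behavior(index: SearchIndex, world: WorldState, idx: np.ndarray,
                         bin_i: int, rng: np.random.Generator) -> None:
    """Resample state, orientation, speed and duration for agents ``idx``.

    Implements the three sequential searches.  Reversals add π before the
    sampled reorientation is applied, so database Δθ values are comparable
    across event types.  Updates the world in place.
    """
    if len(idx) == 0:
        return
    x, y, theta = world.x[idx], world.y[idx], world.theta[idx]
    dens = world.density_at(x, y)
    gamma = world.alignment_at(idx)
    bd, rel, area = world.aggregate_cues(x, y, theta)
    qstd = {"local_density": world.density_stats}

    cues = {"local_density": dens, "alignment_gamma": gamma,
            "boundary_distance": bd, "rel_angle": rel,
            "nearest_aggregate_area": area}

    next_state = np.empty(len(idx), dtype=object)
    is_pers = world.persistent[idx]

    # search 1: state transition (persistent agents only; stopped agents
    # always resume the persistent state)
    p_sel = np.flatnonzero(is_pers)
    if len(p_sel):
        sub = {c: v[p_sel] for c, v in cues.items()}
        rows = index.query(bin_i, PERSISTENT, STATE_SEARCH, sub, rng, qstd)
        ev = rows["end_event"].to_numpy()
        next_state[p_sel] = np.where(ev == "state_change",
                                     NON_PERSISTENT, PERSISTENT)
    next_state[~is_pers] = PERSISTENT
    reversal = is_pers & (next_state == PERSISTENT)

    # search 2: reorientation, conditioned on the next state
    new_theta = theta.copy()
    for state in (PERSISTENT, NON_PERSISTENT):
        sel = np.flatnonzero(next_state == state)
        if not len(sel):
            continue
        sub = {c: v[sel] for c, v in cues.items()}
        try:
            rows = index.query(bin_i, state, ORIENT_SEARCH, sub, rng, qstd)
            dth = rows["delta_orientation"].to_numpy(float)
            dth = np.where(np.isfinite(dth), dth, 0.0)
        except KeyError:
            dth = np.zeros(len(sel))
        new_theta[sel] = theta[sel] + dth
    new_theta = new_theta + np.where(reversal, np.pi, 0.0)
    new_theta = np.arctan2(np.sin(new_theta), np.cos(new_theta))

    # search 3: joint (speed, duration), with rel_angle updated post-turn
    bd2, rel2, area2 = world.aggregate_cues(x, y, new_theta)
    cues3 = {"local_density": dens, "alignment_gamma": gamma,
             "boundary_distance": bd2, "rel_angle": rel2,
             "nearest_aggregate_area": area2}
    speed = np.zeros(len(idx))
    dur = np.full(len(idx), 1.0)
    for state in (PERSISTENT, NON_PERSISTENT):
        sel = np.flatnonzero(next_state == state)
        if not len(sel):
            continue
        sub = {c: v[sel] for c, v in cues3.items()}
        try:
            rows = index.query(bin_i, state, DURATION_SEARCH, sub, rng, qstd)
            dur[sel] = rows["duration"].to_numpy(float)
            if state == PERSISTENT:
                speed[sel] = rows["mean_speed"].to_numpy(float)
        except KeyError:
            dur[sel] = 5.0
    world.theta[idx] = new_theta
    world.persistent[idx] = next_state == PERSISTENT
    world.speed[idx] = np.where(next_state == PERSISTENT, speed, 0.0)
    world.time_remaining[idx] = np.maximum(dur, 1e-6)


def step(world: WorldState, cfg: SimulationConfig, index: SearchIndex,
         bin_i: int, rng: np.random.Generator) -> None:
    """Advance the world by one time step of ``cfg.dt`` minutes."""
    dt = cfg.dt
    mov = world.persistent & (world.speed > 0)
    world.x[mov] += world.speed[mov] * dt * np.cos(world.theta[mov])
    world.y[mov] += world.speed[mov] * dt * np.sin(world.theta[mov])
    _reflect_inplace(world, cfg)
    world.time_remaining -= dt
    expired = np.flatnonzero(world.time_remaining <= 0)
    sample_next_behavior(index, world, expired, bin_i, rng)
    world.t += dt


def _reflect_inplace(world: WorldState, cfg: SimulationConfig) -> None:
    w, h = cfg.fov
    for arr, lim, flip in ((world.x, w, "x"), (world.y, h, "y")):
        low = arr < 0
        high = arr > lim
        arr[low] = -arr[low]
        arr[high] = 2 * lim - arr[high]
        if flip == "x":
            world.theta[low | high] = np.pi - world.theta[low | high]
        else:
            world.theta[low | high] = -world.theta[low | high]
    np.clip(world.x, 0, w, out=world.x)
    np.clip(world.y, 0, h, out=world.y)


# --------------------------------------------------------------------------
# initialization and main loop
# --------------------------------------------------------------------------

def init_world(cfg: SimulationConfig, run_db: RunDatabase,
               rng: np.random.Generator) -> WorldState:
    """Random placement followed by a 90-min spin-up.

    The spin-up samples behavior only from runs in the first
    ``init_sample_window`` minutes of the database, using the reduced cue set
    {local density, alignment}; it develops initial density variations and
    alignment without advancing the main clock.
    """
    world = WorldState(cfg, rng)
    t0 = float(run_db.df["t_mid"].min())
    early = run_db.df[run_db.df["t_mid"]
                      <= t0 + cfg.init_sample_window].copy()
    if len(early) == 0:
        raise ValueError("run database does not cover the init window")
    from .runs import TimeBin
    init_db = RunDatabase(early.drop(columns=["time_bin"]),
                          [TimeBin(-np.inf, np.inf, "aggregation")])
    init_flags = CueFlags(False, False, True, True)
    init_index = _InitIndex(init_db, init_flags, cfg.knn_k)
    n_steps = int(round(cfg.init_duration / cfg.dt))
    refresh_every = max(1, int(round(cfg.density_refresh / cfg.dt)))
    for k in range(n_steps):
        if k and k % refresh_every == 0:
            world.refresh()
        step(world, cfg, init_index, 0, rng)
    world.t = cfg.t_start
    world.refresh()
    return world


class _InitIndex(SearchIndex):
    """Search index restricted to the {density, alignment} cue pair."""

    def cue_names(self, bin_i: int, search: int) -> list[str]:
        return ["local_density", "alignment_gamma"]


@dataclass
class SimResult:
    times: np.ndarray
    aggregate_count: np.ndarray
    total_area: np.ndarray
    field_movie: DensityMovie
    aggset: AggregateSet
    final_positions: np.ndarray
    seed: int
    tracks: Optional[pd.DataFrame] = None


def run_simulation(cfg: SimulationConfig, run_db: RunDatabase,
                   index: SearchIndex | None = None,
                   seed: Optional[int] = None) -> SimResult:
    """Init + main loop; returns time series, the simulated-field movie, and
    aggregate tracks with fates (the imaging pipeline applied to the KDE
    field snapshots)."""
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    if index is None:
        index = SearchIndex(run_db, cfg.cue_flags, cfg.knn_k)
    world = init_world(cfg, run_db, rng)

    n_steps = int(round((cfg.t_end - cfg.t_start) / cfg.dt))
    refresh_every = max(1, int(round(cfg.density_refresh / cfg.dt)))
    times, counts, areas, snapshots = [], [], [], []
    track_rows = []

    def snapshot():
        times.append(world.t)
        counts.append(world.aggregate_count())
        areas.append(world.total_aggregate_area())
        snapshots.append(world.field.copy())

    snapshot()
    for k in range(n_steps):
        bin_i = run_db.bin_of(world.t)
        step(world, cfg, index, bin_i, rng)
        if (k + 1) % refresh_every == 0:
            world.refresh()
            snapshot()
        if cfg.record_tracks:
            track_rows.append(pd.DataFrame({
                "cell_id": np.arange(cfg.n_agents),
                "t_min": world.t,
                "x_um": world.x.copy(),
                "y_um": world.y.copy(),
            }))

    movie = DensityMovie(np.asarray(snapshots), cfg.pixel_size,
                         cfg.density_refresh, t0=cfg.t_start)
    aggset = aggmod.segment_and_track(movie, cfg.threshold(),
                                      min_area=cfg.pinpoint_min_area)
    aggmod.annotate_flags(aggset, movie)
    tracks = pd.concat(track_rows, ignore_index=True) if track_rows else None
    return SimResult(np.asarray(times), np.asarray(counts), np.asarray(areas),
                     movie, aggset, np.column_stack([world.x, world.y]),
                     seed, tracks)


# --------------------------------------------------------------------------
# summaries
# --------------------------------------------------------------------------

def dispersal_summary(result: SimResult, t_coarsen: float) -> dict:
    """Percent decrease in aggregate count over coarsening plus a logistic
    stability fit on the simulated aggregates."""
    ti = int(np.argmin(np.abs(result.times - t_coarsen)))
    c0 = result.aggregate_count[ti]
    c1 = result.aggregate_count[-1]
    pct = float("nan") if c0 == 0 else 100.0 * (c0 - c1) / c0
    fit: LogisticFit | None
    try:
        fit = logistic_from_tracks(result.aggset, t_coarsen)
    except ValueError:
        fit = None
    return {"pct_decrease_in_count": pct, "logistic_fit": fit,
            "count_at_coarsen": int(c0), "count_at_end": int(c1)}


def sub_threshold_dispersal(result: SimResult, t_coarsen: float,
                            area_star: float,
                            margin: float = 30.0) -> tuple[float, int]:
    """(fraction dispersed, n) among aggregates below ``area_star`` at the
    coarsening start.  Short-lived, motile, and merged tracks are excluded:
    only genuine dispersal (density lost to the field) counts."""
    n, gone = 0, 0
    for trk in result.aggset:
        if not (trk.t_first <= t_coarsen <= trk.t_last):
            continue
        if trk.short_lived or trk.motile or trk.fate == "merged":
            continue
        if trk.area_at(t_coarsen) >= area_star:
            continue
        n += 1
        if trk.fate == "unstable":
            gone += 1
    return (gone / n if n else float("nan")), n
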