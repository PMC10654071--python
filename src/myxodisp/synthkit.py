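"""Synthetic trajectories, density movies, and run databases.

This module generates data with the statistical structure the analysis
pipeline assumes, with known ground truth, so that every downstream stage can
be tested without the original microscopy stacks:

* cells perform a biased persistent random walk — exponential run durations
  whose mean is longer when the cell's heading points (within 90°) toward the
  nearest aggregate centroid than when it points away;
* a density-dependent traffic jam — at the end of a persistent run the cell
  either reverses (180° flip plus orientation noise) or, with probability
  ``p_stop(ρ)``, stops for an exponential non-persistent interval of mean
  ``tau_stop(ρ)``;
* aggregates are disks whose radius can grow and, optionally, disperse: after
  ``disperse_at`` the radius (and the matching Gaussian blob in the density
  movie) ramps linearly to zero over ``dispersal_ramp`` minutes;
* an optional coarsening-phase *bias flip*: after ``flip_time``, cells near
  aggregates smaller than ``flip_area`` swap their toward/away run-duration
  means (net drift away from small aggregates) and weaken their jamming
  response — the behavioral signature of aggregate dispersal.

The behavioral local density is a step function (1 inside the nearest
aggregate disk, 0 outside) so that the inside/outside jam dichotomy has an
exact ground truth; the imaging movie uses smooth Gaussian blobs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point

from .aggregates import AggregateSet, AggregateTrack, DensityMovie
from .runs import (NO_AGGREGATE_DISTANCE, NO_AGGREGATE_ID, NON_PERSISTENT,
                   PERSISTENT, RunDatabase, make_time_bins)

ParamFn = Callable[[float], float]


def _as_fn(v) -> ParamFn:
    if callable(v):
        return v
    x = float(v)
    return lambda _a, _x=x: _x


def linear_in_density(lo: float, hi: float) -> ParamFn:
    """Parameter rising linearly from ``lo`` at ρ=0 to ``hi`` at ρ=1."""
    return lambda rho: lo + (hi - lo) * float(np.clip(rho, 0.0, 1.0))


@dataclass
class AggregateSpec:
    """One synthetic aggregate: a disk, optionally growing then dispersing."""

    center: tuple[float, float]       # µm
    radius: float                     # initial radius, µm
    growth_rate: float = 0.0          # µm/min
    disperse_at: Optional[float] = None   # min, None = stable

    def radius_at(self, t: float, ramp: float) -> float:
        r = self.radius + self.growth_rate * min(
            t, self.disperse_at if self.disperse_at is not None else t)
        if self.disperse_at is not None and t > self.disperse_at:
            r *= max(0.0, 1.0 - (t - self.disperse_at) / ramp)
        return max(r, 0.0)

    def area_at(self, t: float, ramp: float) -> float:
        r = self.radius_at(t, ramp)
        return np.pi * r * r


@dataclass
class SyntheticWorldConfig:
    """Ground-truth parameters of a synthetic world.

    ``tau_toward`` / ``tau_away`` map the nearest aggregate's area (µm²) to
    the mean persistent run duration (min); constants are accepted.
    ``p_stop`` and ``tau_stop`` map the relative local density ρ ∈ [0, 1]
    (1 inside an aggregate disk) to the stopping probability at run end and
    the mean stop duration.  When ``flip_time``/``flip_area`` are set, cells
    near sub-``flip_area`` aggregates after ``flip_time`` swap their
    toward/away means and multiply p_stop / tau_stop by the flip factors.
    """

    fov_size: tuple[float, float] = (500.0, 400.0)       # µm
    aggregates: Sequence[AggregateSpec] = field(default_factory=list)
    n_cells: int = 200
    frame_interval: float = 1.0        # min (tdTomato cadence)
    duration: float = 600.0            # min
    speed_mean: float = 2.5            # µm/min
    speed_sd: float = 0.5
    speed_jam: float = 0.0             # fractional speed reduction at ρ=1
                                       # (the jam's slow-down component)
    tau_toward: float | ParamFn = 6.0  # min
    tau_away: float | ParamFn = 4.0
    p_stop: float | ParamFn = 0.0
    tau_stop: float | ParamFn = 6.0
    min_run: float = 3.0               # min; refractory floor on persistent
                                       # run durations (0 = pure exponential)
    min_stop: float = 2.0              # min; floor on stop durations
    orientation_noise_sd: float = 0.2  # radians
    position_noise_sd: float = 0.05    # µm, added to recorded frames
    background_intensity: float = 1.0
    blob_amplitude: float = 5.0
    noise_sd: float = 0.0
    pixel_size: float = 2.0            # µm/px for density movies
    movie_interval: float = 15.0       # min (GFP cadence)
    dispersal_ramp: float = 60.0       # min
    density_profile: str = "step"      # "step" (1 inside, 0 outside) or
                                       # "smooth" (exponential falloff from
                                       # the aggregate boundary)
    density_decay: float = 20.0        # µm; falloff length for "smooth"
    density_noise: float = 0.1         # sd of covariate noise for "smooth"
    aggregate_onset: float = 0.0       # min; run-database rows before this
                                       # time carry no-aggregate sentinels
                                       # (pre-aggregation phase)
    flip_time: Optional[float] = None
    flip_area: Optional[float] = None
    flip_pstop_factor: float = 0.4
    flip_taustop_factor: float = 0.5
    n_runs: int = 10000                # rows for gen_run_database
    seed: int = 0

    def __post_init__(self) -> None:
        w, h = self.fov_size
        if w <= 0 or h <= 0 or self.n_cells < 1 or self.frame_interval <= 0:
            raise ValueError("invalid field of view, cell count, or cadence")
        for name in ("tau_toward", "tau_away", "tau_stop"):
            fn = _as_fn(getattr(self, name))
            probe = fn(1000.0) if name != "tau_stop" else fn(0.5)
            if not np.isfinite(probe) or probe <= 0:
                raise ValueError(f"{name} must be positive and finite")
        p = _as_fn(self.p_stop)(0.5)
        if not np.isfinite(p) or not (0.0 <= p <= 1.0):
            raise ValueError("p_stop must lie in [0, 1]")

    # -- effective (possibly flipped) behavioral parameters ---------------
    def _flipped(self, area: float, t: float) -> bool:
        return (self.flip_time is not None and self.flip_area is not None
                and t >= self.flip_time and 0.0 < area < self.flip_area)

    def run_tau(self, area: float, t: float, toward: bool) -> float:
        tt = _as_fn(self.tau_toward)(area)
        ta = _as_fn(self.tau_away)(area)
        if self._flipped(area, t):
            tt, ta = ta, tt
        return tt if toward else ta

    def stop_prob(self, rho: float, area: float, t: float) -> float:
        p = _as_fn(self.p_stop)(rho)
        if self._flipped(area, t):
            p *= self.flip_pstop_factor
        return float(np.clip(p, 0.0, 1.0))

    def stop_tau(self, rho: float, area: float, t: float) -> float:
        tau = _as_fn(self.tau_stop)(rho)
        if self._flipped(area, t):
            tau *= self.flip_taustop_factor
        return tau

    # -- run-duration model ------------------------------------------------
    # Shifted exponentials: a refractory floor plus an exponential tail, with
    # the mean equal to tau.  Reversal intervals in gliding bacteria are
    # peaked rather than exponential near zero; the floor also keeps run
    # durations resolvable at the tracking cadence.
    def draw_run_duration(self, tau: float, rng: np.random.Generator) -> float:
        floor = min(self.min_run, 0.9 * tau)
        return floor + rng.exponential(tau - floor)

    def draw_stop_duration(self, tau: float, rng: np.random.Generator) -> float:
        floor = min(self.min_stop, 0.9 * tau)
        return floor + rng.exponential(tau - floor)

    def draw_speed(self, rho: float, rng: np.random.Generator) -> float:
        mu = self.speed_mean * (1.0 - self.speed_jam * np.clip(rho, 0, 1))
        return max(0.2, rng.normal(mu, self.speed_sd))

    # -- world queries -----------------------------------------------------
    def nearest_aggregate(self, x: float, y: float, t: float):
        """(index, signed boundary distance, area) of the nearest live
        aggregate, nearest meaning minimal boundary (not centroid) distance —
        the same rule the run-annotation stage uses."""
        best, bd, ba = None, np.inf, 0.0
        for i, agg in enumerate(self.aggregates):
            r = agg.radius_at(t, self.dispersal_ramp)
            if r <= 0:
                continue
            d = float(np.hypot(x - agg.center[0], y - agg.center[1])) - r
            if d < bd:
                best, bd, ba = i, d, np.pi * r * r
        return best, bd, ba

    def density_at_bd(self, bd: float) -> float:
        """Relative density as a function of signed boundary distance."""
        if self.density_profile == "step":
            return 1.0 if bd < 0 else 0.0
        return float(np.exp(-max(bd, 0.0) / self.density_decay))

    def density_rel(self, x: float, y: float, t: float) -> float:
        """Relative behavioral density at a point (1 deep inside a disk)."""
        _, bd, _ = self.nearest_aggregate(x, y, t)
        if bd is None or not np.isfinite(bd):
            return 0.0
        return self.density_at_bd(bd)


def expected_bias(cfg: SyntheticWorldConfig, area: float,
                  t: float = 0.0) -> float:
    """Closed-form reversal bias for the constant-speed, zero-stop regime.

    Under pure alternating reversals, toward and away runs occur in equal
    numbers per track, so the run-level mean of all persistent run durations
    converges to (τ_t + τ_a)/2 and the bias to
    ``(τ_t − τ_a) / ((τ_t + τ_a)/2)``.
    """
    tt = cfg.run_tau(area, t, True)
    ta = cfg.run_tau(area, t, False)
    return (tt - ta) / (0.5 * (tt + ta))


# --------------------------------------------------------------------------
# trajectory generation
# --------------------------------------------------------------------------

def _reflect(p: float, lo: float, hi: float) -> tuple[float, int]:
    """Fold p into [lo, hi]; return folded value and parity of reflections."""
    span = hi - lo
    q = (p - lo) % (2 * span)
    if q <= span:
        return lo + q, 0
    return hi - (q - span), 1


@dataclass
class SyntheticTracks:
    """Generated trajectory table plus ground truth for validation."""

    table: pd.DataFrame        # cell_id, t_min, x_um, y_um
    true_runs: pd.DataFrame    # per-run ground truth
    reversal_times: dict       # cell_id -> array of event times (min)


def gen_trajectories(cfg: SyntheticWorldConfig,
                     rng: np.random.Generator | None = None) -> SyntheticTracks:
    """Simulate biased persistent random walks and sample them at the
    trajectory cadence.  Deterministic given ``cfg.seed``."""
    rng = rng or np.random.default_rng(cfg.seed)
    w, h = cfg.fov_size
    fi = cfg.frame_interval
    n_frames = int(np.floor(cfg.duration / fi)) + 1
    frame_times = np.arange(n_frames) * fi

    rows_cell, rows_t, rows_x, rows_y = [], [], [], []
    true_runs = []
    rev_times: dict = {}

    for cid in range(cfg.n_cells):
        x = rng.uniform(0, w)
        y = rng.uniform(0, h)
        theta = rng.uniform(-np.pi, np.pi)
        t = 0.0
        state = PERSISTENT
        revs = []
        next_frame = 0

        def record(px, py):
            rows_cell.append(cid)
            rows_t.append(frame_times[len(rows_t) - frame_offset])
            rows_x.append(np.clip(px + rng.normal(0, cfg.position_noise_sd), 0, w))
            rows_y.append(np.clip(py + rng.normal(0, cfg.position_noise_sd), 0, h))

        frame_offset = len(rows_t)
        record(x, y)
        next_frame = 1

        while t < cfg.duration - 1e-9:
            x0, y0 = x, y
            agg_i, _, area = cfg.nearest_aggregate(x, y, t)
            if state == PERSISTENT:
                toward = False
                if agg_i is not None:
                    agg = cfg.aggregates[agg_i]
                    to_agg = np.arctan2(agg.center[1] - y, agg.center[0] - x)
                    toward = abs(np.arctan2(np.sin(theta - to_agg),
                                            np.cos(theta - to_agg))) < np.pi / 2
                tau = cfg.run_tau(area, t, toward)
                dur = cfg.draw_run_duration(tau, rng)
                speed = cfg.draw_speed(cfg.density_rel(x, y, t), rng)
            else:
                rho = cfg.density_rel(x, y, t)
                dur = cfg.draw_stop_duration(cfg.stop_tau(rho, area, t), rng)
                speed = 0.0
                toward = False
            t_end = min(t + dur, cfg.duration)

            # advance frame by frame within the run (reflecting walls)
            tc = t
            while tc < t_end - 1e-9:
                t_next = min(frame_times[next_frame]
                             if next_frame < n_frames else np.inf, t_end)
                dt = t_next - tc
                if speed > 0:
                    x += speed * dt * np.cos(theta)
                    y += speed * dt * np.sin(theta)
                    x, px_flip = _reflect(x, 0.0, w)
                    y, py_flip = _reflect(y, 0.0, h)
                    if px_flip:
                        theta = np.pi - theta
                    if py_flip:
                        theta = -theta
                tc = t_next
                if next_frame < n_frames and abs(tc - frame_times[next_frame]) < 1e-9:
                    record(x, y)
                    next_frame += 1

            ended_naturally = t_end < cfg.duration - 1e-9
            end_event = "track_end"
            if ended_naturally:
                if state == PERSISTENT:
                    rho = cfg.density_rel(x, y, t_end)
                    if rng.random() < cfg.stop_prob(rho, area, t_end):
                        end_event = "state_change"
                    else:
                        end_event = "reversal"
                else:
                    end_event = "state_change"
            true_runs.append({
                "cell_id": cid, "state": state, "t_start": t, "t_end": t_end,
                "duration": t_end - t, "toward": bool(toward),
                "end_event": end_event, "area": area,
                "rho_start": cfg.density_rel(x0, y0, t),
                "rho_end": cfg.density_rel(x, y, t_end),
            })
            t = t_end
            if not ended_naturally:
                break
            if end_event == "reversal":
                revs.append(t)
                theta = theta + np.pi + rng.normal(0, cfg.orientation_noise_sd)
            elif state == PERSISTENT:
                state = NON_PERSISTENT
            else:
                state = PERSISTENT
                flip = np.pi if rng.random() < 0.5 else 0.0
                theta = theta + flip + rng.normal(0, cfg.orientation_noise_sd)
        rev_times[cid] = np.asarray(revs)

    table = pd.DataFrame({
        "cell_id": rows_cell, "t_min": rows_t,
        "x_um": rows_x, "y_um": rows_y,
    })
    return SyntheticTracks(table, pd.DataFrame(true_runs), rev_times)


# --------------------------------------------------------------------------
# density movies
# --------------------------------------------------------------------------

def gen_density_movie(cfg: SyntheticWorldConfig,
                      rng: np.random.Generator | None = None) -> DensityMovie:
    """Gaussian-blob density movie at the 15-min imaging cadence.

    Uniform background plus one isotropic Gaussian blob per aggregate
    (σ = radius/2) whose width follows the configured growth and whose
    amplitude ramps to zero over ``dispersal_ramp`` minutes after
    ``disperse_at``.  Additive Gaussian pixel noise.  Deterministic per seed.
    """
    rng = rng or np.random.default_rng(cfg.seed + 1)
    w, h = cfg.fov_size
    nx = int(round(w / cfg.pixel_size))
    ny = int(round(h / cfg.pixel_size))
    xs = (np.arange(nx) + 0.0) * cfg.pixel_size
    ys = (np.arange(ny) + 0.0) * cfg.pixel_size
    gx, gy = np.meshgrid(xs, ys)
    times = np.arange(0.0, cfg.duration + 1e-9, cfg.movie_interval)
    frames = np.empty((len(times), ny, nx), dtype=np.float64)
    for k, t in enumerate(times):
        f = np.full((ny, nx), cfg.background_intensity, dtype=np.float64)
        for agg in cfg.aggregates:
            r = agg.radius_at(t, cfg.dispersal_ramp)
            if r <= 0:
                continue
            amp = cfg.blob_amplitude
            if agg.disperse_at is not None and t > agg.disperse_at:
                amp *= max(0.0, 1.0 - (t - agg.disperse_at) / cfg.dispersal_ramp)
            sigma = r / 2.0
            d2 = (gx - agg.center[0]) ** 2 + (gy - agg.center[1]) ** 2
            f += amp * np.exp(-d2 / (2 * sigma * sigma))
        if cfg.noise_sd > 0:
            f += rng.normal(0, cfg.noise_sd, size=f.shape)
        frames[k] = f
    return DensityMovie(frames, cfg.pixel_size, cfg.movie_interval, 0.0)


def ground_truth_aggregates(cfg: SyntheticWorldConfig) -> AggregateSet:
    """Analytic aggregate tracks (disk contours) matching the generator."""
    times = np.arange(0.0, cfg.duration + 1e-9, cfg.movie_interval)
    tracks = []
    for i, agg in enumerate(cfg.aggregates):
        ts, cents, areas, contours = [], [], [], []
        for t in times:
            r = agg.radius_at(t, cfg.dispersal_ramp)
            if r <= 0:
                continue
            ts.append(t)
            cents.append(agg.center)
            areas.append(np.pi * r * r)
            contours.append(Point(agg.center).buffer(r, quad_segs=64))
        if not ts:
            continue
        fate = "unstable" if agg.disperse_at is not None else "stable"
        tracks.append(AggregateTrack(
            agg_id=i, t=np.asarray(ts), centroid=np.asarray(cents, float),
            area=np.asarray(areas), contours=contours, fate=fate))
    return AggregateSet(tracks)


# --------------------------------------------------------------------------
# direct run-database generation
# --------------------------------------------------------------------------

def gen_run_database(cfg: SyntheticWorldConfig,
                     rng: np.random.Generator | None = None,
                     runs_per_cell: int = 25) -> RunDatabase:
    """Sample run records directly (bypassing trajectory extraction).

    Covariates are drawn over the cue space (time, inside/outside position,
    relative angle, alignment); durations and end events follow the same
    distributions the trajectory generator uses, so the database is a fast
    stand-in for the full extraction pipeline in agent-model tests.
    """
    rng = rng or np.random.default_rng(cfg.seed + 2)
    n = cfg.n_runs
    rows = []
    has_aggs = len(cfg.aggregates) > 0
    for i in range(n):
        cid = i // runs_per_cell
        t_mid = rng.uniform(0, cfg.duration)
        if has_aggs and t_mid >= cfg.aggregate_onset:
            # cells concentrate near larger aggregates: weight by area
            areas_now = np.array([
                a.area_at(t_mid, cfg.dispersal_ramp) for a in cfg.aggregates])
            if areas_now.sum() > 0:
                ai = int(rng.choice(len(cfg.aggregates),
                                    p=areas_now / areas_now.sum()))
            else:
                ai = int(rng.integers(len(cfg.aggregates)))
            agg = cfg.aggregates[ai]
            r = agg.radius_at(t_mid, cfg.dispersal_ramp)
        else:
            ai, r = NO_AGGREGATE_ID, 0.0
        if ai != NO_AGGREGATE_ID and r > 0:
            area = np.pi * r * r
            inside = rng.random() < 0.35
            bd = -rng.uniform(0, r) if inside else min(
                rng.uniform(0, 3 * r), NO_AGGREGATE_DISTANCE)
            rho = cfg.density_at_bd(bd)
            if cfg.density_profile == "smooth":
                rho = float(np.clip(rho + rng.normal(0, cfg.density_noise),
                                    0.0, 1.0))
            rel_angle = rng.uniform(0, np.pi)
            fate = "unstable" if agg.disperse_at is not None else "stable"
        else:
            ai = NO_AGGREGATE_ID
            area, bd = 0.0, NO_AGGREGATE_DISTANCE
            # density still varies without aggregates (streams, fluctuations)
            rho = (float(np.clip(abs(rng.normal(0, 0.25)), 0, 1))
                   if cfg.density_profile == "smooth" else 0.0)
            rel_angle = np.nan
            fate = "unknown"
        toward = bool(rel_angle < np.pi / 2) if np.isfinite(rel_angle) else False
        gamma = float(np.clip(rng.normal(0.5, 0.4), -1, 1))
        persistent = rng.random() < 0.8
        if persistent:
            tau = cfg.run_tau(area, t_mid, toward)
            dur = cfg.draw_run_duration(tau, rng)
            speed = cfg.draw_speed(rho, rng)
            stop = rng.random() < cfg.stop_prob(rho, area, t_mid)
            end_event = "state_change" if stop else "reversal"
            dori = rng.normal(0, cfg.orientation_noise_sd)
            orientation = rng.uniform(-np.pi, np.pi)
        else:
            dur = cfg.draw_stop_duration(cfg.stop_tau(rho, area, t_mid), rng)
            speed = 0.0
            end_event = "state_change"
            dori = rng.normal(0, 1.0)
            orientation = np.nan
        rows.append({
            "cell_id": cid,
            "state": PERSISTENT if persistent else NON_PERSISTENT,
            "t_start": max(0.0, t_mid - dur / 2),
            "t_end": min(cfg.duration, t_mid + dur / 2),
            "t_mid": t_mid,
            "duration": dur,
            "mean_speed": speed,
            "distance": speed * dur,
            "orientation": orientation,
            "end_event": end_event,
            "local_density": rho,
            "alignment_gamma": gamma,
            "delta_orientation": dori,
            "boundary_distance": bd,
            "rel_angle": rel_angle,
            "nearest_aggregate_id": ai,
            "nearest_aggregate_area": area,
            "nearest_aggregate_fate": fate,
        })
    df = pd.DataFrame(rows)
    bins = make_time_bins(0.0, cfg.flip_time, cfg.duration)
    return RunDatabase(df, bins)
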