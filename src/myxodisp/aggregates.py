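"""Aggregate segmentation, tracking, and fate analysis from density movies.

Fruiting-body aggregates are detected in GFP-channel density movies (total
fluorescence intensity is a proxy for cell density).  Frames are normalized so
the total intensity is invariant from frame to frame, a single Otsu threshold
computed on a reference frame is rescaled onto that normalized scale, and
connected components above the threshold are tracked through time.  Tracks are
flagged as motile / short-lived / partial field of view, labeled with a
stable/unstable fate, and used to locate the start of the coarsening phase
(the time at which the total area of long-lived, stationary, ultimately
unstable aggregates begins its final decline).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from shapely.geometry import Point, Polygon
from skimage import measure
from skimage.filters import threshold_otsu


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------

@dataclass
class DensityMovie:
    """A stack of 2-D density frames with physical calibration.

    Parameters
    ----------
    frames : ndarray, shape (n_frames, ny, nx)
        Nonnegative scalar intensity frames (row = y, col = x).
    pixel_size : float
        Pixel edge length in µm.
    frame_interval : float
        Time between frames in minutes.
    t0 : float
        Time of the first frame in minutes.
    """

    frames: np.ndarray
    pixel_size: float
    frame_interval: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n_frames, ny, nx) stack")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValueError("pixel_size and frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.frame_interval * np.arange(self.n_frames)

    def frame_index(self, t: float) -> int:
        """Index of the frame nearest in time to ``t`` (clipped to range)."""
        i = int(round((t - self.t0) / self.frame_interval))
        return min(max(i, 0), self.n_frames - 1)


@dataclass
class AggregateTrack:
    """One aggregate followed through time.

    ``t``, ``centroid`` (µm, image coordinates: x right, y down), ``area``
    (µm²) and ``contours`` (shapely polygons in µm) are per-live-frame series.
    """

    agg_id: int
    t: np.ndarray
    centroid: np.ndarray
    area: np.ndarray
    contours: list = field(default_factory=list)
    motile: bool = False
    short_lived: bool = False
    partial_fov: bool = False
    fate: str = "unknown"
    merged_into: int | None = None

    @property
    def t_first(self) -> float:
        return float(self.t[0])

    @property
    def t_last(self) -> float:
        return float(self.t[-1])

    def frame_index(self, t: float) -> int:
        i = int(np.argmin(np.abs(self.t - t)))
        return i

    def area_at(self, t: float) -> float:
        return float(self.area[self.frame_index(t)])


class AggregateSet:
    """A collection of :class:`AggregateTrack` with spatial query helpers."""

    def __init__(self, tracks: list[AggregateTrack]):
        self.tracks = list(tracks)

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self):
        return iter(self.tracks)

    def alive_at(self, t: float, tol: float = 1e-9) -> list[AggregateTrack]:
        return [a for a in self.tracks if a.t_first - tol <= t <= a.t_last + tol]

    def nearest(self, x: float, y: float, t: float, min_area: float = 0.0,
                exclude_partial: bool = False):
        """Nearest aggregate by signed boundary distance at time ``t``.

        Returns ``(track, signed_distance)`` or ``(None, None)`` if no
        aggregate is alive.  Negative distance means the point lies inside the
        aggregate contour; ties are broken in favor of the larger aggregate.
        """
        pt = Point(x, y)
        best = None
        best_d = None
        best_area = -1.0
        for trk in self.alive_at(t):
            if exclude_partial and trk.partial_fov:
                continue
            i = trk.frame_index(t)
            if trk.area[i] < min_area:
                continue
            poly = trk.contours[i]
            if poly is None:
                # fall back to a disk with matching area about the centroid
                r = float(np.sqrt(trk.area[i] / np.pi))
                d = float(np.hypot(x - trk.centroid[i, 0],
                                   y - trk.centroid[i, 1])) - r
            else:
                d = poly.exterior.distance(pt)
                if poly.contains(pt):
                    d = -d
            if (best_d is None or d < best_d - 1e-12
                    or (abs(d - best_d) <= 1e-12 and trk.area[i] > best_area)):
                best, best_d, best_area = trk, d, float(trk.area[i])
        if best is None:
            return None, None
        return best, float(best_d)

    def to_frame(self):
        """Tidy per-(aggregate, frame) table."""
        import pandas as pd

        rows = []
        for trk in self.tracks:
            for i in range(len(trk.t)):
                rows.append({
                    "agg_id": trk.agg_id,
                    "t_min": trk.t[i],
                    "centroid_x_um": trk.centroid[i, 0],
                    "centroid_y_um": trk.centroid[i, 1],
                    "area_um2": trk.area[i],
                    "motile": trk.motile,
                    "short_lived": trk.short_lived,
                    "partial_fov": trk.partial_fov,
                    "fate": trk.fate,
                })
        return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# normalization and thresholding
# --------------------------------------------------------------------------

def normalize_frames(movie: DensityMovie) -> DensityMovie:
    """Normalize each frame so its total intensity is exactly 1.

    Each frame has its mean subtracted, is then shifted by its minimum so all
    pixels are nonnegative, and is finally divided by its total.  The shift
    makes the total well defined (a mean-subtracted frame sums to zero) while
    keeping the frame-to-frame invariant total that the scaled threshold
    relies on.  Raises on constant frames.
    """
    out = np.empty_like(movie.frames)
    for i, f in enumerate(movie.frames):
        g = f - f.mean()
        if np.ptp(g) == 0:
            raise ValueError(f"frame {i} is constant; cannot normalize")
        g = g - g.min()
        out[i] = g / g.sum()
    return DensityMovie(out, movie.pixel_size, movie.frame_interval, movie.t0)


def compute_scaled_threshold(movie: DensityMovie, t_ref: float) -> float:
    """Otsu threshold on the reference frame, mapped to the normalized scale.

    The reference frame (the frame nearest ``t_ref``, conventionally halfway
    between aggregate initiation and the coarsening start) is rescaled to
    [0, 1]; Otsu's method on a 256-bin histogram gives ``I_thresh``; the
    returned threshold is ``(a_max - a_min) * I_thresh + a_min`` where
    ``a_min``/``a_max`` are the frame's extrema on the normalized scale, so it
    applies directly to every normalized frame.
    """
    f = movie.frames[movie.frame_index(t_ref)]
    a_min, a_max = float(f.min()), float(f.max())
    if a_max == a_min:
        raise ValueError("reference frame is constant")
    scaled = (f - a_min) / (a_max - a_min)
    counts, _ = np.histogram(scaled, bins=256, range=(0.0, 1.0))
    if np.count_nonzero(counts) < 2:
        warnings.warn("reference frame histogram is unimodal; "
                      "Otsu threshold may be unreliable")
    i_thresh = float(threshold_otsu(scaled, nbins=256))
    return (a_max - a_min) * i_thresh + a_min


# --------------------------------------------------------------------------
# segmentation and tracking
# --------------------------------------------------------------------------

def _frame_components(frame: np.ndarray, threshold: float, pixel_size: float,
                      min_area: float):
    """Connected components (8-connectivity) above threshold, in µm units."""
    mask = frame > threshold
    labels = measure.label(mask, connectivity=2)
    comps = []
    for rp in measure.regionprops(labels):
        area = rp.area * pixel_size ** 2
        if area < min_area:
            continue
        cy, cx = rp.centroid
        touches = (rp.bbox[0] == 0 or rp.bbox[1] == 0
                   or rp.bbox[2] == frame.shape[0]
                   or rp.bbox[3] == frame.shape[1])
        comp_mask = labels == rp.label
        poly = _component_polygon(comp_mask, pixel_size)
        comps.append({
            "centroid": np.array([cx * pixel_size, cy * pixel_size]),
            "area": area,
            "polygon": poly,
            "touches_border": touches,
        })
    return comps


def _component_polygon(mask: np.ndarray, pixel_size: float):
    """Largest closed contour of a binary component as a shapely polygon."""
    padded = np.pad(mask.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        return None
    contour = max(contours, key=len)
    # (row, col) -> (x, y) µm; subtract padding offset
    xy = np.column_stack([contour[:, 1] - 1, contour[:, 0] - 1]) * pixel_size
    if len(xy) < 4:
        return None
    poly = Polygon(xy)
    if not poly.is_valid:
        poly = poly.buffer(0)
        if poly.geom_type != "Polygon":
            poly = max(poly.geoms, key=lambda p: p.area)
    return poly


def segment_and_track(movie: DensityMovie, threshold: float,
                      min_area: float = 100.0,
                      gate_um: float = 20.0,
                      max_gap: int = 2) -> AggregateSet:
    """Segment supra-threshold components per frame and link them in time.

    Components are linked to the nearest active track centroid within
    ``gate_um``; unmatched components start new tracks; a track survives up
    to ``max_gap`` consecutive undetected frames (components near the
    threshold flicker) before being terminated.  ``partial_fov`` is set if
    any live frame's component touches the image border.
    """
    times = movie.times
    active: list[int] = []
    finished: list[int] = []
    next_id = 0
    per_track_data: dict[int, dict] = {}

    for fi, t in enumerate(times):
        comps = _frame_components(movie.frames[fi], threshold,
                                  movie.pixel_size, min_area)
        assigned = set()
        # link by maximal contour overlap first (aggregates are nearly
        # stationary at this cadence but their shapes fluctuate); fall back
        # to nearest centroid within the gate
        pairs = []
        for aid in active:
            rec = per_track_data[aid]
            last_c = rec["centroid"][-1]
            last_poly = rec["contours"][-1]
            for ci, c in enumerate(comps):
                ov = 0.0
                if last_poly is not None and c["polygon"] is not None:
                    try:
                        ov = last_poly.intersection(c["polygon"]).area
                    except Exception:
                        ov = 0.0
                d = np.hypot(*(c["centroid"] - last_c))
                if ov > 0:
                    pairs.append((-ov, aid, ci))
                elif d <= gate_um:
                    pairs.append((gate_um + d, aid, ci))
        pairs.sort(key=lambda p: p[0])
        matched_tracks = set()
        for score, aid, ci in pairs:
            if aid in matched_tracks or ci in assigned:
                continue
            matched_tracks.add(aid)
            assigned.add(ci)
            rec = per_track_data[aid]
            c = comps[ci]
            rec["t"].append(t)
            rec["centroid"].append(c["centroid"])
            rec["area"].append(c["area"])
            rec["contours"].append(c["polygon"])
            rec["partial"] = rec["partial"] or c["touches_border"]
            rec["misses"] = 0
        for ci, c in enumerate(comps):
            if ci in assigned:
                continue
            aid = next_id
            next_id += 1
            per_track_data[aid] = {
                "t": [t], "centroid": [c["centroid"]], "area": [c["area"]],
                "contours": [c["polygon"]],
                "partial": c["touches_border"],
                "misses": 0,
            }
            active.append(aid)
        survivors = []
        for aid in active:
            rec = per_track_data[aid]
            if aid not in matched_tracks and rec["t"][-1] != t:
                rec["misses"] += 1
                if rec["misses"] > max_gap:
                    finished.append(aid)
                    continue
            survivors.append(aid)
        active = survivors

    finished.extend(active)
    tracks = []
    for aid in sorted(finished):
        rec = per_track_data[aid]
        tracks.append(AggregateTrack(
            agg_id=aid,
            t=np.asarray(rec["t"], dtype=float),
            centroid=np.asarray(rec["centroid"], dtype=float),
            area=np.asarray(rec["area"], dtype=float),
            contours=rec["contours"],
            partial_fov=bool(rec["partial"]),
        ))
    _mark_merges(tracks)
    return AggregateSet(tracks)


def _mark_merges(tracks: list[AggregateTrack],
                 overlap_frac: float = 0.3) -> None:
    """A track whose final contour is covered by a surviving neighbor at the
    next frame ended by merging, not by dispersal."""
    for trk in tracks:
        poly = trk.contours[-1] if trk.contours else None
        if poly is None or poly.area <= 0:
            continue
        for other in tracks:
            if other.agg_id == trk.agg_id or other.t_last <= trk.t_last:
                continue
            later = np.flatnonzero(other.t > trk.t_last)
            if not len(later):
                continue
            i = int(later[0])
            opoly = other.contours[i]
            if opoly is None:
                continue
            try:
                ov = opoly.intersection(poly).area
            except Exception:
                continue
            if ov > overlap_frac * poly.area:
                trk.merged_into = other.agg_id
                break


# --------------------------------------------------------------------------
# classification
# --------------------------------------------------------------------------

def classify_motility(track: AggregateTrack, frame_interval: float,
                      speed_threshold: float = 3.0) -> bool:
    """Motile iff the median smoothed centroid speed exceeds 3 µm/min."""
    if len(track.t) < 2:
        return False
    c = track.centroid
    if len(c) >= 3:
        kernel = np.ones(3) / 3.0
        c = np.column_stack([
            np.convolve(c[:, 0], kernel, mode="valid"),
            np.convolve(c[:, 1], kernel, mode="valid"),
        ])
    if len(c) < 2:
        return False
    steps = np.hypot(np.diff(c[:, 0]), np.diff(c[:, 1]))
    speed = np.median(steps) / frame_interval
    return bool(speed > speed_threshold)


def filter_short_lived(track: AggregateTrack, movie_end: float,
                       min_lifetime: float = 120.0) -> bool:
    """Short-lived: stationary and gone in under 2 h, or dispersed while motile."""
    dispersed = track.t_last < movie_end
    if not dispersed:
        return False
    if track.motile:
        return True
    return (track.t_last - track.t_first) < min_lifetime


def label_fates(aggset: AggregateSet, movie_end: float,
                margin: float = 30.0) -> AggregateSet:
    """Unstable iff a track disperses at least ``margin`` min before movie
    end; tracks that ended by merging into a neighbor are labeled
    ``merged`` (their cells were not lost to the field)."""
    for trk in aggset:
        if trk.t_last > movie_end - margin:
            trk.fate = "stable"
        elif trk.merged_into is not None:
            trk.fate = "merged"
        else:
            trk.fate = "unstable"
    return aggset


def annotate_flags(aggset: AggregateSet, movie: DensityMovie) -> AggregateSet:
    """Populate motility / short-lived flags and fates in place."""
    movie_end = float(movie.times[-1])
    for trk in aggset:
        trk.motile = classify_motility(trk, movie.frame_interval)
    label_fates(aggset, movie_end)
    for trk in aggset:
        trk.short_lived = filter_short_lived(trk, movie_end)
    return aggset


# --------------------------------------------------------------------------
# coarsening start
# --------------------------------------------------------------------------

NO_COARSENING = float("nan")


def detect_coarsening_start(aggset: AggregateSet, times: np.ndarray,
                            smooth_window: float = 30.0,
                            recovery_frac: float = 0.95) -> float:
    """Start of the coarsening phase from the unstable-aggregate area curve.

    Candidates are stationary, long-lived, unstable tracks.  Their total area
    per frame is smoothed with a ``smooth_window``-minute running median
    (robust to single-frame segmentation noise); the
    coarsening start is the last time the smoothed curve lies within
    ``recovery_frac`` of its global maximum — the end of the plateau, after
    which the curve declines for good.  Returns NaN if no candidate exists or
    the curve never leaves the plateau band (no sustained decline observed).
    """
    times = np.asarray(times, dtype=float)
    cands = [a for a in aggset
             if a.fate == "unstable" and not a.motile and not a.short_lived]
    if not cands:
        return NO_COARSENING
    total = np.zeros_like(times)
    for trk in cands:
        idx = np.searchsorted(times, trk.t)
        idx = np.clip(idx, 0, len(times) - 1)
        for j, i in enumerate(idx):
            total[i] += trk.area[j]
    if len(times) > 1:
        dt = times[1] - times[0]
        w = 2 * max(1, int(round(smooth_window / (2 * dt)))) + 1
        if w > 1:
            total = ndimage.median_filter(total, size=w, mode="nearest")
    peak = total.max()
    if peak <= 0:
        return NO_COARSENING
    i_star = int(np.flatnonzero(total >= recovery_frac * peak)[-1])
    if i_star >= len(times) - 1:
        return NO_COARSENING     # still on the plateau at movie end
    return float(times[i_star])
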