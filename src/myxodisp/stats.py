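"""Reversal-bias and traffic-jam statistics, bootstrap CIs, stability model.

The central quantity is the *reversal bias*

    bias = (t_toward − t_away) / t_all,

the relative difference between the mean duration of persistent runs oriented
toward the nearest aggregate and those oriented away, normalized by the mean
duration of all persistent runs in the subset.  Positive values mean cells
drift toward aggregates.  Traffic-jam metrics compare speed, the probability
of stopping instead of reversing, and stop durations between cells inside and
outside aggregates.  Aggregate stability is modeled with a logistic fit of
fate (stable/unstable) against area at the start of the coarsening phase.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .runs import NON_PERSISTENT, PERSISTENT, RunDatabase


# --------------------------------------------------------------------------
# reversal bias
# --------------------------------------------------------------------------

def _toward_away(df: pd.DataFrame, restricted: bool = False):
    rel = df["rel_angle"].to_numpy(float)
    if restricted:
        toward = rel < np.pi / 4
        away = rel > 3 * np.pi / 4
    else:
        toward = rel < np.pi / 2
        away = rel > np.pi / 2
    return toward & np.isfinite(rel), away & np.isfinite(rel)


def reversal_bias(runs: pd.DataFrame, restricted: bool = False) -> float:
    """(mean duration | toward − mean duration | away) / mean of all runs.

    Operates on persistent runs only; t_all averages every persistent run in
    the subset (including near-perpendicular ones), one run = one sample.
    Returns NaN when either directional stratum is empty.
    """
    p = runs[runs["state"] == PERSISTENT]
    if len(p) == 0:
        return float("nan")
    toward, away = _toward_away(p, restricted)
    if toward.sum() == 0 or away.sum() == 0:
        return float("nan")
    dur = p["duration"].to_numpy(float)
    return float((dur[toward].mean() - dur[away].mean()) / dur.mean())


@dataclass
class BiasSeries:
    """Windowed reversal-bias estimates for one stratum."""

    window_centers: np.ndarray
    bias: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    n_toward: np.ndarray
    n_away: np.ndarray
    stratum: str = "all"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t_center": self.window_centers, "bias": self.bias,
            "ci_lo": self.ci_lo, "ci_hi": self.ci_hi,
            "n_toward": self.n_toward, "n_away": self.n_away,
            "stratum": self.stratum,
        })


def windowed_bias(run_db: RunDatabase, window: float = 60.0,
                  step: float = 15.0,
                  stratifier: Optional[Callable[[pd.DataFrame], dict]] = None,
                  restricted: bool = False, bootstrap_b: int = 200,
                  seed: int = 0) -> dict[str, BiasSeries]:
    """Reversal bias in a sliding time window, per stratum.

    ``stratifier`` maps the run table to ``{label: boolean mask}``; the
    default is a single "all" stratum.  Runs are assigned to windows by
    ``t_mid``.  Cell-level bootstrap CIs are attached per window.
    """
    df = run_db.df
    if stratifier is None:
        strata = {"all": np.ones(len(df), dtype=bool)}
    else:
        strata = stratifier(df)
    t0 = float(df["t_mid"].min())
    t1 = float(df["t_mid"].max())
    centers = np.arange(t0 + window / 2, t1 - window / 2 + 1e-9, step)
    if len(centers) == 0:
        centers = np.array([(t0 + t1) / 2])
    out = {}
    for label, mask in strata.items():
        bias = np.full(len(centers), np.nan)
        lo = np.full(len(centers), np.nan)
        hi = np.full(len(centers), np.nan)
        ntw = np.zeros(len(centers), dtype=int)
        naw = np.zeros(len(centers), dtype=int)
        for i, c in enumerate(centers):
            sel = (mask & (df["t_mid"] >= c - window / 2)
                   & (df["t_mid"] < c + window / 2))
            sub = df[sel]
            b = reversal_bias(sub, restricted)
            bias[i] = b
            p = sub[sub["state"] == PERSISTENT]
            tw, aw = _toward_away(p, restricted) if len(p) else (np.array([]), np.array([]))
            ntw[i] = int(tw.sum()) if len(p) else 0
            naw[i] = int(aw.sum()) if len(p) else 0
            if np.isfinite(b) and sub["cell_id"].nunique() >= 2:
                lo[i], hi[i] = bootstrap_ci(
                    lambda d: reversal_bias(d, restricted), sub,
                    b=bootstrap_b, seed=seed + i)
        out[label] = BiasSeries(centers, bias, lo, hi, ntw, naw, label)
    return out


def stratify_by_fate(df: pd.DataFrame) -> dict:
    return {
        "stable": (df["nearest_aggregate_fate"] == "stable").to_numpy(),
        "unstable": (df["nearest_aggregate_fate"] == "unstable").to_numpy(),
    }


def stratify_by_area_median(df: pd.DataFrame) -> dict:
    """Largest vs smallest 50% of aggregates by area (sentinel rows excluded)."""
    area = df["nearest_aggregate_area"].to_numpy(float)
    valid = area > 0
    med = np.median(area[valid]) if valid.any() else np.nan
    return {"small": valid & (area < med), "large": valid & (area >= med)}


def stratify_by_area_threshold(threshold: float):
    def f(df: pd.DataFrame) -> dict:
        area = df["nearest_aggregate_area"].to_numpy(float)
        valid = area > 0
        return {"below": valid & (area < threshold),
                "above": valid & (area >= threshold)}
    return f


# --------------------------------------------------------------------------
# traffic jam
# --------------------------------------------------------------------------

@dataclass
class JamMetrics:
    speed_inside: float = float("nan")
    speed_outside: float = float("nan")
    p_stop_inside: float = float("nan")
    p_stop_outside: float = float("nan")
    stop_duration_inside: float = float("nan")
    stop_duration_outside: float = float("nan")
    exit_rate_inside: float = float("nan")
    exit_rate_outside: float = float("nan")
    ci: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "speed_inside", "speed_outside", "p_stop_inside",
            "p_stop_outside", "stop_duration_inside", "stop_duration_outside",
            "exit_rate_inside", "exit_rate_outside")}
        d["ci"] = self.ci
        return d


def _p_stop(df: pd.DataFrame) -> float:
    p = df[(df["state"] == PERSISTENT)
           & df["end_event"].isin(["state_change", "reversal"])]
    if len(p) == 0:
        return float("nan")
    return float((p["end_event"] == "state_change").mean())


def jam_metrics(run_db: RunDatabase | pd.DataFrame, bootstrap_b: int = 500,
                seed: int = 0) -> JamMetrics:
    """Inside/outside aggregate comparison of speed, stopping, stop duration.

    Inside means signed boundary distance < 0.  ``p_stop`` is the fraction of
    persistent runs ending in a state change rather than a reversal; the exit
    rate is the reciprocal mean non-persistent duration.  Cluster-bootstrap
    CIs (by cell) are attached under ``.ci``.
    """
    df = run_db.df if isinstance(run_db, RunDatabase) else run_db
    m = JamMetrics()
    rng_i = 0
    for side, mask in (("inside", df["boundary_distance"] < 0),
                       ("outside", df["boundary_distance"] >= 0)):
        sub = df[mask]
        pers = sub[sub["state"] == PERSISTENT]
        nonp = sub[sub["state"] == NON_PERSISTENT]
        if len(pers):
            setattr(m, f"speed_{side}", float(pers["mean_speed"].mean()))
            setattr(m, f"p_stop_{side}", _p_stop(sub))
            if pers["cell_id"].nunique() >= 2:
                m.ci[f"speed_{side}"] = bootstrap_ci(
                    lambda d: d[d["state"] == PERSISTENT]["mean_speed"].mean()
                    if (d["state"] == PERSISTENT).any() else np.nan,
                    sub, b=bootstrap_b, seed=seed + rng_i)
                m.ci[f"p_stop_{side}"] = bootstrap_ci(
                    _p_stop, sub, b=bootstrap_b, seed=seed + rng_i + 1)
        if len(nonp):
            md = float(nonp["duration"].mean())
            setattr(m, f"stop_duration_{side}", md)
            setattr(m, f"exit_rate_{side}", 1.0 / md if md > 0 else np.nan)
            if nonp["cell_id"].nunique() >= 2:
                m.ci[f"stop_duration_{side}"] = bootstrap_ci(
                    lambda d: d[d["state"] == NON_PERSISTENT]["duration"].mean()
                    if (d["state"] == NON_PERSISTENT).any() else np.nan,
                    sub, b=bootstrap_b, seed=seed + rng_i + 2)
        rng_i += 3
    return m


# --------------------------------------------------------------------------
# bootstrap
# --------------------------------------------------------------------------

def bootstrap_ci(statistic: Callable[[pd.DataFrame], float],
                 runs: pd.DataFrame, b: int = 1000, level: float = 0.95,
                 seed: int = 0) -> tuple[float, float]:
    """Percentile cluster-bootstrap CI, resampling whole cells.

    Runs within a cell are autocorrelated, so resampling keeps all runs of
    each sampled cell together.  Deterministic given ``seed``.
    """
    cells = runs["cell_id"].unique()
    if len(cells) < 2:
        raise ValueError("cluster bootstrap needs at least 2 cells")
    rng = np.random.default_rng(seed)
    groups = {c: g for c, g in runs.groupby("cell_id")}
    vals = np.empty(b)
    for i in range(b):
        chosen = rng.choice(cells, size=len(cells), replace=True)
        sample = pd.concat([groups[c] for c in chosen], ignore_index=True)
        vals[i] = statistic(sample)
    vals = vals[np.isfinite(vals)]
    if len(vals) == 0:
        return float("nan"), float("nan")
    alpha = (1 - level) / 2
    lo, hi = np.quantile(vals, [alpha, 1 - alpha])
    if hi - lo <= 0:
        warnings.warn("degenerate bootstrap distribution; zero-width interval")
    return float(lo), float(hi)


# --------------------------------------------------------------------------
# logistic stability model
# --------------------------------------------------------------------------

@dataclass
class LogisticFit:
    beta0: float
    beta1: float            # per µm²
    threshold_area: float   # µm², P(stable) = 0.5
    n_stable: int
    n_unstable: int
    separated: bool = False

    def predict(self, area) -> np.ndarray:
        z = self.beta0 + self.beta1 * np.asarray(area, dtype=float)
        return 1.0 / (1.0 + np.exp(-z))


def logistic_fate_vs_area(areas, stable, max_iter: int = 200,
                          ridge: float = 1e-8, tol: float = 1e-10) -> LogisticFit:
    """Fit P(stable) = logistic(β0 + β1·area) by IRLS with a tiny ridge.

    Complete separation is detected (every unstable aggregate smaller than
    every stable one); the fit is still returned, its threshold set to the
    midpoint of the separating gap and ``separated`` flagged.
    """
    areas = np.asarray(areas, dtype=float)
    y = np.asarray(stable, dtype=float)
    n_stable = int(y.sum())
    n_unstable = int(len(y) - n_stable)
    if n_stable == 0 or n_unstable == 0:
        raise ValueError("logistic fit needs both stable and unstable inputs")

    # standardize for numerical stability; map coefficients back after
    mu, sd = areas.mean(), areas.std()
    sd = sd if sd > 0 else 1.0
    xs = (areas - mu) / sd
    X = np.column_stack([np.ones_like(xs), xs])
    beta = np.zeros(2)
    for _ in range(max_iter):
        z = X @ beta
        p = 1.0 / (1.0 + np.exp(-np.clip(z, -35, 35)))
        w = np.maximum(p * (1 - p), 1e-12)
        H = X.T @ (X * w[:, None]) + ridge * np.eye(2)
        g = X.T @ (y - p) - ridge * beta
        step = np.linalg.solve(H, g)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break

    b1 = beta[1] / sd
    b0 = beta[0] - beta[1] * mu / sd
    separated = (areas[y == 0].max() < areas[y == 1].min()
                 or areas[y == 1].max() < areas[y == 0].min())
    if separated:
        gap = sorted([areas[y == 0].max(), areas[y == 1].min(),
                      areas[y == 1].max(), areas[y == 0].min()])
        threshold = 0.5 * (gap[1] + gap[2])
    else:
        threshold = -b0 / b1 if b1 != 0 else float("nan")
    return LogisticFit(float(b0), float(b1), float(threshold),
                       n_stable, n_unstable, separated)


def logistic_from_tracks(aggset, t_coarsen: float) -> LogisticFit:
    """Stability model from aggregate tracks alive at the coarsening start."""
    areas, stable = [], []
    for trk in aggset:
        if (trk.t_first <= t_coarsen <= trk.t_last and not trk.short_lived
                and trk.fate in ("stable", "unstable")):
            areas.append(trk.area_at(t_coarsen))
            stable.append(1 if trk.fate == "stable" else 0)
    return logistic_fate_vs_area(np.asarray(areas), np.asarray(stable))
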