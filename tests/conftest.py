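import numpy as np
import pandas as pd
import pytest

from myxodisp import presets, synthkit
from myxodisp.runs import annotate_runs, extract_runs


def straight_track(n=60, speed=3.0, dt=1.0, theta=0.0, start=(50.0, 50.0)):
    t = np.arange(n) * dt
    x = start[0] + speed * t * np.cos(theta)
    y = start[1] + speed * t * np.sin(theta)
    return pd.DataFrame({"cell_id": 0, "t_min": t, "x_um": x, "y_um": y})


@pytest.fixture(scope="session")
def bias_pipeline_db():
    """Full extraction pipeline on the area-flip trajectory world (shared
    across tests because generation + extraction is the expensive step)."""
    cfg = presets.bias_recovery_world(seed=7)
    tracks = synthkit.gen_trajectories(cfg)
    runs_df = extract_runs(tracks.table)
    aggset = synthkit.ground_truth_aggregates(cfg)
    db = annotate_runs(runs_df, None, aggset, tracks.table,
                       fov_size=cfg.fov_size)
    return cfg, tracks, db


@pytest.fixture(scope="session")
def jam_pipeline_db():
    cfg = presets.jam_world(seed=7)
    tracks = synthkit.gen_trajectories(cfg)
    runs_df = extract_runs(tracks.table)
    aggset = synthkit.ground_truth_aggregates(cfg)
    db = annotate_runs(runs_df, None, aggset, tracks.table,
                       fov_size=cfg.fov_size)
    return cfg, tracks, db
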