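"""Coarse-graining: state labels, reversals, run segmentation, cues."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Point

from myxodisp.aggregates import AggregateSet, AggregateTrack
from myxodisp.runs import (NON_PERSISTENT, PERSISTENT, RunParams,
                           annotate_runs, classify_states,
                           classify_states_arrays, detect_reversals,
                           extract_runs, local_alignment, nematic_mean,
                           segment_runs)
from myxodisp.synthkit import (AggregateSpec, SyntheticWorldConfig,
                               gen_trajectories)
from tests.conftest import straight_track


def disk_aggregate(center=(200.0, 200.0), radius=50.0, t_max=600.0):
    times = np.arange(0.0, t_max + 1, 15.0)
    return AggregateSet([AggregateTrack(
        agg_id=0, t=times,
        centroid=np.tile(center, (len(times), 1)),
        area=np.full(len(times), np.pi * radius ** 2),
        contours=[Point(center).buffer(radius, quad_segs=64)] * len(times),
        fate="stable")])


class TestStateClassification:
    def test_straight_motion_all_persistent(self):
        traj = straight_track(speed=3.0)
        states = classify_states(traj)[0]
        assert states.all()

    def test_stationary_jitter_all_non_persistent(self):
        rng = np.random.default_rng(0)
        n = 60
        traj = pd.DataFrame({
            "cell_id": 0, "t_min": np.arange(n, dtype=float),
            "x_um": 50 + rng.normal(0, 0.05, n),
            "y_um": 50 + rng.normal(0, 0.05, n)})
        assert not classify_states(traj)[0].any()

    def test_alternating_motion_and_stop_boundaries(self):
        """30-min runs alternating with 30-min stops: ≥95% frame accuracy
        and boundaries within ±2 frames, across seeded tracks."""
        rng = np.random.default_rng(1)
        params = RunParams()
        accs = []
        for rep in range(30):
            segs = []
            pos = np.array([100.0, 100.0])
            theta = rng.uniform(0, 2 * np.pi)
            truth = []
            xs = []
            for block in range(4):
                moving = block % 2 == 0
                for k in range(30):
                    xs.append(pos + rng.normal(0, 0.05, 2))
                    truth.append(moving)
                    if moving:
                        pos = pos + 2.5 * np.array([np.cos(theta),
                                                    np.sin(theta)])
                theta += np.pi / 2
            xy = np.asarray(xs)
            t = np.arange(len(xy), dtype=float)
            labels = classify_states_arrays(t, xy, params)
            accs.append((labels == np.asarray(truth)).mean())
        assert np.mean(accs) >= 0.95

    def test_short_track_warns_non_persistent(self):
        traj = straight_track(n=3)
        with pytest.warns(UserWarning):
            states = classify_states(traj)
        assert not states[0].any()


class TestReversals:
    def test_monotone_track_no_reversals(self):
        traj = straight_track()
        states = classify_states(traj)
        assert len(detect_reversals(traj, states)[0]) == 0

    def test_single_reversal_located(self):
        n = 121
        t = np.arange(n, dtype=float)
        x = np.where(t <= 60, 2.5 * t, 2.5 * 60 - 2.5 * (t - 60))
        traj = pd.DataFrame({"cell_id": 0, "t_min": t, "x_um": x,
                             "y_um": np.full(n, 50.0)})
        states = classify_states(traj)
        rev = detect_reversals(traj, states)[0]
        assert len(rev) == 1
        assert abs(rev[0] - 60) <= 1

    def test_generator_reversals_recovered(self):
        """≥90% of resolvable reversal events (flanking runs ≥ 3 min) are
        matched within ±2 frames; false positives below 5%."""
        cfg = SyntheticWorldConfig(
            aggregates=[AggregateSpec((250, 200), 40.0)],
            n_cells=60, duration=400.0, tau_toward=9.0, tau_away=6.0,
            p_stop=0.0, seed=5)
        tracks = gen_trajectories(cfg)
        states = classify_states(tracks.table)
        revs = detect_reversals(tracks.table, states)
        tr = tracks.true_runs
        matched = total = fp = n_det = 0
        for cid, tv in tracks.reversal_times.items():
            dv = np.sort(revs.get(cid, np.array([])))
            n_det += len(dv)
            tc = tr[tr.cell_id == cid]
            for t_ev in tv:
                before = tc[np.isclose(tc.t_end, t_ev)]
                after = tc[np.isclose(tc.t_start, t_ev)]
                if len(before) == 0 or len(after) == 0:
                    continue
                if min(before.duration.iloc[0], after.duration.iloc[0]) < 3:
                    continue
                total += 1
                if len(dv) and np.abs(dv - t_ev).min() <= 2.0:
                    matched += 1
            for td in dv:
                if len(tv) == 0 or np.abs(tv - td).min() > 2.0:
                    fp += 1
        assert matched / total >= 0.90
        assert fp / n_det < 0.05


class TestSegmentation:
    def test_one_reversal_two_runs(self):
        n = 101
        t = np.arange(n, dtype=float)
        x = np.where(t <= 50, 2.5 * t, 2.5 * 50 - 2.5 * (t - 50))
        traj = pd.DataFrame({"cell_id": 0, "t_min": t, "x_um": x,
                             "y_um": np.full(n, 50.0)})
        runs = extract_runs(traj)
        assert len(runs) == 2
        assert (runs.state == PERSISTENT).all()
        assert runs.t_start.iloc[0] == 0 and runs.t_end.iloc[-1] == 100
        assert runs.duration.sum() == pytest.approx(100.0)

    def test_runs_tile_each_track(self, bias_pipeline_db):
        _, tracks, db = bias_pipeline_db
        runs = extract_runs(tracks.table[tracks.table.cell_id < 20])
        for cid, g in runs.groupby("cell_id"):
            g = g.sort_values("t_start")
            span = (tracks.table[tracks.table.cell_id == cid].t_min.max()
                    - tracks.table[tracks.table.cell_id == cid].t_min.min())
            assert g.duration.sum() == pytest.approx(span)
            assert np.allclose(g.t_end.values[:-1], g.t_start.values[1:])


class TestAlignment:
    @pytest.mark.parametrize("angles,expect", [
        ([0.7, 0.7, 0.7], 0.7),
        ([0.0, np.pi], 0.0),
    ])
    def test_nematic_mean_values(self, angles, expect):
        got = nematic_mean(angles)
        assert np.isclose(np.sin(2 * got), np.sin(2 * expect), atol=1e-9)
        assert np.isclose(np.cos(2 * got), np.cos(2 * expect), atol=1e-9)

    def test_degenerate_pair_is_nan(self):
        assert np.isnan(nematic_mean([0.0, np.pi / 2]))

    def test_empty_is_nan(self):
        assert np.isnan(nematic_mean([]))

    def test_nematic_mean_matches_doubled_vector_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            angles = rng.uniform(-np.pi, np.pi, rng.integers(1, 12))
            v = np.array([np.cos(2 * angles).sum(), np.sin(2 * angles).sum()])
            if np.hypot(*v) < 1e-6:
                continue
            expect = 0.5 * np.arctan2(v[1], v[0])
            assert nematic_mean(angles) == pytest.approx(expect)

    @pytest.mark.parametrize("delta,gamma", [
        (0.0, 1.0), (np.pi / 2, -1.0), (np.pi / 4, 0.0),
    ])
    def test_local_alignment_values(self, delta, gamma):
        theta_bar = 0.3
        assert local_alignment(theta_bar + delta, [theta_bar]) == pytest.approx(
            gamma, abs=1e-9)

    def test_gamma_matches_brute_force_scan(self):
        """The KD-tree neighbor lookup reproduces a brute-force O(n²) scan
        exactly on random fixtures."""
        from myxodisp.runs import _AlignmentLookup, frame_orientations

        rng = np.random.default_rng(3)
        params = RunParams()
        for _ in range(100):
            n_cells, n_frames = 8, 10
            rows = []
            for cid in range(n_cells):
                x, y = rng.uniform(0, 60, 2)
                th = rng.uniform(0, 2 * np.pi)
                for k in range(n_frames):
                    rows.append((cid, float(k), x + 2 * k * np.cos(th),
                                 y + 2 * k * np.sin(th)))
            traj = pd.DataFrame(rows, columns=["cell_id", "t_min",
                                               "x_um", "y_um"])
            traj_o = frame_orientations(traj, params)
            lookup = _AlignmentLookup(traj_o, params)
            t_q = 8.0
            focal = traj_o[(traj_o.cell_id == 0) & (traj_o.t_min == t_q)].iloc[0]
            got = lookup.gamma(0, t_q, focal.x_um, focal.y_um,
                               focal.orientation)
            # brute force
            win = traj_o[(traj_o.t_min > t_q - params.alignment_window)
                         & (traj_o.t_min <= t_q) & (traj_o.cell_id != 0)]
            d = np.hypot(win.x_um - focal.x_um, win.y_um - focal.y_um)
            thetas = win.orientation[d <= params.alignment_radius]
            expect = (local_alignment(focal.orientation, list(thetas))
                      if len(thetas) else float("nan"))
            if np.isnan(expect):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expect)


class TestAnnotation:
    def test_disk_geometry_rel_angle_and_distance(self):
        """Run starting at (300,200) pointing in −x toward a 50-µm disk at
        (200,200): rel_angle 0, boundary distance 50 µm."""
        traj = straight_track(n=40, speed=2.5, theta=np.pi,
                              start=(300.0, 200.0))
        runs = extract_runs(traj)
        db = annotate_runs(runs, None, disk_aggregate(), traj)
        r0 = db.df.iloc[0]
        assert r0.rel_angle == pytest.approx(0.0, abs=0.05)
        assert r0.boundary_distance == pytest.approx(50.0, abs=1.0)
        assert r0.nearest_aggregate_id == 0

    def test_inside_start_negative_distance(self):
        traj = straight_track(n=40, speed=2.5, theta=0.0,
                              start=(200.0, 200.0))
        runs = extract_runs(traj)
        db = annotate_runs(runs, None, disk_aggregate(), traj)
        assert db.df.iloc[0].boundary_distance == pytest.approx(-50.0, abs=1.0)

    def test_pointing_away_rel_angle_pi(self):
        traj = straight_track(n=40, speed=2.5, theta=0.0,
                              start=(300.0, 200.0))
        runs = extract_runs(traj)
        db = annotate_runs(runs, None, disk_aggregate(), traj)
        assert db.df.iloc[0].rel_angle == pytest.approx(np.pi, abs=0.05)

    def test_rel_angle_uniform_for_unbiased_world(self):
        """With equal toward/away means, run orientations are isotropic and
        the angle to the nearest aggregate is uniform on [0, π]."""
        from scipy.stats import kstest

        cfg = SyntheticWorldConfig(
            fov_size=(600, 500),
            aggregates=[AggregateSpec((300, 250), 10.0)],
            n_cells=160, duration=400.0, tau_toward=7.0, tau_away=7.0,
            p_stop=0.0, seed=17)
        tracks = gen_trajectories(cfg)
        runs = extract_runs(tracks.table)
        from myxodisp.synthkit import ground_truth_aggregates
        db = annotate_runs(runs, None, ground_truth_aggregates(cfg),
                           tracks.table, fov_size=cfg.fov_size)
        rel = db.df.rel_angle.dropna()
        assert len(rel) >= 5000
        assert kstest(rel / np.pi, "uniform").pvalue > 0.01

    def test_partial_fov_aggregate_rows_dropped(self):
        aggset = disk_aggregate()
        aggset.tracks[0].partial_fov = True
        traj = straight_track(n=40, start=(300.0, 200.0))
        runs = extract_runs(traj)
        db = annotate_runs(runs, None, aggset, traj)
        assert len(db.df) == 0
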