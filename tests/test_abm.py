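"""Agent model: search index, behavior sampling, world stepping, closure."""

import numpy as np
import pandas as pd
import pytest

from myxodisp.abm import (DURATION_SEARCH, ORIENT_SEARCH, STATE_SEARCH,
                          CueFlags, SearchIndex, SimulationConfig, WorldState,
                          build_search_index, init_world, run_simulation,
                          sample_next_behavior, step, variant_flags)
from myxodisp.presets import abm_sim_config, abm_world, run_set_world
from myxodisp.runs import NON_PERSISTENT, PERSISTENT, RunDatabase, TimeBin
from myxodisp.synthkit import (AggregateSpec, SyntheticWorldConfig,
                               gen_run_database)


def small_db(n=2000, seed=0, **kw):
    cfg = SyntheticWorldConfig(
        aggregates=[AggregateSpec((250, 200), 40.0)],
        tau_toward=6.0, tau_away=4.0, p_stop=0.1, n_runs=n, seed=seed, **kw)
    return gen_run_database(cfg)


def single_row_db():
    row = {
        "cell_id": 0, "state": PERSISTENT, "t_start": 0.0, "t_end": 5.0,
        "t_mid": 2.5, "duration": 5.0, "mean_speed": 2.0, "distance": 10.0,
        "orientation": 0.3, "end_event": "reversal",
        "local_density": 0.1, "alignment_gamma": 0.5,
        "delta_orientation": 0.2, "boundary_distance": 30.0,
        "rel_angle": 0.7, "nearest_aggregate_id": 0,
        "nearest_aggregate_area": 5000.0, "nearest_aggregate_fate": "stable",
    }
    df = pd.DataFrame([row] * 3)
    return RunDatabase(df, [TimeBin(0.0, 1e9, "aggregation")])


class TestSearchIndex:
    def test_identity_query_is_own_nearest_neighbor(self):
        db = small_db()
        idx = build_search_index(db, CueFlags(), knn_k=1)
        st = idx.stratum(0, PERSISTENT, DURATION_SEARCH)
        row = st["rows"].iloc[10]
        cues = {c: np.array([row[c]]) for c in st["cues"]}
        got = idx.query(0, PERSISTENT, DURATION_SEARCH, cues,
                        np.random.default_rng(0))
        assert got.iloc[0].duration == row.duration

    def test_matches_brute_force_scan(self):
        """KD-tree neighbor sets equal a brute-force standardized Euclidean
        scan on 500 random queries."""
        db = small_db(n=1500)
        idx = build_search_index(db, CueFlags(), knn_k=1)
        st = idx.stratum(0, PERSISTENT, DURATION_SEARCH)
        X = np.column_stack([
            (np.where(np.isfinite(st["rows"][c].to_numpy(float)),
                      st["rows"][c].to_numpy(float), st["mean"][j])
             - st["mean"][j]) / st["sd"][j]
            for j, c in enumerate(st["cues"])])
        rng = np.random.default_rng(1)
        q_std = rng.normal(0, 1, (500, X.shape[1]))
        cues = {c: q_std[:, j] * st["sd"][j] + st["mean"][j]
                for j, c in enumerate(st["cues"])}
        got = idx.query(0, PERSISTENT, DURATION_SEARCH, cues,
                        np.random.default_rng(0))
        expect_idx = np.argmin(
            ((X[None, :, :] - q_std[:, None, :]) ** 2).sum(axis=2), axis=1)
        assert np.allclose(got.duration.to_numpy(),
                           st["rows"].duration.to_numpy()[expect_idx])

    def test_zero_variance_cue_dropped(self):
        db = small_db(n=500)
        db.df["alignment_gamma"] = 0.7
        with pytest.warns(UserWarning, match="zero variance"):
            idx = build_search_index(db, CueFlags(), knn_k=5)
        st = idx.stratum(0, PERSISTENT, DURATION_SEARCH)
        assert "alignment_gamma" not in st["cues"]

    def test_empty_persistent_stratum_raises(self):
        db = small_db(n=300)
        db.df = db.df[db.df.state != PERSISTENT]
        with pytest.raises(ValueError, match="empty stratum"):
            build_search_index(db, CueFlags())


class TestSampling:
    def _world(self, cfg=None, seed=0):
        cfg = cfg or SimulationConfig(fov=(500, 400), n_agents=50, seed=seed)
        return cfg, WorldState(cfg, np.random.default_rng(seed))

    def test_all_reversal_db_keeps_agents_persistent(self):
        db = small_db(n=2000)
        db.df.loc[db.df.state == PERSISTENT, "end_event"] = "reversal"
        idx = build_search_index(db, CueFlags(), knn_k=10)
        cfg, world = self._world()
        world.persistent[:] = True
        rng = np.random.default_rng(0)
        sample_next_behavior(idx, world, np.arange(50), 0, rng)
        assert world.persistent.all()

    def test_single_row_db_reproduces_row(self):
        db = single_row_db()
        idx = build_search_index(db, CueFlags(), knn_k=5)
        cfg, world = self._world()
        rng = np.random.default_rng(0)
        sample_next_behavior(idx, world, np.arange(50), 0, rng)
        assert np.allclose(world.speed[world.persistent], 2.0)
        assert np.allclose(world.time_remaining, 5.0)

    def test_toward_away_duration_means(self):
        """Queries pointing at (rel_angle 0) vs away from (π) the aggregate
        draw durations with means near the generator's 6 and 4 min."""
        db = small_db(n=20000, seed=3)
        idx = build_search_index(db, CueFlags(), knn_k=20)
        st = idx.stratum(0, PERSISTENT, DURATION_SEARCH)
        rng = np.random.default_rng(0)
        n_q = 5000
        base = {
            "local_density": np.zeros(n_q),
            "alignment_gamma": np.full(n_q, 0.5),
            "boundary_distance": np.full(n_q, 40.0),
        }
        for rel, expect in ((0.25, 6.0), (2.9, 4.0)):
            cues = dict(base, rel_angle=np.full(n_q, rel))
            got = idx.query(0, PERSISTENT, DURATION_SEARCH, cues, rng)
            d = got.duration.to_numpy()
            assert d.mean() == pytest.approx(
                expect, abs=3 * d.std() / np.sqrt(n_q) + 0.3)

    def test_sampled_marginal_matches_stratum(self):
        """Sampling with queries drawn from the database's own cue
        distribution preserves the stratum's duration marginal."""
        from scipy.stats import ks_2samp

        db = small_db(n=8000, seed=5)
        idx = build_search_index(db, CueFlags(), knn_k=20)
        st = idx.stratum(0, PERSISTENT, DURATION_SEARCH)
        rows = st["rows"]
        rng = np.random.default_rng(2)
        pick = rng.integers(len(rows), size=5000)
        cues = {c: rows[c].to_numpy(float)[pick] for c in st["cues"]}
        got = idx.query(0, PERSISTENT, DURATION_SEARCH, cues, rng)
        assert ks_2samp(got.duration, rows.duration).pvalue > 0.01


class TestWorld:
    def test_persistent_step_displacement(self):
        cfg = SimulationConfig(fov=(500, 400), n_agents=1, dt=1.0, seed=0)
        world = WorldState(cfg, np.random.default_rng(0))
        world.x[0], world.y[0] = 250.0, 200.0
        world.theta[0] = 0.0
        world.speed[0] = 2.0
        world.persistent[0] = True
        world.time_remaining[0] = 10.0
        db = single_row_db()
        idx = build_search_index(db, CueFlags(), knn_k=1)
        step(world, cfg, idx, 0, np.random.default_rng(0))
        assert world.x[0] == pytest.approx(252.0)
        assert world.y[0] == pytest.approx(200.0)

    def test_non_persistent_agent_does_not_move(self):
        cfg = SimulationConfig(fov=(500, 400), n_agents=1, dt=1.0, seed=0)
        world = WorldState(cfg, np.random.default_rng(0))
        world.persistent[0] = False
        world.speed[0] = 0.0
        world.time_remaining[0] = 10.0
        x0, y0 = world.x[0], world.y[0]
        db = single_row_db()
        idx = build_search_index(db, CueFlags(), knn_k=1)
        step(world, cfg, idx, 0, np.random.default_rng(0))
        assert world.x[0] == x0 and world.y[0] == y0

    def test_density_field_normalized_and_count_conserved(self):
        cfg = SimulationConfig(fov=(300, 300), n_agents=200, seed=1)
        world = WorldState(cfg, np.random.default_rng(1))
        db = small_db(n=2000)
        idx = build_search_index(db, CueFlags(), knn_k=10)
        rng = np.random.default_rng(1)
        for k in range(60):
            step(world, cfg, idx, 0, rng)
            if k % 15 == 0:
                world.refresh()
                assert world.field.sum() == pytest.approx(1.0, abs=1e-9)
        assert len(world.x) == 200
        assert np.isfinite(world.x).all()

    def test_pinpoint_components_excluded_from_cues(self):
        cfg = SimulationConfig(fov=(200, 200), n_agents=10, pixel_size=2.0,
                               pinpoint_min_area=300.0, seed=0)
        world = WorldState(cfg, np.random.default_rng(0))
        ny, nx = cfg.grid_shape
        field = np.full((ny, nx), 1e-9)
        thr = cfg.threshold()
        # one 5x5-px (100 µm²) and one 12x12-px (576 µm²) component
        field[10:15, 10:15] = thr * 10
        field[60:72, 60:72] = thr * 10
        world.field = field / field.sum()
        world._detect_aggregates()
        assert len(world.label_area) == 1
        assert list(world.label_area.values())[0] == pytest.approx(576.0)
        bd, rel, area = world.aggregate_cues(
            np.array([24.0]), np.array([24.0]), np.array([0.0]))
        assert area[0] == pytest.approx(576.0)

    def test_no_aggregates_sentinel_cues(self):
        cfg = SimulationConfig(fov=(200, 200), n_agents=5, seed=0)
        world = WorldState(cfg, np.random.default_rng(0))
        world.field = np.full(cfg.grid_shape, 1.0)
        world.field /= world.field.sum()
        world._detect_aggregates()
        bd, rel, area = world.aggregate_cues(
            np.array([50.0]), np.array([50.0]), np.array([0.0]))
        assert bd[0] == cfg.no_aggregate_distance
        assert np.isnan(rel[0])
        assert area[0] == 0.0


class TestInitAndSimulation:
    def test_init_conserves_agents_and_is_deterministic(self):
        db = small_db(n=3000, seed=2)
        cfg = SimulationConfig(fov=(300, 250), n_agents=300,
                               init_duration=30.0, seed=5)
        w1 = init_world(cfg, db, np.random.default_rng(5))
        w2 = init_world(cfg, db, np.random.default_rng(5))
        assert len(w1.x) == 300
        assert np.array_equal(w1.x, w2.x) and np.array_equal(w1.theta, w2.theta)

    def test_init_stays_uniform_without_jam_or_bias(self):
        from scipy.stats import chi2_contingency

        cfg_world = SyntheticWorldConfig(aggregates=[], tau_toward=5.0,
                                         tau_away=5.0, p_stop=0.0,
                                         n_runs=4000, seed=3)
        db = gen_run_database(cfg_world)
        cfg = SimulationConfig(fov=(400, 400), n_agents=1200,
                               init_duration=60.0, seed=6)
        world = init_world(cfg, db, np.random.default_rng(6))
        hx = np.histogram2d(world.x, world.y,
                            bins=[4, 4], range=[[0, 400], [0, 400]])[0]
        expected = np.full((4, 4), 1200 / 16)
        chi2 = ((hx - expected) ** 2 / expected).sum()
        from scipy.stats import chi2 as chi2_dist
        assert chi2_dist.sf(chi2, 15) > 0.01

    def test_simulation_seed_determinism(self):
        db = small_db(n=3000, seed=2)
        cfg = SimulationConfig(fov=(300, 250), n_agents=200, t_end=120.0,
                               init_duration=30.0, seed=9)
        r1 = run_simulation(cfg, db)
        r2 = run_simulation(cfg, db)
        assert np.array_equal(r1.final_positions, r2.final_positions)
        assert np.array_equal(r1.aggregate_count, r2.aggregate_count)
        assert np.array_equal(r1.field_movie.frames, r2.field_movie.frames)

    def test_behavior_closure_bias_sign(self):
        """Extracting runs from simulated agent tracks recovers the
        database's positive reversal bias."""
        from myxodisp.runs import annotate_runs, extract_runs
        from myxodisp.stats import reversal_bias
        from myxodisp.aggregates import (annotate_flags, segment_and_track)

        db_world = abm_world(seed=21, n_runs=15000)
        db = gen_run_database(db_world)
        cfg = abm_sim_config("no-area", seed=3, n_agents=1200, t_end=420.0,
                             record_tracks=True)
        res = run_simulation(cfg, db)
        tracks = res.tracks[res.tracks.cell_id < 250].copy()
        runs = extract_runs(tracks)
        aggset = res.aggset
        run_db = annotate_runs(runs, None, aggset, tracks,
                               fov_size=cfg.fov)
        sub = run_db.df[(run_db.df.t_mid > 150)
                        & run_db.df.rel_angle.notna()]
        assert reversal_bias(sub) > 0
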