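"""Neighbor counting, conditional velocity, turn events and lead-lag."""

import numpy as np
import pandas as pd
import pytest

import chemorelay as cr
from chemorelay.neighborhood import UndefinedLeadLagError

from conftest import make_table, straight_track

NCFG = cr.NeighborhoodConfig()


def motile_gate_rows(table, window=1000):
    """Gated metrics marking every leader tracklet as directional (motile)."""
    rows = []
    for cid in table.cells:
        n = len(table.positions(cid))
        rows.append({"cell_id": cid, "group": table.group_of(cid),
                     "start": 0, "end": min(window, n),
                     "arrest": 0.0, "directionality": 1.0, "gate": "directional"})
    return pd.DataFrame(rows)


class TestMotileNeighborCount:
    def test_inclusive_radius_boundary(self):
        for d, expected in [(49.9, 1), (50.0, 1), (50.1, 0)]:
            t = make_table({
                "f": ("ko", np.zeros((3, 3))),
                "l": ("wt", straight_track(3, 0.0, origin=(d, 0, 0))),
            })
            gates = motile_gate_rows(t)
            assert cr.motile_neighbor_count(t, gates, "f", 0.0, NCFG) == expected

    def test_isolated_cell(self):
        t = make_table({"f": ("ko", np.zeros((3, 3)))})
        assert cr.motile_neighbor_count(t, motile_gate_rows(t), "f", 60.0, NCFG) == 0

    def test_time_outside_range_errors(self):
        t = make_table({"f": ("ko", np.zeros((3, 3)))})
        with pytest.raises(ValueError):
            cr.motile_neighbor_count(t, motile_gate_rows(t), "f", 1e6, NCFG)

    def test_brute_force_oracle_200_cells(self, rng):
        """KD-tree counts equal an all-pairs distance scan, exactly."""
        n_cells, n_frames = 200, 50
        tracks = {}
        for i in range(n_cells):
            group = "wt" if i < 100 else "ko"
            start = rng.uniform(0, 300, size=3)
            walk = start + rng.normal(scale=2.0, size=(n_frames, 3)).cumsum(axis=0)
            tracks[f"c{i:03d}"] = (group, walk)
        t = make_table(tracks, dt=20.0)
        tcfg = cr.TrackletConfig(window=10)
        gated = cr.classify_table(
            cr.metrics_table(cr.decompose(t, tcfg), tcfg), cr.GateConfig())

        # independent brute force: covering-gate lookup + all-pairs distances
        gate_by_cell_frame = {}
        for _, row in gated.iterrows():
            for fr in range(int(row["start"]), int(row["end"])):
                gate_by_cell_frame[(row["cell_id"], fr)] = row["gate"]
        pos = {cid: t.positions(cid) for cid in t.cells}
        checks = 0
        for _ in range(50):
            focal = f"c{rng.integers(n_cells):03d}"
            fr = int(rng.integers(n_frames))
            expected = 0
            for cid in t.cells:
                if cid == focal or t.group_of(cid) != "wt":
                    continue
                gate = gate_by_cell_frame.get((cid, fr))
                if gate not in NCFG.motile_gates:
                    continue
                if np.linalg.norm(pos[cid][fr] - pos[focal][fr]) <= NCFG.radius:
                    expected += 1
            got = cr.motile_neighbor_count(t, gated, focal, fr * 20.0, NCFG)
            assert got == expected
            checks += 1
        assert checks == 50

    def test_invariant_under_rigid_motion_and_relabeling(self, rng):
        from scipy.spatial.transform import Rotation
        tracks = {f"c{i}": ("wt" if i % 2 else "ko",
                            rng.uniform(0, 100, 3) + rng.normal(size=(6, 3)).cumsum(axis=0))
                  for i in range(20)}
        t = make_table(tracks, dt=20.0)
        R = Rotation.random(rng=np.random.default_rng(5)).as_matrix()
        shift = np.array([50.0, -20.0, 10.0])
        moved = {cid: (g, p @ R.T + shift) for cid, (g, p) in tracks.items()}
        t2 = make_table(moved, dt=20.0)
        for focal in ["c0", "c3", "c8"]:
            a = cr.motile_neighbor_count(t, motile_gate_rows(t), focal, 40.0, NCFG)
            b = cr.motile_neighbor_count(t2, motile_gate_rows(t2), focal, 40.0, NCFG)
            assert a == b


class TestConditionalVelocity:
    def test_hand_built_fixture_means(self):
        """Follower escorted by a motile leader at 5 µm/min, isolated at 1."""
        n = 13
        t = make_table({
            "leader": ("wt", straight_track(n, 5.0)),
            "near": ("ko", straight_track(n, 5.0, origin=(0, 10, 0))),
            "far": ("ko", straight_track(n, 1.0, origin=(600, 0, 0))),
        })
        tcfg = cr.TrackletConfig(window=4, stride=4)
        gated = cr.classify_table(
            cr.metrics_table(cr.decompose(t, tcfg), tcfg), cr.GateConfig())
        out = cr.conditional_velocity(t, gated, NCFG)
        ko = out.records[out.records["group"] == "ko"]
        assert ko.loc[ko["cell_id"] == "near", "n_motile"].eq(1).all()
        assert ko.loc[ko["cell_id"] == "far", "n_motile"].eq(0).all()
        summ = out.summary.set_index(["group", "bin"])
        assert summ.loc[("ko", "1"), "mean"] == pytest.approx(5.0)
        assert summ.loc[("ko", "0"), "mean"] == pytest.approx(1.0)

    def test_immobile_leaders_never_count(self):
        n = 13
        t = make_table({
            "leader": ("wt", np.zeros((n, 3))),
            "f": ("ko", straight_track(n, 3.0, origin=(0, 5, 0))),
        })
        tcfg = cr.TrackletConfig(window=4, stride=4)
        gated = cr.classify_table(
            cr.metrics_table(cr.decompose(t, tcfg), tcfg), cr.GateConfig())
        out = cr.conditional_velocity(t, gated, NCFG)
        assert (out.records["n_motile"] == 0).all()


class TestDirectionalitySeries:
    def test_ballistic_track(self):
        s = cr.directionality_series(straight_track(20, 5.0), 60.0 * np.arange(20),
                                     window=6, cfg=NCFG)
        assert np.allclose(s.gamma, 1.0)
        assert s.event_times.size == 0

    def test_single_right_angle_turn(self):
        pos = np.concatenate([straight_track(8, 5.0),
                              straight_track(7, 5.0, direction=(0, 1, 0),
                                             origin=(35, 5, 0))])
        cfg = cr.NeighborhoodConfig(turn_angle=45.0)
        s = cr.directionality_series(pos, 60.0 * np.arange(15), window=6, cfg=cfg)
        assert list(s.event_frames) == [7]

    def test_stationary_track_has_no_events(self):
        s = cr.directionality_series(np.zeros((15, 3)), 60.0 * np.arange(15),
                                     window=6, cfg=NCFG)
        assert s.event_times.size == 0


class TestLeadLag:
    def test_perfect_precedence_scores_one(self):
        follower = np.array([100.0, 200.0, 300.0])
        trains = [np.array([t - 20.0]) for t in follower]
        r = cr.lead_lag_score(follower, trains, NCFG, duration=400.0,
                              n_shifts=199, seed=0)
        assert r.fraction == 1.0
        assert r.p_value < 0.05

    def test_no_leader_events_scores_zero(self):
        r = cr.lead_lag_score(np.array([100.0, 200.0]), np.array([]), NCFG,
                              duration=400.0, n_shifts=99, seed=0)
        assert r.fraction == 0.0

    def test_zero_follower_events_is_undefined(self):
        with pytest.raises(UndefinedLeadLagError):
            cr.lead_lag_score(np.array([]), np.array([10.0]), NCFG, duration=100.0)

    def test_independent_poisson_trains_match_null(self, rng):
        """Observed fraction of independent trains sits inside the null."""
        duration = 20000.0
        follower = np.sort(rng.uniform(0, duration, size=60))
        leader = np.sort(rng.uniform(0, duration, size=200))
        r = cr.lead_lag_score(follower, leader, NCFG, duration=duration,
                              n_shifts=499, seed=1)
        assert abs(r.fraction - r.null_mean) <= 3 * max(r.null_sd, 1e-9)
        assert r.p_value > 0.01

    def test_time_reversal_symmetric_fixture(self):
        duration = 400.0
        follower = np.array([100.0, 200.0, 300.0])
        leader = np.sort(np.concatenate([follower - 20.0, follower + 20.0]))
        fwd = cr.lead_lag_score(follower, leader, NCFG, duration=duration,
                                n_shifts=99, seed=0)
        rev = cr.lead_lag_score(np.sort(duration - follower),
                                np.sort(duration - leader), NCFG,
                                duration=duration, n_shifts=99, seed=0)
        assert fwd.fraction == rev.fraction == 1.0


class TestNeighborhoodMeanDirectionality:
    def test_single_neighbor_equals_its_series(self):
        t = make_table({
            "f": ("ko", np.zeros((12, 3))),
            "n": ("wt", straight_track(12, 5.0, origin=(0, 10, 0))),
        })
        out = cr.neighborhood_mean_directionality(t, "f", NCFG, window=6)
        s = cr.directionality_series(t.positions("n"), t.times("n"), 6, NCFG)
        # neighbor drifts out of the 50 µm radius after ~9 frames
        near = out["mean_directionality"].notna()
        assert near.any()
        assert np.allclose(out.loc[near, "mean_directionality"],
                           s.gamma[near.to_numpy()])

    def test_no_neighbors_all_gaps(self):
        t = make_table({
            "f": ("ko", np.zeros((12, 3))),
            "n": ("wt", straight_track(12, 1.0, origin=(500, 0, 0))),
        })
        out = cr.neighborhood_mean_directionality(t, "f", NCFG, window=6)
        assert out["mean_directionality"].isna().all()

    def test_mean_of_ballistic_and_stationary_neighbors(self):
        t = make_table({
            "f": ("ko", np.zeros((12, 3))),
            "ballistic": ("wt", straight_track(12, 4.0, direction=(0, 1, 0),
                                               origin=(10, 0, 0))),
            "still": ("wt", np.tile([0.0, 10.0, 0.0], (12, 1))),
        })
        out = cr.neighborhood_mean_directionality(t, "f", NCFG, window=6)
        mid = out["mean_directionality"].iloc[2]
        assert mid == pytest.approx((1.0 + 0.0) / 2)


class TestCommonOrigin:
    def test_first_point_is_origin(self, rng):
        t = make_table({"a": ("wt", 50 + rng.normal(size=(8, 3)).cumsum(axis=0))})
        out = cr.common_origin(t)
        assert np.allclose(out[["x", "y", "z"]].iloc[0], 0.0)

    def test_translation_invariance(self, rng):
        pos = rng.normal(size=(9, 3)).cumsum(axis=0)
        t1 = make_table({"a": ("wt", pos)})
        t2 = make_table({"a": ("wt", pos + np.array([123.0, -45.0, 6.0]))})
        a, b = cr.common_origin(t1), cr.common_origin(t2)
        assert np.allclose(a[["x", "y", "z"]], b[["x", "y", "z"]], atol=1e-9)

    def test_final_displacement_matches_track_summary(self, rng):
        pos = rng.normal(size=(11, 3)).cumsum(axis=0)
        t = make_table({"a": ("wt", pos)})
        out = cr.common_origin(t)
        m = cr.summarize_track(pos, dt=60.0)
        assert out["displacement"].iloc[-1] == pytest.approx(m.displacement, abs=1e-9)
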