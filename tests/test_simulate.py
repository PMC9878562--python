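"""Simulator fields, dynamics, presets, determinism and transwell surrogate."""

import dataclasses

import numpy as np
import pytest

import chemorelay as cr

from conftest import sim_cached

CFG = cr.SimulationConfig()


class TestCxcl12Field:
    def test_linear_profile_endpoints_and_midpoint(self):
        L = CFG.arena[0]
        assert cr.cxcl12_field(np.array([0.0, 10, 10]), CFG) == 0.0
        assert cr.cxcl12_field(np.array([L, 10, 10]), CFG) == pytest.approx(CFG.c0)
        assert cr.cxcl12_field(np.array([L / 2, 10, 10]), CFG) == pytest.approx(CFG.c0 / 2)

    def test_outside_arena_errors(self):
        with pytest.raises(ValueError):
            cr.cxcl12_field(np.array([-1.0, 0, 0]), CFG)

    def test_erf_profile_monotone(self):
        cfg = dataclasses.replace(CFG, profile="erf")
        xs = np.linspace(0, cfg.arena[0], 50)
        pos = np.column_stack([xs, np.full(50, 10.0), np.full(50, 10.0)])
        c = cr.cxcl12_field(pos, cfg)
        assert np.all(np.diff(c) >= 0)


class TestLtb4Field:
    def test_no_sources_is_zero(self):
        assert cr.ltb4_field(np.zeros(3), np.empty((0, 3)), None, CFG) == 0.0

    def test_at_source_equals_q(self):
        src = np.array([[100.0, 50, 50]])
        assert cr.ltb4_field(src[0], src, np.array([True]), CFG) == pytest.approx(
            CFG.ltb4_source)

    def test_at_range_equals_q_over_e(self):
        src = np.array([[100.0, 50, 50]])
        p = src[0] + np.array([CFG.ltb4_range, 0, 0])
        assert cr.ltb4_field(p, src, np.array([True]), CFG) == pytest.approx(
            CFG.ltb4_source / np.e)

    def test_brute_force_sum_oracle(self, rng):
        src = rng.uniform(0, 500, size=(40, 3))
        sec = rng.random(40) < 0.6
        p = rng.uniform(0, 500, size=3)
        expected = sum(
            CFG.ltb4_source * np.exp(-np.linalg.norm(p - s) / CFG.ltb4_range)
            for s, on in zip(src, sec) if on
        )
        assert cr.ltb4_field(p, src, sec, CFG) == pytest.approx(expected, rel=1e-12)

    def test_effective_reach_below_50um(self):
        assert CFG.ltb4_reach < 50.0


class TestStepDynamics:
    def test_lone_followers_stay_essentially_stationary(self):
        table, _ = sim_cached("ko_alone", 1)
        disp = [np.linalg.norm(table.positions(c)[-1] - table.positions(c)[0])
                for c in table.cells]
        # σ_v0 = 0.3 µm/min for 360 min of diffusive jitter: stay local
        assert np.median(disp) < 20.0
        assert max(disp) < 100.0

    def test_full_bias_converges_to_gradient_direction(self):
        cfg = cr.SimulationConfig(n_leaders=1, n_followers=0, duration=4000.0,
                                  chemotactic_bias=1.0, persistence=0.5,
                                  p_stop=0.0, arena=(100000.0, 500.0, 100.0),
                                  seed=3)
        table, _ = cr.simulate(cfg)
        m = cr.summarize_track(table.positions(table.cells[0]), cfg.dt)
        assert m.directionality > 0.99
        pos = table.positions(table.cells[0])
        assert pos[-1, 0] > pos[0, 0]  # moved up the gradient

    def test_zero_bias_has_no_mean_drift(self):
        cfg = cr.SimulationConfig(n_leaders=120, n_followers=0, duration=7200.0,
                                  chemotactic_bias=0.0, p_stop=0.0,
                                  arena=(4000.0, 4000.0, 4000.0), seed=4)
        table, _ = cr.simulate(cfg)
        dx = np.array([table.positions(c)[-1, 0] - table.positions(c)[0, 0]
                       for c in table.cells])
        se = dx.std(ddof=1) / np.sqrt(len(dx))
        assert abs(dx.mean()) < 3 * se

    def test_zero_bias_directional_gate_not_enriched(self):
        """Unbiased motile walkers must not look spuriously chemotactic."""
        cfg = cr.SimulationConfig(n_leaders=100, n_followers=0, duration=7200.0,
                                  chemotactic_bias=0.0, p_stop=0.0,
                                  arena=(4000.0, 4000.0, 4000.0), seed=5)
        table, _ = cr.simulate(cfg)
        tcfg = cr.TrackletConfig()
        m = cr.metrics_table(cr.decompose(table, tcfg), tcfg)
        counts = cr.classify_table(m, cr.GateConfig())["gate"].value_counts()
        assert counts.get("directional", 0) <= counts.get("chemokinesis", 0)


class TestSecretionRules:
    def _field_at_followers(self, cfg):
        table, truth = cr.simulate(cfg)
        return truth

    def test_perturbed_leaders_never_activate_followers(self):
        for flag in ("ptx_leaders", "ackr3_deltaC", "blt1r_ko", "ptx_followers"):
            cfg = cr.SimulationConfig(n_leaders=30, n_followers=30,
                                      duration=2400.0, seed=6, **{flag: True})
            _, truth = cr.simulate(cfg)
            assert not truth.activation["active"].any(), flag

    def test_unperturbed_mixture_activates_some_followers(self):
        cfg = cr.SimulationConfig(n_leaders=30, n_followers=30, duration=2400.0, seed=6)
        _, truth = cr.simulate(cfg)
        assert truth.activation["active"].any()

    def test_low_cxcl12_blocks_secretion(self):
        # all sources below c_min: field never reaches any follower
        cfg = cr.SimulationConfig(n_leaders=30, n_followers=30, duration=2400.0,
                                  c_min=1e9, seed=6)
        _, truth = cr.simulate(cfg)
        assert not truth.activation["active"].any()


class TestSimulate:
    def test_short_run_frame_count(self):
        cfg = cr.SimulationConfig(n_leaders=2, n_followers=2, duration=40.0, dt=20.0)
        table, _ = cr.simulate(cfg)
        assert all(len(table.positions(c)) == 3 for c in table.cells)

    def test_determinism_same_seed(self):
        cfg = cr.SimulationConfig(n_leaders=10, n_followers=10, duration=600.0, seed=11)
        a, _ = cr.simulate(cfg)
        b, _ = cr.simulate(cfg)
        assert a.df.equals(b.df)

    def test_different_seed_differs(self):
        base = dict(n_leaders=10, n_followers=10, duration=600.0)
        a, _ = cr.simulate(cr.SimulationConfig(seed=1, **base))
        b, _ = cr.simulate(cr.SimulationConfig(seed=2, **base))
        assert not a.df.equals(b.df)

    def test_agents_conserved_and_inside_arena(self):
        table, _ = sim_cached("mixed_1to1", 1)
        assert table.n_cells == 200
        box = np.asarray(CFG.arena)
        xyz = table.df[["x", "y", "z"]].to_numpy()
        assert (xyz >= 0).all() and (xyz <= box).all()

    def test_activation_false_at_start(self):
        _, truth = sim_cached("mixed_1to1", 1)
        frame0 = truth.activation[truth.activation["frame"] == 0]
        assert not frame0["active"].any()

    def test_invalid_config_rejected_before_running(self):
        with pytest.raises(ValueError, match="dt must divide"):
            cr.SimulationConfig(duration=101.0, dt=20.0)
        with pytest.raises(ValueError, match="persistence"):
            cr.SimulationConfig(persistence=1.5)


class TestPresets:
    def test_mixed_is_one_to_one(self):
        cfg = cr.preset("mixed_1to1")
        assert cfg.n_leaders == cfg.n_followers > 0

    def test_ko_alone_has_no_leaders(self):
        assert cr.preset("ko_alone").n_leaders == 0

    def test_blt1rko_flag_only_difference(self):
        a = cr.preset("mixed_1to1", seed=9)
        b = cr.preset("mixed_blt1rko", seed=9)
        assert b.blt1r_ko and not a.blt1r_ko
        assert dataclasses.replace(b, blt1r_ko=False) == a

    def test_unknown_preset(self):
        with pytest.raises(ValueError, match="unknown preset"):
            cr.preset("nope")


class TestTranswellSurrogate:
    def test_all_agents_beyond_plane(self):
        from conftest import make_table
        t = make_table({"a": ("wt", np.tile([900.0, 0, 0], (3, 1))),
                        "b": ("wt", np.tile([950.0, 0, 0], (3, 1)))})
        out = cr.transwell_surrogate(t, plane=800.0)
        assert out["percent_crossed"].iloc[0] == 100.0

    def test_ko_alone_barely_crosses(self):
        table, _ = sim_cached("ko_alone", 1)
        out = cr.transwell_surrogate(table, plane=750.0)
        assert out.loc[out["group"] == "ko", "percent_crossed"].iloc[0] < 5.0

    def test_rescued_followers_cross_more(self):
        ko_table, _ = sim_cached("ko_alone", 1)
        mx_table, _ = sim_cached("mixed_1to1", 1)
        plane = 750.0
        alone = cr.transwell_surrogate(ko_table, plane=plane)
        mixed = cr.transwell_surrogate(mx_table, plane=plane)
        pct = lambda df: df.loc[df["group"] == "ko", "percent_crossed"].iloc[0]
        assert pct(mixed) > pct(alone)


def test_deposit_mode_runs_and_differs():
    base = dict(n_leaders=20, n_followers=20, duration=1200.0, seed=13)
    a, _ = cr.simulate(cr.SimulationConfig(**base))
    b, _ = cr.simulate(cr.SimulationConfig(deposit_mode=True, **base))
    assert len(a.df) == len(b.df)
    assert not a.df.equals(b.df)
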