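"""Initialization rules, stepping, full runs, and sweeps."""

import math
from dataclasses import replace

import numpy as np
import pytest

from mtpush.mechanics import CellGeometry
from mtpush.mt_dynamics import CatastropheModel, KineticParams, Phase, Side
from mtpush.simulator import (
    NucleusState,
    SimConfig,
    initialize,
    replicate_seed,
    sample_axis_angle,
    simulate,
    step,
    sweep,
)
from mtpush.stats import stationarity_check, summarize


class TestInitialize:
    def test_bundle_quotient_rule(self, rng):
        _, mts = initialize(SimConfig(n_right=9, n_left=9, seed=0), rng)
        assert len({mt.anchor_id for mt in mts}) <= 4
        assert max(mt.anchor_id for mt in mts) <= 3

    def test_bundle_quotient_small(self, rng):
        _, mts = initialize(SimConfig(n_right=3, n_left=3, seed=0), rng)
        assert {mt.anchor_id for mt in mts} == {0}

    def test_fewer_than_four_mts_clamps_to_one_bundle(self, rng):
        _, mts = initialize(SimConfig(n_right=1, n_left=1, seed=0), rng)
        assert {mt.anchor_id for mt in mts} == {0}

    def test_spb_is_most_populated_anchor_at_zero(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            _, mts = initialize(SimConfig(seed=seed), rng)
            counts = {}
            angles = {}
            for mt in mts:
                counts[mt.anchor_id] = counts.get(mt.anchor_id, 0) + 1
                angles[mt.anchor_id] = mt.anchor_angle
            best = max(sorted(counts), key=lambda k: counts[k])
            assert angles[best] == pytest.approx(0.0)

    def test_nucleus_starts_at_left_tip(self, rng):
        cfg = SimConfig(seed=0)
        nucleus, _ = initialize(cfg, rng)
        L, rnuc = cfg.geometry.half_length, cfg.drag.nucleus_radius
        assert nucleus.position == (-(L - rnuc), 0.0)

    def test_sides_split_right_left(self, rng):
        _, mts = initialize(SimConfig(n_right=5, n_left=5, seed=1), rng)
        assert sum(mt.side is Side.RIGHT for mt in mts) == 5
        assert all(mt.length == 0.0 and mt.phase is Phase.GROWING for mt in mts)

    def test_correlated_mode_mirrors_sites_and_angles(self, rng):
        _, mts = initialize(SimConfig(lr_mode="correlated", seed=2), rng)
        for i in range(9):
            left = mts[i + 9]
            assert left.partner == i and mts[i].partner == i + 9
            assert left.axis_angle == mts[i].axis_angle
            # site mirrored about the transverse axis
            assert math.cos(left.anchor_angle) == pytest.approx(
                -math.cos(mts[i].anchor_angle), abs=1e-12
            )


class TestAxisAngles:
    def test_degenerate_spread(self):
        cfg = SimConfig(theta_spread=0.0)
        assert sample_axis_angle(cfg, Side.RIGHT) == 0.0

    def test_partner_angle_reused_in_correlated_mode(self, rng):
        cfg = SimConfig(lr_mode="correlated")
        assert sample_axis_angle(cfg, Side.LEFT, partner_angle=0.42, rng=rng) == 0.42

    def test_broader_spread_gives_larger_mean_tilt(self, rng):
        narrow = SimConfig(theta_spread=0.1)
        broad = SimConfig(theta_spread=0.6)
        a = [abs(sample_axis_angle(narrow, Side.RIGHT, rng=rng)) for _ in range(2000)]
        b = [abs(sample_axis_angle(broad, Side.RIGHT, rng=rng)) for _ in range(2000)]
        assert np.mean(b) > 2 * np.mean(a)

    def test_angles_within_open_half_pi_interval(self, rng):
        cfg = SimConfig(theta_spread=1.5)
        draws = [sample_axis_angle(cfg, Side.RIGHT, rng=rng) for _ in range(2000)]
        assert all(-math.pi / 2 < th < math.pi / 2 for th in draws)


class TestStep:
    def test_no_contact_means_no_motion(self, rng):
        cfg = SimConfig(seed=0)
        nucleus, mts = initialize(cfg, rng)
        nucleus = NucleusState(position=(0.0, 0.0))  # all MTs at length 0, centered
        out = step(nucleus, mts, cfg, rng)
        assert out.position == (0.0, 0.0) and out.rotation == 0.0

    def test_single_pushing_filament_moves_nucleus_back(self, rng, kinetics):
        cfg = SimConfig(n_right=1, n_left=1, seed=0, theta_spread=0.0)
        _, mts = initialize(cfg, rng)
        mts[0].length = 5.7
        mts[0].anchor_angle = 0.0
        mts[1].length = 0.0
        nucleus = NucleusState(position=(0.0, 0.0))
        out = step(nucleus, mts, cfg, rng)
        assert out.position[0] < 0.0

    def test_mirror_pair_cancels_to_machine_precision(self, rng):
        cfg = SimConfig(n_right=1, n_left=1, seed=0, theta_spread=0.0)
        _, mts = initialize(cfg, rng)
        for mt, psi in zip(mts, (0.0, math.pi)):
            mt.anchor_angle = psi
            mt.axis_angle = 0.0
            mt.length = 5.7
            mt.drawn_tau = 1e9
        nucleus = NucleusState(position=(0.0, 0.0))
        out = step(nucleus, mts, cfg, rng)
        assert out.position[0] == 0.0
        # sin(pi) is not exactly zero in floating point; the residual torque
        # is at the round-off level
        assert abs(out.rotation) < 1e-18


class TestSimulate:
    def test_fixed_seed_is_bit_identical(self):
        cfg = SimConfig(seed=7, duration=600.0, burn_in=0.0)
        a, b = simulate(cfg), simulate(cfg)
        assert np.array_equal(a.x, b.x)
        assert np.array_equal(a.omega, b.omega)

    def test_wt_cell_centers_from_the_tip(self, wt_trajectory):
        cfg = SimConfig()
        x = wt_trajectory.x[wt_trajectory.times >= cfg.burn_in]
        assert abs(x.mean()) < 0.2 * cfg.geometry.half_length

    def test_spb_rides_on_the_nucleus_surface(self, wt_trajectory):
        r = np.hypot(
            wt_trajectory.spb_x - wt_trajectory.x, wt_trajectory.spb_y - wt_trajectory.y
        )
        np.testing.assert_allclose(r, 1.4, rtol=1e-12)

    def test_short_filaments_stall_nucleus_near_tip(self, mal3_model):
        # mean excursion v_grow * N * T ~ 1.3 um << L/2: the nucleus cannot be
        # pushed to the center and keeps a large offset toward its start tip
        kin = KineticParams(0.01, 0.0034, 0.15, 5.0, 1.25, mal3_model)
        cfg = SimConfig(kinetics=kin, seed=3)
        traj = simulate(cfg)
        x = traj.x[traj.times >= cfg.burn_in]
        assert x.mean() < -2.0

    def test_trajectory_is_stationary_after_burn_in(self, wt_trajectory):
        x = wt_trajectory.spb_x[wt_trajectory.times >= 1800.0]
        report = stationarity_check(x, n_windows=6)
        assert report.stationary

    def test_output_grid_coarsening_subsamples_same_path(self):
        fine = simulate(SimConfig(seed=5, duration=1200.0, burn_in=0.0, out_dt=1.0))
        coarse = simulate(SimConfig(seed=5, duration=1200.0, burn_in=0.0, out_dt=2.0))
        assert np.array_equal(fine.x[::2], coarse.x)

    def test_mirrored_mode_keeps_centered_nucleus_centered(self):
        cfg = SimConfig(lr_mode="mirrored", seed=11, duration=1200.0, burn_in=0.0)
        traj = simulate(cfg)
        assert np.all(traj.x == 0.0)

    def test_healthy_wt_run_has_no_wall_clamps(self, wt_trajectory):
        assert wt_trajectory.clamp_events == 0


class TestSweep:
    def test_degenerate_grid_equals_direct_run(self):
        base = SimConfig(seed=9, duration=1200.0, burn_in=300.0)
        df = sweep(base, [14.0], [18], replicates=1)
        assert len(df) == 1
        cfg = replace(base, seed=replicate_seed(9, 0, 0, 0))
        direct = summarize(simulate(cfg), burn_in=base.burn_in, n_boot=0)
        row = df.iloc[0]
        assert row["delta"] == pytest.approx(direct.delta)
        assert row["sigma_x"] == pytest.approx(direct.sigma_x)

    def test_tidy_output_shape_and_reproducibility(self):
        base = SimConfig(seed=9, duration=600.0, burn_in=0.0)
        df1 = sweep(base, [12.0, 14.0], [6], replicates=2)
        df2 = sweep(base, [12.0, 14.0], [6], replicates=2)
        assert list(df1.columns[:3]) == ["length", "n_mt", "replicate"]
        assert len(df1) == 4 and df1["ok"].all()
        assert np.allclose(df1["delta"], df2["delta"])

    def test_odd_mt_number_rejected(self):
        with pytest.raises(ValueError):
            sweep(SimConfig(), [14.0], [7], replicates=1)
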