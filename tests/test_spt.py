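"""Tracking and diffusion estimation: MSD oracle, linking, classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from spineneck import (IMMOBILE_THRESHOLD, NeckGeometry, SimulationConfig,
                       classify_mobility, classify_trajectory_region,
                       compute_msd, filter_trajectories, fit_diffusion,
                       link_spots, simulate_trajectories_on_cylinder)
from spineneck.spt import (DiffusionEstimate, Trajectory, principal_axis,
                           table_to_trajectories, trajectories_to_table)
from spineneck.synthetic import NO_SP_AREA, SP_AREA

from conftest import brute_force_msd, make_trajectory

DT = 0.012
XAXIS = np.array([1.0, 0.0])


class TestMsd:
    def test_static_trajectory_msd_zero(self):
        traj = make_trajectory(np.tile([10.0, 20.0], (10, 1)))
        assert np.all(compute_msd(traj, 2).msd == 0.0)

    def test_ballistic_1d_closed_form(self):
        s = 7.0
        xy = np.stack([s * np.arange(12), np.zeros(12)], axis=1)
        msd = compute_msd(make_trajectory(xy), 1, axis=XAXIS)
        assert np.allclose(msd.msd, (msd.lags * s) ** 2)

    def test_matches_brute_force_oracle_both_dims(self, rng):
        for _ in range(100):
            n = rng.integers(5, 40)
            xy = rng.normal(0, 50, (n, 2))
            traj = make_trajectory(xy)
            assert np.allclose(compute_msd(traj, 2).msd,
                               brute_force_msd(xy, 2), rtol=1e-12, atol=1e-9)
            assert np.allclose(compute_msd(traj, 1, axis=XAXIS).msd,
                               brute_force_msd(xy, 1, XAXIS), rtol=1e-12,
                               atol=1e-9)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(0, 10_000), st.integers(5, 30))
    def test_brute_force_property(self, seed, n):
        rng = np.random.default_rng(seed)
        xy = rng.normal(0, 100, (n, 2))
        u = rng.normal(size=2)
        u /= np.linalg.norm(u)
        traj = make_trajectory(xy)
        assert np.allclose(compute_msd(traj, 1, axis=u).msd,
                           brute_force_msd(xy, 1, u), rtol=1e-12, atol=1e-9)

    def test_pairs_decrease_and_axis_required(self):
        traj = make_trajectory(np.random.default_rng(0).normal(0, 10, (20, 2)))
        msd = compute_msd(traj, 2)
        assert np.all(np.diff(msd.n_pairs) < 0)
        with pytest.raises(ValueError, match="axis"):
            compute_msd(traj, 1)


class TestFitDiffusion:
    def test_exact_line_recovers_slope_and_intercept(self):
        D, b = 0.05, 0.001                   # um^2/s, um^2
        lags = np.arange(1, 10)
        msd_um2 = 2 * D * lags * DT + b
        from spineneck.spt import MsdCurve
        curve = MsdCurve(lags=lags, msd=msd_um2 * 1e6, n_pairs=100 - lags,
                         dimensionality=1)
        est = fit_diffusion(curve, DT)
        assert est.D == pytest.approx(D, rel=1e-9)
        assert est.intercept == pytest.approx(b, rel=1e-9)

    def test_zero_msd_is_immobile(self):
        from spineneck.spt import MsdCurve
        curve = MsdCurve(lags=np.arange(1, 8), msd=np.zeros(7),
                         n_pairs=np.arange(7, 0, -1), dimensionality=1)
        est = fit_diffusion(curve, DT)
        assert est.D == 0.0 and est.intercept == 0.0 and not est.mobile

    def test_short_curve_rejected(self):
        from spineneck.spt import MsdCurve
        curve = MsdCurve(lags=np.arange(1, 4), msd=np.ones(3),
                         n_pairs=np.array([3, 2, 1]), dimensionality=2)
        with pytest.raises(ValueError, match="lag"):
            fit_diffusion(curve, DT)

    def test_simulation_recovery_median_within_15pct(self, no_sp_geom):
        D = 0.02
        cfg = SimulationConfig(n_frames=100, D_map={NO_SP_AREA: D},
                               loc_noise_sigma=15.0, rng_seed=5)
        table, _ = simulate_trajectories_on_cylinder(no_sp_geom, cfg, 200)
        ds = [fit_diffusion(compute_msd(t, 1, axis=XAXIS, max_lag=5), DT).D
              for t in table_to_trajectories(table, DT)]
        assert abs(np.median(ds) - D) / D < 0.15

    def test_2d_projection_biased_low_on_cylinder(self, no_sp_geom):
        cfg = SimulationConfig(n_frames=100, D_map={NO_SP_AREA: 0.05},
                               loc_noise_sigma=15.0, rng_seed=6)
        table, _ = simulate_trajectories_on_cylinder(no_sp_geom, cfg, 150)
        trajs = table_to_trajectories(table, DT)
        d1 = np.median([fit_diffusion(compute_msd(t, 1, axis=XAXIS, max_lag=5),
                                      DT).D for t in trajs])
        d2 = np.median([fit_diffusion(compute_msd(t, 2, max_lag=5), DT).D
                        for t in trajs])
        assert d2 < d1


class TestMobility:
    @pytest.mark.parametrize("D,expected", [
        (9e-5, False), (2e-4, True), (-1e-5, False), (1e-4, True)])
    def test_threshold_rule(self, D, expected):
        est = DiffusionEstimate(D=D, intercept=0.0, fit_points=(2, 5),
                                estimator="D_1Dlong", mobile=D >= IMMOBILE_THRESHOLD)
        assert classify_mobility(est) is expected


class TestFilter:
    def test_fifteen_frame_threshold(self, rng):
        def traj_of(n):
            return make_trajectory(rng.normal(0, 10, (n, 2)))
        kept, dropped = filter_trajectories([traj_of(14), traj_of(15), traj_of(30)])
        assert [len(t) for t in kept] == [15, 30] and dropped == 1

    def test_empty_input(self):
        assert filter_trajectories([]) == ([], 0)


class TestLinking:
    def test_single_drifting_spot_one_trajectory(self):
        frames = np.arange(30)
        locs = pd.DataFrame({"frame": frames, "x_nm": 10.0 * frames,
                             "y_nm": np.zeros(30)})
        trajs = link_spots(locs, max_disp=50.0, dt=DT)
        assert len(trajs) == 1 and len(trajs[0]) == 30

    def test_two_distant_static_spots_never_swap(self):
        frames = np.repeat(np.arange(20), 2)
        locs = pd.DataFrame({"frame": frames,
                             "x_nm": np.tile([0.0, 5000.0], 20),
                             "y_nm": np.zeros(40)})
        trajs = link_spots(locs, max_disp=500.0, dt=DT)
        assert len(trajs) == 2
        for t in trajs:
            assert np.ptp(t.xy[:, 0]) == 0.0

    def test_links_match_ground_truth_at_low_density(self, no_sp_geom):
        # sparse simulated particles; >=95% of links correct
        cfg = SimulationConfig(n_frames=100, D_map={NO_SP_AREA: 0.05},
                               loc_noise_sigma=10.0, rng_seed=8)
        table, _ = simulate_trajectories_on_cylinder(no_sp_geom, cfg, 5)
        # spread particles far apart (one neck each) to emulate low density
        shift = table["traj_id"].to_numpy() * 5000.0
        locs = pd.DataFrame({"frame": table["frame"],
                             "x_nm": table["x_nm"] + shift,
                             "y_nm": table["y_nm"],
                             "true_id": table["traj_id"]})
        trajs = link_spots(locs, max_disp=600.0, dt=DT)
        correct = total = 0
        truth_pos = {(int(f), round(x, 6)): tid for f, x, tid in
                     zip(locs["frame"], locs["x_nm"], locs["true_id"])}
        for t in trajs:
            ids = [truth_pos[(int(f), round(x, 6))]
                   for f, x in zip(t.frames, t.xy[:, 0])]
            correct += sum(a == b for a, b in zip(ids[:-1], ids[1:]))
            total += len(ids) - 1
        assert total > 0 and correct / total >= 0.95


class TestRegionClassification:
    SPINE = {"spine": [(-100.0, -400.0), (1100.0, -400.0),
                       (1100.0, 400.0), (-100.0, 400.0)]}

    def _sp_mask(self, px=20.0):
        mask = np.zeros((40, 60), bool)
        xs = np.arange(60) * px - 100.0
        mask[:, (xs >= 300.0) & (xs <= 700.0)] = True
        return mask, px, (-100.0, -400.0)

    def test_empty_mask_means_sp_negative(self):
        traj = make_trajectory(np.tile([500.0, 0.0], (10, 1)))
        mask, px, origin = self._sp_mask()
        label = classify_trajectory_region(traj, np.zeros_like(mask), px,
                                           self.SPINE, origin)
        assert label.spine_class == "SP- spine" and label.area_class is None

    def test_all_points_on_mask_is_sp_area(self):
        traj = make_trajectory(np.tile([500.0, 0.0], (10, 1)))
        mask, px, origin = self._sp_mask()
        label = classify_trajectory_region(traj, mask, px, self.SPINE, origin)
        assert label.spine_class == "SP+ spine" and label.area_class == "SP area"

    def test_outside_all_rois_is_dendrite(self):
        traj = make_trajectory(np.tile([9000.0, 9000.0], (10, 1)))
        mask, px, origin = self._sp_mask()
        assert classify_trajectory_region(traj, mask, px, self.SPINE,
                                          origin).spine_class == "dendrite"

    def test_agreement_with_simulator_truth(self, geom):
        cfg = SimulationConfig(n_frames=50, rng_seed=11)
        table, truth = simulate_trajectories_on_cylinder(geom, cfg, 80)
        mask, px, origin = self._sp_mask()
        lookup = truth.trajectories.set_index("traj_id")["region"]
        agree = []
        for t in table_to_trajectories(table, DT):
            label = classify_trajectory_region(t, mask, px, self.SPINE, origin)
            agree.append(label.area_class == lookup.loc[t.traj_id])
        assert np.mean(agree) >= 0.90


class TestTrajectoryType:
    def test_gap_rejected(self):
        with pytest.raises(ValueError, match="consecutive"):
            Trajectory(0, np.array([0, 1, 3]), np.zeros((3, 2)), DT)

    def test_roundtrip_table(self, rng):
        trajs = [make_trajectory(rng.normal(0, 10, (8, 2)), traj_id=i)
                 for i in range(3)]
        back = table_to_trajectories(trajectories_to_table(trajs), DT)
        assert len(back) == 3
        assert np.allclose(back[1].xy, trajs[1].xy)

    def test_principal_axis_sign_deterministic(self, rng):
        xy = rng.normal(0, 1, (50, 2)) @ np.array([[3.0, 0.0], [0.0, 0.5]])
        u = principal_axis(xy)
        assert u[0] > 0 and np.isclose(np.linalg.norm(u), 1.0)
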