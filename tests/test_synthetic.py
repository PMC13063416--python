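"""Generator correctness: charge populations, Langevin dynamics, rendering."""

import numpy as np
import pytest

from cellcharge import synthetic as syn
from cellcharge.types import CellModel, FieldSchedule, MediumConditions, SceneSpec


class TestChargePopulation:
    def test_lognormal_population_all_negative_with_peak_near_median(self):
        cells = syn.sample_charge_population(429, seed=7)
        q = np.array([c.charge_C for c in cells])
        assert np.all(q < 0)
        assert np.all(np.abs(q) >= 1.0e-18) and np.all(np.abs(q) <= 1.8e-16)
        # lognormal: sample median of |q| close to the 2e-17 C population median
        assert np.median(np.abs(q)) == pytest.approx(2.0e-17, rel=0.25)

    def test_fixed_family_gives_neutral_controls(self):
        cells = syn.sample_charge_population(5, {"family": "fixed", "params": {"q_C": 0.0}}, seed=0)
        assert [c.charge_C for c in cells] == [0.0] * 5

    def test_same_seed_reproduces_charges(self):
        a = syn.sample_charge_population(10_000, seed=42)
        b = syn.sample_charge_population(10_000, seed=42)
        assert np.array_equal([c.charge_C for c in a], [c.charge_C for c in b])

    def test_unknown_family_and_bad_params_raise(self):
        with pytest.raises(KeyError):
            syn.sample_charge_population(3, {"family": "gamma", "params": {}}, seed=0)
        with pytest.raises(ValueError):
            syn.sample_charge_population(
                3, {"family": "fixed", "params": {"q_C": np.nan}}, seed=0
            )
        with pytest.raises(ValueError):
            syn.sample_charge_population(0, seed=0)


class TestDrift:
    def test_drift_magnitude_matches_force_balance_arithmetic(self):
        # q = -1.56e-16 C at 380 V/m in water, r = 0.5 um -> 6.29 um/s anode-ward
        v = syn.drift_velocity_um_per_s(-1.56e-16, 380.0, 1.0e-3, 5.0e-7)
        assert v == pytest.approx(-6.29, abs=0.005)

    def test_drift_linear_in_charge_and_field(self):
        base = syn.drift_velocity_um_per_s(-2e-17, 380.0, 1e-3, 5e-7)
        assert syn.drift_velocity_um_per_s(-4e-17, 380.0, 1e-3, 5e-7) == pytest.approx(2 * base)
        assert syn.drift_velocity_um_per_s(-2e-17, 760.0, 1e-3, 5e-7) == pytest.approx(2 * base)

    def test_invalid_medium_raises(self):
        with pytest.raises(ValueError):
            syn.drift_velocity_um_per_s(-2e-17, 380.0, 0.0, 5e-7)
        with pytest.raises(ValueError):
            MediumConditions(diffusion_um2_per_s=-0.1)


class TestTrajectories:
    scene = SceneSpec(width_px=600, height_px=600, n_frames=150, noise_sigma=0)

    def _cells(self, n, q=0.0):
        rng = np.random.default_rng(5)
        w = self.scene.width_um
        return [
            CellModel(cell_id=i, charge_C=q,
                      start_xy_um=tuple(rng.uniform(0.3 * w, 0.7 * w, 2)))
            for i in range(n)
        ]

    def test_brownian_msd_slope_recovers_diffusion(self):
        # Monte-Carlo oracle: ensemble MSD slope / 4 ~ D for 100 pure-Brownian tracks
        medium = MediumConditions(diffusion_um2_per_s=0.16)
        tracks = syn.simulate_trajectories(
            self._cells(100), medium, FieldSchedule(E_V_per_m=0.0), self.scene,
            seed=np.random.default_rng(8),
        )
        disp = np.stack([t.positions_um - t.positions_um[0] for t in tracks])
        lags = np.arange(1, 30)
        msd = [np.mean(np.sum(disp[:, k, :] ** 2, axis=-1)) for k in lags]
        slope = np.polyfit(lags * self.scene.frame_interval_s, msd, 1)[0]
        assert slope / 4 == pytest.approx(0.16, rel=0.20)

    def test_deterministic_drift_speed_without_diffusion(self):
        medium = MediumConditions(diffusion_um2_per_s=0.0)
        field = FieldSchedule(E_V_per_m=380.0)
        (track,) = syn.simulate_trajectories(
            self._cells(1, q=-1.56e-16), medium, field, self.scene, seed=np.random.default_rng(1)
        )
        vy = np.diff(track.positions_um[:, 1]) / self.scene.frame_interval_s
        assert np.allclose(vy, -6.2898, atol=1e-3)  # constant anode-ward speed
        assert np.allclose(np.diff(track.positions_um[:, 0]), 0.0)

    def test_no_field_means_no_axis_drift(self):
        medium = MediumConditions(diffusion_um2_per_s=0.16)
        field = FieldSchedule(E_V_per_m=0.0)
        tracks = syn.simulate_trajectories(
            self._cells(100, q=-1e-16), medium, field, self.scene, seed=np.random.default_rng(3)
        )
        dy = np.concatenate([np.diff(t.positions_um[:, 1]) for t in tracks])
        se = dy.std(ddof=1) / np.sqrt(dy.size)
        assert abs(dy.mean()) < 3 * se

    def test_field_schedule_gates_drift_in_time(self):
        medium = MediumConditions(diffusion_um2_per_s=0.0)
        field = FieldSchedule(E_V_per_m=380.0, on_intervals=((0.0, 10.0),))
        scene = SceneSpec(width_px=2000, height_px=2000, n_frames=100)
        cell = CellModel(cell_id=0, charge_C=-2e-17, start_xy_um=(90.0, 90.0))
        (track,) = syn.simulate_trajectories([cell], medium, field, scene,
                                             seed=np.random.default_rng(2))
        on = track.times_s[:-1] < 10.0
        dy = np.diff(track.positions_um[:, 1])
        assert np.all(dy[on] < 0) and np.allclose(dy[~on], 0.0)

    def test_absorbing_boundary_truncates_and_flags(self):
        medium = MediumConditions(diffusion_um2_per_s=0.0)
        field = FieldSchedule(E_V_per_m=380.0)
        scene = SceneSpec(width_px=100, height_px=100, n_frames=100)
        cell = CellModel(cell_id=0, charge_C=-1.56e-16, start_xy_um=(4.0, 4.0))
        (track,) = syn.simulate_trajectories([cell], medium, field, scene,
                                             seed=np.random.default_rng(2))
        assert track.left_scene and len(track.times_s) < 100

    def test_same_seed_identical_tracks(self):
        medium = MediumConditions(diffusion_um2_per_s=0.16)
        field = FieldSchedule(E_V_per_m=380.0)
        cells = self._cells(5, q=-2e-17)
        a = syn.simulate_trajectories(cells, medium, field, self.scene, seed=9)
        b = syn.simulate_trajectories(cells, medium, field, self.scene, seed=9)
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.positions_um, tb.positions_um)

    def test_step_isotropy_rayleigh_uniform_when_uncharged(self):
        # >= 1e4 Brownian steps: angular distribution passes uniformity at alpha=0.01
        from pingouin import circ_rayleigh

        medium = MediumConditions(diffusion_um2_per_s=0.16)
        tracks = syn.simulate_trajectories(
            self._cells(100), medium, FieldSchedule(E_V_per_m=0.0), self.scene,
            seed=np.random.default_rng(10),
        )
        steps = np.concatenate([np.diff(t.positions_um, axis=0) for t in tracks])
        assert steps.shape[0] >= 10_000
        _, p = circ_rayleigh(np.arctan2(steps[:, 1], steps[:, 0]))
        assert p > 0.01

    def test_mean_axis_velocity_linear_in_charge_and_field(self):
        # with D=0 the fitted slope of v vs q (and v vs E) is exact to <2%
        medium = MediumConditions(diffusion_um2_per_s=0.0)
        scene = SceneSpec(width_px=4000, height_px=4000, n_frames=20)
        qs = -np.linspace(1, 9, 5) * 1e-17
        vels = []
        for q in qs:
            cell = CellModel(cell_id=0, charge_C=q, start_xy_um=(180.0, 300.0))
            (tr,) = syn.simulate_trajectories(
                [cell], medium, FieldSchedule(E_V_per_m=380.0), scene,
                seed=np.random.default_rng(0),
            )
            vels.append(np.mean(np.diff(tr.positions_um[:, 1])) / scene.frame_interval_s)
        slope = np.polyfit(qs, vels, 1)[0]
        expected = 380.0 / (6 * np.pi * 1e-3 * 5e-7) * 1e6
        assert slope == pytest.approx(expected, rel=0.02)


class TestRendering:
    def test_static_cell_renders_at_its_position(self):
        scene = SceneSpec(width_px=120, height_px=120, n_frames=1, noise_sigma=0)
        tr = syn.GroundTruthTrack(
            cell_id=0, times_s=[0.0],
            positions_um=[[50.0 * scene.pixel_scale_um, 60.0 * scene.pixel_scale_um]],
            drift_velocity_um_per_s=0.0,
        )
        stack, truth = syn.render_frames([tr], scene)
        # darkness-weighted centroid: the disk interior is flat, so weight by
        # depth below background rather than taking a bare argmin
        depth = scene.background_level - stack[0].astype(float)
        yy, xx = np.mgrid[: stack[0].shape[0], : stack[0].shape[1]]
        x = np.sum(xx * depth) / np.sum(depth)
        y = np.sum(yy * depth) / np.sum(depth)
        assert abs(x - 50.0) <= 0.5 and abs(y - 60.0) <= 0.5
        assert truth.loc[0, ["x_px", "y_px"]].tolist() == pytest.approx([50.0, 60.0])

    def test_truth_table_conserves_cells_per_frame(self, brownian_bench):
        truth = brownian_bench["truth"]
        counts = truth.groupby("frame")["cell_id"].nunique()
        assert counts.iloc[0] == 100  # all cells present at the start

    def test_rendering_is_deterministic(self):
        scene = SceneSpec(width_px=100, height_px=100, n_frames=3, noise_sigma=4, seed=17)
        cells = [CellModel(cell_id=0, start_xy_um=(4.0, 4.0))]
        medium = MediumConditions(diffusion_um2_per_s=0.1)
        field = FieldSchedule(E_V_per_m=0.0)
        out = [syn.simulate_scene(cells, medium, field, scene) for _ in range(2)]
        assert np.array_equal(out[0][0], out[1][0])

    def test_close_pair_flagged_overlapping(self):
        scene = SceneSpec(width_px=100, height_px=100, n_frames=1, noise_sigma=0)
        s = scene.pixel_scale_um
        trs = [
            syn.GroundTruthTrack(cell_id=i, times_s=[0.0],
                                 positions_um=[[(40 + 8 * i) * s, 50 * s]],
                                 drift_velocity_um_per_s=0.0)
            for i in range(2)  # 8 px apart < one disk diameter
        ]
        _, truth = syn.render_frames(trs, scene)
        assert truth["overlapping"].all()
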