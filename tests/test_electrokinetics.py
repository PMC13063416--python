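"""Force-balance inversion, field arithmetic and population statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from cellcharge import electrokinetics as ek
from cellcharge import synthetic as syn
from cellcharge.types import ChargeEstimate, FieldSchedule, MediumConditions, SceneSpec


class TestFieldStrength:
    def test_ohms_law_unit_conversion(self):
        # I = 5e-7 A, sigma = 13.37 uS/cm = 1.337e-3 S/m, A = 2e-6 m^2
        E = ek.field_strength(5e-7, 1.337e-3, 2e-6)
        assert E == pytest.approx(187.0, abs=0.1)

    def test_zero_current_zero_field(self):
        assert ek.field_strength(0.0, 1.337e-3, 2e-6) == 0.0

    def test_linearity_in_current(self):
        E1 = ek.field_strength(5e-7, 1.337e-3, 2e-6)
        assert ek.field_strength(1e-6, 1.337e-3, 2e-6) == pytest.approx(2 * E1)

    def test_nonpositive_conductivity_or_area_rejected(self):
        with pytest.raises(ValueError):
            ek.field_strength(5e-7, 0.0, 2e-6)
        with pytest.raises(ValueError):
            ek.field_strength(5e-7, 1.337e-3, -1e-6)


class TestChargeFromVelocity:
    def test_worked_inversion_arithmetic(self):
        # |v| = 6.29 um/s at 380 V/m -> |q| = 1.56e-16 C
        q = ek.charge_from_velocity(-6.29e-6, 380.0)
        assert q == pytest.approx(-1.56e-16, rel=1e-3)

    def test_zero_velocity_zero_charge(self):
        assert ek.charge_from_velocity(0.0, 380.0) == 0.0

    def test_field_off_inversion_is_explicit_error(self):
        with pytest.raises(ZeroDivisionError):
            ek.charge_from_velocity(1e-6, 0.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.floats(min_value=1e-18, max_value=2e-16),
        st.sampled_from([190.0, 380.0, 1200.0]),
    )
    def test_round_trip_is_exact(self, q_mag, E):
        for q in (q_mag, -q_mag):
            v = syn.drift_velocity_um_per_s(q, E, 1e-3, 5e-7) * 1e-6
            assert ek.charge_from_velocity(v, E) == pytest.approx(q, rel=1e-12)

    def test_antisymmetry(self):
        q_pos = ek.charge_from_velocity(3.1e-6, 380.0)
        q_neg = ek.charge_from_velocity(-3.1e-6, 380.0)
        assert q_pos == -q_neg and q_pos > 0


class TestNoiseFloor:
    def test_predicted_noise_floor_value(self):
        se = ek.charge_noise_floor(50, 0.16, 0.2, 380.0)
        assert se == pytest.approx(4.4e-18, rel=0.02)

    def test_empirical_scatter_matches_prediction(self):
        # 200 simulated cells, fixed q, K = 50 steps: sd(q_hat) within 1.3x
        scene = SceneSpec(width_px=3000, height_px=3000, n_frames=51, noise_sigma=0)
        medium = MediumConditions(diffusion_um2_per_s=0.16)
        field = FieldSchedule(E_V_per_m=380.0)
        cells = syn.sample_charge_population(
            200, {"family": "fixed", "params": {"q_C": -5e-17}}, seed=0
        )
        cells = syn.place_cells(cells, scene, min_separation_px=0.0, seed=1,
                                y_band_px=(1500, 2800))
        gt = syn.simulate_trajectories(cells, medium, field, scene,
                                       seed=np.random.default_rng(2))
        tracks = syn.as_tracks(gt, scene)
        q_hat = [
            ek.charge_from_velocity(
                np.mean(np.diff(np.array(t.centroids_px)[:, 1]))
                * scene.pixel_scale_um / scene.frame_interval_s * 1e-6,
                380.0,
            )
            for t in tracks if len(t) == 51
        ]
        predicted = ek.charge_noise_floor(50, 0.16, 0.2, 380.0)
        assert np.std(q_hat, ddof=1) < 1.3 * predicted
        assert np.std(q_hat, ddof=1) > predicted / 1.3


class TestScaleCovariance:
    def test_charge_invariant_to_imaging_calibration(self):
        # same physical motion sampled at two pixel scales / frame intervals
        from cellcharge import kinematics as km
        from tests.conftest import make_track

        rng = np.random.default_rng(9)
        steps_um = rng.normal(0, 0.25, (60, 2)) + [0.0, -1.2]
        pts_um = np.vstack([[50, 400], np.cumsum(steps_um, axis=0) + [50, 400]])
        qs = []
        for scale in (0.093, 0.2):
            tr = make_track(pts_um / scale)
            v = km.axis_projected_velocity(tr, (0, 1), scale, 0.2)
            qs.append(ek.charge_from_velocity(v * 1e-6, 380.0))
        assert qs[0] == pytest.approx(qs[1], rel=1e-12)


def _estimates(qs, level=None):
    return [
        ChargeEstimate(track_id=i, mean_axis_vel_um_s=0.0, q_C=q, E_V_per_m=380.0,
                       viscosity_Pa_s=1e-3, radius_m=5e-7, field_level=level)
        for i, q in enumerate(qs)
    ]


class TestFieldIndependence:
    def test_null_population_uncorrelated(self):
        rng = np.random.default_rng(1)
        ests = []
        for E in (190.0, 380.0, 760.0, 1200.0):
            ests += _estimates(-2e-17 + rng.normal(0, 2e-18, 50), level=E)
        out = ek.field_independence_test(ests)
        assert out["p_value"] > 0.05

    def test_planted_proportionality_detected(self):
        rng = np.random.default_rng(2)
        ests = []
        for E in (190.0, 380.0, 760.0, 1200.0):
            ests += _estimates(-1e-19 * E + rng.normal(0, 2e-18, 50), level=E)
        assert ek.field_independence_test(ests)["p_value"] < 0.001

    def test_identical_sets_per_level_give_zero_r(self):
        ests = _estimates([-1e-17, -2e-17, -3e-17], level=190.0)
        ests += _estimates([-1e-17, -2e-17, -3e-17], level=380.0)
        assert ek.field_independence_test(ests)["pearson_r"] == pytest.approx(0.0, abs=1e-12)

    def test_constant_charges_are_an_error(self):
        ests = _estimates([-2e-17] * 3, level=190.0) + _estimates([-2e-17] * 3, level=380.0)
        with pytest.raises(ValueError):
            ek.field_independence_test(ests)


class TestCompareGroups:
    def test_identical_groups_null(self):
        g = [-1e-17, -2e-17, -3e-17, -4e-17]
        out = ek.compare_groups({"L": g, "E": g, "S": g})
        assert out["anova_F"] == pytest.approx(0.0, abs=1e-12)
        assert out["anova_p"] > 0.99

    def test_two_well_separated_groups(self):
        # 10-sd separation: closed-form two-sample t ~ astronomically significant
        rng = np.random.default_rng(3)
        a = rng.normal(0.0, 1.0, 40)
        b = rng.normal(10.0, 1.0, 40)
        out = ek.compare_groups({"a": a, "b": b})
        assert out["anova_p"] < 1e-6
        t, p = stats.ttest_ind(a, b, equal_var=False)  # oracle: single-pair case
        assert out["pairwise_p"]["a vs b"] == pytest.approx(min(1.0, p), rel=1e-9)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            ek.compare_groups({"a": [1.0, 2.0], "b": [1.0, 2.0, 3.0]})


class TestIsoelectricScan:
    def test_interpolated_crossing(self):
        out = ek.isoelectric_scan({3.0: [1e-18], 5.0: [-1e-17]})
        assert out["iep_interval"] == (3.0, 5.0)
        assert out["iep_pH"] == pytest.approx(3.0 + 2.0 * (1e-18 / 1.1e-17), rel=1e-9)

    def test_no_sign_change_reports_none(self):
        out = ek.isoelectric_scan({5.0: [-1e-17], 7.0: [-3e-17]})
        assert out["iep_interval"] is None and out["iep_pH"] is None

    def test_planted_crossing_at_ph4(self):
        # mean charge linear in pH, zero at exactly 4.0, on a 0.5-wide grid
        phs = np.arange(3.0, 6.5, 0.5)
        rng = np.random.default_rng(8)
        groups = {
            float(ph): (4.0 - ph) * 1e-17 + rng.normal(0, 1e-20, 30) for ph in phs
        }
        out = ek.isoelectric_scan(groups)
        assert out["iep_pH"] == pytest.approx(4.0, abs=0.5)

    def test_single_level_rejected(self):
        with pytest.raises(ValueError):
            ek.isoelectric_scan({7.0: [-1e-17]})
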