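"""Wing-plane fits, trailing-edge deflections, mid-stroke extraction,
allometry and the chord-corrected stiffness proxy."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from scarabwing.bending import flexural_stiffness
from scarabwing.deformation import (
    deflection_series,
    fit_allometry,
    fit_wing_plane,
    midstroke_values,
    spanwise_profile,
    stiffness_proxy,
    te_deflection,
)
from scarabwing.kinematics import wing_angles
from scarabwing.simulate import (
    FlightSimParams,
    simulate_allometry,
    simulate_bending,
    simulate_flight,
)


class TestWingPlane:
    def test_normal_follows_motion_direction(self):
        wb, mj, wt = [0, 0, 0], [1, 0, 0], [0, 1, 0]
        up = fit_wing_plane(wb, mj, wt, [0, 0, 1])
        down = fit_wing_plane(wb, mj, wt, [0, 0, -1])
        np.testing.assert_allclose(up.unit_normal, [0, 0, 1], atol=1e-14)
        np.testing.assert_allclose(down.unit_normal, [0, 0, -1], atol=1e-14)

    def test_collinear_points_rejected(self):
        with pytest.raises(ValueError, match="collinear"):
            fit_wing_plane([0, 0, 0], [1, 0, 0], [2, 0, 0], [0, 0, 1])

    def test_zero_motion_rejected(self):
        with pytest.raises(ValueError, match="motion"):
            fit_wing_plane([0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 0])


class TestTeDeflection:
    def test_point_in_plane_and_offset_point(self):
        plane = fit_wing_plane([0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1])
        pts = {
            "RP": np.array([0.3, 0.3, 0.0]),
            "MP": np.array([0.2, 0.5, 1.0]),
            "CuA": np.array([0.1, 0.4, 0.0]),
            "AA": np.array([0.1, 0.2, 0.0]),
        }
        d = te_deflection(plane, pts, R=20.0)
        assert d["RP"] == pytest.approx(0.0, abs=1e-14)
        assert d["MP"] == pytest.approx(1.0 / 20.0, rel=1e-12)

    def test_missing_landmark_rejected(self):
        plane = fit_wing_plane([0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1])
        with pytest.raises(ValueError, match="AA"):
            te_deflection(plane, {"RP": np.zeros(3)}, R=20.0)

    @given(st.integers(0, 2**31 - 1))
    def test_rigid_motion_invariance(self, seed):
        rng = np.random.default_rng(seed)
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        w, x, y, z = q
        Q = np.array(
            [
                [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
                [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
                [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
            ]
        )
        shift = rng.normal(scale=10, size=3)
        wb, mj, wt = rng.normal(size=(3, 3))
        motion = rng.normal(size=3)
        te = {l: rng.normal(size=3) for l in ("RP", "MP", "CuA", "AA")}
        d0 = te_deflection(fit_wing_plane(wb, mj, wt, motion), te, R=20.0)
        d1 = te_deflection(
            fit_wing_plane(Q @ wb + shift, Q @ mj + shift, Q @ wt + shift, Q @ motion),
            {l: Q @ p + shift for l, p in te.items()},
            R=20.0,
        )
        for l in d0:
            assert d0[l] == pytest.approx(d1[l], abs=1e-10)


class TestMidstroke:
    def test_commanded_amplitudes_recovered_exactly(self):
        params = FlightSimParams(frequency_f=100.0, seed=0)
        rec = simulate_flight(params)
        kin = wing_angles(rec)
        defl = deflection_series(rec, R=params.wing_length_R)
        down, up = midstroke_values(kin, defl)
        for l, amp in params.te_deflection_amplitudes.items():
            assert down[l] == pytest.approx(amp, abs=1e-10)
            assert up[l] == pytest.approx(amp, abs=1e-10)

    def test_rigid_wing_all_zero(self):
        params = FlightSimParams(
            frequency_f=100.0,
            te_deflection_amplitudes={l: 0.0 for l in ("RP", "MP", "CuA", "AA")},
        )
        rec = simulate_flight(params)
        kin = wing_angles(rec)
        down, up = midstroke_values(kin, deflection_series(rec, R=params.wing_length_R))
        for l in down:
            assert abs(down[l]) < 1e-10 and abs(up[l]) < 1e-10

    def test_periodic_signal_gives_consistent_cycles(self):
        params = FlightSimParams(frequency_f=100.0, n_cycles=3, seed=0)
        rec = simulate_flight(params)
        kin = wing_angles(rec)
        defl = deflection_series(rec, R=params.wing_length_R)
        # values at each down-stroke crossing agree: recompute per half-stroke
        down, up = midstroke_values(kin, defl)
        assert down["CuA"] == pytest.approx(up["CuA"], abs=1e-9)

    def test_monotone_angle_rejected(self):
        params = FlightSimParams(frequency_f=100.0, seed=0)
        rec = simulate_flight(params)
        kin = wing_angles(rec)
        defl = deflection_series(rec, R=params.wing_length_R)
        kin2 = kin
        kin2.flapping = np.linspace(0, 60, kin.flapping.size)
        with pytest.raises(ValueError):
            midstroke_values(kin2, defl)


class TestSpanwiseProfile:
    def test_flat_input_flat_curve(self):
        f = spanwise_profile([0.1, 0.1, 0.1, 0.1], [0.25, 0.45, 0.65, 0.85])
        assert np.allclose(f(np.linspace(0.25, 0.85, 50)), 0.1)

    def test_interpolates_landmarks_exactly(self):
        r = np.array([0.25, 0.45, 0.65, 0.85])
        v = np.array([0.1, 0.12, 0.09, 0.05])
        f = spanwise_profile(v, r)
        np.testing.assert_allclose(f(r), v, atol=1e-14)

    def test_linear_input_linear_curve(self):
        r = np.array([0.2, 0.4, 0.6, 0.8])
        v = 0.05 + 0.1 * r
        f = spanwise_profile(v, r)
        x = np.linspace(0.2, 0.8, 100)
        np.testing.assert_allclose(f(x), 0.05 + 0.1 * x, atol=1e-12)

    def test_duplicate_positions_rejected(self):
        with pytest.raises(ValueError, match="duplicated"):
            spanwise_profile([1, 2, 3], [0.2, 0.2, 0.6])


class TestAllometry:
    def test_noise_free_round_trip(self):
        tbl = simulate_allometry(a=0.038, b=0.43, n=34, log_noise_sigma=0.0)
        fit = fit_allometry(tbl["Fv_N"], tbl["beta"])
        assert fit.coefficient_a == pytest.approx(0.038, abs=1e-10)
        assert fit.exponent_b == pytest.approx(0.43, abs=1e-10)
        assert fit.ci95_b[0] <= fit.exponent_b <= fit.ci95_b[1]

    def test_constant_deflection_zero_exponent(self):
        Fv = np.geomspace(0.002, 0.009, 10)
        fit = fit_allometry(Fv, np.full(10, 0.05))
        assert fit.exponent_b == pytest.approx(0.0, abs=1e-12)

    def test_noisy_exponent_within_sampling_error(self):
        tbl = simulate_allometry(a=0.038, b=0.43, n=1000, log_noise_sigma=0.1, seed=0)
        fit = fit_allometry(tbl["Fv_N"], tbl["beta"])
        se = (fit.ci95_b[1] - fit.ci95_b[0]) / (2 * 1.96)
        assert abs(fit.exponent_b - 0.43) < 3 * se

    def test_nonpositive_values_rejected(self):
        with pytest.raises(ValueError, match="log transform"):
            fit_allometry([0.1, -0.2, 0.3], [1, 2, 3])


class TestStiffnessProxy:
    def test_arithmetic_and_cubic_scaling(self):
        assert stiffness_proxy(2.0, 4.0) == 2.0
        assert stiffness_proxy(4.0, 4.0) == 8 * stiffness_proxy(2.0, 4.0)

    def test_undeflected_rejected(self):
        with pytest.raises(ValueError):
            stiffness_proxy(2.0, 0.0)

    def test_proxy_ratio_tracks_EI_ratio_under_equal_load(self):
        # two wings, EI ratio 3:1, equal applied force: deflections from the
        # cantilever forward model, proxies recover the stiffness ratio
        EI_a, EI_b, l = 3e-8, 1e-8, 8.4e-3
        F = simulate_bending(EI_a, l=l, displacement=1e-3)["force_N"].iloc[0]
        beta_a = F * l**3 / (3 * EI_a)
        beta_b = F * l**3 / (3 * EI_b)
        ratio = stiffness_proxy(l, beta_a) / stiffness_proxy(l, beta_b)
        assert ratio == pytest.approx(3.0, rel=1e-12)
        # consistency: inverting each deflection recovers the EIs
        assert flexural_stiffness(F, l, beta_a) == pytest.approx(EI_a, rel=1e-12)
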