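"""Analytic and numerical checks of the stimulus motion profiles."""

import io

import numpy as np
import pytest

from headingcues import (
    combine_profiles,
    heading_profile,
    peak_kinematics,
    vibration_profile,
)
from headingcues.kinematics import G_CM_S2, profile_to_csv


class TestHeadingProfile:
    def test_standard_stimulus_peaks(self):
        """16 cm over 2 s: peak velocity 16 cm/s, peak acceleration 8*pi cm/s^2."""
        pk = peak_kinematics(heading_profile(16, 2, 0, dt=1e-4))
        assert pk.peak_speed == pytest.approx(16.0, rel=1e-6)
        assert pk.peak_acceleration == pytest.approx(8 * np.pi, rel=1e-6)
        assert round(pk.peak_acceleration) == 25
        assert pk.total_displacement == pytest.approx(16.0, rel=1e-6)

    @pytest.mark.parametrize("d,T", [(16, 2), (8, 2), (16, 1), (5.5, 4)])
    def test_closed_form_peaks(self, d, T):
        """Peak velocity 2d/T and peak acceleration 2*pi*d/T^2 on the numeric grid."""
        pk = peak_kinematics(heading_profile(d, T, 0, dt=T / 20000))
        assert pk.peak_speed == pytest.approx(2 * d / T, rel=1e-3)
        assert pk.peak_acceleration == pytest.approx(2 * np.pi * d / T**2, rel=1e-3)

    def test_starts_at_rest_at_origin(self):
        p = heading_profile(16, 2, 30, dt=1e-3)
        assert p.pos[0] == pytest.approx([0, 0, 0], abs=1e-12)
        assert p.vel[0] == pytest.approx([0, 0, 0], abs=1e-12)

    @pytest.mark.parametrize("angle", [-50, -30, 0, 12.5, 50, 90])
    def test_displacement_direction_matches_heading(self, angle):
        p = heading_profile(16, 2, angle, dt=1e-3)
        dx, dy = p.pos_x[-1], p.pos_y[-1]
        recovered = np.rad2deg(np.arctan2(dx, dy))
        assert recovered == pytest.approx(angle, abs=1e-9)
        assert np.all(p.pos_z == 0)

    def test_angled_displacement_by_numeric_integration(self):
        """At 30 deg the 16 cm path splits 8.0 / 13.856 cm onto sway/surge."""
        p = heading_profile(16, 2, 30, dt=1e-4)
        assert p.pos_x[-1] == pytest.approx(16 * np.sin(np.deg2rad(30)), abs=1e-6)
        assert p.pos_y[-1] == pytest.approx(13.856, abs=1e-3)
        # independent check: trapezoid-integrate the acceleration trace twice
        vx = np.concatenate([[0], np.cumsum((p.acc_x[1:] + p.acc_x[:-1]) / 2) * 1e-4])
        x = np.concatenate([[0], np.cumsum((vx[1:] + vx[:-1]) / 2) * 1e-4])
        assert x[-1] == pytest.approx(8.0, abs=1e-3)

    def test_derivative_consistency(self):
        """pos/vel/acc agree under numerical differentiation within 2*dt*max|jerk|."""
        dt = 1e-3
        p = heading_profile(16, 2, 0, dt=dt)
        max_jerk = (2 * np.pi * 16 / 4) * (2 * np.pi / 2)  # A * omega
        tol = 2 * dt * max_jerk
        assert np.abs(np.gradient(p.pos_y, dt) - p.vel_y).max() <= tol
        assert np.abs(np.gradient(p.vel_y, dt) - p.acc_y).max() <= tol

    def test_zero_displacement_gives_zero_profile(self):
        p = heading_profile(0, 2, 30, dt=1e-3)
        assert not np.any(p.pos) and not np.any(p.vel) and not np.any(p.acc)

    def test_linearity_in_displacement(self):
        pk1 = peak_kinematics(heading_profile(8, 2, 0, dt=1e-4))
        pk2 = peak_kinematics(heading_profile(16, 2, 0, dt=1e-4))
        assert pk1.peak_speed == pytest.approx(8.0, rel=1e-3)
        assert 2 * pk1.peak_speed == pytest.approx(pk2.peak_speed, rel=1e-9)
        assert 2 * pk1.peak_acceleration == pytest.approx(pk2.peak_acceleration, rel=1e-9)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(displacement=-1, duration=2, heading_angle=0),
            dict(displacement=16, duration=-2, heading_angle=0),
            dict(displacement=16, duration=2, heading_angle=0, dt=0.3),
            dict(displacement=16, duration=2, heading_angle=95),
        ],
    )
    def test_invalid_arguments(self, kwargs):
        with pytest.raises(ValueError):
            heading_profile(**kwargs)


class TestVibrationProfile:
    def test_printed_platform_values(self):
        """0.20 cm p2p at 6 Hz: peak velocity 3.77 cm/s, peak acceleration 0.145 g."""
        pk = peak_kinematics(vibration_profile(0.20, 6, 2, dt=1e-5))
        assert float(f"{pk.peak_speed:.3g}") == 3.77
        assert float(f"{pk.peak_acceleration / G_CM_S2:.3g}") == 0.145

    @pytest.mark.parametrize("a,f", [(0.10, 6), (0.15, 6), (0.20, 6), (0.3, 2)])
    def test_closed_form_peaks(self, a, f):
        pk = peak_kinematics(vibration_profile(a, f, 2, dt=1e-5))
        assert pk.peak_speed == pytest.approx(np.pi * f * a, rel=1e-3)
        assert pk.peak_acceleration == pytest.approx(2 * np.pi**2 * f**2 * a, rel=1e-3)

    def test_zero_amplitude_is_zero_profile(self):
        p = vibration_profile(0.0, 6, 2, dt=1e-3)
        assert not np.any(p.pos) and not np.any(p.vel) and not np.any(p.acc)

    def test_planar_axes_silent(self):
        p = vibration_profile(0.2, 6, 2, dt=1e-3)
        assert not np.any(p.pos_x) and not np.any(p.pos_y)

    def test_negative_amplitude_rejected(self):
        with pytest.raises(ValueError):
            vibration_profile(-0.1, 6, 2)


class TestCombineProfiles:
    def test_additive_identities(self):
        h = heading_profile(16, 2, 20, dt=1e-3)
        z = vibration_profile(0.0, 6, 2, dt=1e-3)
        c = combine_profiles(h, z)
        assert np.array_equal(c.pos, h.pos) and np.array_equal(c.acc, h.acc)
        zero_h = heading_profile(0, 2, 0, dt=1e-3)
        v = vibration_profile(0.2, 6, 2, dt=1e-3)
        c2 = combine_profiles(zero_h, v)
        assert np.array_equal(c2.pos, v.pos)

    def test_heave_peak_unchanged_by_superposition(self):
        """Axes are orthogonal: the combined z peak acceleration stays 0.145 g."""
        h = heading_profile(16, 2, 0, dt=1e-5)
        v = vibration_profile(0.20, 6, 2, dt=1e-5)
        pk = peak_kinematics(combine_profiles(h, v))
        assert float(f"{pk.per_axis_peak_acc['z'] / G_CM_S2:.3g}") == 0.145

    def test_heading_angle_inherited(self):
        h = heading_profile(16, 2, 35, dt=1e-3)
        v = vibration_profile(0.2, 6, 2, dt=1e-3)
        assert combine_profiles(h, v).heading_angle == 35

    def test_mismatched_grids_rejected(self):
        h = heading_profile(16, 2, 0, dt=1e-3)
        v = vibration_profile(0.2, 6, 2, dt=2e-3)
        with pytest.raises(ValueError):
            combine_profiles(h, v)


def test_csv_export_round_trip():
    p = heading_profile(16, 2, 30, dt=0.1)
    buf = io.StringIO()
    profile_to_csv(p, buf)
    text = buf.getvalue()
    assert text.startswith("# units:")
    body = np.loadtxt(io.StringIO(text), delimiter=",", skiprows=2)
    assert body.shape == (p.t.size, 10)
    np.testing.assert_allclose(body[:, 1], p.pos_x, rtol=1e-9)
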