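"""Force-motion model primitives against closed forms and numerical oracles."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from fesfatigue.dynamics import (ACC_DEG_S2_TO_DEG_MS2, angular_acceleration,
                                 cn_rate, cn_series, force_length_A,
                                 force_rate, force_velocity_G,
                                 lambda_from_rest_angle, pulse_gain,
                                 ri_sequence, stim_force_from_dyno)


class TestPulseGain:
    def test_first_pulse_is_unity(self):
        assert pulse_gain(0.0, None) == 1.0

    def test_large_gap_approaches_unity(self):
        assert pulse_gain(1e6, 0.0) == pytest.approx(1.0, abs=1e-12)

    def test_gap_of_one_tauc(self):
        assert pulse_gain(20.0, 0.0, R0=2.0, tauc=20.0) == pytest.approx(
            1.0 + math.exp(-1.0), rel=1e-12)

    def test_non_increasing_times_rejected(self):
        with pytest.raises(ValueError):
            pulse_gain(5.0, 5.0)
        with pytest.raises(ValueError):
            ri_sequence(np.array([0.0, 10.0, 10.0]))


class TestActivation:
    def test_no_pulses_no_drive(self):
        assert cn_rate(5.0, 0.0, np.array([])) == 0.0

    def test_single_pulse_closed_form_peak(self):
        """CN(t) = x·e^{-x} with x = (t-t_i)/tauc; peak e⁻¹ at x = 1, for any
        tauc."""
        for tauc in (10.0, 20.0, 37.5):
            t = np.linspace(0, 10 * tauc, 2001)
            cn = cn_series(t, np.array([0.0]), R0=2.0, tauc=tauc)
            ipeak = int(np.argmax(cn))
            assert cn[ipeak] == pytest.approx(math.exp(-1.0), abs=1e-5)
            assert t[ipeak] == pytest.approx(tauc, rel=2e-2)

    def test_closed_form_matches_ode_integration(self):
        """The superposition solution equals direct integration of the
        activation ODE on a two-pulse train to < 1e-6."""
        pulses = np.array([0.0, 12.5])
        sol = solve_ivp(lambda t, y: [cn_rate(t, y[0], pulses)], (0, 200),
                        [0.0], rtol=1e-10, atol=1e-12, dense_output=True,
                        max_step=1.0)
        t = np.linspace(0.5, 200, 101)
        np.testing.assert_allclose(cn_series(t, pulses),
                                   sol.sol(t)[0], atol=1e-6)

    def test_heaviside_gating(self):
        """Pulses later than t contribute nothing to the rate or the state."""
        pulses = np.array([0.0, 50.0])
        cn_before = cn_series(np.array([49.9]), pulses)[0]
        cn_single = cn_series(np.array([49.9]), pulses[:1])[0]
        assert cn_before == pytest.approx(cn_single, rel=1e-12)


class TestForceLength:
    def test_bracket_is_unity_at_90(self):
        assert force_length_A(90.0, 2.10, -4.49e-4, 3.44e-2) == pytest.approx(2.10)

    def test_representative_values_at_40deg(self):
        A = force_length_A(40.0, 2.10, -4.49e-4, 3.44e-2)
        assert A == pytest.approx(2.10 * 1.5975, rel=1e-6)
        assert A == pytest.approx(3.3548, abs=2e-4)

    def test_flat_shape_when_coefficients_vanish(self):
        for theta in (0.0, 45.0, 120.0):
            assert force_length_A(theta, 2.10, 0.0, 0.0) == 2.10


class TestForceVelocity:
    @pytest.mark.parametrize("theta, omega", [(50.0, 0.0), (0.0, -0.3)])
    def test_vanishes_at_zero_velocity_or_angle(self, theta, omega):
        assert force_velocity_G(theta, omega, 0.371, 0.0229) == 0.0

    def test_negative_during_extension(self):
        G = force_velocity_G(50.0, -0.2, 0.371, 0.0229)
        assert G == pytest.approx(-1.181, abs=1e-3)
        assert G < 0


class TestForceRate:
    def test_pure_decay_without_activation(self):
        assert force_rate(0.0, 12.0, 3.0, 0.0, 0.35, 36.1, 52.1) == pytest.approx(
            -12.0 / 36.1)

    def test_saturation_limit(self):
        """CN >> Km: the Michaelis-Menten factor saturates at 1."""
        r = force_rate(1e9, 10.0, 3.0, 0.5, 0.35, 36.1, 52.1)
        assert r == pytest.approx((3.0 + 0.5) - 10.0 / (36.1 + 52.1), rel=1e-6)

    def test_steady_state_at_cn_equal_km(self):
        """At CN = Km the factor is 1/2: F_ss = (G+A)/2 · (tau1 + tau2/2)."""
        A, G, Km, tau1, tau2 = 3.0, 0.0, 0.35, 36.1, 52.1
        F_ss = (G + A) / 2 * (tau1 + tau2 / 2)
        assert force_rate(Km, F_ss, A, G, Km, tau1, tau2) == pytest.approx(0.0,
                                                                           abs=1e-12)


class TestAngularAcceleration:
    def test_equilibrium_when_force_balances_gravity(self):
        F = (44.5 + 247.5) * math.cos(math.radians(60.0))
        assert angular_acceleration(55.0, F, 44.5, 247.5, 5.0, 9.85) == pytest.approx(0.0)

    def test_zero_at_rest_angle_construction(self):
        """With lam = 90 − theta_rest the unstimulated resting leg has zero
        angular acceleration."""
        for theta_rest in (80.0, 85.0, 90.0):
            lam = lambda_from_rest_angle(theta_rest)
            assert angular_acceleration(theta_rest, 0.0, 44.5, 247.5, lam,
                                        9.85) == pytest.approx(0.0, abs=1e-12)

    def test_pre_mapping_product(self):
        """L/I = 9.85, net torque-equivalent 292·cos60° − 0: the raw product
        is 1438.1 before the deg/s² → deg/ms² mapping."""
        acc = angular_acceleration(55.0, 0.0, 44.5, 247.5, 5.0, 9.85,
                                   unit="deg_per_s2")
        assert acc == pytest.approx(9.85 * (292.0 * 0.5), rel=1e-3)
        assert angular_acceleration(55.0, 0.0, 44.5, 247.5, 5.0, 9.85) == \
            pytest.approx(acc * ACC_DEG_S2_TO_DEG_MS2, rel=1e-12)


class TestIsovelocityForceExtraction:
    def test_no_correction_at_90deg(self):
        assert stim_force_from_dyno(50.0, 90.0, 86.3) == pytest.approx(50.0)

    def test_full_correction_at_zero(self):
        assert stim_force_from_dyno(0.0, 0.0, 100.0) == pytest.approx(100.0)

    def test_representative_correction(self):
        assert stim_force_from_dyno(50.0, 60.0, 86.3) == pytest.approx(93.15)


class TestLambda:
    @pytest.mark.parametrize("rest, lam", [(90.0, 0.0), (85.0, 5.0)])
    def test_values(self, rest, lam):
        assert lambda_from_rest_angle(rest) == lam

    @pytest.mark.parametrize("rest", [0.0, -5.0, 120.0, 150.0])
    def test_out_of_range(self, rest):
        with pytest.raises(ValueError):
            lambda_from_rest_angle(rest)
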