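"""Fatigue ODE rates, recovery behavior, and the betaTau1 predictor."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from fesfatigue.fatigue import beta_tau1_from_params, fatigue_rates, km_total


def baseline_state(fat):
    return np.array([fat.A90_0, fat.Km1_0, 0.0, fat.tau1_0])


class TestFatigueRates:
    def test_zero_at_baseline_without_force(self, fat_default):
        rates = fatigue_rates(baseline_state(fat_default), 0.0, 0.0, fat_default)
        np.testing.assert_allclose(rates, 0.0)

    def test_isometric_reduction_drops_velocity_terms(self, fat_default):
        """With omega = 0 the tau1 rate uses alphaTau1 alone, and the legacy
        betaA/betaKm terms change nothing."""
        state = baseline_state(fat_default)
        r_simplified = fatigue_rates(state, 50.0, 0.0, fat_default)
        legacy = fat_default.replace(betaA=1e-5, betaKm=1e-6)
        r_legacy = fatigue_rates(state, 50.0, 0.0, legacy, legacy_betas=True)
        np.testing.assert_array_equal(r_simplified, r_legacy)
        assert r_simplified[3] == pytest.approx(fat_default.alphaTau1 * 50.0)

    def test_steady_state_offsets(self, fat_default):
        """Constant F, omega = 0: A90_ss = A90_0 + tauFat·alphaA·F
        (1.299 with the representative parameters and F = 20 N)."""
        F = 20.0
        A90_ss = fat_default.A90_0 + fat_default.tauFat_ms * fat_default.alphaA * F
        assert A90_ss == pytest.approx(1.2988, abs=2e-4)
        state = np.array([A90_ss,
                          fat_default.Km1_0 + fat_default.tauFat_ms
                          * fat_default.alphaKm * F,
                          0.123,  # Km2 has no restoring term
                          fat_default.tau1_0 + fat_default.tauFat_ms
                          * fat_default.alphaTau1 * F])
        rates = fatigue_rates(state, F, 0.0, fat_default)
        np.testing.assert_allclose(rates[[0, 1, 3]], 0.0, atol=1e-15)
        assert rates[2] == pytest.approx(-fat_default.alphaKm * F)

    def test_beta_term_counteracts_alpha_during_extension(self, fat_default):
        """For omega < 0 and alphaTau1, betaTau1 > 0 the velocity coupling
        opposes alphaTau1, reducing the net fatigue push on tau1 for
        extension velocities below the crossover 2·alphaTau1/betaTau1
        (beyond it the coupling overshoots and tau1 is pushed *below*
        baseline — this subject's betaTau1 is larger than average)."""
        state = baseline_state(fat_default)
        push_iso = fatigue_rates(state, 80.0, 0.0, fat_default)[3]
        crossover = 2 * fat_default.alphaTau1 / fat_default.betaTau1
        for omega in (-0.2 * crossover, -0.8 * crossover):
            push_free = fatigue_rates(state, 80.0, omega, fat_default)[3]
            assert abs(push_free) < abs(push_iso)
        # beyond the crossover the push reverses sign but still opposes the
        # isometric direction
        overshoot = fatigue_rates(state, 80.0, -0.2, fat_default)[3]
        assert overshoot < 0 < push_iso


class TestKmTotal:
    def test_sum(self):
        assert km_total((0.0, 0.3, 0.0, 0.0)) == 0.3
        assert km_total((0.0, 0.3, 0.2, 0.0)) == 0.5

    def test_km_monotone_under_constant_force(self, fat_default):
        """With alphaKm < 0 the total Km never decreases under load: the Km2
        secular term dominates the Km1 decline."""
        def rhs(t, y):
            return fatigue_rates(y, 60.0, 0.0, fat_default)

        sol = solve_ivp(rhs, (0, 600e3), baseline_state(fat_default),
                        rtol=1e-9, atol=1e-12, max_step=5e3)
        km = sol.y[1] + sol.y[2]
        assert np.all(np.diff(km) > -1e-12)


class TestRecovery:
    def test_exponential_relaxation_to_baseline(self, fat_default):
        """After force returns to zero, A90/Km1/tau1 relax to baseline with
        time constant tauFat (Km2 stays put); matches the closed form to
        < 1e-8."""
        y0 = np.array([1.4, 0.30, 0.21, 80.0])
        tf = fat_default.tauFat_ms

        def rhs(t, y):
            return fatigue_rates(y, 0.0, 0.0, fat_default)

        t_eval = np.linspace(0.0, 3 * tf, 7)
        sol = solve_ivp(rhs, (0, t_eval[-1]), y0, rtol=1e-12, atol=1e-14,
                        t_eval=t_eval, max_step=tf / 100)
        decay = np.exp(-t_eval / tf)
        base = [fat_default.A90_0, fat_default.Km1_0, None, fat_default.tau1_0]
        for i, b in enumerate(base):
            if b is None:
                np.testing.assert_allclose(sol.y[i], y0[i], atol=1e-9)
            else:
                expected = b + (y0[i] - b) * decay
                np.testing.assert_allclose(sol.y[i], expected, atol=1e-8)


class TestBetaTau1Predictor:
    def test_regression_pin(self):
        """Direct evaluation with the representative parameter set (frozen
        once; guards against accidental formula edits)."""
        v = beta_tau1_from_params(2.10, 247.5, 36.1, 2.93e-5, 99.4, 0.371)
        assert v == pytest.approx(1.4786272108656354e-07, rel=1e-12)

    def test_vanishes_with_alpha_or_gain(self):
        ref = beta_tau1_from_params(2.10, 247.5, 36.1, 2.93e-5, 99.4, 0.371)
        tiny_alpha = beta_tau1_from_params(2.10, 247.5, 36.1, 2.93e-11, 99.4, 0.371)
        tiny_gain = beta_tau1_from_params(2.10e-6, 247.5, 36.1, 2.93e-5, 99.4, 0.371)
        assert tiny_alpha < 1e-6 * ref
        assert tiny_gain < 1e-6 * ref

    def test_rejects_non_positive_inputs(self):
        with pytest.raises(ValueError):
            beta_tau1_from_params(0.0, 247.5, 36.1, 2.93e-5, 99.4, 0.371)
        with pytest.raises(ValueError):
            beta_tau1_from_params(2.1, 247.5, 36.1, -1e-5, 99.4, 0.371)
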