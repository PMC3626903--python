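"""Optimizer core and individual identification stages on synthetic data."""

import numpy as np
import pytest

from fesfatigue.identify import (IdentificationConfig, PSOOptions, StageError,
                                 fit_isovelocity, fit_parabola_ab,
                                 fit_iso_nonfatigue, pso_then_lsq)
from fesfatigue.synthetic import default_subject, synthesize_session


@pytest.fixture(scope="module")
def quick_cfg():
    return IdentificationConfig(pso=PSOOptions(n_particles=16, n_iter=30),
                                n_restarts=2)


class TestPsoThenLsq:
    def test_quadratic_bowl(self):
        fit = pso_then_lsq(lambda x: np.array([x[0] - 3.0]), ("x",),
                           [-10.0], [10.0], seed=0,
                           pso=PSOOptions(n_particles=10, n_iter=20))
        assert fit.x[0] == pytest.approx(3.0, abs=1e-6)
        assert fit.dispersion < 1e-6

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_rosenbrock(self, seed):
        def resid(x):
            return np.array([10.0 * (x[1] - x[0] ** 2), 1.0 - x[0]])

        fit = pso_then_lsq(resid, ("x", "y"), [-5.0, -5.0], [5.0, 5.0],
                           seed=seed, pso=PSOOptions(n_particles=20, n_iter=60))
        np.testing.assert_allclose(fit.x, [1.0, 1.0], atol=1e-4)

    def test_same_seed_same_result(self):
        def resid(x):
            return np.array([x[0] ** 2 - 2.0, np.sin(x[1])])

        a = pso_then_lsq(resid, ("x", "y"), [-3.0, -3.0], [3.0, 3.0], seed=11)
        b = pso_then_lsq(resid, ("x", "y"), [-3.0, -3.0], [3.0, 3.0], seed=11)
        np.testing.assert_array_equal(a.x, b.x)
        assert a.ssr == b.ssr

    def test_infinite_bounds_rejected(self):
        with pytest.raises(ValueError):
            pso_then_lsq(lambda x: x, ("x",), [-np.inf], [np.inf], seed=0)


class TestParabola:
    def test_exact_inversion_from_generated_values(self):
        a, b, A90 = -4.49e-4, 3.44e-2, 2.10
        angles = [15.0, 40.0, 65.0, 90.0]
        A = {th: A90 * (a * (90 - th) ** 2 + b * (90 - th) + 1) for th in angles}
        out = fit_parabola_ab(A, A90)
        assert out.estimates["a"] == pytest.approx(a, rel=1e-10)
        assert out.estimates["b"] == pytest.approx(b, rel=1e-10)

    def test_flat_profile_gives_zero_coefficients(self):
        out = fit_parabola_ab({15.0: 2.1, 40.0: 2.1, 65.0: 2.1, 90.0: 2.1}, 2.1)
        assert out.estimates["a"] == pytest.approx(0.0, abs=1e-12)
        assert out.estimates["b"] == pytest.approx(0.0, abs=1e-12)

    def test_permutation_invariance(self):
        a, b, A90 = -3.27e-4, 4.21e-2, 1.11
        angles = [90.0, 15.0, 65.0, 40.0]
        A = {th: A90 * (a * (90 - th) ** 2 + b * (90 - th) + 1) for th in angles}
        out = fit_parabola_ab(A, A90)
        assert out.estimates["a"] == pytest.approx(a, rel=1e-8)

    def test_too_few_angles(self):
        with pytest.raises(StageError, match="3"):
            fit_parabola_ab({90.0: 2.1, 40.0: 2.5}, 2.1)


class TestIsoNonFatigueStage:
    def test_noiseless_recovery_within_one_percent(self, quick_cfg):
        subject = default_subject()
        ms = synthesize_session(subject, "iso_nonfatigue", seed=0,
                                noise_force_N=0.0)
        out = fit_iso_nonfatigue(ms, quick_cfg, seed=0)
        assert out.estimates["A90"] == pytest.approx(subject.fm.A90, rel=1e-2)
        assert out.estimates["Km"] == pytest.approx(subject.fm.Km, rel=1e-2)
        assert out.estimates["tau1"] == pytest.approx(subject.fm.tau1, rel=1e-2)
        assert out.estimates["tau2"] == pytest.approx(subject.fm.tau2, rel=1e-2)
        # decay-based initial tau1 is reported and is the right scale
        assert out.extras["tau1_decay"] == pytest.approx(subject.fm.tau1,
                                                         rel=0.15)

    def test_noisy_recovery_within_ten_percent(self, quick_cfg):
        subject = default_subject()
        ms = synthesize_session(subject, "iso_nonfatigue", seed=42,
                                noise_force_N=subject.noise_force_N * 2)
        out = fit_iso_nonfatigue(ms, quick_cfg, seed=1)
        for key, truth in (("A90", subject.fm.A90), ("Km", subject.fm.Km),
                           ("tau1", subject.fm.tau1), ("tau2", subject.fm.tau2)):
            assert out.estimates[key] == pytest.approx(truth, rel=0.10), key


class TestIsovelocityStage:
    def test_noiseless_recovery(self, quick_cfg):
        subject = default_subject()
        ms = synthesize_session(subject, "isovelocity", seed=0,
                                noise_force_N=0.0)
        out = fit_isovelocity(ms, subject.fm, quick_cfg, seed=0)
        assert out.estimates["V1"] == pytest.approx(subject.fm.V1, rel=1e-2)
        assert out.estimates["V2"] == pytest.approx(subject.fm.V2, rel=1e-2)

    def test_stim_equal_passive_gives_zero_force_trace(self, quick_cfg):
        """If the stimulated trial equals the passive trial the extracted
        stimulation force is identically zero."""
        subject = default_subject()
        ms = synthesize_session(subject, "isovelocity", seed=0,
                                noise_force_N=0.0)
        passive = next(tr for tr in ms.traces if tr.role == "passive")
        stim = ms.traces[0]
        np.testing.assert_allclose(
            (passive.values - passive.values) / subject.L_m, 0.0)
        # and the session-level extraction reproduces simulated force
        F = (stim.values - passive.values) / subject.L_m
        assert F.max() > 50.0  # genuine stimulation force present

    def test_missing_passive_trial(self, quick_cfg):
        subject = default_subject()
        ms = synthesize_session(subject, "isovelocity", seed=0)
        ms.traces = [tr for tr in ms.traces if tr.role != "passive"]
        with pytest.raises(StageError, match="passive"):
            fit_isovelocity(ms, subject.fm, quick_cfg, seed=0)
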