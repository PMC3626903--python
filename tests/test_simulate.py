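"""The coupled simulator: grid convergence, oracle equivalence, state policy."""

import math

import numpy as np
import pytest

from fesfatigue.dynamics import cn_series
from fesfatigue.protocol import (make_cft, make_fatigue_protocol, make_vft,
                                 ProtocolEntry, PulseTrain, StimulationProtocol)
from fesfatigue.simulate import (SimulationError, ThetaRamp,
                                 euler_reference_contraction,
                                 extract_testing_pairs, simulate_contraction,
                                 simulate_protocol)


class TestSingleContraction:
    def test_single_pulse_isometric_force_rises_then_decays(self, fm_default):
        train = make_cft(1.0, 500.0)  # one pulse at t = 0
        res = simulate_contraction(train, "isometric", fm_default, dt=0.2,
                                   t_end=600.0)
        assert res.cn.max() == pytest.approx(math.exp(-1.0), abs=1e-4)
        ipeak = int(np.argmax(res.F))
        assert 0 < ipeak < len(res.t) - 1
        assert res.F[-1] < 0.05 * res.F[ipeak]
        assert np.all(res.F >= 0)

    def test_free_swing_without_pulses_is_at_equilibrium(self, fm_default, load_N):
        train = PulseTrain((0.0,), 1.0, "CFT", 1.0)  # single pulse, but we
        # zero the drive by zeroing A and V1 so no force develops
        fm = fm_default.replace(A90=1e-9, V1=0.0)
        res = simulate_contraction(train, "free_swing", fm, dt=0.2,
                                   t_end=1000.0, load_N=load_N)
        np.testing.assert_allclose(res.theta, 85.0, atol=1e-6)
        np.testing.assert_allclose(res.omega, 0.0, atol=1e-9)

    def test_grid_convergence(self, fm_default, load_N):
        """Halving dt changes peak force and minimum angle by < 0.1 %."""
        train = make_cft(50.0, 240.0)
        r1 = simulate_contraction(train, "free_swing", fm_default, dt=0.2,
                                  t_end=1000.0, load_N=load_N)
        r2 = simulate_contraction(train, "free_swing", fm_default, dt=0.1,
                                  t_end=1000.0, load_N=load_N)
        assert r1.F.max() == pytest.approx(r2.F.max(), rel=1e-3)
        assert r1.theta.min() == pytest.approx(r2.theta.min(), rel=1e-3)

    def test_isovelocity_requires_profile(self, fm_default):
        with pytest.raises(ValueError, match="profile"):
            simulate_contraction(make_cft(50, 1000), "isovelocity", fm_default)

    def test_determinism(self, fm_default, fat_default, load_N):
        train = make_vft(12.5, 240.0)
        kw = dict(dt=0.2, t_end=1440.0, load_N=load_N)
        a = simulate_contraction(train, "free_swing", fm_default, fat_default, **kw)
        b = simulate_contraction(train, "free_swing", fm_default, fat_default, **kw)
        np.testing.assert_array_equal(a.Y, b.Y)
        np.testing.assert_array_equal(a.cn, b.cn)

    def test_hyperextension_raises(self, fm_default, load_N):
        """Non-physical parameters (no gravity resistance) drive the knee
        past full extension and must be flagged."""
        bad = fm_default.replace(FM=1e-6, A90=6.0)
        with pytest.raises(SimulationError):
            simulate_contraction(make_cft(50, 1000), "free_swing", bad,
                                 dt=0.2, t_end=1000.0, load_N=0.0)

    def test_fast_cn_equals_closed_form(self, fm_default):
        train = make_vft(12.5, 1000.0)
        res = simulate_contraction(train, "isometric", fm_default, dt=0.2,
                                   t_end=1500.0)
        ref = cn_series(res.t, train.pulse_array(), fm_default.R0,
                        fm_default.tauc)
        np.testing.assert_allclose(res.cn, ref, atol=1e-12)


class TestOracleEquivalence:
    def test_rk4_matches_fine_euler_free_swing(self, fm_default, fat_default,
                                               load_N):
        """Production RK4 (dt = 0.2 ms) vs independent Euler (dt = 0.001 ms)
        agree on force and angle to < 1e-3 relative error."""
        train = make_cft(50.0, 240.0)
        rk4 = simulate_contraction(train, "free_swing", fm_default,
                                   fat_default, dt=0.2, t_end=1440.0,
                                   load_N=load_N)
        T, CN, Y = euler_reference_contraction(
            train, "free_swing", fm_default, fat_default, dt=0.001,
            t_end=1440.0, load_N=load_N, out_stride=500)
        F_rk4 = np.interp(T, rk4.t, rk4.F)
        th_rk4 = np.interp(T, rk4.t, rk4.theta)
        assert np.max(np.abs(F_rk4 - Y[:, 0])) / np.max(np.abs(Y[:, 0])) < 1e-3
        assert np.max(np.abs(th_rk4 - Y[:, 1])) / np.max(np.abs(Y[:, 1])) < 1e-3
        assert np.max(np.abs(np.interp(T, rk4.t, rk4.cn) - CN)) < 1e-3


class TestFreeSwingBehavior:
    def test_oscillates_after_train_without_catch(self, fm_default, load_N):
        """Without the manual-stop emulation the undamped leg oscillates
        about the rest angle after the train ends."""
        train = make_cft(33.0, 240.0)
        res = simulate_contraction(train, "free_swing", fm_default, dt=0.2,
                                   t_end=900.0, load_N=load_N,
                                   catch_at_rest=False, on_clamp="flag")
        tail = res.theta[res.t > 240.0]
        assert tail.min() < 60.0
        assert tail.max() > 86.0  # swings back past the rest angle

    def test_catch_stops_the_returning_leg(self, fm_default, load_N):
        train = make_cft(33.0, 240.0)
        res = simulate_contraction(train, "free_swing", fm_default, dt=0.2,
                                   t_end=1440.0, load_N=load_N)
        assert res.theta[-1] == pytest.approx(85.0)
        assert res.omega[-1] == 0.0
        assert res.theta.max() <= 85.0 + 1e-9


class TestProtocolSimulation:
    def test_fatigue_accumulates_across_isometric_protocol(self, fm_default,
                                                           fat_default):
        protocol = make_fatigue_protocol("isometric", 1000.0,
                                         inter_train_rest=1000.0)
        sim = simulate_protocol(protocol, fm_default, fat_default, dt=0.5,
                                theta_iso=90.0, store_stride=10)
        assert len(sim.records) == 225
        assert sim.A90[-1] < sim.A90[0]
        assert sim.tau1[-1] > sim.tau1[0]
        peaks = [r.peak_force for r in sim.records if r.role == "fatiguing_33CFT"]
        assert peaks[-1] < 0.8 * peaks[0]

    def test_without_fatigue_testing_pairs_repeat_identically(self, fm_default):
        protocol = make_fatigue_protocol("isometric", 300.0,
                                         inter_train_rest=1000.0)
        sim = simulate_protocol(protocol, fm_default, None, dt=0.5,
                                theta_iso=90.0)
        pairs = extract_testing_pairs(sim)
        assert len(pairs) == 15
        first = [sim.F[sim.window(p[0])] for p in pairs][0]
        for p in pairs[1:]:
            f = sim.F[sim.window(p[0])]
            np.testing.assert_allclose(f[:len(first)], first[:len(f)],
                                       atol=1e-12)

    def test_zero_drive_protocol_keeps_fatigue_at_baseline(self, fm_default,
                                                           fat_default):
        fm = fm_default.replace(A90=1e-9, V1=0.0)
        fat = fat_default.replace(A90_0=1e-9)
        protocol = make_fatigue_protocol("isometric", 300.0,
                                         inter_train_rest=500.0)
        sim = simulate_protocol(protocol, fm, fat, dt=0.5, theta_iso=90.0,
                                store_stride=10)
        np.testing.assert_allclose(sim.Km1, fat.Km1_0, rtol=1e-9)
        np.testing.assert_allclose(sim.tau1, fat.tau1_0, rtol=1e-6)

    def test_pair_ordering_matches_block_onsets(self, fm_default):
        protocol = make_fatigue_protocol("isometric", 300.0,
                                         inter_train_rest=500.0)
        sim = simulate_protocol(protocol, fm_default, None, dt=0.5)
        pairs = extract_testing_pairs(sim)
        onsets = [p[0].onset for p in pairs]
        assert onsets == sorted(onsets)
        assert extract_testing_pairs(
            simulate_protocol(StimulationProtocol(
                (ProtocolEntry(make_cft(33, 300.0), 0.0, 500.0,
                               "fatiguing_33CFT"),), "isometric"),
                fm_default, None, dt=0.5)) == []

    def test_cn_and_force_carry_over_short_rests(self, fm_default):
        """With a rest shorter than 5·tauc the activation from the previous
        train persists into the next one."""
        train = make_cft(50.0, 100.0)
        short = StimulationProtocol((
            ProtocolEntry(train, 0.0, 40.0, "fatiguing_33CFT"),
            ProtocolEntry(train, 140.0, 1000.0, "fatiguing_33CFT")),
            "isometric")
        sim = simulate_protocol(short, fm_default, None, dt=0.2)
        rec2 = sim.records[1]
        start = sim.window(rec2).start
        assert sim.cn[start] > 0.1  # carried, not reset
        assert sim.F[start] > 1.0
        # the carried trace must equal one continuous two-train simulation
        both = PulseTrain(tuple(list(train.pulse_times)
                                + [140.0 + t for t in train.pulse_times]),
                          241.0, "CFT", 50.0)
        cont = simulate_contraction(both, "isometric", fm_default, dt=0.2,
                                    t_end=1140.0)
        f_at = np.interp(sim.t[start:], cont.t, cont.F)
        np.testing.assert_allclose(sim.F[start:], f_at, atol=1e-6)

    def test_dataframe_export_columns(self, fm_default):
        protocol = StimulationProtocol(
            (ProtocolEntry(make_cft(50, 200.0), 0.0, 300.0, "testing_50CFT"),),
            "isometric")
        df = simulate_protocol(protocol, fm_default, None, dt=0.5).to_dataframe()
        assert list(df.columns) == ["t_ms", "CN", "F_N", "theta_deg",
                                    "omega_deg_per_ms", "A90", "Km", "tau1",
                                    "train_index", "role"]
        assert np.all(np.diff(df["t_ms"].to_numpy()) > 0)
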