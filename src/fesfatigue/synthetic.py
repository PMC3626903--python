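"""Synthetic subjects and synthetic measurement sessions.

A :class:`SyntheticSubject` is a complete ground-truth parameter set plus the
session constants (train durations, resting angle, moment arm, load).  The
default subject carries the force-motion and fatigue parameters of a
representative able-bodied subject fitted at a 600 μs pulse duration
(A90 = 2.10 N/ms, Km = 0.352, tau1 = 36.1 ms, tau2 = 52.1 ms, tauc = 20 ms,
R0 = 2, a = −4.49e-4 deg⁻², b = 3.44e-2 deg⁻¹, V1 = 0.371 N/deg²,
V2 = 2.29e-2 deg⁻¹, L/I = 9.85 kg⁻¹m⁻¹, FM = 247.5 N; tauFat = 99.4 s,
alphaA = −4.03e-7 ms⁻², alphaKm = −1.36e-8 ms⁻¹N⁻¹, alphaTau1 = 2.93e-5 N⁻¹,
betaTau1 = 8.54e-4 ms·deg⁻¹·N⁻¹).

:func:`synthesize_session` simulates a full testing session (one of the five
session types) with the forward model, samples it at 300 Hz, and adds seeded
additive Gaussian noise on the measured channels (torque or knee angle).
Angular-velocity "measurements" are always *derived* by central differencing
of the (noisy) angle channel downstream, as an experimenter would derive
them — they are never independently noised.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import MeasurementSet, Trace
from .params import FatigueParams, ForceMotionParams
from .protocol import (ROLE_TESTING_50CFT, ROLE_TESTING_VFT, StimulationProtocol,
                       make_cft, make_fatigue_protocol, make_vft)
from .simulate import SimulationResult, ThetaRamp, simulate_contraction, simulate_protocol

__all__ = ["SyntheticSubject", "default_subject", "synthesize_session",
           "SESSION_TYPES", "GRAVITY_M_S2"]

SESSION_TYPES = ("iso_nonfatigue", "isovelocity", "free_nonfatigue",
                 "iso_fatigue", "free_fatigue")

GRAVITY_M_S2 = 9.81

ISO_ANGLES = (15.0, 40.0, 65.0, 90.0)


@dataclass(frozen=True)
class SyntheticSubject:
    """Ground-truth parameters and session constants of one synthetic subject."""

    fm: ForceMotionParams
    fat: FatigueParams
    #: free-swing train duration per pulse-duration label (μs -> ms)
    train_durations_ms: dict = field(default_factory=lambda: {
        170: 640.0, 200: 510.0, 250: 360.0, 400: 290.0, 600: 240.0})
    pulse_duration_us: int = 600
    iso_train_duration_ms: float = 1000.0
    theta_rest: float = 85.0
    L_m: float = 0.40
    load_kg: float = 4.54
    fs_hz: float = 300.0
    noise_force_N: float = 1.0
    noise_angle_deg: float = 0.5

    @property
    def load_N(self) -> float:
        return self.load_kg * GRAVITY_M_S2

    @property
    def free_train_duration_ms(self) -> float:
        return self.train_durations_ms[self.pulse_duration_us]

    def with_noise(self, force_N: float, angle_deg: float) -> "SyntheticSubject":
        return replace(self, noise_force_N=force_N, noise_angle_deg=angle_deg)


def default_subject() -> SyntheticSubject:
    """The representative synthetic subject (600 μs session)."""
    fm = ForceMotionParams(
        A90=2.10, a=-4.49e-4, b=3.44e-2, Km=3.52e-1, tau1=36.1, tau2=52.1,
        V1=3.71e-1, V2=2.29e-2, L_over_I=9.85, FM=247.5, lam=5.0,
        tauc=20.0, R0=2.0)
    fat = FatigueParams(
        alphaA=-4.03e-7, alphaKm=-1.36e-8, alphaTau1=2.93e-5,
        tauFat_ms=99.4e3, betaTau1=8.54e-4,
        A90_0=fm.A90, Km1_0=fm.Km, tau1_0=fm.tau1, tau1_0_iso=fm.tau1,
        beta_source="fitted")
    return SyntheticSubject(fm=fm, fat=fat)


def _sample(t_grid: np.ndarray, values: np.ndarray, fs: float,
            t_end: float) -> tuple[np.ndarray, np.ndarray]:
    st = np.arange(0.0, min(t_end, t_grid[-1]) + 1e-9, 1000.0 / fs)
    return st, np.interp(st, t_grid, values)


def _isovelocity_profile() -> ThetaRamp:
    # dynamometer passive mode: 150 deg/s from ~110° down to ~4°
    return ThetaRamp(theta0=110.0, slope=-0.15, theta_min=4.0)


def synthesize_session(subject: SyntheticSubject, session_type: str,
                       seed: int = 0, dt: float = 0.2,
                       noise_force_N: float | None = None,
                       noise_angle_deg: float | None = None) -> MeasurementSet:
    """Simulate one testing session and return it as a measurement set.

    Noise defaults to the subject's channel standard deviations; pass 0 to
    obtain noiseless measurements (exactly the down-sampled simulation).
    The torque-channel sd is ``noise_force_N × L`` (the noise model is
    specified on the force scale).
    """
    if session_type not in SESSION_TYPES:
        raise ValueError(f"unknown session type {session_type!r}; "
                         f"expected one of {SESSION_TYPES}")
    sd_F = subject.noise_force_N if noise_force_N is None else noise_force_N
    sd_th = subject.noise_angle_deg if noise_angle_deg is None else noise_angle_deg
    rng = np.random.default_rng(seed)
    fm, fat = subject.fm, subject.fat
    L = subject.L_m
    fs = subject.fs_hz
    meta = {
        "L_m": L, "theta_rest_deg": subject.theta_rest,
        "load_kg": subject.load_kg, "fs_hz": fs, "dt_ms": dt, "seed": seed,
        "pulse_duration_us": subject.pulse_duration_us,
        "noise_force_N": sd_F, "noise_angle_deg": sd_th,
    }
    traces: list[Trace] = []

    if session_type == "iso_nonfatigue":
        mode = "isometric"
        dur = subject.iso_train_duration_ms
        pdus = subject.pulse_duration_us
        trains = [make_cft(50.0, dur, pdus), make_vft(12.5, dur, 5.0, pdus)]
        roles = [ROLE_TESTING_50CFT, ROLE_TESTING_VFT]
        onset = 0.0
        idx = 0
        for angle in ISO_ANGLES:
            for _pair in range(2):
                for train, role in zip(trains, roles):
                    res = simulate_contraction(
                        train, mode, fm, None, dt=dt, t_end=dur + 1000.0,
                        theta_iso=angle)
                    st, F = _sample(res.t, res.F, fs, dur + 1000.0)
                    torque = F * L + rng.normal(0.0, sd_F * L, st.size)
                    traces.append(Trace(
                        index=idx, role=role, channel="torque_Nm", mode=mode,
                        onset_ms=onset, fs_hz=fs, t_ms=st, values=torque,
                        train_spec=train.spec(), rest_after_ms=10_000.0,
                        angle_deg=angle))
                    idx += 1
                    onset += dur + 10_000.0

    elif session_type == "isovelocity":
        mode = "isovelocity"
        dur = subject.iso_train_duration_ms
        pdus = subject.pulse_duration_us
        prof = _isovelocity_profile()
        meta["profile"] = {"theta0_deg": prof.theta0,
                           "slope_deg_per_ms": prof.slope,
                           "theta_min_deg": prof.theta_min}
        trains = [make_cft(50.0, dur, pdus), make_vft(12.5, dur, 5.0, pdus)]
        roles = [ROLE_TESTING_50CFT, ROLE_TESTING_VFT]
        t_end = 1000.0
        costh = None
        onset = 0.0
        idx = 0
        for _pair in range(2):
            for train, role in zip(trains, roles):
                res = simulate_contraction(
                    train, mode, fm, None, dt=dt, t_end=t_end, profile=prof)
                st, F = _sample(res.t, res.F, fs, t_end)
                th = prof.theta(st)
                torque = (F - fm.FM * np.cos(np.deg2rad(th))) * L
                torque = torque + rng.normal(0.0, sd_F * L, st.size)
                traces.append(Trace(
                    index=idx, role=role, channel="torque_Nm", mode=mode,
                    onset_ms=onset, fs_hz=fs, t_ms=st, values=torque,
                    train_spec=train.spec(), rest_after_ms=10_000.0))
                idx += 1
                onset += t_end + 10_000.0
        # passive trial: dynamometer extends the relaxed leg (no stimulation)
        st = np.arange(0.0, t_end + 1e-9, 1000.0 / fs)
        th = prof.theta(st)
        passive = -fm.FM * np.cos(np.deg2rad(th)) * L
        passive = passive + rng.normal(0.0, sd_F * L, st.size)
        traces.append(Trace(
            index=idx, role="passive", channel="torque_Nm", mode=mode,
            onset_ms=onset, fs_hz=fs, t_ms=st, values=passive,
            train_spec=None, rest_after_ms=10_000.0))

    elif session_type == "free_nonfatigue":
        mode = "free_swing"
        dur = subject.free_train_duration_ms
        pdus = subject.pulse_duration_us
        trains = [make_cft(50.0, dur, pdus), make_vft(12.5, dur, 5.0, pdus)]
        roles = [ROLE_TESTING_50CFT, ROLE_TESTING_VFT]
        t_end = dur + 1200.0
        onset = 0.0
        idx = 0
        for _pair in range(2):
            for train, role in zip(trains, roles):
                res = simulate_contraction(
                    train, mode, fm, None, dt=dt, t_end=t_end,
                    theta_rest=subject.theta_rest, load_N=subject.load_N)
                st, th = _sample(res.t, res.theta, fs, t_end)
                th = th + rng.normal(0.0, sd_th, st.size)
                traces.append(Trace(
                    index=idx, role=role, channel="theta_deg", mode=mode,
                    onset_ms=onset, fs_hz=fs, t_ms=st, values=th,
                    train_spec=train.spec(), rest_after_ms=10_000.0))
                idx += 1
                onset += t_end + 10_000.0

    elif session_type in ("iso_fatigue", "free_fatigue"):
        if session_type == "iso_fatigue":
            mode = "isometric"
            dur = subject.iso_train_duration_ms
            rest = 1000.0
        else:
            mode = "free_swing"
            dur = subject.free_train_duration_ms
            rest = 1200.0
        protocol = make_fatigue_protocol(mode, dur, subject.pulse_duration_us,
                                         first_pair_rest=10_000.0,
                                         inter_train_rest=rest)
        meta["protocol"] = {"mode": mode, "train_duration_ms": dur,
                            "first_pair_rest_ms": 10_000.0,
                            "inter_train_rest_ms": rest}
        sim = simulate_protocol(
            protocol, fm, fat, dt=dt, theta_iso=90.0,
            theta_rest=subject.theta_rest,
            load_N=subject.load_N if mode == "free_swing" else 0.0)
        for rec in sim.records:
            sl = sim.window(rec)
            t_loc = sim.local_time(rec)
            entry = protocol.entries[rec.index]
            t_end = entry.train.train_duration + entry.rest_after
            if mode == "isometric":
                st, F = _sample(t_loc, sim.F[sl], fs, t_end)
                vals = F * L + rng.normal(0.0, sd_F * L, st.size)
                channel = "torque_Nm"
            else:
                st, th = _sample(t_loc, sim.theta[sl], fs, t_end)
                vals = th + rng.normal(0.0, sd_th, st.size)
                channel = "theta_deg"
            traces.append(Trace(
                index=rec.index, role=rec.role, channel=channel, mode=mode,
                onset_ms=rec.onset, fs_hz=fs, t_ms=st, values=vals,
                train_spec=entry.train.spec(),
                rest_after_ms=entry.rest_after, block=rec.index // 15,
                angle_deg=90.0 if mode == "isometric" else None))

    return MeasurementSet(session_type, traces[0].mode, traces, meta)


def synthesize_all_sessions(subject: SyntheticSubject, seed: int = 0,
                            dt: float = 0.2, noise_scale: float = 1.0
                            ) -> dict[str, MeasurementSet]:
    """All five session types with per-session derived seeds; ``noise_scale``
    scales both channel noise sds (0 gives noiseless sessions)."""
    out = {}
    for k, stype in enumerate(SESSION_TYPES):
        out[stype] = synthesize_session(
            subject, stype, seed=(seed * 1009 + 13 * k) % (2**31 - 1), dt=dt,
            noise_force_N=subject.noise_force_N * noise_scale,
            noise_angle_deg=subject.noise_angle_deg * noise_scale)
    return out
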