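"""Forward simulation of the coupled force-motion-fatigue system.

Single contractions (one train plus its rest) and whole stimulation protocols
are integrated with a fixed-step RK4 scheme over a merged event grid (pulse
times inserted as grid nodes) for bit-reproducibility.  The activation state
CN is evaluated from its closed form (exact for the linear activation ODE);
the remaining seven states are integrated numerically.  When fatigue is
enabled, (A90, Km1, Km2, tau1) are co-integrated with the force-motion states
in one coupled system and persist across trains, relaxing toward baseline
during rests; CN and F are reset to zero at each train onset whenever the
preceding rest exceeds 5·tauc (numerically exact to < e⁻⁵⁰ for the ≥1 s rests
used here), and otherwise persist.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import _kernels
from .params import FatigueParams, ForceMotionParams
from .protocol import PulseTrain, StimulationProtocol

__all__ = [
    "ThetaRamp",
    "ResetPolicy",
    "ContractionResult",
    "TrainRecord",
    "SimulationResult",
    "simulate_contraction",
    "simulate_protocol",
    "extract_testing_pairs",
    "euler_reference_contraction",
    "SimulationError",
]

log = logging.getLogger(__name__)

MODE_CODES = {"isometric": 0, "isovelocity": 1, "free_swing": 2}


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class ThetaRamp:
    """Prescribed isovelocity angle profile: theta0 + slope·(t − t0), clamped
    below at theta_min (slope is negative during extension, deg/ms)."""

    theta0: float
    slope: float
    theta_min: float
    t0: float = 0.0

    def theta(self, t) -> np.ndarray:
        th = self.theta0 + self.slope * (np.asarray(t, dtype=float) - self.t0)
        return np.maximum(th, self.theta_min)

    def omega(self, t) -> np.ndarray:
        th = self.theta0 + self.slope * (np.asarray(t, dtype=float) - self.t0)
        return np.where(th > self.theta_min, self.slope, 0.0)


@dataclass(frozen=True)
class ResetPolicy:
    """Inter-train state policy: CN/F reset when the rest exceeds
    ``cn_reset_rest_factor · tauc``; in free-swing mode (theta, omega) are
    reset to (theta_rest, 0) at each onset (the experimenter stopped the leg
    by hand)."""

    cn_reset_rest_factor: float = 5.0
    reset_limb_each_train: bool = True


def merged_grid(t_end: float, dt: float, pulse_times: np.ndarray) -> np.ndarray:
    """Uniform grid of nominal step ``dt`` on [0, t_end] with pulse times
    inserted as nodes (near-duplicates within 1e-9 ms merged)."""
    nb = max(1, int(np.ceil(t_end / dt - 1e-9)))
    base = np.linspace(0.0, t_end, nb + 1)
    pt = np.asarray(pulse_times, dtype=float)
    pt = pt[(pt > 0.0) & (pt < t_end)]
    ts = np.union1d(base, pt)
    keep = np.ones(ts.size, dtype=bool)
    keep[1:] = np.diff(ts) > 1e-9
    return ts[keep]


def _pack_p(fm: ForceMotionParams, load_N: float, theta_iso: float,
            profile: ThetaRamp | None,
            catch: tuple[float, float, float] | None = None) -> np.ndarray:
    p = np.zeros(14)
    p[0] = fm.a
    p[1] = fm.b
    p[2] = fm.tau2
    p[3] = fm.V1
    p[4] = fm.V2
    p[5] = fm.L_over_I
    p[6] = fm.FM
    p[7] = fm.lam
    p[8] = load_N
    p[9] = theta_iso
    if profile is not None:
        p[10] = profile.t0
        p[11] = profile.theta0
        p[12] = profile.slope
        p[13] = profile.theta_min
    elif catch is not None:
        p[10], p[11], p[12] = catch
    return p


def _cn_on_grid(ts: np.ndarray, pulses: np.ndarray, R0: float,
                tauc: float) -> np.ndarray:
    from .dynamics import ri_sequence

    ri = ri_sequence(pulses, R0, tauc)
    return _kernels.cn_profile(ts, np.asarray(pulses, dtype=float), ri, tauc)


def _pack_fat(fat: FatigueParams | None, legacy_betas: bool) -> tuple[np.ndarray, bool]:
    arr = np.zeros(10)
    if fat is None:
        arr[3] = 1.0  # unused but must be nonzero (divisor)
        return arr, False
    arr[0] = fat.alphaA
    arr[1] = fat.alphaKm
    arr[2] = fat.alphaTau1
    arr[3] = fat.tauFat_ms
    arr[4] = fat.betaTau1
    arr[5] = fat.A90_0
    arr[6] = fat.Km1_0
    arr[7] = fat.tau1_0
    if legacy_betas:
        arr[8] = fat.betaA
        arr[9] = fat.betaKm
    return arr, True


@dataclass
class ContractionResult:
    """Trajectories over one train-plus-rest window (times local to onset)."""

    t: np.ndarray
    cn: np.ndarray
    Y: np.ndarray  # columns: F, theta, omega, A90, Km1, Km2, tau1
    mode: str
    status: int
    train: PulseTrain

    @property
    def F(self) -> np.ndarray:
        return self.Y[:, 0]

    @property
    def theta(self) -> np.ndarray:
        return self.Y[:, 1]

    @property
    def omega(self) -> np.ndarray:
        return self.Y[:, 2]

    @property
    def A90(self) -> np.ndarray:
        return self.Y[:, 3]

    @property
    def Km1(self) -> np.ndarray:
        return self.Y[:, 4]

    @property
    def Km2(self) -> np.ndarray:
        return self.Y[:, 5]

    @property
    def Km(self) -> np.ndarray:
        return self.Y[:, 4] + self.Y[:, 5]

    @property
    def tau1(self) -> np.ndarray:
        return self.Y[:, 6]

    def end_state(self) -> np.ndarray:
        return self.Y[-1].copy()

    def negative_drive_mask(self, fm: ForceMotionParams) -> np.ndarray:
        """Diagnostic: time steps where the total drive G + A is negative."""
        x = 90.0 - self.theta
        A = self.A90 * (fm.a * x * x + fm.b * x + 1.0)
        G = fm.V1 * self.theta * np.exp(-fm.V2 * self.theta) * self.omega
        return (G + A) < 0.0


def simulate_contraction(train: PulseTrain, mode: str, fm: ForceMotionParams,
                         fat: FatigueParams | None = None, *, dt: float = 0.2,
                         t_end: float | None = None, theta_iso: float = 90.0,
                         theta_rest: float | None = None,
                         profile: ThetaRamp | None = None,
                         load_N: float = 0.0, F0: float = 0.0,
                         fatigue_state: Sequence[float] | None = None,
                         carry_pulses: np.ndarray | None = None,
                         on_clamp: str = "raise",
                         catch_at_rest: bool = True,
                         legacy_betas: bool = False) -> ContractionResult:
    """Integrate one contraction from train onset through ``t_end``
    (default: the train duration; pass duration + rest to cover the rest).

    ``carry_pulses`` may hold onset-relative (negative) pulse times of a
    closely preceding train whose activation has not yet decayed.
    ``fatigue_state`` carries (A90, Km1, Km2, tau1) across trains; when
    omitted it is initialised from ``fat`` baselines (or ``fm`` if no fatigue).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if mode not in MODE_CODES:
        raise ValueError(f"mode must be one of {tuple(MODE_CODES)}")
    if mode == "isovelocity" and profile is None:
        raise ValueError("isovelocity mode requires a prescribed theta profile")
    if t_end is None:
        t_end = train.train_duration
    pulses = train.pulse_array()
    if carry_pulses is not None and len(carry_pulses):
        pulses = np.concatenate([np.asarray(carry_pulses, dtype=float), pulses])
    ts = merged_grid(t_end, dt, pulses)
    mids = 0.5 * (ts[:-1] + ts[1:])
    cn_nodes = _cn_on_grid(ts, pulses, fm.R0, fm.tauc)
    cn_mids = _cn_on_grid(mids, pulses, fm.R0, fm.tauc)
    if fatigue_state is not None:
        fstate = np.asarray(fatigue_state, dtype=float)
    elif fat is not None:
        fstate = np.array([fat.A90_0, fat.Km1_0, 0.0, fat.tau1_0])
    else:
        fstate = np.array([fm.A90, fm.Km, 0.0, fm.tau1])
    if mode == "free_swing":
        th0 = (90.0 - fm.lam) if theta_rest is None else float(theta_rest)
    elif mode == "isovelocity":
        th0 = profile.theta0
    else:
        th0 = theta_iso
    y0 = np.array([F0, th0, 0.0, fstate[0], fstate[1], fstate[2], fstate[3]])
    catch = None
    if mode == "free_swing" and catch_at_rest:
        catch = (1.0, th0, train.train_duration)
    p = _pack_p(fm, load_N, theta_iso, profile, catch)
    fat_arr, fatigue_on = _pack_fat(fat, legacy_betas)
    Y, status = _kernels.rk4_integrate(ts, cn_nodes, cn_mids, y0,
                                       MODE_CODES[mode], p, fat_arr, fatigue_on)
    if mode == "isovelocity":
        Y[:, 1] = profile.theta(ts)
        Y[:, 2] = profile.omega(ts)
    elif mode == "isometric":
        Y[:, 1] = theta_iso
        Y[:, 2] = 0.0
    if status != 0:
        if on_clamp == "raise":
            raise SimulationError(
                "knee angle left [0°, 120°]: non-physical hyperextension "
                "(check parameters)")
        log.warning("knee angle clamp triggered; trajectory truncated")
    return ContractionResult(ts, cn_nodes, Y, mode, status, train)


@dataclass(frozen=True)
class TrainRecord:
    index: int
    role: str
    onset: float
    i0: int  # slice into the concatenated arrays
    i1: int
    peak_force: float
    theta_min: float
    end_fatigue_state: tuple[float, float, float, float]


@dataclass
class SimulationResult:
    """Concatenated trajectories over a whole protocol plus per-train records."""

    t: np.ndarray
    cn: np.ndarray
    F: np.ndarray
    theta: np.ndarray
    omega: np.ndarray
    A90: np.ndarray
    Km1: np.ndarray
    Km2: np.ndarray
    tau1: np.ndarray
    train_index: np.ndarray
    records: list[TrainRecord]
    mode: str
    protocol: StimulationProtocol

    @property
    def Km(self) -> np.ndarray:
        return self.Km1 + self.Km2

    def window(self, record: TrainRecord) -> slice:
        return slice(record.i0, record.i1)

    def local_time(self, record: TrainRecord) -> np.ndarray:
        return self.t[self.window(record)] - record.onset

    def to_dataframe(self) -> pd.DataFrame:
        roles = np.empty(self.t.shape, dtype=object)
        for r in self.records:
            roles[r.i0:r.i1] = r.role
        return pd.DataFrame({
            "t_ms": self.t,
            "CN": self.cn,
            "F_N": self.F,
            "theta_deg": self.theta,
            "omega_deg_per_ms": self.omega,
            "A90": self.A90,
            "Km": self.Km,
            "tau1": self.tau1,
            "train_index": self.train_index,
            "role": roles,
        })

    def plot(self, ax=None):
        """Quick-look force/angle plot (matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 4))
        ax.plot(self.t / 1000.0, self.F, lw=0.6, label="force (N)")
        if self.mode != "isometric":
            ax2 = ax.twinx()
            ax2.plot(self.t / 1000.0, self.theta, lw=0.6, color="C1",
                     label="knee angle (deg)")
            ax2.set_ylabel("knee angle (deg)")
        ax.set_xlabel("time (s)")
        ax.set_ylabel("force (N)")
        return ax


def simulate_protocol(protocol: StimulationProtocol, fm: ForceMotionParams,
                      fat: FatigueParams | None = None, *, dt: float = 0.2,
                      load_N: float = 0.0, theta_iso: float = 90.0,
                      theta_rest: float | None = None,
                      profile: ThetaRamp | None = None,
                      reset_policy: ResetPolicy | None = None,
                      store_stride: int = 1, on_clamp: str = "raise",
                      catch_at_rest: bool = True,
                      legacy_betas: bool = False,
                      log_progress: bool = False) -> SimulationResult:
    """Integrate a whole protocol train by train.

    The fatigue state persists across trains (relaxing during rests, which
    are always integrated — the fatigue ODEs have no gating); CN and F are
    reset at train onsets after long rests per the :class:`ResetPolicy`.
    """
    policy = reset_policy or ResetPolicy()
    rows_t, rows = [], []
    records: list[TrainRecord] = []
    tr_idx_rows = []
    cn_rows = []
    fstate = None
    F_carry = 0.0
    prev_pulses_abs: np.ndarray | None = None
    prev_rest = np.inf
    n = len(protocol.entries)
    for i, e in enumerate(protocol.entries):
        t_end = e.train.train_duration + e.rest_after
        carry = None
        F0 = 0.0
        if prev_rest < policy.cn_reset_rest_factor * fm.tauc:
            carry = prev_pulses_abs - e.onset
            F0 = F_carry
            log.warning("short rest before train %d: CN/F carried over", i)
        res = simulate_contraction(
            e.train, protocol.mode, fm, fat, dt=dt, t_end=t_end,
            theta_iso=theta_iso, theta_rest=theta_rest, profile=profile,
            load_N=load_N, F0=F0, fatigue_state=fstate, carry_pulses=carry,
            on_clamp=on_clamp, catch_at_rest=catch_at_rest,
            legacy_betas=legacy_betas)
        fstate = res.Y[-1, 3:7].copy()
        F_carry = res.Y[-1, 0]
        prev_pulses_abs = e.onset + res.train.pulse_array()
        prev_rest = e.rest_after
        last = i == n - 1
        sl = slice(None) if last else slice(0, -1)
        ts = res.t[sl]
        Ys = res.Y[sl]
        cns = res.cn[sl]
        if store_stride > 1:
            keep = np.zeros(ts.size, dtype=bool)
            keep[::store_stride] = True
            keep[-1] = True
            ts, Ys, cns = ts[keep], Ys[keep], cns[keep]
        i0 = sum(len(x) for x in rows_t)
        rows_t.append(e.onset + ts)
        rows.append(Ys)
        cn_rows.append(cns)
        tr_idx_rows.append(np.full(ts.size, i, dtype=np.int64))
        in_train = res.t <= e.train.train_duration
        records.append(TrainRecord(
            index=i, role=e.role, onset=e.onset, i0=i0, i1=i0 + ts.size,
            peak_force=float(res.F[in_train].max()),
            theta_min=float(res.theta.min()),
            end_fatigue_state=tuple(fstate),
        ))
        if log_progress and (i + 1) % 15 == 0:
            log.info("simulated %d/%d trains", i + 1, n)
    t = np.concatenate(rows_t)
    Y = np.vstack(rows)
    return SimulationResult(
        t=t, cn=np.concatenate(cn_rows), F=Y[:, 0], theta=Y[:, 1],
        omega=Y[:, 2], A90=Y[:, 3], Km1=Y[:, 4], Km2=Y[:, 5], tau1=Y[:, 6],
        train_index=np.concatenate(tr_idx_rows), records=records,
        mode=protocol.mode, protocol=protocol)


def extract_testing_pairs(result: SimulationResult) -> list[tuple[TrainRecord, TrainRecord]]:
    """The 15 (50CFT, 12.5VFT) testing pairs of a fatigue protocol, in block
    onset order.  Returns an empty list (with a warning) if the protocol has
    no testing pairs."""
    from .protocol import ROLE_TESTING_50CFT, ROLE_TESTING_VFT

    pairs = []
    recs = result.records
    for k in range(len(recs) - 1):
        if recs[k].role == ROLE_TESTING_50CFT and recs[k + 1].role == ROLE_TESTING_VFT:
            pairs.append((recs[k], recs[k + 1]))
    if not pairs:
        log.warning("protocol contains no testing pairs")
    return pairs


def euler_reference_contraction(train: PulseTrain, mode: str,
                                fm: ForceMotionParams,
                                fat: FatigueParams | None = None, *,
                                dt: float = 0.001, t_end: float | None = None,
                                theta_iso: float = 90.0,
                                theta_rest: float | None = None,
                                profile: ThetaRamp | None = None,
                                load_N: float = 0.0,
                                out_stride: int = 200,
                                catch_at_rest: bool = True,
                                legacy_betas: bool = False):
    """Validation-grade fine-step Euler integration of the full system
    (activation ODE included, evaluated numerically).  Returns
    ``(t, cn, Y)`` sampled every ``out_stride`` steps."""
    from .dynamics import ri_sequence

    if t_end is None:
        t_end = train.train_duration
    pulses = train.pulse_array()
    ri = ri_sequence(pulses, fm.R0, fm.tauc)
    if fat is not None:
        fstate = np.array([fat.A90_0, fat.Km1_0, 0.0, fat.tau1_0])
    else:
        fstate = np.array([fm.A90, fm.Km, 0.0, fm.tau1])
    if mode == "free_swing":
        th0 = (90.0 - fm.lam) if theta_rest is None else float(theta_rest)
    elif mode == "isovelocity":
        th0 = profile.theta0
    else:
        th0 = theta_iso
    y0 = np.array([0.0, th0, 0.0, fstate[0], fstate[1], fstate[2], fstate[3]])
    catch = None
    if mode == "free_swing" and catch_at_rest:
        catch = (1.0, th0, train.train_duration)
    p = _pack_p(fm, load_N, theta_iso, profile, catch)
    fat_arr, fatigue_on = _pack_fat(fat, legacy_betas)
    T, CN, Y = _kernels.euler_reference(t_end, dt, pulses, ri, fm.tauc, y0,
                                        MODE_CODES[mode], p, fat_arr,
                                        fatigue_on, out_stride)
    return T, CN, Y
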