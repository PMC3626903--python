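"""Force-motion model primitives: activation, force generation, limb motion.

The model chain is

1. activation dynamics — the normalized Ca²⁺-troponin complex concentration
   ``CN`` rises with each stimulation pulse (pulses closely following a
   predecessor are amplified by the catch-like gain ``Ri``) and decays with
   time constant ``tauc``;
2. force generation — force ``F`` is driven by the Michaelis–Menten coupling
   ``CN/(Km+CN)`` scaled by the angle-dependent gain ``A`` and the
   velocity-dependent term ``G``, and decays over the two time constants
   ``tau1``/``tau2``;
3. limb motion — the leg distal to the knee is a rigid body accelerated by the
   imbalance between muscle force and the gravity/load resistance.

Sign conventions: the knee flexion angle ``theta`` is 0° at full extension,
so extension means ``theta`` decreasing and angular velocity ``omega`` < 0;
the force–velocity term ``G`` is therefore negative (a force loss) during
extension.

Units: time ms, angle deg, force N, angular velocity deg/ms.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "ri_sequence",
    "pulse_gain",
    "cn_series",
    "cn_rate",
    "force_length_A",
    "force_velocity_G",
    "force_rate",
    "angular_acceleration",
    "ACC_DEG_S2_TO_DEG_MS2",
    "stim_force_from_dyno",
    "lambda_from_rest_angle",
]

#: The limb equation of motion is evaluated in deg/s² (the fitted L/I values
#: are bound to that convention; see :func:`angular_acceleration`); the
#: integrators work in deg/ms², hence this factor.
ACC_DEG_S2_TO_DEG_MS2 = 1e-6

DEG2RAD = math.pi / 180.0


def pulse_gain(t_i: float, t_prev: float | None, R0: float = 2.0,
               tauc: float = 20.0) -> float:
    """Activation gain of one pulse relative to the first pulse of the train.

    Returns 1 for the first pulse (``t_prev`` is None) and
    ``1 + (R0-1)·exp(-(t_i - t_prev)/tauc)`` otherwise: a pulse arriving
    shortly after its predecessor is enhanced, approaching ``R0``.
    """
    if t_prev is None:
        return 1.0
    if t_i <= t_prev:
        raise ValueError("pulse times must be strictly increasing")
    return 1.0 + (R0 - 1.0) * math.exp(-(t_i - t_prev) / tauc)


def ri_sequence(pulse_times: np.ndarray, R0: float = 2.0,
                tauc: float = 20.0) -> np.ndarray:
    """Vector of per-pulse gains ``Ri`` for an ordered pulse-time array."""
    pt = np.asarray(pulse_times, dtype=float)
    if pt.size and np.any(np.diff(pt) <= 0):
        raise ValueError("pulse times must be strictly increasing")
    r = np.ones_like(pt)
    if pt.size > 1:
        r[1:] = 1.0 + (R0 - 1.0) * np.exp(-np.diff(pt) / tauc)
    return r


def cn_series(t, pulse_times, R0: float = 2.0, tauc: float = 20.0) -> np.ndarray:
    """Closed-form CN(t) for a pulse train (exact solution of the linear
    activation ODE): a superposition of ``Ri·x·exp(-x)`` terms with
    ``x = (t - t_i)/tauc``, each gated to ``t >= t_i``.

    A single pulse therefore peaks at ``CN = e⁻¹`` exactly ``tauc`` after the
    pulse, independent of ``tauc``.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    pt = np.asarray(pulse_times, dtype=float)
    if pt.size == 0:
        return np.zeros_like(t)
    ri = ri_sequence(pt, R0, tauc)
    dt = t[:, None] - pt[None, :]
    active = dt >= 0
    x = np.where(active, dt / tauc, 0.0)
    return (ri[None, :] * np.where(active, x * np.exp(-x), 0.0)).sum(axis=1)


def cn_rate(t: float, CN: float, pulse_times, R0: float = 2.0,
            tauc: float = 20.0) -> float:
    """Instantaneous dCN/dt: pulse drive (Heaviside-gated, pulses with
    ``t_i <= t`` only) minus first-order decay ``CN/tauc``."""
    pt = np.asarray(pulse_times, dtype=float)
    if pt.size == 0:
        return -CN / tauc
    ri = ri_sequence(pt, R0, tauc)
    mask = pt <= t
    drive = float(np.sum(ri[mask] * np.exp(-(t - pt[mask]) / tauc))) / tauc
    return drive - CN / tauc


def force_length_A(theta: float, A90: float, a: float, b: float) -> float:
    """Angle-dependent force gain ``A = A90·[a(90-θ)² + b(90-θ) + 1]`` (N/ms).

    The bracket equals 1 at θ = 90°, so ``A90`` is by construction the gain at
    a 90° knee angle.
    """
    x = 90.0 - theta
    return A90 * (a * x * x + b * x + 1.0)


def force_velocity_G(theta: float, omega: float, V1: float, V2: float) -> float:
    """Velocity-dependent force term ``G = V1·θ·exp(-V2·θ)·ω`` (N/ms).

    Negative during extension (ω < 0): the faster the leg extends, the less
    force the muscle can transmit.
    """
    return V1 * theta * math.exp(-V2 * theta) * omega


def force_rate(CN: float, F: float, A_effective: float, G: float, Km: float,
               tau1: float, tau2: float) -> float:
    """dF/dt = (G + A)·CN/(Km+CN) − F / (tau1 + tau2·CN/(Km+CN))."""
    mm = CN / (Km + CN)
    return (G + A_effective) * mm - F / (tau1 + tau2 * mm)


def angular_acceleration(theta: float, F: float, F_load: float, FM: float,
                         lam: float, L_over_I: float,
                         unit: str = "deg_per_ms2") -> float:
    """Angular acceleration of the free-swinging leg.

    ``θ̈ = L/I · [(F_load + FM)·cos(θ+λ) − F]``, evaluated in deg/s² — the
    convention to which the fitted ``L_over_I`` values are bound (a leg with
    these parameters then swings at its natural pendulum frequency of ~1 Hz).
    With ``unit="deg_per_ms2"`` (default, the integrator unit) the result is
    scaled by 1e-6; ``unit="deg_per_s2"`` returns the raw product.

    Positive muscle force beyond the gravity/load resistance makes θ̈ < 0,
    i.e. drives the knee toward extension (θ → 0).
    """
    acc = L_over_I * ((F_load + FM) * math.cos((theta + lam) * DEG2RAD) - F)
    if unit == "deg_per_s2":
        return acc
    if unit == "deg_per_ms2":
        return acc * ACC_DEG_S2_TO_DEG_MS2
    raise ValueError("unit must be 'deg_per_ms2' or 'deg_per_s2'")


def stim_force_from_dyno(F_bio: float, theta: float, FM: float) -> float:
    """Stimulation force from a dynamometer measurement during isovelocity
    extension: ``F = F_bio + FM·cos θ`` (passive-trial subtraction is assumed
    to have been applied upstream where needed)."""
    return F_bio + FM * math.cos(theta * DEG2RAD)


def lambda_from_rest_angle(theta_rest: float) -> float:
    """Angle offset making the resting leg an equilibrium: ``λ = 90 − θ_rest``.

    With this λ, ``cos(θ_rest + λ) = cos 90° = 0`` and the resting leg has zero
    angular acceleration before stimulation.
    """
    if not (0.0 < theta_rest < 120.0):
        raise ValueError("theta_rest must lie in (0°, 120°)")
    return 90.0 - theta_rest
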