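"""Outcome measures and the validation statistic.

Per-contraction outcomes: angular excursion (initial minus minimum knee
angle), torque-time integral (TTI), maximum power and the torque / angular
velocity at maximum power.  Torque is force × moment arm ``L`` (a measured
constant, distinct from the fitted lumped ``L/I``); power is torque (N·m) ×
angular velocity (rad/s).  Protocol-level summaries follow the fatigue-curve
conventions: per-33CFT series normalized to the first contraction, and the
"end of protocol" value is the mean of the last seven fatiguing trains of the
final block (the last half of a 13-train set, rounded up).

The validation statistic is the coefficient of determination of predicted vs
measured series under a forced identity line (slope 1, intercept 0):
``r² = 1 − Σ(pred−meas)² / Σ(meas−mean(meas))²``.  It can be negative for bad
predictions and is reported unclipped.  An uncentered variant (denominator
``Σ meas²``) is available behind a flag.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "excursion",
    "torque_and_power",
    "tti",
    "fatigue_curve",
    "last_set_summary",
    "r2_fixed_identity",
    "contraction_window",
    "protocol_outcomes",
    "OMEGA_DEG_MS_TO_RAD_S",
]

#: deg/ms -> rad/s
OMEGA_DEG_MS_TO_RAD_S = (np.pi / 180.0) * 1000.0


def excursion(theta: np.ndarray) -> float:
    """Angular excursion of one contraction: initial minus minimum knee angle
    (deg) within the supplied window."""
    th = np.asarray(theta, dtype=float)
    if th.size == 0:
        raise ValueError("empty angle trace")
    return float(th[0] - th.min())


def contraction_window(t: np.ndarray, theta: np.ndarray | None,
                       train_duration: float, extra_ms: float = 300.0) -> np.ndarray:
    """Boolean mask of the contraction window: train onset to the later of
    (train end + ``extra_ms``) and the time of minimum angle, bounded by the
    end of the supplied (inter-train) window."""
    t = np.asarray(t, dtype=float)
    end = train_duration + extra_ms
    if theta is not None and len(theta):
        t_min = float(t[int(np.argmin(theta))])
        end = max(end, t_min)
    return t <= end + 1e-9


def torque_and_power(F: np.ndarray, omega: np.ndarray, L: float
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Torque (N·m) and power (W) traces from force (N) and angular velocity
    (deg/ms).  Power uses the velocity magnitude (extension speed), in rad/s."""
    if not L > 0:
        raise ValueError("moment arm L must be > 0")
    torque = np.asarray(F, dtype=float) * L
    power = torque * np.abs(np.asarray(omega, dtype=float)) * OMEGA_DEG_MS_TO_RAD_S
    return torque, power


def tti(torque: np.ndarray, t_ms: np.ndarray) -> float:
    """Torque-time integral (N·m·s) by the trapezoid rule over the window."""
    return float(np.trapezoid(np.asarray(torque, dtype=float),
                              np.asarray(t_ms, dtype=float)) / 1000.0)


def fatigue_curve(values) -> np.ndarray:
    """Series normalized to its first element (the first 33CFT contraction)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty series")
    if v[0] == 0:
        raise ValueError("first contraction value is zero; cannot normalize")
    return v / v[0]


def last_set_summary(values, block_size: int = 13, n_last: int = 7) -> float:
    """Mean of the last ``n_last`` values of the final complete block of
    fatiguing contractions (default: last 7 of a 13-train set)."""
    v = np.asarray(values, dtype=float)
    if v.size % block_size != 0 or v.size == 0:
        raise ValueError("incomplete final block of fatiguing contractions")
    return float(v[-n_last:].mean())


def r2_fixed_identity(predicted, measured, centered: bool = True) -> float:
    """Coefficient of determination with a forced slope of 1 and intercept 0.

    ``centered=True`` (default) uses the standard denominator about the
    measured mean; ``centered=False`` uses the uncentered sum of squares."""
    p = np.asarray(predicted, dtype=float)
    m = np.asarray(measured, dtype=float)
    if p.shape != m.shape or p.size < 2:
        raise ValueError("series must have equal length >= 2")
    denom = np.sum((m - m.mean()) ** 2) if centered else np.sum(m ** 2)
    if denom == 0:
        raise ValueError("measured series has zero variance")
    return float(1.0 - np.sum((p - m) ** 2) / denom)


def protocol_outcomes(result, L: float, extra_ms: float = 300.0):
    """Per-contraction outcome table for a simulated protocol.

    Columns: train index, role, onset, excursion (deg), TTI (N·m·s), max
    power (W), torque at max power (N·m), angular velocity magnitude at max
    power (rad/s).  Power columns are identically zero in isometric mode.
    """
    import pandas as pd

    rows = []
    for rec in result.records:
        sl = result.window(rec)
        t = result.t[sl] - rec.onset
        th = result.theta[sl]
        entry = result.protocol.entries[rec.index]
        mask = contraction_window(t, th if result.mode == "free_swing" else None,
                                  entry.train.train_duration, extra_ms)
        torque, power = torque_and_power(result.F[sl][mask],
                                         result.omega[sl][mask], L)
        imax = int(np.argmax(power))
        rows.append({
            "train_index": rec.index,
            "role": rec.role,
            "onset_ms": rec.onset,
            "excursion_deg": excursion(th[mask]) if result.mode == "free_swing" else 0.0,
            "tti_Nms": tti(torque, t[mask]),
            "max_power_W": float(power[imax]),
            "torque_at_max_power_Nm": float(torque[imax]),
            "velocity_at_max_power_rad_s": float(
                abs(result.omega[sl][mask][imax]) * OMEGA_DEG_MS_TO_RAD_S),
        })
    return pd.DataFrame(rows)
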