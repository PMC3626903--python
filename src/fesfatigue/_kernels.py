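"""Compiled integration kernels (numba).

Two independent code paths:

* :func:`rk4_integrate` — the production fixed-step RK4 over a merged event
  grid.  CN(t) is supplied precomputed from its closed form (the activation
  ODE is linear and driven only by the pulse train, so its solution is exact
  and parameter-independent given ``R0``/``tauc``); the remaining seven states
  (F, theta, omega, A90, Km1, Km2, tau1) are integrated.
* :func:`euler_reference` — a deliberately simple fine-step explicit Euler
  integrator of the *full* system including the activation ODE evaluated
  numerically from its pulse-sum right-hand side.  Used only as an oracle to
  validate the production path; it shares no discretisation machinery with it.

Parameter packing (float64 arrays):

``p``:   0 a, 1 b, 2 tau2, 3 V1, 4 V2, 5 L_over_I, 6 FM, 7 lam, 8 F_load,
         9 theta_iso, 10 prof_t0, 11 prof_theta0, 12 prof_slope (deg/ms),
         13 prof_theta_min.  In free-swing mode slots 10–12 are reused:
         10 catch flag (1 = emulate the experimenter stopping the returning
         leg at the rest angle), 11 catch angle (deg), 12 time after which
         the catch is active (ms, normally the train end).
``fat``: 0 alphaA, 1 alphaKm, 2 alphaTau1, 3 tauFat_ms, 4 betaTau1,
         5 A90_0, 6 Km1_0, 7 tau1_0, 8 betaA (legacy), 9 betaKm (legacy)

State vector ``y``: 0 F, 1 theta, 2 omega, 3 A90, 4 Km1, 5 Km2, 6 tau1.
Modes: 0 isometric (theta fixed at p[9]), 1 isovelocity (theta ramped from
p[11] at p[12] deg/ms from t = p[10], clamped at p[13]), 2 free swing.
"""

from __future__ import annotations

import numpy as np
from numba import njit

DEG2RAD = np.pi / 180.0
#: deg/s² -> deg/ms² (the equation of motion is evaluated in deg/s²)
ACC_SCALE = 1e-6


@njit(cache=False)
def _deriv(t, y, cn, mode, p, fat, fatigue_on, dy):
    F = y[0]
    A90 = y[3]
    Km1 = y[4]
    Km2 = y[5]
    tau1 = y[6]
    if mode == 0:
        th = p[9]
        om = 0.0
    elif mode == 1:
        th = p[11] + p[12] * (t - p[10])
        om = p[12]
        if th <= p[13]:
            th = p[13]
            om = 0.0
    else:
        th = y[1]
        om = y[2]
    x = 90.0 - th
    A = A90 * (p[0] * x * x + p[1] * x + 1.0)
    G = p[3] * th * np.exp(-p[4] * th) * om
    Km = Km1 + Km2
    mm = cn / (Km + cn)
    dy[0] = (G + A) * mm - F / (tau1 + p[2] * mm)
    if mode == 2:
        dy[1] = om
        dy[2] = p[5] * ((p[8] + p[6]) * np.cos((th + p[7]) * DEG2RAD) - F) * ACC_SCALE
    else:
        dy[1] = 0.0
        dy[2] = 0.0
    if fatigue_on:
        dy[3] = -(A90 - fat[5]) / fat[3] + (fat[0] + fat[8] * om) * F
        dy[4] = -(Km1 - fat[6]) / fat[3] + (fat[1] + fat[9] * om) * F
        dy[5] = -fat[1] * F
        dy[6] = -(tau1 - fat[7]) / fat[3] + (fat[2] + fat[4] * om) * F
    else:
        dy[3] = 0.0
        dy[4] = 0.0
        dy[5] = 0.0
        dy[6] = 0.0


@njit(cache=False)
def rk4_integrate(ts, cn_nodes, cn_mids, y0, mode, p, fat, fatigue_on):
    """Fixed-step RK4 over the (possibly non-uniform) merged grid ``ts``.

    Returns (Y, status); status 1 flags a non-physical knee angle
    (theta outside [0°, 120°] beyond a 0.5° guard), in which case the
    remaining rows hold the last state.
    """
    n = ts.shape[0]
    Y = np.empty((n, 7))
    y = y0.copy()
    for j in range(7):
        Y[0, j] = y[j]
    k1 = np.empty(7)
    k2 = np.empty(7)
    k3 = np.empty(7)
    k4 = np.empty(7)
    yt = np.empty(7)
    status = 0
    caught = False
    for i in range(n - 1):
        t = ts[i]
        h = ts[i + 1] - ts[i]
        tm = t + 0.5 * h
        _deriv(t, y, cn_nodes[i], mode, p, fat, fatigue_on, k1)
        for j in range(7):
            yt[j] = y[j] + 0.5 * h * k1[j]
        _deriv(tm, yt, cn_mids[i], mode, p, fat, fatigue_on, k2)
        for j in range(7):
            yt[j] = y[j] + 0.5 * h * k2[j]
        _deriv(tm, yt, cn_mids[i], mode, p, fat, fatigue_on, k3)
        for j in range(7):
            yt[j] = y[j] + h * k3[j]
        _deriv(ts[i + 1], yt, cn_nodes[i + 1], mode, p, fat, fatigue_on, k4)
        for j in range(7):
            y[j] = y[j] + h / 6.0 * (k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j])
        if mode == 2 and p[10] > 0.5:
            # the experimenter catches the returning leg at the rest angle
            if caught or (ts[i + 1] >= p[12] and y[2] > 0.0 and y[1] >= p[11]):
                caught = True
                y[1] = p[11]
                y[2] = 0.0
        for j in range(7):
            Y[i + 1, j] = y[j]
        if mode == 2 and (y[1] < -0.5 or y[1] > 120.5):
            status = i + 1  # step index at which the clamp fired
            for r in range(i + 2, n):
                for j in range(7):
                    Y[r, j] = y[j]
            break
    return Y, status


@njit(cache=False)
def cn_profile(ts, pulse_times, ri, tauc):
    """Exact CN at the sorted times ``ts`` via incremental propagation of the
    closed-form superposition (equivalent to the vectorised closed form in
    :mod:`fesfatigue.dynamics`, but O(n) instead of O(n·pulses))."""
    n = ts.shape[0]
    out = np.zeros(n)
    npulse = pulse_times.shape[0]
    P = 0.0  # sum of Ri * exp(-(t - ti)/tauc)
    Q = 0.0  # sum of Ri * ((t - ti)/tauc) * exp(-(t - ti)/tauc)
    if n == 0:
        return out
    cur = ts[0]
    if npulse > 0 and pulse_times[0] < cur:
        cur = pulse_times[0]
    ip = 0
    for k in range(n):
        t = ts[k]
        while ip < npulse and pulse_times[ip] <= t:
            h = pulse_times[ip] - cur
            if h > 0.0:
                e = np.exp(-h / tauc)
                Q = e * (Q + (h / tauc) * P)
                P = e * P
                cur = pulse_times[ip]
            P += ri[ip]
            ip += 1
        h = t - cur
        if h > 0.0:
            e = np.exp(-h / tauc)
            Q = e * (Q + (h / tauc) * P)
            P = e * P
            cur = t
        out[k] = Q
    return out


@njit(cache=False)
def euler_reference(t_end, dt, pulse_times, ri, tauc, y0, mode, p, fat,
                    fatigue_on, out_stride):
    """Fine-step explicit Euler oracle integrating CN numerically.

    Returns (T, CN, Y) sampled every ``out_stride`` steps (plus the final
    state).  Independent of :func:`rk4_integrate`: uniform grid, first-order
    updates, and the activation equation evaluated from its pulse sum.
    """
    nst = int(np.round(t_end / dt))
    nout = nst // out_stride + 1
    T = np.empty(nout)
    CN = np.empty(nout)
    Y = np.empty((nout, 7))
    cn = 0.0
    y = y0.copy()
    dy = np.empty(7)
    T[0] = 0.0
    CN[0] = cn
    for j in range(7):
        Y[0, j] = y[j]
    k = 1
    npulse = pulse_times.shape[0]
    caught = False
    for step in range(nst):
        t = step * dt
        drive = 0.0
        for ip in range(npulse):
            tp = pulse_times[ip]
            if tp <= t:
                drive += ri[ip] * np.exp(-(t - tp) / tauc)
        dcn = drive / tauc - cn / tauc
        _deriv(t, y, cn, mode, p, fat, fatigue_on, dy)
        cn += dt * dcn
        for j in range(7):
            y[j] += dt * dy[j]
        if mode == 2 and p[10] > 0.5:
            if caught or ((step + 1) * dt >= p[12] and y[2] > 0.0 and y[1] >= p[11]):
                caught = True
                y[1] = p[11]
                y[2] = 0.0
        if (step + 1) % out_stride == 0:
            T[k] = (step + 1) * dt
            CN[k] = cn
            for j in range(7):
                Y[k, j] = y[j]
            k += 1
    return T[:k], CN[:k], Y[:k]
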