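"""Fatigue model: drift of the three fatiguing force parameters.

During repetitive stimulation the force-model parameters A90, Km and tau1
drift away from their pre-fatigue baselines at rates proportional to the
instantaneous force, and relax back with a common time constant tauFat:

    dA90/dt  = −(A90 − A90_0)/tauFat + alphaA·F
    Km       = Km1 + Km2
    dKm1/dt  = −(Km1 − Km1_0)/tauFat + alphaKm·F
    dKm2/dt  = −alphaKm·F
    dtau1/dt = −(tau1 − tau1_0)/tauFat + (alphaTau1 + betaTau1·ω)·F

The simplified model retains a single velocity coupling, betaTau1: multiplied
by the (negative) extension velocity it counteracts alphaTau1, keeping tau1
closer to its baseline during non-isometric fatigue.  The removed couplings
betaA/betaKm are available in an optional legacy mode (all β terms multiply ω,
so isometric trajectories are unaffected either way).

betaTau1 can alternatively be *predicted* from already-identified parameters
(:func:`beta_tau1_from_params`), so non-isometric fatigue measurements are not
needed to predict non-isometric fatigue.
"""

from __future__ import annotations

import numpy as np

from .params import FatigueParams

__all__ = ["fatigue_rates", "km_total", "beta_tau1_from_params", "FatigueState"]

#: index order of the fatigue state vector used throughout
FatigueState = ("A90", "Km1", "Km2", "tau1")


def fatigue_rates(state, F: float, omega: float, params: FatigueParams,
                  legacy_betas: bool = False) -> np.ndarray:
    """Rates (per ms) of (A90, Km1, Km2, tau1) at force ``F`` (N) and angular
    velocity ``omega`` (deg/ms).

    With ``legacy_betas=True`` the removed velocity couplings ``betaA`` and
    ``betaKm`` are re-enabled (for comparison with the earlier model); the
    default simplified model uses only ``betaTau1``.
    """
    A90, Km1, Km2, tau1 = (float(state[0]), float(state[1]),
                           float(state[2]), float(state[3]))
    p = params
    bA = p.betaA if legacy_betas else 0.0
    bKm = p.betaKm if legacy_betas else 0.0
    dA90 = -(A90 - p.A90_0) / p.tauFat_ms + (p.alphaA + bA * omega) * F
    dKm1 = -(Km1 - p.Km1_0) / p.tauFat_ms + (p.alphaKm + bKm * omega) * F
    dKm2 = -p.alphaKm * F
    dtau1 = -(tau1 - p.tau1_0) / p.tauFat_ms + (p.alphaTau1 + p.betaTau1 * omega) * F
    return np.array([dA90, dKm1, dKm2, dtau1])


def km_total(state) -> float:
    """Total Michaelis–Menten constant ``Km = Km1 + Km2``."""
    return float(state[1]) + float(state[2])


def beta_tau1_from_params(A90_0: float, FM: float, tau1_0_iso: float,
                          alphaTau1: float, tauFat_s: float, V1: float) -> float:
    """Closed-form predictor of the velocity coupling betaTau1
    (ms·deg⁻¹·N⁻¹) from already-identified model parameters:

        betaTau1 = 8.5e-11 · A90_0^1.6 · FM^0.5 · tau1_0_iso^3.5
                   · alphaTau1^1.3 · tauFat_s^0.9 / V1^0.4

    Input units are part of the calibration of the leading constant and are
    fixed: ``A90_0`` N/ms, ``FM`` N, ``tau1_0_iso`` ms (the pre-fatigue tau1
    of the *isometric* fatigue session, a distinct quantity from a given
    day's non-isometric tau1_0), ``alphaTau1`` N⁻¹, ``tauFat_s`` **seconds**,
    ``V1`` N/deg².  All inputs must be positive (fractional powers).
    """
    vals = dict(A90_0=A90_0, FM=FM, tau1_0_iso=tau1_0_iso,
                alphaTau1=alphaTau1, tauFat_s=tauFat_s, V1=V1)
    for name, v in vals.items():
        if not v > 0:
            raise ValueError(f"{name} must be > 0 (fractional powers)")
    return (8.5e-11 * A90_0 ** 1.6 * FM ** 0.5 * tau1_0_iso ** 3.5
            * alphaTau1 ** 1.3 * tauFat_s ** 0.9 / V1 ** 0.4)
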