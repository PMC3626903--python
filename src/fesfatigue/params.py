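"""Parameter containers for the force-motion-fatigue model.

Two parameter sets drive the model:

* :class:`ForceMotionParams` — the non-fatigue muscle/limb constants: activation
  (``tauc``, ``R0``), force generation (``A90``, ``Km``, ``tau1``, ``tau2``),
  the parabolic force–angle shape (``a``, ``b``), the force–velocity term
  (``V1``, ``V2``) and the rigid-body limb constants (``L_over_I``, ``FM``,
  ``lam``).
* :class:`FatigueParams` — the drift rates of the three fatiguing force
  parameters (``alphaA``, ``alphaKm``, ``alphaTau1``), the common recovery time
  constant ``tauFat``, the single retained velocity-coupling coefficient
  ``betaTau1``, and the pre-fatigue baselines ``A90_0``, ``Km1_0``, ``tau1_0``.

Unit conventions (used consistently throughout the package): time in ms, angle
in deg, force in N, angular velocity in deg/ms.  ``tauFat`` is stored in ms
internally but read and written in seconds at the file interface, because the
closed-form ``betaTau1`` predictor consumes it in seconds (its calibration
constant is unit-bound).  Parameter files are flat YAML documents whose keys
carry explicit unit suffixes; unknown or missing keys are rejected.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = [
    "ForceMotionParams",
    "FatigueParams",
    "tau_fat_ms_from_s",
    "tau_fat_s_from_ms",
]


def tau_fat_ms_from_s(tau_fat_s: float) -> float:
    """Convert the fatigue recovery time constant from seconds to ms."""
    return float(tau_fat_s) * 1000.0


def tau_fat_s_from_ms(tau_fat_ms: float) -> float:
    """Convert the fatigue recovery time constant from ms to seconds."""
    return float(tau_fat_ms) / 1000.0


class ParameterError(ValueError):
    """Raised for invalid or inconsistent model parameters."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ParameterError(msg)


@dataclass(frozen=True)
class ForceMotionParams:
    """Constants of the activation/force/motion equations.

    Parameters
    ----------
    A90 : float
        Force scaling factor at a 90° knee angle, N/ms.
    a, b : float
        Parabolic force–angle shape coefficients, deg⁻² and deg⁻¹.
    Km : float
        Michaelis–Menten-like constant of the activation-to-force coupling
        (dimensionless).  This is the pre-fatigue total Km (Km1 with Km2 = 0).
    tau1, tau2 : float
        Force decay time constants, ms.
    V1, V2 : float
        Force–velocity term constants, N/deg² and deg⁻¹.
    L_over_I : float
        Lumped moment-arm over inertia constant of the limb equation of
        motion, kg⁻¹m⁻¹ (see the angular-acceleration unit note in
        :func:`fesfatigue.dynamics.angular_acceleration`).
    FM : float
        Passive resistance to knee extension (leg weight plus passive joint
        structures), N.
    lam : float
        Offset added to the knee angle so that angular acceleration is zero at
        the resting angle: ``lam = 90 − theta_rest``, deg.
    tauc : float
        Time constant of the Ca²⁺-troponin activation dynamics, ms (held at
        20 ms).
    R0 : float
        Magnitude of activation enhancement by closely spaced pulses
        (held at 2).
    """

    A90: float
    a: float
    b: float
    Km: float
    tau1: float
    tau2: float
    V1: float
    V2: float
    L_over_I: float
    FM: float
    lam: float = 0.0
    tauc: float = 20.0
    R0: float = 2.0

    def __post_init__(self) -> None:
        _require(self.tauc > 0, "tauc must be > 0")
        _require(self.tau1 > 0, "tau1 must be > 0")
        _require(self.tau2 >= 0, "tau2 must be >= 0")
        _require(self.A90 > 0, "A90 must be > 0")
        _require(self.Km > 0, "Km must be > 0")
        _require(self.R0 >= 1, "R0 must be >= 1")

    def replace(self, **changes: float) -> "ForceMotionParams":
        return dataclasses.replace(self, **changes)

    # --- flat keyed file format -------------------------------------------
    _FILE_KEYS = {
        "A90": "A90_N_per_ms",
        "a": "a_per_deg2",
        "b": "b_per_deg",
        "Km": "Km",
        "tau1": "tau1_ms",
        "tau2": "tau2_ms",
        "V1": "V1_N_per_deg2",
        "V2": "V2_per_deg",
        "L_over_I": "L_over_I_per_kg_m",
        "FM": "FM_N",
        "lam": "lam_deg",
        "tauc": "tauc_ms",
        "R0": "R0",
    }

    def to_file_dict(self) -> dict[str, float]:
        return {k: float(getattr(self, f)) for f, k in self._FILE_KEYS.items()}

    @classmethod
    def from_file_dict(cls, d: dict[str, Any]) -> "ForceMotionParams":
        inv = {v: k for k, v in cls._FILE_KEYS.items()}
        unknown = set(d) - set(inv)
        _require(not unknown, f"unknown force-motion parameter keys: {sorted(unknown)}")
        missing = set(inv) - set(d)
        _require(not missing, f"missing force-motion parameter keys: {sorted(missing)}")
        return cls(**{inv[k]: float(v) for k, v in d.items()})

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_file_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "ForceMotionParams":
        return cls.from_file_dict(yaml.safe_load(Path(path).read_text()))


@dataclass(frozen=True)
class FatigueParams:
    """Constants of the fatigue ODEs (drift of A90, Km1/Km2 and tau1).

    ``betaA`` and ``betaKm`` exist only for the optional legacy mode that
    re-enables the removed velocity couplings of the earlier model; they
    default to 0 and the simplified model never uses them.

    ``tauFat`` is stored here in ms (``tauFat_ms``); the file interface and
    the ``betaTau1`` predictor use seconds.
    """

    alphaA: float
    alphaKm: float
    alphaTau1: float
    tauFat_ms: float
    betaTau1: float
    A90_0: float
    Km1_0: float
    tau1_0: float
    betaA: float = 0.0
    betaKm: float = 0.0
    beta_source: str = "fitted"  # "fitted" | "predicted"
    tau1_0_iso: float | None = None

    def __post_init__(self) -> None:
        _require(self.tauFat_ms > 0, "tauFat must be > 0")
        _require(self.A90_0 > 0, "A90_0 must be > 0")
        _require(self.Km1_0 > 0, "Km1_0 must be > 0")
        _require(self.tau1_0 > 0, "tau1_0 must be > 0")
        _require(self.beta_source in ("fitted", "predicted"),
                 "beta_source must be 'fitted' or 'predicted'")

    @property
    def tauFat_s(self) -> float:
        return tau_fat_s_from_ms(self.tauFat_ms)

    def replace(self, **changes: Any) -> "FatigueParams":
        return dataclasses.replace(self, **changes)

    _FILE_KEYS = {
        "alphaA": "alphaA_per_ms2",
        "alphaKm": "alphaKm_per_ms_N",
        "alphaTau1": "alphaTau1_per_N",
        "betaTau1": "betaTau1_ms_per_deg_N",
        "A90_0": "A90_0_N_per_ms",
        "Km1_0": "Km1_0",
        "tau1_0": "tau1_0_ms",
        "betaA": "betaA_per_ms_deg",
        "betaKm": "betaKm_per_deg_N",
    }

    def to_file_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {k: float(getattr(self, f)) for f, k in self._FILE_KEYS.items()}
        d["tauFat_s"] = self.tauFat_s
        d["beta_source"] = self.beta_source
        if self.tau1_0_iso is not None:
            d["tau1_0_iso_ms"] = float(self.tau1_0_iso)
        return d

    @classmethod
    def from_file_dict(cls, d: dict[str, Any]) -> "FatigueParams":
        inv = {v: k for k, v in cls._FILE_KEYS.items()}
        allowed = set(inv) | {"tauFat_s", "beta_source", "tau1_0_iso_ms"}
        unknown = set(d) - allowed
        _require(not unknown, f"unknown fatigue parameter keys: {sorted(unknown)}")
        missing = (set(inv) | {"tauFat_s", "beta_source"}) - set(d)
        _require(not missing, f"missing fatigue parameter keys: {sorted(missing)}")
        kwargs: dict[str, Any] = {inv[k]: float(v) for k, v in d.items() if k in inv}
        kwargs["tauFat_ms"] = tau_fat_ms_from_s(float(d["tauFat_s"]))
        kwargs["beta_source"] = str(d["beta_source"])
        if "tau1_0_iso_ms" in d:
            kwargs["tau1_0_iso"] = float(d["tau1_0_iso_ms"])
        return cls(**kwargs)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_file_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "FatigueParams":
        return cls.from_file_dict(yaml.safe_load(Path(path).read_text()))
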