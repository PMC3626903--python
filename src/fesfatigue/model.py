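"""statsmodels-style model surface: build a model from measurement sessions,
``fit()`` it, inspect a results object.

``FesFatigueModel`` holds the measurement sessions (read from disk or
generated synthetically) and the identification configuration; ``fit()``
runs the staged identification pipeline and returns ``FesFatigueResults``,
which carries the parameter estimates, per-stage diagnostics (SSR, restart
dispersion), a ``summary()`` table, and simulation / prediction /
self-validation methods.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .identify import IdentificationConfig, PipelineResult, run_pipeline
from .io import MeasurementSet, read_measurement_dir
from .outcomes import protocol_outcomes, r2_fixed_identity
from .params import FatigueParams, ForceMotionParams
from .protocol import make_fatigue_protocol
from .simulate import SimulationResult, simulate_protocol

__all__ = ["FesFatigueModel", "FesFatigueResults"]

PARAM_UNITS = {
    "A90": "N/ms", "a": "deg^-2", "b": "deg^-1", "Km": "-", "tau1": "ms",
    "tau2": "ms", "V1": "N/deg^2", "V2": "deg^-1", "L_over_I": "kg^-1 m^-1",
    "FM": "N", "A90_0": "N/ms", "Km1_0": "-", "tau1_0": "ms",
    "alphaA": "ms^-2", "alphaKm": "ms^-1 N^-1", "alphaTau1": "N^-1",
    "tauFat_s": "s", "betaTau1": "ms deg^-1 N^-1",
}

PARAM_STAGE = {
    "A90": "iso_nonfatigue", "Km": "iso_nonfatigue", "tau1": "iso_nonfatigue",
    "tau2": "iso_nonfatigue", "a": "parabola_ab", "b": "parabola_ab",
    "V1": "isovelocity", "V2": "isovelocity", "L_over_I": "free_nonfatigue",
    "FM": "free_nonfatigue", "A90_0": "free_nonfatigue",
    "Km1_0": "free_nonfatigue", "tau1_0": "free_nonfatigue",
    "alphaA": "iso_fatigue", "alphaKm": "iso_fatigue",
    "alphaTau1": "iso_fatigue", "tauFat_s": "iso_fatigue",
    "betaTau1": "beta_tau1",
}


class FesFatigueModel:
    """Force-motion-fatigue model bound to one subject's measurement sessions.

    Parameters
    ----------
    sessions : mapping of session type to :class:`MeasurementSet`
        Any of ``iso_nonfatigue``, ``isovelocity``, ``free_nonfatigue``,
        ``iso_fatigue``, ``free_fatigue``; the full pipeline needs all five
        (``free_fatigue`` only when betaTau1 is fitted rather than predicted).
    config : IdentificationConfig, optional
    """

    def __init__(self, sessions: dict[str, MeasurementSet],
                 config: IdentificationConfig | None = None):
        self.sessions = dict(sessions)
        self.config = config or IdentificationConfig()
        self.subject = None

    @classmethod
    def from_directory(cls, root: str | Path,
                       config: IdentificationConfig | None = None
                       ) -> "FesFatigueModel":
        """Load every session subdirectory (named by session type) under
        ``root``."""
        root = Path(root)
        sessions = {}
        for sub in sorted(root.iterdir()):
            if sub.is_dir() and (sub / "manifest.json").exists():
                ms = read_measurement_dir(sub)
                sessions[ms.session_type] = ms
        if not sessions:
            raise FileNotFoundError(f"no measurement sessions under {root}")
        return cls(sessions, config)

    @classmethod
    def from_synthetic(cls, subject=None, noise_scale: float = 1.0,
                       seed: int = 0, dt: float = 0.2,
                       config: IdentificationConfig | None = None
                       ) -> "FesFatigueModel":
        """Synthesize all five sessions from a (default) synthetic subject."""
        from .synthetic import default_subject, synthesize_all_sessions

        subject = subject or default_subject()
        sessions = synthesize_all_sessions(subject, seed=seed, dt=dt,
                                           noise_scale=noise_scale)
        model = cls(sessions, config)
        model.subject = subject
        return model

    def fit(self, seed: int = 0, beta_mode: str = "fit") -> "FesFatigueResults":
        """Run the staged identification pipeline (PSO + least squares per
        stage) and return the results object."""
        pipe = run_pipeline(self.sessions, self.config, seed=seed,
                            beta_mode=beta_mode)
        return FesFatigueResults(self, pipe)


@dataclass
class FesFatigueResults:
    """Estimates, diagnostics and prediction methods of a fitted model."""

    model: FesFatigueModel
    pipeline: PipelineResult

    @property
    def params(self) -> pd.Series:
        return pd.Series(self.pipeline.params, name="estimate")

    @property
    def fm_day(self) -> ForceMotionParams:
        return self.pipeline.fm_day

    @property
    def fm_iso(self) -> ForceMotionParams:
        return self.pipeline.fm_iso

    @property
    def fat(self) -> FatigueParams:
        return self.pipeline.fat

    def stage_ssr(self) -> dict[str, float]:
        return {name: s.fit.ssr for name, s in self.pipeline.stages.items()
                if s.fit is not None}

    def restart_dispersion(self) -> dict[str, float]:
        return {name: s.fit.dispersion
                for name, s in self.pipeline.stages.items() if s.fit is not None}

    def summary(self) -> str:
        rows = []
        for name, value in self.pipeline.params.items():
            rows.append(f"{name:<12}{value: .6g}".ljust(27)
                        + f"{PARAM_UNITS.get(name, ''):<16}"
                        + PARAM_STAGE.get(name, ""))
        lines = [
            "       Force-motion-fatigue model — identification results",
            "=" * 68,
            f"{'parameter':<12}{'estimate':<15}{'units':<16}stage",
            "-" * 68,
            *rows,
            "-" * 68,
            f"betaTau1 source: {self.fat.beta_source}    seed: {self.pipeline.seed}",
        ]
        ssr = self.stage_ssr()
        disp = self.restart_dispersion()
        for name in ssr:
            lines.append(f"stage {name:<16} SSR = {ssr[name]:<12.4g} "
                         f"restart dispersion = {disp[name]:.2e}")
        lines.append("=" * 68)
        return "\n".join(lines)

    # --- prediction ------------------------------------------------------
    def simulate_fatigue_protocol(self, mode: str = "free_swing", *,
                                  dt: float | None = None,
                                  store_stride: int = 5) -> SimulationResult:
        """Simulate the 225-train fatiguing protocol with the fitted
        parameters, using the session's own protocol geometry."""
        key = "free_fatigue" if mode == "free_swing" else "iso_fatigue"
        ms = self.model.sessions[key]
        meta = ms.meta["protocol"]
        protocol = make_fatigue_protocol(
            mode, meta["train_duration_ms"],
            first_pair_rest=meta["first_pair_rest_ms"],
            inter_train_rest=meta["inter_train_rest_ms"])
        kwargs = dict(dt=dt or self.model.config.dt, store_stride=store_stride)
        if mode == "free_swing":
            return simulate_protocol(
                protocol, self.fm_day, self.fat,
                theta_rest=float(ms.meta["theta_rest_deg"]),
                load_N=float(ms.meta["load_kg"]) * 9.81, **kwargs)
        return simulate_protocol(
            protocol, self.fm_iso,
            self.fat.replace(A90_0=self.fm_iso.A90, Km1_0=self.fm_iso.Km,
                             tau1_0=self.fm_iso.tau1),
            theta_iso=90.0, **kwargs)

    def predict_outcomes(self, mode: str = "free_swing") -> pd.DataFrame:
        sim = self.simulate_fatigue_protocol(mode)
        key = "free_fatigue" if mode == "free_swing" else "iso_fatigue"
        L = float(self.model.sessions[key].meta["L_m"])
        return protocol_outcomes(sim, L)

    def validate(self, centered: bool = True, smooth_window: int = 11) -> dict:
        """Self-validation against the free-swinging fatigue measurements:
        r² (forced identity line) of predicted vs measured per-contraction
        angular excursion and peak extension velocity.

        Angle traces are Savitzky–Golay smoothed (``smooth_window`` samples,
        cubic; 0 disables) before differencing — the same operator is applied
        to measured and predicted traces."""
        from scipy.signal import savgol_filter

        def prep(t, th):
            if smooth_window and th.size > smooth_window:
                th = savgol_filter(th, smooth_window, 3)
            return th, np.gradient(th, t)

        ms = self.model.sessions["free_fatigue"]
        sim = self.simulate_fatigue_protocol("free_swing")
        exc_m, vel_m, exc_p, vel_p = [], [], [], []
        for tr in sorted(ms.traces, key=lambda t: t.index):
            th_m, om = prep(tr.t_ms, tr.values)
            exc_m.append(float(th_m[0] - th_m.min()))
            vel_m.append(float(np.max(-om)))
            rec = sim.records[tr.index]
            sl = sim.window(rec)
            t_loc = sim.t[sl] - rec.onset
            th = np.interp(tr.t_ms, t_loc, sim.theta[sl])
            th_p, om_p = prep(tr.t_ms, th)
            exc_p.append(float(th_p[0] - th_p.min()))
            vel_p.append(float(np.max(-om_p)))
        return {
            "r2_excursion": r2_fixed_identity(exc_p, exc_m, centered),
            "r2_velocity": r2_fixed_identity(vel_p, vel_m, centered),
            "n_contractions": len(exc_m),
        }

    def plot_fatigue_curves(self, ax=None):
        """Predicted vs measured normalized excursion of the fatiguing
        trains (matplotlib)."""
        import matplotlib.pyplot as plt

        from .protocol import ROLE_FATIGUING

        ms = self.model.sessions["free_fatigue"]
        sim = self.simulate_fatigue_protocol("free_swing")
        meas, pred = [], []
        for tr in sorted(ms.traces, key=lambda t: t.index):
            if tr.role != ROLE_FATIGUING:
                continue
            meas.append(float(tr.values[0] - tr.values.min()))
            rec = sim.records[tr.index]
            sl = sim.window(rec)
            pred.append(float(sim.theta[sl][0] - sim.theta[sl].min()))
        meas = np.asarray(meas) / meas[0]
        pred = np.asarray(pred) / pred[0]
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(meas, "o", ms=2, label="measured")
        ax.plot(pred, "-", label="predicted")
        ax.set_xlabel("33 Hz fatiguing contraction #")
        ax.set_ylabel("excursion (normalized to first)")
        ax.legend()
        return ax
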