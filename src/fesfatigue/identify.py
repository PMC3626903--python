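"""Staged parameter identification: particle swarm + nonlinear least squares.

The pipeline mirrors the experimental identification flow:

1. ``iso_nonfatigue``  — isometric testing pairs at four knee angles give the
   per-angle force gain A(θ), the shared Km, tau1 and tau2.  tau1 is first
   estimated from the exponential force decline after each train (once the
   modeled activation has faded), then refined jointly.
2. ``parabola_ab``     — the parabolic force–angle shape (a, b) is fitted to
   the per-angle A values normalized by A90.
3. ``isovelocity``     — stimulated minus passive dynamometer extensions at
   150°/s give the force–velocity constants (V1, V2).
4. ``free_nonfatigue`` — free-swinging testing pairs give the limb constants
   (L/I, FM) and the day's pre-fatigue baselines (A90_0, Km1_0, tau1_0).
5. ``iso_fatigue``     — the 15 testing pairs of the isometric fatiguing
   protocol are each fitted for (A90, Km, tau1); the ω=0 fatigue ODEs, driven
   by the force history of the full 225-train protocol, are then fitted to
   those series for (alphaA, alphaKm, alphaTau1, tauFat).
6. ``beta_tau1``       — the single velocity coupling is either fitted
   one-dimensionally to the free-swinging fatigue measurements or predicted
   from the other parameters.

Each nonlinear stage minimizes a sum of squared residuals with a particle
swarm (global phase) followed by bounded nonlinear least squares, repeated
from independent restarts; the spread of the restart solutions (restart
dispersion) operationalizes the "converged to the global minimum" check.
All randomness is seeded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import least_squares, minimize_scalar

from . import _kernels
from .dynamics import cn_series, ri_sequence
from .io import MeasurementSet, Trace
from .params import FatigueParams, ForceMotionParams, tau_fat_ms_from_s
from .protocol import (ROLE_TESTING_50CFT, ROLE_TESTING_VFT, PulseTrain,
                       make_fatigue_protocol)
from .simulate import (MODE_CODES, ThetaRamp, _pack_fat, _pack_p, merged_grid,
                       simulate_protocol)

log = logging.getLogger(__name__)

__all__ = [
    "PSOOptions", "IdentificationConfig", "FitResult", "FitStageSpec",
    "StageOutcome", "StageError", "particle_swarm", "pso_then_lsq",
    "fit_iso_nonfatigue", "fit_parabola_ab", "fit_isovelocity",
    "fit_free_nonfatigue", "fit_iso_fatigue", "fit_beta_tau1",
    "run_pipeline", "PipelineResult",
]


class StageError(RuntimeError):
    """A stage's preconditions are not met or all its fits failed."""


# --------------------------------------------------------------------------
# optimizer core
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PSOOptions:
    n_particles: int = 40
    n_iter: int = 200
    inertia: float = 0.729
    cognitive: float = 1.49445
    social: float = 1.49445


@dataclass
class FitResult:
    names: tuple[str, ...]
    x: np.ndarray
    ssr: float
    restart_solutions: np.ndarray  # (n_restarts, dim)
    dispersion: float  # max pairwise bound-normalized distance of restarts
    converged: bool
    seed: int

    @property
    def estimates(self) -> dict[str, float]:
        return dict(zip(self.names, map(float, self.x)))


def particle_swarm(fun: Callable[[np.ndarray], float], lb: np.ndarray,
                   ub: np.ndarray, opts: PSOOptions,
                   rng: np.random.Generator,
                   x_init: np.ndarray | None = None) -> tuple[np.ndarray, float]:
    """Global-best particle swarm with reflecting bounds.  ``x_init``
    (e.g. a physiologic seed) is injected as one initial particle."""
    lb = np.asarray(lb, dtype=float)
    ub = np.asarray(ub, dtype=float)
    d = lb.size
    span = ub - lb
    X = lb + span * rng.random((opts.n_particles, d))
    if x_init is not None:
        X[0] = np.clip(np.asarray(x_init, dtype=float), lb, ub)
    V = span * (rng.random((opts.n_particles, d)) - 0.5) * 0.2
    pbest = X.copy()
    pval = np.array([fun(x) for x in X])
    g = int(np.argmin(pval))
    gbest, gval = pbest[g].copy(), float(pval[g])
    for _ in range(opts.n_iter):
        r1 = rng.random((opts.n_particles, d))
        r2 = rng.random((opts.n_particles, d))
        V = (opts.inertia * V + opts.cognitive * r1 * (pbest - X)
             + opts.social * r2 * (gbest[None, :] - X))
        X = X + V
        low = X < lb
        X = np.where(low, 2 * lb - X, X)
        V = np.where(low, -V, V)
        high = X > ub
        X = np.where(high, 2 * ub - X, X)
        V = np.where(high, -V, V)
        X = np.clip(X, lb, ub)
        vals = np.array([fun(x) for x in X])
        improved = vals < pval
        pbest[improved] = X[improved]
        pval[improved] = vals[improved]
        g = int(np.argmin(pval))
        if pval[g] < gval:
            gbest, gval = pbest[g].copy(), float(pval[g])
    return gbest, gval


def _dispersion(solutions: np.ndarray, lb: np.ndarray, ub: np.ndarray) -> float:
    if len(solutions) < 2:
        return 0.0
    norm = (solutions - lb) / np.where(ub > lb, ub - lb, 1.0)
    dmax = 0.0
    for i in range(len(norm)):
        for j in range(i + 1, len(norm)):
            dmax = max(dmax, float(np.max(np.abs(norm[i] - norm[j]))))
    return dmax


def pso_then_lsq(residual_fn: Callable[[np.ndarray], np.ndarray],
                 names: Sequence[str], lb, ub, *, seed: int,
                 pso: PSOOptions = PSOOptions(), n_restarts: int = 2,
                 x0: np.ndarray | None = None) -> FitResult:
    """Particle swarm (global phase) seeding bounded nonlinear least squares,
    repeated from ``n_restarts`` independently seeded restarts; the best
    solution and the restart dispersion are returned.

    ``residual_fn`` maps a parameter vector to a residual vector.  An
    optional ``x0`` is polished directly as an extra restart.
    """
    lb = np.asarray(lb, dtype=float)
    ub = np.asarray(ub, dtype=float)
    if not (np.all(np.isfinite(lb)) and np.all(np.isfinite(ub))):
        raise ValueError("bounds must be finite")

    def scalar(x):
        r = residual_fn(x)
        return float(np.dot(r, r))

    solutions, ssrs = [], []
    starts: list[np.ndarray] = []
    for r in range(n_restarts):
        rng = np.random.default_rng((seed + 7919 * r) % (2**31 - 1))
        xg, _ = particle_swarm(scalar, lb, ub, pso, rng, x_init=x0)
        starts.append(xg)
    if x0 is not None:
        starts.append(np.clip(np.asarray(x0, dtype=float), lb, ub))
    ok = False
    for xs in starts:
        try:
            res = least_squares(residual_fn, xs, bounds=(lb, ub), method="trf")
            solutions.append(res.x)
            ssrs.append(float(2 * res.cost))
            ok = ok or res.success
        except Exception as exc:  # pragma: no cover - defensive
            log.warning("least-squares restart failed: %s", exc)
    if not solutions:
        raise StageError("all optimizer restarts failed")
    solutions = np.asarray(solutions)
    best = int(np.argmin(ssrs))
    return FitResult(tuple(names), solutions[best], ssrs[best],
                     solutions, _dispersion(solutions, lb, ub), ok, seed)


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

#: physiologic seed values used to centre the default parameter bounds
DEFAULT_SEEDS = {
    "A90": 2.10, "a": -4.49e-4, "b": 3.44e-2, "Km": 3.52e-1, "tau1": 36.1,
    "tau2": 52.1, "V1": 3.71e-1, "V2": 2.29e-2, "L_over_I": 9.85,
    "FM": 247.5, "alphaA": -4.03e-7, "alphaKm": -1.36e-8,
    "alphaTau1": 2.93e-5, "tauFat_s": 99.4, "betaTau1": 8.54e-4,
}


@dataclass
class IdentificationConfig:
    dt: float = 0.2  # ms, integration step for objective simulations
    #: global-phase budget used by the pipeline stages (all are <= 5-D and
    #: are polished by bounded least squares from every restart)
    pso: PSOOptions = field(default_factory=lambda: PSOOptions(
        n_particles=24, n_iter=60))
    n_restarts: int = 2
    bound_factors: tuple[float, float] = (0.1, 10.0)
    seeds: dict = field(default_factory=lambda: dict(DEFAULT_SEEDS))
    decay_cn_frac: float = 0.01   # CN threshold starting the tau1 decay window
    decay_force_frac: float = 0.05  # force floor ending the decay window
    pair_fit_window_ms: float = 500.0  # post-train tail used in pair fits
    fatigue_history: str = "simulated"  # "simulated" | "measured"
    fatigue_outer_iters: int = 2
    clamp_penalty: float = 1e3

    def bounds(self, name: str) -> tuple[float, float]:
        s = self.seeds[name]
        lo, hi = self.bound_factors
        if s >= 0:
            return (lo * s, hi * s)
        return (hi * s, lo * s)


STAGE_NAMES = ("iso_nonfatigue", "parabola_ab", "isovelocity",
               "free_nonfatigue", "iso_fatigue_series", "fatigue_ode",
               "beta_tau1_fit")


@dataclass(frozen=True)
class FitStageSpec:
    """Declarative description of one identification stage: which parameters
    are free (with finite bounds), which are held fixed, which measurement
    session feeds the residuals, and the residual definition tag."""

    stage: str
    free: dict  # name -> (lower, upper)
    fixed: dict  # name -> value
    measurements: str  # session type consumed
    residual: str  # residual definition tag

    def __post_init__(self) -> None:
        if self.stage not in STAGE_NAMES:
            raise ValueError(f"unknown stage {self.stage!r}")
        overlap = set(self.free) & set(self.fixed)
        if overlap:
            raise ValueError(f"parameters both free and fixed: {sorted(overlap)}")
        for name, (lo, hi) in self.free.items():
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"free parameter {name} needs finite bounds")


@dataclass
class StageOutcome:
    name: str
    estimates: dict
    fit: FitResult | None = None
    extras: dict = field(default_factory=dict)
    spec: FitStageSpec | None = None


# --------------------------------------------------------------------------
# compiled per-trace plans
# --------------------------------------------------------------------------

class _Plan:
    """Pre-built integration grid, closed-form CN, and measurement sampling
    for one contraction; reused across thousands of objective evaluations."""

    def __init__(self, train: PulseTrain, mode: str, t_end: float, dt: float,
                 R0: float, tauc: float, sample_t: np.ndarray,
                 profile: ThetaRamp | None = None, theta_iso: float = 90.0):
        self.train = train
        self.mode_code = MODE_CODES[mode]
        self.mode = mode
        pulses = train.pulse_array()
        self.ts = merged_grid(t_end, dt, pulses)
        mids = 0.5 * (self.ts[:-1] + self.ts[1:])
        ri = ri_sequence(pulses, R0, tauc)
        self.cn_nodes = _kernels.cn_profile(self.ts, pulses, ri, tauc)
        self.cn_mids = _kernels.cn_profile(mids, pulses, ri, tauc)
        self.profile = profile
        self.theta_iso = theta_iso
        self.sample_t = np.asarray(sample_t, dtype=float)

    def run(self, fm: ForceMotionParams, fat: FatigueParams | None = None, *,
            load_N: float = 0.0, theta_rest: float | None = None,
            catch_at_rest: bool = True):
        if self.mode == "free_swing":
            th0 = (90.0 - fm.lam) if theta_rest is None else float(theta_rest)
        elif self.mode == "isovelocity":
            th0 = self.profile.theta0
        else:
            th0 = self.theta_iso
        catch = (1.0, th0, self.train.train_duration) \
            if (self.mode == "free_swing" and catch_at_rest) else None
        p = _pack_p(fm, load_N, self.theta_iso, self.profile, catch)
        fat_arr, fatigue_on = _pack_fat(fat, False)
        if fat is not None:
            y0 = np.array([0.0, th0, 0.0, fat.A90_0, fat.Km1_0, 0.0, fat.tau1_0])
        else:
            y0 = np.array([0.0, th0, 0.0, fm.A90, fm.Km, 0.0, fm.tau1])
        Y, status = _kernels.rk4_integrate(self.ts, self.cn_nodes, self.cn_mids,
                                           y0, self.mode_code, p, fat_arr,
                                           fatigue_on)
        return Y, status

    def sampled(self, Y: np.ndarray, col: int) -> np.ndarray:
        return np.interp(self.sample_t, self.ts, Y[:, col])


def _central_diff(t_ms: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Angular velocity (deg/ms) by central differencing, as an experimenter
    derives it from a sampled angle trace."""
    return np.gradient(np.asarray(values, dtype=float),
                       np.asarray(t_ms, dtype=float))


# --------------------------------------------------------------------------
# stage 1: isometric non-fatigue
# --------------------------------------------------------------------------

def _tau1_from_decay(trace: Trace, L: float, cfg: IdentificationConfig,
                     R0: float, tauc: float) -> float | None:
    """Single-exponential fit to the force decline after the train, from the
    time the modeled CN falls below ``decay_cn_frac``·max to the time force
    falls below ``decay_force_frac``·peak."""
    train = trace.train()
    F = trace.values / L
    t = trace.t_ms
    cn = cn_series(t, train.pulse_array(), R0, tauc)
    peak = F.max()
    start_ok = (t > train.train_duration) & (cn < cfg.decay_cn_frac * cn.max())
    if not np.any(start_ok):
        return None
    i0 = int(np.argmax(start_ok))
    below = np.where(F[i0:] < cfg.decay_force_frac * peak)[0]
    i1 = i0 + (int(below[0]) if below.size else len(F) - i0)
    if i1 - i0 < 4:
        return None
    seg_t, seg_F = t[i0:i1], F[i0:i1]
    if np.any(seg_F <= 0):
        return None
    slope = np.polyfit(seg_t, np.log(seg_F), 1)[0]
    if slope >= 0:
        return None
    return -1.0 / slope


def fit_iso_nonfatigue(ms: MeasurementSet, cfg: IdentificationConfig,
                       seed: int) -> StageOutcome:
    """Per-angle A, shared Km, tau1, tau2 from the isometric testing pairs.

    The force response is linear in A at fixed (Km, tau1, tau2), and the
    Michaelis–Menten coupling is angle-independent, so the global phase
    searches only (Km, tau2) with per-angle A profiled out analytically and
    tau1 held at its decay estimate; the final least squares refines all
    parameters jointly.
    """
    L = float(ms.meta["L_m"])
    traces = [tr for tr in ms.traces if tr.channel == "torque_Nm"]
    if not traces:
        raise StageError("no isometric torque traces")
    angles = sorted({float(tr.angle_deg) for tr in traces})
    fm0 = _seed_fm(cfg)

    decay = [_tau1_from_decay(tr, L, cfg, fm0.R0, fm0.tauc) for tr in traces]
    decay = [d for d in decay if d is not None]
    if not decay:
        raise StageError("tau1 decay estimation failed on every trace")
    tau1_decay = float(np.median(decay))

    # one plan per train kind; A and the angle enter only as a scale factor
    kinds: dict[str, _Plan] = {}
    by_kind_angle: dict[tuple[str, float], list[Trace]] = {}
    for tr in traces:
        train = tr.train()
        key = train.kind
        if key not in kinds:
            kinds[key] = _Plan(train, "isometric", tr.t_ms[-1], cfg.dt,
                               fm0.R0, fm0.tauc, tr.t_ms)
        by_kind_angle.setdefault((key, float(tr.angle_deg)), []).append(tr)

    def unit_responses(Km: float, tau1: float, tau2: float) -> dict[str, np.ndarray]:
        fm_u = fm0.replace(A90=1.0, a=0.0, b=0.0, Km=Km, tau1=tau1, tau2=tau2,
                           V1=0.0)
        out = {}
        for kind, plan in kinds.items():
            Y, _ = plan.run(fm_u)
            out[kind] = plan.sampled(Y, 0)
        return out

    def profile_A(units: dict[str, np.ndarray]) -> tuple[dict[float, float], float]:
        """Per-angle least-squares A and the total SSR."""
        A_hat: dict[float, float] = {}
        ssr = 0.0
        for angle in angles:
            num = den = 0.0
            for kind in kinds:
                for tr in by_kind_angle.get((kind, angle), []):
                    u = units[kind]
                    F = tr.values / L
                    num += float(u @ F)
                    den += float(u @ u)
            A_hat[angle] = max(num / den, 1e-9) if den > 0 else 1e-9
            for kind in kinds:
                for tr in by_kind_angle.get((kind, angle), []):
                    r = A_hat[angle] * units[kind] - tr.values / L
                    ssr += float(r @ r)
        return A_hat, ssr

    def pso_obj(x: np.ndarray) -> float:
        units = unit_responses(x[0], tau1_decay, x[1])
        return profile_A(units)[1]

    lbKm, ubKm = cfg.bounds("Km")
    lbt2, ubt2 = cfg.bounds("tau2")
    rng = np.random.default_rng(seed % (2**31 - 1))
    restart_xs = []
    for r in range(cfg.n_restarts):
        rr = np.random.default_rng((seed + 104729 * r) % (2**31 - 1))
        xg, _ = particle_swarm(pso_obj, np.array([lbKm, lbt2]),
                               np.array([ubKm, ubt2]), cfg.pso, rr)
        restart_xs.append(xg)

    # joint refinement: per-angle A + Km + tau1 + tau2
    names = tuple(f"A_{int(a)}" for a in angles) + ("Km", "tau1", "tau2")
    nA = len(angles)

    def residuals(x: np.ndarray) -> np.ndarray:
        units = unit_responses(x[nA], x[nA + 1], x[nA + 2])
        out = []
        for i, angle in enumerate(angles):
            for kind in kinds:
                for tr in by_kind_angle.get((kind, angle), []):
                    out.append(x[i] * units[kind] - tr.values / L)
        return np.concatenate(out)

    lbt1, ubt1 = cfg.bounds("tau1")
    sols, ssrs = [], []
    for xg in restart_xs:
        A0, _ = profile_A(unit_responses(xg[0], tau1_decay, xg[1]))
        x0 = np.array([A0[a] for a in angles] + [xg[0], tau1_decay, xg[1]])
        lb = np.array([max(v / 10, 1e-9) for v in x0[:nA]] + [lbKm, lbt1, lbt2])
        ub = np.array([v * 10 for v in x0[:nA]] + [ubKm, ubt1, ubt2])
        res = least_squares(residuals, np.clip(x0, lb, ub), bounds=(lb, ub),
                            method="trf")
        sols.append(res.x)
        ssrs.append(float(2 * res.cost))
    sols = np.asarray(sols)
    best = int(np.argmin(ssrs))
    lbn = np.array([1e-9] * nA + [lbKm, lbt1, lbt2])
    ubn = np.array([100.0] * nA + [ubKm, ubt1, ubt2])
    fit = FitResult(names, sols[best], ssrs[best], sols,
                    _dispersion(sols, lbn, ubn), True, seed)
    x = sols[best]
    A_by_angle = {angles[i]: float(x[i]) for i in range(nA)}
    est = {
        "A_by_angle": A_by_angle,
        "A90": A_by_angle.get(90.0, float(x[nA - 1])),
        "Km": float(x[nA]),
        "tau1": float(x[nA + 1]),
        "tau2": float(x[nA + 2]),
    }
    spec = FitStageSpec(
        "iso_nonfatigue",
        free={**{f"A_{int(a)}": (1e-9, 100.0) for a in angles},
              "Km": (lbKm, ubKm), "tau1": (lbt1, ubt1), "tau2": (lbt2, ubt2)},
        fixed={"tauc": fm0.tauc, "R0": fm0.R0},
        measurements="iso_nonfatigue", residual="force_trace")
    return StageOutcome("iso_nonfatigue", est, fit,
                        extras={"tau1_decay": tau1_decay, "angles": angles},
                        spec=spec)


def fit_parabola_ab(A_by_angle: dict, A90: float) -> StageOutcome:
    """Parabolic force–angle coefficients from ≥ 3 per-angle A values:
    least-squares fit of a·(90−θ)² + b·(90−θ) to A(θ)/A90 − 1."""
    if len(A_by_angle) < 3:
        raise StageError("at least 3 distinct knee angles are required")
    th = np.array(sorted(A_by_angle), dtype=float)
    y = np.array([A_by_angle[t] for t in th]) / A90 - 1.0
    x = 90.0 - th
    M = np.column_stack([x * x, x])
    coef, *_ = np.linalg.lstsq(M, y, rcond=None)
    spec = FitStageSpec("parabola_ab", free={"a": (-1.0, 1.0), "b": (-1.0, 1.0)},
                        fixed={"A90": A90}, measurements="iso_nonfatigue",
                        residual="A_ratio_parabola")
    return StageOutcome("parabola_ab",
                        {"a": float(coef[0]), "b": float(coef[1])}, spec=spec)


# --------------------------------------------------------------------------
# stage 3: isovelocity (V1, V2)
# --------------------------------------------------------------------------

def fit_isovelocity(ms: MeasurementSet, fm_base: ForceMotionParams,
                    cfg: IdentificationConfig, seed: int) -> StageOutcome:
    """Force–velocity constants from stimulated-minus-passive isovelocity
    extensions, restricted to the constant-velocity window."""
    L = float(ms.meta["L_m"])
    prof_meta = ms.meta.get("profile")
    if prof_meta is None:
        raise StageError("isovelocity session lacks a velocity profile")
    prof = ThetaRamp(prof_meta["theta0_deg"], prof_meta["slope_deg_per_ms"],
                     prof_meta["theta_min_deg"])
    passives = ms.by_role("passive")
    if not passives:
        raise StageError("matched passive trial is missing")
    passive = passives[0]
    stims = [tr for tr in ms.traces if tr.role != "passive"]
    if not stims:
        raise StageError("no stimulated isovelocity traces")
    for tr in stims:
        if tr.t_ms.shape != passive.t_ms.shape or tr.fs_hz != passive.fs_hz:
            raise StageError("velocity profile mismatch between stim and passive trials")

    th_s = prof.theta(stims[0].t_ms)
    window = (th_s <= 85.0 + 1e-9) & (th_s >= 20.0 - 1e-9)
    plans = {}
    for tr in stims:
        train = tr.train()
        if train.kind not in plans:
            plans[train.kind] = _Plan(train, "isovelocity", tr.t_ms[-1],
                                      cfg.dt, fm_base.R0, fm_base.tauc,
                                      tr.t_ms, profile=prof)
    F_meas = {id(tr): (tr.values - passive.values) / L for tr in stims}

    def residuals(x: np.ndarray) -> np.ndarray:
        fm_c = fm_base.replace(V1=x[0], V2=x[1])
        sims = {}
        for kind, plan in plans.items():
            Y, _ = plan.run(fm_c)
            sims[kind] = plan.sampled(Y, 0)
        out = []
        for tr in stims:
            out.append((sims[tr.train().kind] - F_meas[id(tr)])[window])
        return np.concatenate(out)

    lb = np.array([cfg.bounds("V1")[0], cfg.bounds("V2")[0]])
    ub = np.array([cfg.bounds("V1")[1], cfg.bounds("V2")[1]])
    fit = pso_then_lsq(residuals, ("V1", "V2"), lb, ub, seed=seed,
                       pso=cfg.pso, n_restarts=cfg.n_restarts)
    spec = FitStageSpec("isovelocity",
                        free={"V1": (lb[0], ub[0]), "V2": (lb[1], ub[1])},
                        fixed={"A90": fm_base.A90, "Km": fm_base.Km,
                               "tau1": fm_base.tau1, "tau2": fm_base.tau2},
                        measurements="isovelocity",
                        residual="stim_minus_passive_force")
    return StageOutcome("isovelocity", fit.estimates, fit, spec=spec)


# --------------------------------------------------------------------------
# stage 4: free-swinging non-fatigue (L/I, FM, day baselines)
# --------------------------------------------------------------------------

def fit_free_nonfatigue(ms: MeasurementSet, fm_base: ForceMotionParams,
                        cfg: IdentificationConfig, seed: int) -> StageOutcome:
    """Limb constants and day baselines from free-swinging testing pairs,
    fitting modeled knee angle and angular velocity jointly (each channel
    normalized by its measurement standard deviation)."""
    load_N = float(ms.meta["load_kg"]) * 9.81
    theta_rest = float(ms.meta["theta_rest_deg"])
    traces = [tr for tr in ms.traces if tr.channel == "theta_deg"]
    if not traces:
        raise StageError("no free-swing angle traces")
    for tr in traces:
        if abs(tr.values[0] - theta_rest) > 3.0:
            raise StageError("free-swing trace does not start at rest")
    lam = 90.0 - theta_rest
    plans, om_meas, sd_th, sd_om = {}, {}, {}, {}
    for tr in traces:
        train = tr.train()
        if train.kind not in plans:
            plans[train.kind] = _Plan(train, "free_swing", tr.t_ms[-1],
                                      cfg.dt, fm_base.R0, fm_base.tauc, tr.t_ms)
        om = _central_diff(tr.t_ms, tr.values)
        om_meas[id(tr)] = om
        sd_th[id(tr)] = max(float(np.std(tr.values)), 1e-6)
        sd_om[id(tr)] = max(float(np.std(om)), 1e-9)
    n_res = sum(2 * tr.t_ms.size for tr in traces)

    def residuals(x: np.ndarray) -> np.ndarray:
        fm_c = fm_base.replace(L_over_I=x[0], FM=x[1], A90=x[2], Km=x[3],
                               tau1=x[4], lam=lam)
        out = []
        for tr in traces:
            plan = plans[tr.train().kind]
            Y, status = plan.run(fm_c, load_N=load_N, theta_rest=theta_rest)
            if status != 0:
                # graded penalty: the earlier the trajectory clamps, the
                # worse — gives the optimizer a slope off the plateau
                frac = status / max(plan.ts.size - 1, 1)
                return np.full(n_res, cfg.clamp_penalty * (2.0 - frac))
            th = plan.sampled(Y, 1)
            # same discrete observation operator as the measurement channel
            om = _central_diff(tr.t_ms, th)
            out.append((th - tr.values) / sd_th[id(tr)])
            out.append((om - om_meas[id(tr)]) / sd_om[id(tr)])
        return np.concatenate(out)

    names = ("L_over_I", "FM", "A90_0", "Km1_0", "tau1_0")
    lb = np.array([cfg.bounds("L_over_I")[0], cfg.bounds("FM")[0],
                   cfg.bounds("A90")[0], cfg.bounds("Km")[0],
                   cfg.bounds("tau1")[0]])
    ub = np.array([cfg.bounds("L_over_I")[1], cfg.bounds("FM")[1],
                   cfg.bounds("A90")[1], cfg.bounds("Km")[1],
                   cfg.bounds("tau1")[1]])
    x0 = np.array([cfg.seeds["L_over_I"], cfg.seeds["FM"], fm_base.A90,
                   fm_base.Km, fm_base.tau1])
    fit = pso_then_lsq(residuals, names, lb, ub, seed=seed, pso=cfg.pso,
                       n_restarts=cfg.n_restarts, x0=x0)
    est = dict(fit.estimates)
    est["lam"] = lam
    spec = FitStageSpec("free_nonfatigue",
                        free={n: (float(l), float(u))
                              for n, l, u in zip(names, lb, ub)},
                        fixed={"a": fm_base.a, "b": fm_base.b,
                               "tau2": fm_base.tau2, "V1": fm_base.V1,
                               "V2": fm_base.V2, "lam": lam},
                        measurements="free_nonfatigue",
                        residual="angle_and_velocity_normalized")
    return StageOutcome("free_nonfatigue", est, fit, spec=spec)


# --------------------------------------------------------------------------
# stage 5: isometric fatigue (per-pair series, then the fatigue ODE constants)
# --------------------------------------------------------------------------

def _fit_testing_pair(pair: tuple[Trace, Trace], plans: dict, L: float,
                      fm_ref: ForceMotionParams, x0: np.ndarray,
                      cfg: IdentificationConfig, seed: int,
                      do_pso: bool) -> np.ndarray:
    """Fit (A90, Km, tau1) of one testing pair with tau2 fixed.  The traces
    must already be clipped to the plans' sampling grids."""

    def residuals(x: np.ndarray) -> np.ndarray:
        fm_c = fm_ref.replace(A90=x[0], Km=x[1], tau1=x[2])
        out = []
        for tr in pair:
            plan = plans[tr.train().kind]
            Y, _ = plan.run(fm_c)
            out.append(plan.sampled(Y, 0) - tr.values / L)
        return np.concatenate(out)

    lb = np.array([cfg.bounds("A90")[0], cfg.bounds("Km")[0], cfg.bounds("tau1")[0]])
    ub = np.array([cfg.bounds("A90")[1], cfg.bounds("Km")[1],
                   cfg.bounds("tau1")[1] * 3])
    if do_pso:
        def scalar(x):
            r = residuals(x)
            return float(r @ r)
        rng = np.random.default_rng(seed % (2**31 - 1))
        small = PSOOptions(n_particles=20, n_iter=40)
        xg, _ = particle_swarm(scalar, lb, ub, small, rng)
        starts = [xg, np.clip(x0, lb, ub)]
    else:
        starts = [np.clip(x0, lb, ub)]
    best_x, best_ssr = None, np.inf
    for xs in starts:
        res = least_squares(residuals, xs, bounds=(lb, ub), method="trf")
        if 2 * res.cost < best_ssr:
            best_x, best_ssr = res.x, float(2 * res.cost)
    return best_x


def _history_from_traces(ms: MeasurementSet, L: float,
                         grid_ms: float = 2.0) -> tuple[np.ndarray, np.ndarray]:
    """Concatenated measured force history of the whole protocol on a uniform
    grid (the traces tile the protocol timeline)."""
    t_all = np.concatenate([tr.onset_ms + tr.t_ms for tr in ms.traces])
    F_all = np.concatenate([tr.values / L for tr in ms.traces])
    order = np.argsort(t_all)
    t_all, F_all = t_all[order], F_all[order]
    grid = np.arange(0.0, t_all[-1], grid_ms)
    return grid, np.interp(grid, t_all, F_all)


def _separable_fatigue_fit(T: np.ndarray, series: dict[str, np.ndarray],
                           baselines: dict[str, float], hist_t: np.ndarray,
                           hist_F: np.ndarray, cfg: IdentificationConfig
                           ) -> dict[str, float]:
    """Fit (alphaA, alphaKm, alphaTau1, tauFat) to the per-pair parameter
    series given a force history.  With ω = 0 the fatigue ODEs are linear in
    state, so each trajectory is baseline + α·J(t; tauFat) (Km additionally
    carries the −α·∫F secular term); the α's are profiled out by linear least
    squares and tauFat found by bounded 1-D search.
    """
    dA = series["A90"] - baselines["A90"]
    dK = series["Km"] - baselines["Km"]
    dT = series["tau1"] - baselines["tau1"]
    sds = {k: max(float(np.std(v)), 1e-12)
           for k, v in (("A", dA), ("K", dK), ("T", dT))}
    cumF = np.concatenate([[0.0], np.cumsum(
        0.5 * (hist_F[1:] + hist_F[:-1]) * np.diff(hist_t))])
    C_T = np.interp(T, hist_t, cumF)

    def components(tau_fat_ms: float):
        w = np.exp(hist_t / tau_fat_ms) * hist_F
        Iw = np.concatenate([[0.0], np.cumsum(
            0.5 * (w[1:] + w[:-1]) * np.diff(hist_t))])
        J_T = np.exp(-T / tau_fat_ms) * np.interp(T, hist_t, Iw)
        XK = J_T - C_T  # Km = Km1 + Km2 regressor
        aA = float(J_T @ dA / (J_T @ J_T))
        aK = float(XK @ dK / (XK @ XK)) if float(XK @ XK) > 0 else 0.0
        aT = float(J_T @ dT / (J_T @ J_T))
        ssr = (np.sum(((dA - aA * J_T) / sds["A"]) ** 2)
               + np.sum(((dK - aK * XK) / sds["K"]) ** 2)
               + np.sum(((dT - aT * J_T) / sds["T"]) ** 2))
        return ssr, aA, aK, aT

    lo = tau_fat_ms_from_s(cfg.bounds("tauFat_s")[0])
    hi = tau_fat_ms_from_s(cfg.bounds("tauFat_s")[1])
    grid = np.geomspace(lo, hi, 40)
    ssrs = [components(tf)[0] for tf in grid]
    k = int(np.argmin(ssrs))
    bl = grid[max(k - 1, 0)]
    bh = grid[min(k + 1, len(grid) - 1)]
    res = minimize_scalar(lambda lt: components(np.exp(lt))[0],
                          bounds=(np.log(bl), np.log(bh)), method="bounded",
                          options={"xatol": 1e-6})
    tau_fat = float(np.exp(res.x))
    _, aA, aK, aT = components(tau_fat)
    return {"alphaA": aA, "alphaKm": aK, "alphaTau1": aT,
            "tauFat_ms": tau_fat}


def fit_iso_fatigue(ms: MeasurementSet, fm_iso: ForceMotionParams,
                    cfg: IdentificationConfig, seed: int) -> StageOutcome:
    """Fatigue ODE constants from the isometric fatiguing protocol.

    Stage 1 fits (A90, Km, tau1) per testing pair (tau2 fixed from the
    non-fatigue stage, warm-starting each pair from the previous one);
    stage 2 fits the ω = 0 fatigue ODEs, driven by the force history of the
    full 225-train protocol, to those 15 series.  The history is initialised
    from the measured forces and, with ``fatigue_history="simulated"``,
    refreshed by re-simulating the coupled protocol with the current fit.
    """
    L = float(ms.meta["L_m"])
    pairs: list[tuple[Trace, Trace]] = []
    traces = sorted(ms.traces, key=lambda tr: tr.index)
    for i in range(len(traces) - 1):
        if (traces[i].role == ROLE_TESTING_50CFT
                and traces[i + 1].role == ROLE_TESTING_VFT):
            pairs.append((traces[i], traces[i + 1]))
    if len(pairs) != 15:
        raise StageError(f"expected 15 testing pairs, found {len(pairs)}")

    t50, tvft = pairs[0][0].train(), pairs[0][1].train()
    t_pair_end = t50.train_duration + cfg.pair_fit_window_ms
    sample_t = pairs[0][0].t_ms
    plans = {
        "CFT": _Plan(t50, "isometric", min(t_pair_end, sample_t[-1]), cfg.dt,
                     fm_iso.R0, fm_iso.tauc, sample_t[sample_t <= t_pair_end]),
        "VFT": _Plan(tvft, "isometric", min(t_pair_end, sample_t[-1]), cfg.dt,
                     fm_iso.R0, fm_iso.tauc, sample_t[sample_t <= t_pair_end]),
    }
    # clip measured traces onto the pair-fit window (grids are uniform, so
    # the clipped traces line up with the plans' sampling grids)
    pairs_w = [(_clip_trace(p50, p50.t_ms <= t_pair_end),
                _clip_trace(pv, pv.t_ms <= t_pair_end))
               for p50, pv in pairs]

    series = {"A90": [], "Km": [], "tau1": []}
    T_mid = []
    x_prev = np.array([fm_iso.A90, fm_iso.Km, fm_iso.tau1])
    for k, (p50, pv) in enumerate(pairs_w):
        x = _fit_testing_pair((p50, pv), plans, L, fm_iso, x_prev, cfg,
                              seed + k, do_pso=(k == 0))
        series["A90"].append(x[0])
        series["Km"].append(x[1])
        series["tau1"].append(x[2])
        x_prev = x
        T_mid.append(0.5 * (p50.onset_ms
                            + pv.onset_ms + pv.train().train_duration))
    for key in series:
        series[key] = np.asarray(series[key])
    T_mid = np.asarray(T_mid)

    baselines = {"A90": fm_iso.A90, "Km": fm_iso.Km, "tau1": fm_iso.tau1}
    hist_t, hist_F = _history_from_traces(ms, L)
    est = _separable_fatigue_fit(T_mid, series, baselines, hist_t, hist_F, cfg)

    if cfg.fatigue_history == "simulated":
        proto_meta = ms.meta.get("protocol")
        protocol = make_fatigue_protocol(
            "isometric", proto_meta["train_duration_ms"],
            first_pair_rest=proto_meta["first_pair_rest_ms"],
            inter_train_rest=proto_meta["inter_train_rest_ms"])
        for _ in range(cfg.fatigue_outer_iters):
            fat_c = FatigueParams(
                alphaA=est["alphaA"], alphaKm=est["alphaKm"],
                alphaTau1=est["alphaTau1"], tauFat_ms=est["tauFat_ms"],
                betaTau1=0.0, A90_0=baselines["A90"], Km1_0=baselines["Km"],
                tau1_0=baselines["tau1"])
            sim = simulate_protocol(protocol, fm_iso, fat_c, dt=cfg.dt,
                                    theta_iso=90.0, store_stride=10)
            est = _separable_fatigue_fit(T_mid, series, baselines,
                                         sim.t, sim.F, cfg)
    est["tauFat_s"] = est["tauFat_ms"] / 1000.0
    spec = FitStageSpec(
        "fatigue_ode",
        free={"alphaA": cfg.bounds("alphaA"), "alphaKm": cfg.bounds("alphaKm"),
              "alphaTau1": cfg.bounds("alphaTau1"),
              "tauFat_s": cfg.bounds("tauFat_s")},
        fixed=dict(baselines), measurements="iso_fatigue",
        residual="parameter_series_vs_ode")
    return StageOutcome("iso_fatigue", est, None,
                        extras={"series": series, "T_mid": T_mid,
                                "baselines": baselines}, spec=spec)


def _clip_trace(tr: Trace, m) -> Trace:
    if isinstance(m, int):
        mask = np.zeros(tr.t_ms.size, dtype=bool)
        mask[:m] = True
    else:
        mask = m
    return Trace(index=tr.index, role=tr.role, channel=tr.channel,
                 mode=tr.mode, onset_ms=tr.onset_ms, fs_hz=tr.fs_hz,
                 t_ms=tr.t_ms[mask], values=tr.values[mask],
                 train_spec=tr.train_spec, rest_after_ms=tr.rest_after_ms,
                 angle_deg=tr.angle_deg, block=tr.block)


# --------------------------------------------------------------------------
# stage 6: the non-isometric velocity coupling betaTau1
# --------------------------------------------------------------------------

def fit_beta_tau1(ms: MeasurementSet, fm_day: ForceMotionParams,
                  fat: FatigueParams, cfg: IdentificationConfig,
                  seed: int) -> StageOutcome:
    """One-dimensional bounded fit of betaTau1 to the free-swinging fatigue
    measurements (angle and central-differenced velocity, each normalized by
    its measurement standard deviation)."""
    load_N = float(ms.meta["load_kg"]) * 9.81
    theta_rest = float(ms.meta["theta_rest_deg"])
    proto_meta = ms.meta["protocol"]
    protocol = make_fatigue_protocol(
        "free_swing", proto_meta["train_duration_ms"],
        first_pair_rest=proto_meta["first_pair_rest_ms"],
        inter_train_rest=proto_meta["inter_train_rest_ms"])
    traces = sorted(ms.traces, key=lambda tr: tr.index)
    om_meas = {tr.index: _central_diff(tr.t_ms, tr.values) for tr in traces}
    sd_th = max(float(np.std(np.concatenate([tr.values for tr in traces]))), 1e-9)
    sd_om = max(float(np.std(np.concatenate(list(om_meas.values())))), 1e-12)

    def sse(beta: float) -> float:
        fat_c = fat.replace(betaTau1=float(beta))
        sim = simulate_protocol(protocol, fm_day, fat_c, dt=cfg.dt,
                                theta_rest=theta_rest, load_N=load_N,
                                store_stride=5, on_clamp="flag")
        total = 0.0
        for tr in traces:
            rec = sim.records[tr.index]
            sl = sim.window(rec)
            t_loc = sim.t[sl] - rec.onset
            th = np.interp(tr.t_ms, t_loc, sim.theta[sl])
            om = _central_diff(tr.t_ms, th)
            total += float(np.sum(((th - tr.values) / sd_th) ** 2))
            total += float(np.sum(((om - om_meas[tr.index]) / sd_om) ** 2))
        return total

    lo, hi = 0.0, cfg.bounds("betaTau1")[1]
    grid = np.linspace(lo, hi, 9)
    vals = [sse(b) for b in grid]
    k = int(np.argmin(vals))
    bl, bh = grid[max(k - 1, 0)], grid[min(k + 1, len(grid) - 1)]
    res = minimize_scalar(sse, bounds=(bl, bh), method="bounded",
                          options={"xatol": max(hi * 1e-4, 1e-8)})
    beta = float(res.x)
    if res.fun > min(vals):
        beta = float(grid[k])
    spec = FitStageSpec("beta_tau1_fit", free={"betaTau1": (lo, hi)},
                        fixed={"alphaTau1": fat.alphaTau1,
                               "tauFat_ms": fat.tauFat_ms},
                        measurements="free_fatigue",
                        residual="angle_and_velocity_normalized")
    return StageOutcome("beta_tau1", {"betaTau1": beta}, spec=spec)


# --------------------------------------------------------------------------
# the full pipeline
# --------------------------------------------------------------------------

@dataclass
class PipelineResult:
    params: dict
    fm_iso: ForceMotionParams
    fm_day: ForceMotionParams
    fat: FatigueParams
    stages: dict[str, StageOutcome]
    seed: int


def _seed_fm(cfg: IdentificationConfig) -> ForceMotionParams:
    s = cfg.seeds
    return ForceMotionParams(A90=s["A90"], a=s["a"], b=s["b"], Km=s["Km"],
                             tau1=s["tau1"], tau2=s["tau2"], V1=s["V1"],
                             V2=s["V2"], L_over_I=s["L_over_I"], FM=s["FM"])


def run_pipeline(sessions: dict[str, MeasurementSet],
                 cfg: IdentificationConfig | None = None, seed: int = 0,
                 beta_mode: str = "fit") -> PipelineResult:
    """Run every identification stage in order on a full set of sessions.

    ``beta_mode``: "fit" identifies betaTau1 from the free-swinging fatigue
    session; "predict" computes it from the other parameters (no
    non-isometric fatigue measurements needed).
    """
    cfg = cfg or IdentificationConfig()
    stages: dict[str, StageOutcome] = {}

    s1 = fit_iso_nonfatigue(sessions["iso_nonfatigue"], cfg, seed)
    stages[s1.name] = s1
    s2 = fit_parabola_ab(s1.estimates["A_by_angle"], s1.estimates["A90"])
    stages[s2.name] = s2

    fm_iso = _seed_fm(cfg).replace(
        A90=s1.estimates["A90"], Km=s1.estimates["Km"],
        tau1=s1.estimates["tau1"], tau2=s1.estimates["tau2"],
        a=s2.estimates["a"], b=s2.estimates["b"])

    s3 = fit_isovelocity(sessions["isovelocity"], fm_iso, cfg, seed + 1)
    stages[s3.name] = s3
    fm_iso = fm_iso.replace(V1=s3.estimates["V1"], V2=s3.estimates["V2"])

    s4 = fit_free_nonfatigue(sessions["free_nonfatigue"], fm_iso, cfg, seed + 2)
    stages[s4.name] = s4
    e4 = s4.estimates
    fm_day = fm_iso.replace(A90=e4["A90_0"], Km=e4["Km1_0"], tau1=e4["tau1_0"],
                            L_over_I=e4["L_over_I"], FM=e4["FM"], lam=e4["lam"])

    s5 = fit_iso_fatigue(sessions["iso_fatigue"], fm_iso, cfg, seed + 3)
    stages[s5.name] = s5
    e5 = s5.estimates

    fat = FatigueParams(
        alphaA=e5["alphaA"], alphaKm=e5["alphaKm"], alphaTau1=e5["alphaTau1"],
        tauFat_ms=e5["tauFat_ms"], betaTau1=0.0,
        A90_0=e4["A90_0"], Km1_0=e4["Km1_0"], tau1_0=e4["tau1_0"],
        tau1_0_iso=s1.estimates["tau1"])

    if beta_mode == "fit":
        s6 = fit_beta_tau1(sessions["free_fatigue"], fm_day, fat, cfg, seed + 4)
        fat = fat.replace(betaTau1=s6.estimates["betaTau1"],
                          beta_source="fitted")
    elif beta_mode == "predict":
        from .fatigue import beta_tau1_from_params

        beta = beta_tau1_from_params(e4["A90_0"], e4["FM"],
                                     s1.estimates["tau1"], e5["alphaTau1"],
                                     e5["tauFat_s"], s3.estimates["V1"])
        s6 = StageOutcome("beta_tau1", {"betaTau1": beta})
        fat = fat.replace(betaTau1=beta, beta_source="predicted")
    else:
        raise ValueError("beta_mode must be 'fit' or 'predict'")
    stages[s6.name] = s6

    params = {
        "A90": s1.estimates["A90"], "a": s2.estimates["a"],
        "b": s2.estimates["b"], "Km": s1.estimates["Km"],
        "tau1": s1.estimates["tau1"], "tau2": s1.estimates["tau2"],
        "V1": s3.estimates["V1"], "V2": s3.estimates["V2"],
        "L_over_I": e4["L_over_I"], "FM": e4["FM"],
        "A90_0": e4["A90_0"], "Km1_0": e4["Km1_0"], "tau1_0": e4["tau1_0"],
        "alphaA": e5["alphaA"], "alphaKm": e5["alphaKm"],
        "alphaTau1": e5["alphaTau1"], "tauFat_s": e5["tauFat_s"],
        "betaTau1": fat.betaTau1,
    }
    return PipelineResult(params, fm_iso, fm_day, fat, stages, seed)
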