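# Methods

## The model

`fesfatigue` simulates and identifies a coupled force–motion–fatigue model of
the electrically stimulated quadriceps driving knee extension.

**Activation.** Each stimulation pulse at time `t_i` injects an impulse into
the normalized Ca²⁺–troponin complex concentration `CN`:

    dCN/dt = (1/τc) Σ_i R_i exp(−(t − t_i)/τc) − CN/τc,      t ≥ t_i only
    R_i = 1 (first pulse),  1 + (R0 − 1)·exp(−(t_i − t_{i−1})/τc) otherwise

`R0 = 2` and `τc = 20 ms` are held constant.  Because this equation is linear
and driven only by the (known) pulse train, the simulator evaluates `CN`
from its exact closed form — a superposition of `R_i·x·e^{−x}` terms with
`x = (t − t_i)/τc` — rather than integrating it numerically.  A single pulse
therefore peaks at `CN = e⁻¹` exactly `τc` after the pulse, which is used as
an analytic self-check.

**Force.** Force near the ankle follows

    dF/dt = (G + A)·CN/(Km + CN) − F / (τ1 + τ2·CN/(Km + CN))

with the force–angle gain `A = A90·[a(90−θ)² + b(90−θ) + 1]` (so `A90` is by
construction the gain at a 90° knee angle) and the force–velocity term
`G = V1·θ·exp(−V2·θ)·ω`.  Knee flexion angle `θ` is 0° at full extension;
extension means `θ` decreasing, so `ω < 0` and `G < 0` (a force loss) while
the leg extends.  `F` is not clamped; a negative total drive `G + A` is
flagged by a diagnostic rather than silently truncated.

**Motion.** The leg distal to the knee is a rigid pendulum:

    θ̈ = (L/I)·[(F_load + FM)·cos(θ + λ) − F]

`FM` lumps the leg weight and all passive resistances, `F_load` is the ankle
load (mass × 9.81 m/s²), and `λ = 90° − θ_rest` makes the resting leg an
equilibrium.  **Units of the lumped L/I:** the fitted values of `L/I`
reported for this model (≈ 5–25 kg⁻¹m⁻¹) are roughly 25–60× larger than
anthropometric estimates (≈ 0.1–0.4 kg⁻¹m⁻¹).  They are consistent with the
bracket being read in newtons and the acceleration in **deg/s²**: under that
convention the leg's natural pendulum frequency is ≈ 1.1 Hz and a 240 ms
50 Hz train produces a tens-of-degrees extension at ≈ 180 °/s peak velocity —
physically sensible — whereas a rad/s² reading would make the limb ~57×
stiffer than physical.  The package therefore evaluates the equation of
motion in deg/s² and converts to its internal deg/ms² (×1e-6).  The unit
mapping is pinned by a test against a fine-step oracle.

**Fatigue.** Three force parameters drift with force and recover with a
common time constant:

    dA90/dt  = −(A90 − A90_0)/τfat + αA·F
    Km = Km1 + Km2;  dKm1/dt = −(Km1 − Km1_0)/τfat + αKm·F;  dKm2/dt = −αKm·F
    dτ1/dt   = −(τ1 − τ1_0)/τfat + (ατ1 + βτ1·ω)·F

This is the simplified form: the two other velocity couplings (βA, βKm) are
removed entirely (an optional legacy mode re-enables them for comparison;
because every β term multiplies ω, isometric trajectories are bit-identical
either way, which is tested).  `Km2(0) = 0` at protocol start, so baseline
Km equals `Km1_0`.  βτ1 is multiplied by the negative extension velocity and
so *counteracts* ατ1, keeping τ1 closer to baseline during non-isometric
fatigue.  It can either be fitted (one bounded 1-D fit) or predicted from
already-identified parameters:

    βτ1 = 8.5e-11 · A90_0^1.6 · FM^0.5 · τ1_0_iso^3.5 · ατ1^1.3 · τfat^0.9 / V1^0.4

The calibration constant is unit-bound; this package declares the inputs as
A90_0 in N/ms, FM in N, τ1_0_iso in ms (the *isometric* session's pre-fatigue
τ1, stored separately from a day's non-isometric τ1_0), ατ1 in N⁻¹, τfat in
**seconds**, V1 in N/deg².  Evaluating the predictor with the representative
parameter set does not reproduce that subject's fitted βτ1 (the predictor is
a population-level correlation, not an identity); the directly evaluated
value is frozen as a regression pin, and no test asserts agreement with a
fitted value.  `τfat` is stored in ms internally and read/written in seconds
at the file interface; both conversions are explicit named functions.

## Simulation

Production integration is fixed-step classical RK4 over a merged event grid
(nominal `dt = 0.2 ms`, pulse times inserted as nodes) — chosen over adaptive
stepping for bit-reproducibility; identical inputs give identical outputs.
CN is exact (closed form); the remaining seven states (F, θ, ω, A90, Km1,
Km2, τ1) are co-integrated as one coupled system, so the fatigue state feeds
the force equation continuously.  Halving `dt` changes peak force and
minimum angle by < 0.1 %, and the production path agrees with an independent
fine-step explicit-Euler oracle (dt = 0.001 ms, CN integrated numerically
from its pulse-sum right-hand side) to < 1e-3 relative error; both are
tested.

Inter-train state policy: fatigue state persists across trains and relaxes
during rests (the fatigue ODEs have no gating); CN and F are reset at a train
onset when the preceding rest exceeds `5·τc` (exact to < e⁻⁵⁰ for the ≥ 1 s
rests used here) and otherwise persist — the carried case superposes the
previous train's pulses into the closed-form CN and is tested against a
single continuous simulation.  In free-swing mode (θ, ω) restart from
(θ_rest, 0) at each train onset.

**Manual-stop emulation.** The model has no damping term, so after a large
extension the freely swinging leg would oscillate and overshoot the
flexion range during the rest (in the experiments the returning leg was
stopped by hand).  The simulator therefore "catches" the leg at the rest
angle the first time it returns there after train end (ω > 0 and θ ≥ θ_rest),
freezing (θ, ω) while force and fatigue states continue to evolve.  The
catch is configurable and off-switchable; with it disabled the undamped
oscillation is visible and tested.  Hyperextension (θ < 0) or θ > 120° still
terminates the simulation with an error (or a flag inside optimizers, where
it becomes a penalty).

## Stimulation protocols

CFTs place singlets at `k·(1000/f)` for all `k ≥ 0` with `t < duration`
(half-open convention); VFTs start with a doublet (5 ms gap) and space
singlets one inter-pulse interval after the doublet's second pulse.  The
fatiguing protocol is 15 blocks of [50CFT, 12.5VFT, 13 × 33CFT] (225 trains;
30 testing, 195 fatiguing); the first testing pair's trains are each followed
by 10 s rests, all other rests are 1 s (isometric) or 1.2 s (free-swing).
The potentiation protocol (twelve 14 Hz, 0.8 s trains, 5 s rests) is
generated but excluded from identification objectives — the model carries no
potentiation term.  Pulse duration (170–600 μs) and amplitude are metadata:
their effects enter only through the measured forces of the session.

## Parameter identification

Stages (each feeding the next):

1. **Isometric non-fatigue** (testing pairs at 15/40/65/90°): τ1 is first
   estimated from the post-train exponential force decline, windowed from
   where modeled CN < 0.01·max(CN) to where force < 5 % of peak.  That
   estimate alone is biased high by ≈ 5 % (the τ2·CN/(Km+CN) term has not
   fully vanished at the window start), so it serves as the initialisation
   and τ1 is refined in the final joint least squares.  The global phase
   searches only (Km, τ2): the force response is linear in A and the
   Michaelis–Menten coupling is angle-independent, so the per-angle A values
   are profiled out analytically from two unit-response simulations per
   evaluation.
2. **Force–angle parabola**: linear least squares of a(90−θ)² + b(90−θ)
   against A(θ)/A90 − 1 (≥ 3 angles required; exact on noiseless data).
3. **Isovelocity** (150 °/s, residuals restricted to the 85°→20° window):
   stimulation force = (stimulated − passive trace)/L; (V1, V2) by PSO +
   least squares.
4. **Free-swing non-fatigue**: (L/I, FM, A90_0, Km1_0, τ1_0) from angle and
   angular-velocity residuals of the 2 testing pairs, each channel
   normalized by its measurement standard deviation.  The modeled velocity
   channel is obtained by central-differencing the model's *sampled* angle —
   the same discrete operator applied to the measurements — otherwise the
   catch kink and 300 Hz sampling bias the noiseless fit by several percent.
   L/I and FM covary (both scale the equation of motion); their joint
   identifiability is flagged as weak rather than failed.
5. **Isometric fatigue**: (A90, Km, τ1) fitted per testing pair (τ2 fixed,
   each pair warm-started from the previous one), then the ω = 0 fatigue
   ODEs — driven by the force history of the full 225-train protocol — are
   fitted to the 15-point series.  Given a candidate τfat the ODEs are
   linear in the α's, which are profiled out by linear least squares; τfat
   is a bounded 1-D search over a log grid.  The force history is
   initialised from the measured forces and refreshed twice by re-simulating
   the coupled protocol with the current fit.  The residual ≈ 2 % bias on
   αA/ατ1 comes from treating the parameters as constant within each
   2-second testing pair.
6. **βτ1**: bounded 1-D fit over the free-swing fatigue protocol (angle +
   derived velocity residuals), or the closed-form predictor (mode
   `predict`), in which case no non-isometric fatigue measurements are used.

The optimizer is a global-best particle swarm (inertia 0.729, cognitive =
social = 1.49445, reflecting bounds) followed by bounded trust-region least
squares, repeated from independently seeded restarts; the maximum pairwise
bound-normalized distance between restart solutions ("restart dispersion")
operationalizes the converged-to-global-minimum check.  `pso_then_lsq`
defaults to swarm 40 / 200 iterations; the pipeline configuration uses
swarm 24 / 60 for its ≤ 5-dimensional stage problems, which the restart
dispersion and recovery tests show is ample once least squares polishes each
restart.  Parameter bounds default to [0.1×, 10×] of physiologic seed values
(sign-preserving for negative rates); all bounds, budgets and seeds live in
`IdentificationConfig`, and every random draw is seeded.

## Synthetic data

The synthetic subject reproduces a representative able-bodied 600 μs session:
A90 = 2.10 N/ms, Km = 0.352, τ1 = 36.1 ms, τ2 = 52.1 ms, a = −4.49e-4,
b = 3.44e-2, V1 = 0.371, V2 = 0.0229, L/I = 9.85 kg⁻¹m⁻¹, FM = 247.5 N;
τfat = 99.4 s, αA = −4.03e-7, αKm = −1.36e-8, ατ1 = 2.93e-5, βτ1 = 8.54e-4.
Session constants: isometric trains 1 s (rests 1 s), free-swing trains
240 ms (rests 1.2 s; per-pulse-duration durations 0.64/0.51/0.36/0.29/0.24 s
are carried as session inputs), 4.54 kg ankle load, θ_rest = 85°,
L = 0.40 m, 300 Hz sampling.  Noise is additive Gaussian on the measured
channels — sd 1 N (force-equivalent, i.e. 1 N × L on the torque channel) and
0.5° on angle — and the velocity channel is always *derived* by central
differencing of the (noisy) angle, never independently noised.

What the generator does *not* emulate: potentiation staircase (the model has
no term for it), electrode-impedance drift, out-of-plane leg motion,
volitional contamination, day-to-day parameter variability, or the
per-subject amplitude tuning that drove experimental excursions to ~70°
(this parameter set yields ~30–45° excursions under the same train
durations).  Passing recovery tests therefore demonstrate the pipeline's
correctness and conditioning under the model's own dynamics — an
inverse-crime design in which simulator and objective share the integrator —
not robustness to structural model error in real measurements.

## Numerical choices and degenerate inputs

- merged event grids deduplicate nodes closer than 1e-9 ms; pulses exactly at
  a node contribute from that node on (Heaviside convention `t ≥ t_i`).
- the pair fits and decay windows guard against empty windows, non-positive
  forces (log-decay fit) and zero-variance channels (divide-by-sd).
- fatigue fitting exponentials `exp(t/τfat)` stay < e⁴⁶ over the 450 s
  protocol for the smallest admissible τfat, within float64 range.
- θ leaving [0°, 120°] raises by default; optimizers receive a flat penalty
  vector instead (flag mode), which the particle swarm treats as any other
  bad objective value.
- zero-fatigue data make τfat unidentifiable (the α's go to ~0 and the
  baseline-pull term has nothing to restore); the separable fit then returns
  α ≈ 0 with τfat at its search optimum, and the recovery harness documents
  rather than asserts τfat in that case.

## Problem sizes

The default test-and-acceptance configuration synthesizes and identifies one
subject end-to-end twice (noiseless and noisy), integrates the 225-train
protocols at dt = 0.2 ms (~1.6–2.3 M RK4 steps per protocol), and runs the
fine-step oracle at dt = 0.001 ms over one contraction.  These sizes were
chosen so the full suite exercises every stage at full protocol length on a
single CPU.

## Known limitations

- The deg/s² reading of the equation of motion is an inference from the
  magnitudes of published fitted L/I values; all internal consistency checks
  pin it, but a different acquisition convention would rescale L/I.
- α-parameter recovery carries a ≈ 2 % structural bias (constant-per-pair
  approximation); βτ1 inherits part of it.
- The βτ1 predictor's calibration constant is treated as given; no attempt
  is made to re-derive it from synthetic populations.
- No antagonist co-contraction, tendon compliance, pennation, or
  out-of-sagittal-plane motion; no potentiation.
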