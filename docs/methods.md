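# Methods

`myostep` simulates and analyzes the motility of a processive,
plus-end-directed actin motor (myosin-5B-like) in two complementary
assay geometries: an unloaded single-molecule TIRF motility assay, and
an ultrafast force-clamp dumbbell assay in which a constant load of
chosen sign and magnitude acts on the motor while it steps. This note
describes the models, the detectors, the numerical choices, and what
the simulators do and do not emulate.

## Conventions

Motor plus-end motion is the positive position direction. Forces are
signed in the motor frame: **assistive < 0, resistive > 0**. Thermal
energy defaults to kBT = 4.114 pN·nm (T = 298 K) and is configurable
everywhere it appears.

## Kinetic model of stepping under load

While attached, the motor is governed by three competing exponential
clocks: forward step, backward step, and detachment. Each rate follows
a Bell-type exponential,

    k_f,b(F) = k0_f,b^± · exp(F · d_f,b^± / kBT)         (signed F)
    k_d(F)   = kd0^±    · exp(|F| · d_k^± / kBT)

with independent parameters on the assistive (−) and resistive (+)
branches; the distance parameter d (nm) measures force sensitivity.
Detachment accelerates with load of either sign, which is why its
exponent uses |F|. At exactly F = 0 the simulator uses the mean of the
two branch rates; the branches are independent empirical fits and need
not meet at zero. Steps advance the position by +36 nm (forward, the
actin pseudo-repeat) or −30 nm (backward). An optional "inchworm"
mixture (off by default) replaces the forward step by 20 nm with a
probability rising sigmoidally toward stall, emulating the trail head
binding one actin monomer short of the next pseudo-repeat.

Realizations are exact Gillespie samples; detachment competes
memorylessly with stepping within a dwell (an explicit modeling
assumption). Useful identities used as test oracles: the
forward/backward step-count ratio converges to k_f/k_b, mean run
duration to 1/k_d, and mean run length to
(36·k_f − 30·k_b)/k_d.

The default parameter values are the reference myosin-5B set recovered
by this package's own fits (see `experiments.REFERENCE` and
`MotorModel` defaults). Note one internal tension in that set: the
stepping-*rate* parameters imply a forward/backward rate ratio below
one at low resistive force, while the step-count *ratio* model has
R ≫ 1 below a ~2 pN stall. These are separate empirical summaries of
the same data with different normalizations; the recovery experiments
sample each model directly rather than deriving one from the other.

## Force-clamp geometry and censoring

The dumbbell oscillates inside a window [0, D]: while the motor is
unbound, the clamp drags it at `drag_velocity` toward one edge,
reversing the force there (triangular wave). Attachment occurs after an
exponential waiting time (nuisance rate, default 1 s⁻¹), at whatever
phase position the ramp has reached (≈ uniform in [0, D]). The force at
the moment of attachment sets the run's signed load: force toward the
plus end is assistive.

Under assistive load the motor walks toward the reversal edge; a run
that reaches it is terminated there and flagged *truncated* — this is
the censoring the run-length correction inverts. Resistive runs move
away from the edge and are not length-limited. The 200-kHz force
feedback is emulated as instantaneous clamping: steps are rendered as
instantaneous plateau changes, with Gaussian position noise per sample
(default σ = 8 nm). No bead–trap–filament mechanics (trap stiffness,
hydrodynamics, feedback latency, Brownian dynamics of the dumbbell) are
modeled; consequently passing tests validate the *analysis chain*, not
instrument physics.

## Run-length correction for assistive loads (window censoring)

Assume the true run length is exponential with mean L (survival
e^(−x/L)) and the attachment position uniform in the window, so a run
longer than x also requires x < distance-to-edge (survival 1 − x/D).
The measured run length then has survival e^(−x/L)(1 − x/D) on [0, D],
density

    p(x) = e^(−x/L) (1/L + 1/D − x/(L·D)),   0 ≤ x ≤ D,

and expectation

    <Lm> = (1/D) [ L² (e^(−D/L) − 1) + L·D ].

<Lm> is strictly increasing in L with supremum D/2, so a measured mean
below D/2 determines L uniquely; `correct_run_length` inverts the
expectation by bracketing + Brent's method (tolerance 10⁻³ nm), with a
series expansion of <Lm> for D/L < 10⁻⁴ to avoid cancellation.
Measured means ≥ D/2 have no finite solution and raise. Uncertainties
propagate by the delta method through the closed-form d<Lm>/dL.
`sample_truncated_run_lengths` draws from p(x) by inverse-CDF bisection
and serves as the independent Monte-Carlo oracle.

## Force-clamp detectors

**Velocity estimator.** Sliding-window least-squares slope (first-order
Savitzky–Golay derivative), window 0.5–2 ms. The velocity noise floor
scales as σ·√(12/n³)/dt, so it depends on both position noise and
sample rate; defaults assume the 200-kHz acquisition.

**Attachment events.** The unbound dumbbell moves at the drag speed
v_ref = |F|/γ; attachment stops it. Events are intervals where the
*velocity drop* v_ref − |v| exceeds a threshold, sustained for at least
`min_duration_s` (default 3 ms; this also rejects the brief speed dips
at the triangular-wave turning points). Gaps inside an event are closed
only when they are high-speed step spikes (deviation < −v_ref/2 in the
gap): a myosin step drives the velocity estimate far *above* the drag
speed for about one window, whereas a genuine detach/re-attach gap
shows drag-speed motion and keeps the events separate.

**Threshold calibration.** On ≥100 simulated motor-free records at the
experiment's noise and oscillation settings, the false-event rate is
monotone decreasing in the threshold; the smallest threshold meeting
the budget (default 1% of records) is selected and then inflated by a
1.5× safety factor (capped below v_ref) because the empirical rate at
the selection boundary underestimates the true tail with ~100 records.
Genuine attachments sit at a velocity drop of the full drag speed for
tens of milliseconds, so the margin costs no sensitivity. Calibration
is unattainable when the velocity noise floor approaches the drag speed
(e.g. low sample rates); `CalibrationError` then reports the best
achievable rate.

**Steps within a run.** Threshold crossings of |v| in either direction
(default 6 robust sigmas of the in-run velocity noise, with a small
floor so noiseless records work) mark transitions; plateaus are the
complement; the signed step size is the difference of adjacent plateau
means and the step time the transition center. Two steps inside one
window merge into a single ~72-nm apparent step; this is why the run
assembler treats amplitudes ≥ 90 nm (more than two merged lattice
steps) as a missed detach/re-attach and splits the run there.

**Run assembly.** Runs are primarily the attachment intervals. Two
post-processing rules make the chain consistent with the generator's
ground truth: oversized steps (≥ 90 nm) split a run; conversely,
detected runs separated by < 3 ms in the same force phase with a
position jump < 90 nm are re-joined (opposing steps within one window
mimic a brief detachment), the jump being recorded as a step when it
exceeds 2 nm. `assemble_runs` also exposes the bare grouping rule
(join iff gap < 3 ms and |size| < 90 nm) for step lists without a
record. On noiseless records the chain reproduces the generator
event-for-event whenever all dwells exceed ~2.5 velocity windows;
sub-resolution events (steps within one window of each other or of a
run boundary) are merged or lost, which is inherent to any
velocity-threshold detector at finite bandwidth.

**Per-force statistics.** Signed-force bins (default edges supplied by
the caller) aggregate run length, duration, velocity, step sizes and
counts. The detachment rate is k = 1/⟨τ⟩ with the propagated error
σ_k = σ_τ·⟨τ⟩⁻², computed, never fitted. Stepping rates are counts per
total attached time. Truncated assistive runs are retained and flagged;
correction happens in the model layer via the censoring inversion, not
by discarding.

## Model fits

Bell fits are nonlinear weighted least squares on the natural scale
(s.e.m. weights when available), with a log-linear weighted regression
(delta-method errors) as a selectable cross-check; starting values come
from the log-linear solution. Non-positive values are excluded with a
warning since the model is strictly positive. The stall force of the
step-ratio model R(F) = R0·e^(−F·d/kBT) is F\* = (kBT/d)·ln R0, defined
for R0 > 1. Michaelis–Menten fits use `scipy.optimize.curve_fit` with
data-derived starting values. Zero-force (unloaded-assay) points are
not included in Bell fits by default.

## TIRF arm: localization, tracking, motility observables

Simulated stacks render each emitter as an *integrated* symmetric
Gaussian (pixel-area integral via erf) at its true sub-pixel center,
plus Poisson shot noise over spot + background; 91-nm pixels and a
130-nm PSF sigma by default. Detection thresholds local maxima at
median + k·σ_MAD (k = 5) with one ROI (half-width ≥ 3 PSF sigmas) per
maximum and plateau-tie suppression. Fitting is least-squares with a
symmetric sampled Gaussian; the center estimate is unbiased for the
integrated-Gaussian data by symmetry. Linking is greedy nearest
neighbor with a per-frame jump bound (ties broken by fit residual), no
gap closing, tracks < 10 frames discarded and counted. Localization
precision is the pooled per-axis standard deviation of an immobile spot
over ≥ 20 frames; a linear trend exceeding twice the residual noise
marks the spot as drifting and invalidates the estimate.

**Run length.** The raw arc length of a noisy track is upward-biased
(each hop adds noise displacement). The estimator builds anchor points
(block means of 5 frames, plus the raw endpoints), estimates the noise
from the radial residual about the anchor polyline (rotation
invariant), then decimates vertices to a minimum spacing of 12 anchor
sigmas before summing segment lengths; the residual inflation is then
below ~1%. Velocity is run length over run duration, per run.

**Unloaded steps.** Trajectories are projected on their principal axis
and segmented by penalized binary change-point detection (BIC-style
penalty 10·σ²·log n, σ from first differences, minimum plateau 3
frames), calibrated so that stepless 4-nm-noise traces produce a false
step in < 1% of traces. Step size is the difference of adjacent plateau
means. Plateau differences above 54 nm (halfway between one and two
lattice steps) are excluded from the single-step mean as unresolved
double steps — two steps whose intervening dwell is shorter than the
minimum plateau merge into one apparent ~72-nm difference; the gate is
the automatic analog of isolating unambiguous stepping events by eye.

**Counts and filters.** Runs per second is a plain ratio. The gliding
filter keeps a filament iff std(v)/mean(v) ≤ 0.33 (boundary inclusive)
and flags non-positive mean velocities.

## Recovery experiments and problem sizes

`myostep.experiments` regenerates the headline quantities end to end at
the reference conditions; `scripts/acceptance.py` runs them from a
single seed (child seeds via `SeedSequence`). Problem sizes were chosen
so sampling error sits comfortably inside each check's band while the
whole script completes in seconds: 6 force levels × 125 runs for the
run-length and detachment fits; 3418 Bernoulli step directions over 6
sub-stall force levels (matching the reference counts of 2729 forward
+ 689 backward); 127 velocities over 6 ATP levels with 15%
multiplicative noise; low-ATP stepping trajectories until ≥ 42 single
steps; and 2400 motility trajectories pooled over 0.3/1/2 µM ATP at
50-ms frames for the run-length ensemble. The low-ATP pooling for the
last experiment is deliberate: with a ≥ 10-frame track filter the
conditional mean of an exponential run length is biased upward by
roughly the censoring length v·(10·Δt), which at these velocities stays
below 2% of the mean; at millimolar ATP the same filter would censor
hundreds of nanometers.

## Known limitations

- No dumbbell mechanics or feedback latency: detector performance on
  real records with correlated bead noise will be worse than on the
  white-noise simulations.
- Linking has no gap closing and assumes sparse fields; dense or
  blinking emitters will fragment tracks.
- Events shorter than the minimum duration (3 ms) and steps within one
  velocity window of each other or of a run boundary are unresolvable
  by construction.
- The filament path in motility analysis is taken from the trajectory
  itself (straight or gently curved); no independent actin-channel
  tracing.
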