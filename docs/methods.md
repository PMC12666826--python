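# Methods

## Scope

`aclrqc` covers the computational layer of the noninvasive mouse
ACL-rupture (ACLR) procedure: the loading protocol and crosshead
kinematics, a forward simulator of load/displacement traces with the four
clinically relevant outcomes (successful rupture, no rupture, tibial
fracture, physeal displacement), a trace analyzer that extracts the
per-procedure QC metric vector, a rule-based outcome classifier, and
cohort-level descriptive reporting. Fixture design, animal handling,
imaging and downstream biology are out of scope, as are inferential
statistics beyond exact binomial intervals and Pearson correlation.

## Crosshead kinematics

Displacement-controlled ramps are modelled as ideal jerk-free
piecewise-constant-acceleration motion: accelerate at *a*, cruise at
*v*max, decelerate at *d* (defaults 650 mm/s², 604.5 mm/s², 10 mm/s,
matching the published performance envelope of the target tester class).
The profile collapses from trapezoidal to triangular when the distance
falls below v²max/(2a) + v²max/(2d) ≈ 0.1596 mm at the defaults. Real
hardware reports slightly different accel timing than the ideal closed
form; we deliberately model the ideal profile because it is reproducible
and analytically checkable, and treat vendor-measured timings as hardware
characteristics, not constraints. The simulator enforces a hard
no-overshoot contract: measured displacement equals the command, so
ultimate displacement never exceeds the 1.5 mm target.

## Joint model

The quasi-static load–displacement law `joint_load(δ)` is piecewise
linear and continuous: a toe region (k_toe, default 5 N/mm, up to
δ_toe = 0.2 mm, i.e. a 1 N plateau equal to the preload), linear
elongation at stiffness k up to the failure displacement, a linear drop of
a fraction f ∈ (0,1] of the failure load over a finite width (default
0.02 mm — "abrupt" at any realistic sampling rate, but finite so event
geometry is well-defined), a flat trough spanning the catch gap, then
catch re-loading at k_catch. Fracture mode forces f = 1 and k_catch = 0
(complete unloading, no catch); physis mode carries an elevated linear
stiffness (bone/fixture engagement rather than the ligament).

Viscoelasticity follows a standard-linear-solid creep law,
d(t) = P·(1/k + ΔJ·(1 − e^(−t/τ))), integrated during the load-controlled
phases as a first-order state driven by the measured load. Load control is
a first-order lag (time constant 50 ms, configurable) rather than a full
PID loop: it is sufficient to reproduce realistic 1–5 % preconditioning
amplitude errors, and its frequency response (gain 1/√(1+(ωτ)²)) provides
an analytic oracle for the amplitude-error metric.

### Ramp-load composition

During the ~150 ms injury ramp the creep state is frozen (its drift over
the ramp is < 10⁻³ mm) and the ramp displacement is treated as the joint
coordinate. Because the 1 N preload has already seated the joint through
its toe region, the residual preload is blended out linearly across the
toe while the piecewise law takes over; with the default calibration
(k_toe·δ_toe = preload) this renders the flat ~1 N shelf seen at ramp
onset on real traces, keeps the load channel continuous, and makes the
failure displacement parameter exactly the displacement-from-ramp-start at
which the trace peaks — which is what the analyzer is asked to recover.

## Default population

`default_population()` ships a documented parameter table calibrated once
so that a large simulated C57Bl/6 cohort reproduces the descriptive ranges
reported for the live procedure: ultimate injury loads generally 9–15 N,
rupture at 0.9–1.3 mm of ramp displacement in ~90 % of animals, higher
failure loads in males than females, weak positive mass–load correlation
(r² ≈ 0.1 pooled), and a 99 % prior of successful rupture (the observed
failures split between unsuccessful ruptures and physeal displacements;
fractures were not observed, so their default prior is 0).

Failure load is the primary per-animal draw (truncated normal, male
12.8 ± 1.65 N on [9.4, 14.85], female 11.6 ± 1.45 N on [9.2, 14.5]); the
failure displacement is derived as δ_toe + (P − P_toe)/k. Deriving
displacement rather than drawing it independently builds in the
anticorrelation between stiffness and failure displacement that is
required for loads and displacements to respect their population ranges
simultaneously. Stiffness draws (male 13.26 ± 1.14 N/mm, female
11.91 ± 1.02 N/mm) are truncated at ±1.8 SD: joints outside that band are
not credible ligament-failure mechanics, and the truncation guarantees
that a successful procedure can never reach the physis classifier's
z ≥ 2.5 stiffness rule. Physis-mode stiffness is set to 1.5× the
population mean (±2 % jitter) rather than 1.5× the animal's own draw —
physeal failure reflects engagement of the long bones and fixture, whose
stiffness varies far less than ligament failure properties. Unsuccessful
(no-rupture) procedures double the creep compliance, emulating improper
limb seating; their failure point lies beyond the commanded ramp.

Covariates: mass (male 26 ± 2.4 g, female 23 ± 2.2 g), age 100 ± 20 days,
with weak linear effects on failure load (0.06 N/g, 0.003 N/day).

### What the generator does and does not emulate

It reproduces the five-phase protocol's load/displacement geometry, creep,
tracking lag, Gaussian load-cell noise (default SD 0.05 N), the four
failure-mode signatures, and sex/covariate structure. It does **not**
model contact mechanics, 3-D kinematics, bone density, rate-dependent
tissue failure, drift or quantization in the transducers, or operator
variability beyond what the parameter distributions carry. Passing tests
therefore demonstrate that the analyzer recovers the truth of *this*
family of traces; on real data the configurable thresholds may need
retuning, which is why every detection parameter lives in
`DetectionParams` and the TOML config.

## Analyzer numerical choices

- **Sampling**: default 1 kHz. The injury ramp then spans ~166 samples;
  event detection needs ≥150.
- **Segmentation**: the logged command-phase channel is used verbatim when
  present; otherwise ramp onset is detected as displacement rate exceeding
  50 % of the commanded ramp rate sustained for 5 samples (then backed off
  to where motion begins), and the other phases are laid out by nominal
  durations anchored to that onset.
- **Rupture detection**: within a 10 ms sliding window, a drop of at least
  max(1 N, 15 % of the running ramp maximum) qualifies; the rupture point
  is the last local maximum preceding the first qualifying drop. The point
  is then refined to sub-sample precision by intersecting the pre-drop
  regression line (last 20 samples) with the steepest falling segment of
  the drop; this removes the half-sample discretization bias (~0.07 N at
  13 N/mm) from both rupture displacement and load.
- **Catch rule**: after the drop trough, either a re-rise of ≥25 % of the
  drop magnitude or a load floor ≥0.5 N counts as a catch; a rupture with
  neither is full unloading (fracture signature).
- **Stiffness**: maximum least-squares slope among load-vs-displacement
  windows with R² ≥ 0.99, windows 0.3 mm wide advancing by their own
  width. Overlapping one-sample strides would let the max-slope rule ride
  noise maxima (measured +2.4 % bias with 4 % tails at the default noise);
  non-overlapping 0.3 mm windows keep the recovery error within ±3 %
  (measured max 2.3 % over 300 seeded simulations). If no window meets the
  R² guard the best-R² window is reported flagged unreliable.
- **Creep**: displacement at the end of the second preload hold minus
  displacement at the first phase-1 sample where load reaches 95 % of the
  preload target. Against the superposition closed form (steps of 1 N at
  t = 0, +1 N at t = 10 s for the 2 N sinusoid mean, −1 N at t = 30 s) the
  measured creep agrees to ≲0.1 % noiseless.
- **Preconditioning amplitude error**: per cycle,
  (|P−3|/3 + |V−1|/1)/2 averaged over cycles. Extrema are located on a
  50 ms moving-average copy (raw noise spikes otherwise masquerade as
  extrema) and valued as ±25 ms raw-signal means, which leaves the
  estimate unbiased by noise (~0.5 % at default noise) and attenuates the
  0.5 Hz signal by <0.1 %.
- **Spring check**: the daily calibration run is analyzed with the same
  pipeline; pass requires stiffness within tolerance of nominal and no
  rupture-like drop (a drop on a spring flags an instrument fault).

## Classifier

Ordered rules: (1) no rupture event → unsuccessful rupture; (2) rupture
with post-drop floor < 0.5 N and no re-loading → tibial fracture;
(3) rupture + catch with stiffness z ≥ 2.5 against the reference cohort →
physis rupture; (4) rupture + catch → successful. Elevated creep
(z ≥ 2.5) raises a positioning warning on any label. The reference is
built from ≥20 known-successful procedures (optionally sex-stratified);
without one, the z-rules are disabled and noted in the fired rules, which
by construction never changes a successful/unsuccessful/fracture call.
On simulated 4-class cohorts (priors 0.85/0.05/0.05/0.05, n = 200) the
classifier is exact without noise and ≥95 % accurate at default noise.

## Problem sizes

The test suite and the acceptance script simulate cohorts of 200–500
procedures at 1 kHz (~41 k samples each); the full suite runs in about
half a minute and the acceptance script in ~20 s on one CPU. These sizes
put Monte-Carlo standard errors well inside the tolerances being checked
(e.g. ±1.3 percentage points on the 90 % displacement-window fraction at
n = 500).

## Known limitations

- The piecewise law has a single failure event; multi-stage partial tears
  are only representable through constructed fixtures.
- Creep during the preconditioning sinusoid is driven by the filtered
  measured load, so the small ripple component of creep (≈1–2 %) is not in
  the closed-form oracle; tolerances account for it.
- The physis/fracture discrimination is purely mechanical; the audible
  "pop" and visual cues used at the bench have no computational analogue.
- Display rounding follows lab convention (one decimal for percentages);
  CSV outputs keep full precision.
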