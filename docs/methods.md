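# Methods

This note documents the models, algorithms and design choices behind
`kneestab`: what each stage computes, why the defaults are what they are,
what the synthetic-data generator does and does not emulate, and the known
limitations a user should understand before trusting numbers on real data.

## Sensor model and conventions

Signals are tri-axial accelerometer (specific force, m/s²), gyroscope
(rad/s) and magnetometer (µT) streams at 500 Hz from two sensors (tibia,
foot dorsum), with the sensor x-axis aligned to the segment's longitudinal
axis, plus vertical ground-reaction force (GRFv, N) at 1000 Hz. Internal
units are SI throughout; the reporting layer converts angular rates to °/s
to match clinical usage. Gravity is fixed at g = 9.80665 m/s². Every
trial is assumed to begin with ≥ 2 s of quiet standing: the static
interval anchors gyro-bias estimation, filter initialisation, and the
squat onset threshold.

## Orientation estimation

The orientation estimator is a quaternion error-state complementary
filter. The gyroscope is integrated each sample; two proportional
corrections are blended into the angular rate before integration:

* gravity correction `k1 · (â × v̂_g)`, where `â` is the normalized
  accelerometer reading and `v̂_g` the predicted body-frame gravity
  direction — gain k₁ = 2.33 s⁻¹;
* heading correction `k2 · ((m̂ × v̂_m)·v̂_g) v̂_g`, the magnetometer
  mismatch projected onto the vertical axis so it can only correct yaw —
  gain k₂ = 7.44 s⁻¹.

k₁ and k₂ are interpreted as feedback gains in 1/s (their dimensionality
is not fixed by the protocol's published description; the values are used
as stated). With k₁ = k₂ = 0 the filter reduces to pure gyro integration;
with very large k₁ it locks onto the accelerometer inclination. A small
initial attitude error decays as exp(−k₁t): a 10° error falls below 1°
within 5/k₁ ≈ 2.1 s, which the test suite verifies.

Initialisation is a deterministic TRIAD fit of the mean accelerometer and
magnetometer vectors over the first still second, so the pitch is exactly
zero at rest and there is no integration drift at t = 0. The magnetic
reference vector is taken from the same fit, making the filter
self-consistent without knowing the local field. Initialisation refuses
accelerometer means more than 50% away from g.

The tibia pitch (`pitch_y`) is the rotation about the sensor y-axis
relative to the initial posture, extracted from the relative rotation
matrix; the sign convention — knee flexion positive — is declared, not
inferred, and an inverted y-axis mounting can be flagged on the recording
to restore it.

Two intrinsic error sources matter downstream and are deliberately not
hidden:

* **dynamic accelerometer error** — during movement the accelerometer
  measures gravity plus motion acceleration; the k₁ feedback cannot
  distinguish them, so the fused pitch carries a transient error of order
  `a_motion/g · √(k₁·dt/2)` plus a slowly decaying residual. With a
  0.15 m sensor lever arm and a 75° squat this is a few tenths of a
  degree at the flexion peak.
* **integration truncation** — first-order quaternion integration leaves
  a ~0.02° residual after a 4.4 s squat even with perfect signals, which
  decays at the filter time constant (~0.43 s).

## Task segmentation

**Single leg squat.** σ(t) is the trailing 10-sample moving SD of the
pitch (20 ms at 500 Hz); the onset is the first sample with
σ > 2·σ_static, where σ_static is the SD of the first 1000 samples. Both
sides carry a ×10 presentation factor that cancels in the comparison (it
is retained only for fidelity to the published form). Peak flexion (EPe)
is the pitch maximum; the end is the first return of the pitch to within
2·σ_static of its onset value, the same scale as the start rule. A signal
that never returns yields the last sample with a warning; a flat signal
raises a no-movement error.

This onset rule has an inherent latency on smooth movement starts: a
raised-cosine squat starts with zero velocity, so the trailing-window
trend grows quadratically, and the threshold cannot fire within 10 ms of
the true onset unless σ_static ≲ 0.002° — below what any fused pitch with
realistic accelerometer noise achieves. At the default simulated noise
the onset fires ~20–40 ms late, and the return rule mirrors that latency.
On noise-free signals recovery is exact to one sample. Users comparing
event times across sessions should treat SLS_start/SLS_end as reliable
only to a few tens of milliseconds; T_tot inherits this as a small
positive-negative cancellation.

**Crossover hop.** Both detectors run on vector norms, which are
rotation-invariant, so no orientation estimate is needed. Take-offs are
the first crossings of d|ω|/dt below −0.6 rad/s² (central differences,
per-second units); landings are the first local maximum of the smoothed
|a|-derivative (jerk) above 7 m/s³ after the take-off, refined to the raw
jerk maximum in a forward window. After each landing a 200 ms refractory
period suppresses the secondary crossings that the landing transient
itself produces (the refractory is shorter than any plausible
flight-plus-contact time). The 100 ms risk window t_risk starts at each
landing; windows are truncated at the recording end with a warning.

Two numerical facts shaped the defaults. First, at 500 Hz the raw
derivative noise floor exceeds both thresholds for any realistic sensor
(e.g. 0.002 rad/s gyro noise gives ~1 rad/s² derivative noise against a
−0.6 rad/s² threshold), so smoothing is mandatory on real data: the
|gyro| derivative uses a 9-sample moving average (≈5σ false-crossing
margin at default noise), the |acc| derivative an 81-sample one. Second,
because the take-off threshold is tiny relative to take-off edge slopes
(~100 rad/s²), the first crossing hugs the corner where the fall begins,
and any symmetric smoother leaks across that corner: the 9-sample window
biases take-offs ~7 ms early, a bias the defaults deliberately keep under
10 ms. The landing refinement step removes the corresponding (much
larger) smoothing lag on the jerk peak because the physical jerk peak
exceeds the raw noise by orders of magnitude. With smoothing disabled,
noise-free signals are segmented to within one sample.

**Countermovement jump.** Body weight is the mean force over the first
0.5 s. The end of the unweighting phase is the first concave-up →
concave-down inflection of GRFv after the force has dropped an onset band
(default 50 N) below body weight — the point of steepest force rise,
where the vertical velocity crosses zero, so that integrating the net
force from there to take-off equals the take-off momentum. The second
derivative is estimated by a cubic Savitzky–Golay fit over 151 samples
(151 ms at 1 kHz), sized so that plate noise of a few newtons leaves the
zero-crossing jitter at ~2–5 ms; because the true second derivative is
close to linear near the crossing, the wide window introduces no bias.
Flight starts when GRFv falls to ≤ 5 N ("zero" with a plate noise floor;
configurable). F_max is the maximum raw GRFv in the segmented window;
AUC_F is the trapezoidal net-force integral over the window divided by
body mass (m/s), which equals the take-off velocity √(2·g·h) by the
impulse–momentum theorem — the physics oracle the tests enforce to 2%.

## Features

All RMS and peak parameters operate on the vector magnitude of the
tri-axial signal (one value per sensor, as in the clinical tables), over
the eccentric phase for the SLS and the second hop's risk window for the
CHT. Only the second hop enters CHT features because first-hop take-off
and last-hop landing technique are highly variable. CHT total duration is
first take-off to final landing.

SLS acceleration parameters (RMS, sway path, sway area) use the
gravity-removed signal: the orientation-predicted body-frame gravity
vector is subtracted per sample, leaving postural acceleration — raw
magnitudes would be pinned near 9.81 m/s² and uninformative at squat
intensities. CHT risk-window parameters use the raw bias-free body-frame
signal (impacts of several g dominate; configurable).

The sway ellipse encloses ≈90% of the tibia y–z acceleration trajectory:
semi-axes √(q·λᵢ) from the sample-covariance eigenvalues, with the
small-sample quantile q = 2(N−1)/(N−2)·F₀.₉₀(2, N−2) by default (the
asymptotic χ²₂ form, 4.60517, is available and the two agree for the
window lengths in practice). Collinear point clouds raise a degenerate-
ellipse error carrying eccentricity 1; the SLS extractor records that
case (SA = NaN, SAecc = 1) rather than failing the trial. Note that the
*sample* eccentricity of a perfectly isotropic cloud is not 0 but
≈ (8/N)^¼ from eigenvalue splitting — about 0.1 even at N = 10⁵.

Sway area is reported in (m/s²)² = m²/s⁴.

## Reliability statistics

The ICC is the single-measure absolute-agreement form from the two-way
ANOVA (subjects random, trials fixed):
ICC = (MSR − MSE)/(MSR + (k−1)·MSE + (k/n)(MSC − MSE)), with the exact
F-based 95% CI (Satterthwaite degrees of freedom) and the F = MSR/MSE
test of ICC = 0. The single-measure form is the default because SEM/MDC
describe a single measurement's error; the averaged-trials form is
exposed via the Spearman–Brown relation. The implementation is verified
against a from-first-principles sums-of-squares oracle (to 1e−12) and
against an independent statistics package.

SEM = SD·√(1−ICC) uses the SD of all n·k trial values — the trial-level
SD is the scale on which a single measurement errs; MDC = SEM·1.96·√2.
Cohort tables take the median over a subject's trials (lower median for
even counts), then mean ± SD across subjects; the LSI is computed per
subject from those medians. Group-level ICC averages over named parameter
families (acceleration-based vs angular-velocity-based) are plain means
of the per-parameter, per-limb ICC cells.

Sample-size planning uses the Walter–Eliasziw–Donner closed form with
two-sided α and nearest-integer rounding; ρ₀ = 0.3, ρ₁ = 0.7, α = 0.05,
power 0.8, k = 3 gives n = 16 (the one-sided variant, 13, is selectable).

## Synthetic data: what it emulates, what it does not

The generator's defaults are the study conditions: 500/1000 Hz sampling,
three trials, seventeen subjects, gyro bias (0.01, −0.02, 0.005) rad/s,
and white sensor noise at datasheet-typical densities for this sensor
class over the full bandwidth — 0.02 m/s² accelerometer, 0.002 rad/s
(≈0.11 °/s) gyroscope, 0.3 µT magnetometer, 2 N force plate.

* **SLS** trials are fully rotationally consistent: a raised-cosine
  flexion profile (smooth, zero end-velocities, analytic derivatives)
  drives the gyroscope, the rotated gravity vector plus the lever-arm
  motion term drives the accelerometer, and a constant earth field
  rotated into the sensor frame drives the magnetometer. Band-limited
  (~3 Hz) postural-sway acceleration of 0.5/0.15 m/s² (medio-lateral /
  antero-posterior) is added on the tibia transverse plane during
  movement.
* **CHT** trials emulate the *magnitude morphology* the detectors key on:
  |ω| rises through each push-off and falls sharply only at take-offs;
  each landing injects a 28 ms raised-cosine acceleration rise (foot peak
  120 m/s², tibia 80 m/s² with a damped 30 Hz oscillation). Channel-level
  3-D rigid-body consistency is *not* enforced — segmentation and
  risk-window features operate on norms, which are rotation-invariant, so
  this sacrifices nothing the pipeline measures. Ground-truth take-offs
  are the analytic −0.6 rad/s² crossings; landings the analytic jerk
  peaks.
* **CMJ** traces are built from a cubic net-acceleration polynomial
  solved (deterministically) so that force reaches zero exactly at
  take-off, take-off velocity equals √(2·g·h), and the vertical velocity
  is zero exactly at the force curve's single inflection — making the
  impulse–momentum identity hold by construction from the ground-truth
  unweighting end. Flight force is exactly zero; a landing spike and
  settling follow.
* **Cohorts** draw per-parameter subject means N(μ, σ_b²) and trial
  values N(subject mean, σ_w²), so the true single-measure ICC is
  σ_b²/(σ_b²+σ_w²). Default σ_b/σ_w splits are derived from typical
  healthy-cohort SDs and test-retest ICCs of these parameters.

What passing tests on this generator show: the detectors recover events
at their design accuracy under realistic noise, the feature definitions
are correct against analytic oracles, and the reliability statistics
recover known variance structure without bias and with nominal CI
coverage. What they do not show: robustness to soft-tissue artifact,
magnetometer disturbance indoors, inter-subject technique variation
beyond amplitude scaling, sensor mounting error beyond a declared y-flip,
or any biofidelic joint kinetics — none of which the generator models.

## Numerical choices and degenerate inputs

Derivatives are central differences scaled by the sampling rate (the
thresholds are in per-second units). Moving averages are centred with
reflected edges. Problem sizes in the validation suite — 100 trials per
task for event accuracy, 200 replicate cohorts of n = 100 for ICC
recovery, 10⁵ points for ellipse coverage — were chosen so the whole
suite completes in about a minute on one core while keeping Monte-Carlo
standard errors well inside the asserted tolerances. All random draws
flow from explicitly passed seeds; identical configuration and seed give
bit-identical signals, and the pipeline writes byte-identical reports for
identical inputs.

Degenerate inputs fail loudly and specifically: too-short still windows,
non-gravitational initialisation, flat pitch (no movement), unpaired
take-offs (with the detected events attached to the error), fewer than
two hops, force never reaching the flight threshold, zero total variance
in an ICC matrix, and a zero dominant-limb value in the LSI each raise a
dedicated exception; per-trial failures are recorded and skipped by the
pipeline, which fails only if every trial fails.

## Known limitations

* SLS onset/end timing carries the detector latency discussed above;
  EPe (peak flexion) is substantially more accurate. Reliability
  statistics of SLS temporal parameters on real data inherit this.
* The complementary filter's dynamic error during vigorous movement is
  bounded but not zero; parameters derived from orientation (pitch,
  gravity-removed acceleration) are correspondingly approximate during
  high-acceleration phases.
* CHT take-off detection is biased ~7 ms early by the necessary
  smoothing; flight/contact times shift accordingly (consistently, so
  differences between sessions are unaffected).
* The F_max/AUC_F stage models one force signal per limb trial; summing
  or splitting across two plates is the caller's responsibility.
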