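# Methods

`chestgait` implements a complete desk-scale version of a single-sensor
gait validation analysis: a synthetic study generator, a trunk-accelerometer
gait-extraction pipeline, and the agreement/inference statistics used to
compare a chest-worn device against a lumbar reference. This note records
the models, the parameters that matter, the numerical choices, and what the
synthetic data can and cannot establish.

## The signal model and its inversion

Walking is modelled with the inverted pendulum: during each step the stance
leg vaults the centre of mass (CoM) over an arc of length `l` (the pendulum
length). Given a step length `sl`, the vertical CoM excursion is

    h = l - sqrt(l^2 - (sl/2)^2),        equivalently   sl = 2*sqrt(2*l*h - h^2).

The generator runs this model forward: from a true gait speed `v` and
stride time `T`, `sl = v*T/2`; the vertical displacement is a sinusoidal
arc at the step frequency `2/T` with peak-to-peak amplitude `h`, whose
minima define the initial contacts; the sensor reads its second derivative
plus gravity, in units of g. The anterior-posterior and mediolateral
channels carry low-amplitude harmonics (25% and 15% of the vertical dynamic
amplitude, at step and stride frequency) so the recording is genuinely
tri-axial. Final contacts are placed at 75% of the step period after each
initial contact, which is where the event detector's second transform peaks
for this signal family; they are carried in the ground truth for
completeness but no spatial quantity depends on them.

The pipeline inverts the same model, so estimator correctness is exactly
testable: a perfect pipeline recovers the generator's parameters. This
circularity is deliberate and is the main caveat of every end-to-end
number: recovery errors of ~0.5% on synthetic data say the implementation
is faithful to the model, not that the model matches human gait.

## Generator parameters

| parameter | default | why |
|---|---|---|
| subjects x visits | 20 x 2 | study design being emulated |
| sampling rate | 128 Hz | study design |
| normal-pace speed | 1.25 +/- 0.15 m/s (between-subject SD) | healthy self-paced walking |
| slow/fast multipliers | 0.75 / 1.25 | bracket of self-paced range |
| stride time | 1.05 +/- 0.08 s | healthy range; scaled by 1/sqrt(multiplier) across paces |
| sensor noise | chest 0.02 g, lumbar 0.015 g | chest harness is less stable than a lumbar belt |
| chest amplitude bias | 0 m/s | no device effect unless injected |
| visit retest correlation | 0.8 | bivariate-normal coupling of subject parameters |
| pendulum length | 0.53 x height (lumbar), 0.72 x height (chest) | anthropometric convention |
| orientation jitter | 2 degrees SD per recording | exercises vertical-axis estimation |
| walking tasks | 30 s continuous | roughly three lab-walkway laps |
| activity sessions | 7 min in-lab (40% walking), 20 min outside (50%) | free-living emulation |

Each location's signal amplitude is generated from its own pendulum length
(the generator inverts the reconstruction per location), so chest and
lumbar share identical ground-truth kinematics and their extracted
endpoints are directly comparable. With equal sensor heights, zero noise
and zero bias the two channels are bit-identical.

Randomness derives from a single study seed through `numpy` seed-sequence
spawning (one stream per subject, then per visit/task/location), so adding
subjects does not perturb existing ones and every output is byte-reproducible.

## Extraction pipeline

1. **Vertical axis.** The gravity direction is the mean specific-force
   vector; a proper rotation maps it to +z. Recordings whose mean
   magnitude is below 0.5 g are rejected (no stable gravity direction).
2. **Bout detection.** Non-overlapping 3 s windows are scored by a logistic
   rule on three features of the vertical channel: log10 RMS of the dynamic
   component, fraction of spectral power in the 0.5-3 Hz locomotor band,
   and the autocorrelation peak in the 0.25-1.2 s lag range. The
   coefficients (-6, 0.5, 6, 6) were calibrated once on simulator output
   and are frozen in the configuration; the rule is transparent and
   swappable. Adjacent positive windows merge into maximal bouts with
   boundaries on the window grid — so a bout boundary is only ever resolved
   to 3 s, which bounds the achievable overlap with truth for short bouts.
3. **Contact events.** Per bout, the de-meaned vertical acceleration is
   integrated (trapezoid) and smooth-differentiated by a continuous wavelet
   transform with the first derivative of a Gaussian (`gaus1`), at the
   scale whose pseudo-frequency is 1.25x the dominant step frequency
   (estimated by Welch in 0.5-3 Hz). Minima of the transform are initial
   contacts; the transform is differentiated and re-transformed and its
   maxima give final contacts, one kept per inter-contact interval.
   Segments with less than 10% of their power in the locomotor band return
   empty events with a warning.
4. **Spatial reconstruction.** For each step (between consecutive initial
   contacts) the vertical acceleration is double-integrated to displacement
   and `h` is its peak-to-peak range. Drift is controlled per step: the
   segment mean is removed before each integration and a linear trend from
   the final displacement. A fixed very-low-cutoff high-pass was rejected
   for this stage: on 10-60 s bouts the impulse response of a 0.1 Hz
   4th-order zero-phase filter is longer than the data and its edge
   transients dominate the metre-scale double integral; per-step
   integration recovers an analytic excursion to <0.5% instead. An
   optional high-pass remains available via `highpass_cutoff_hz`.
5. **Strides.** A stride spans initial contacts (i, i+2); its length is the
   sum of the two step lengths `2*sqrt(2*l*h - h^2)`; speed is length over
   time and cadence is `120/stride time`. Strides with infeasible geometry
   (h >= l) or outside the plausibility guards (stride time 0.4-2.25 s,
   length 0.3-3 m) are dropped and counted. The pendulum length comes from
   recording metadata, with anthropometric defaults per wearing location.
6. **Endpoints.** Per subject/task/visit the median over all pooled strides
   (pooling across bouts rather than averaging per-bout medians — the
   simpler convention, flagged as an assumption); then the mean across
   visits, with single-visit cells passing through unchanged. The 95th
   percentile of gait speed (linear-interpolation quantile) is computed for
   activity sessions only.
7. **Bout accounting.** For the outside-lab sessions, bouts shorter than
   9 s or with fewer than 4 complete gait cycles are discarded before
   computing per-recording statistics (count, mean duration, total walking
   time, total steps). k initial contacts count as (k-1)//2 cycles. This
   filter applies to the bout-comparison analysis only, not to endpoint
   computation (configurable).

The pipeline holds no random state: identical input and configuration give
identical output.

## Agreement statistics

* **Bland-Altman**: bias = mean(test - ref), LoA = bias +/- 1.96 SD of the
  differences; bias CI from the t distribution, LoA CIs from the standard
  variance `SD^2 (1/n + 1.96^2 / (2(n-1)))`.
* **Error metrics**: mean absolute difference; mean percent error with the
  reference (not the pair mean) in the denominator, since the comparison is
  against reference devices. Zero-reference pairs are excluded with a warning.
* **ICC(2,1)**: single-measure, two-way random effects, absolute agreement,
  from explicitly computed ANOVA mean squares, with the F-based
  (Shrout-Fleiss style) 95% interval using a Satterthwaite denominator df.
  Negative values are admissible and returned as-is. Single-measure rather
  than average-measure is the default because one device's endpoint is a
  single measurement; it is switchable by transposing the question, not a
  hidden option. Benchmarks: <=0.4 poor, <0.6 moderate, <0.75 good,
  otherwise excellent.
* **Pearson r** with the usual t-based two-sided p.
* **Test-retest**: ICC(2,1) on the subjects x 2-visits matrix plus Pearson r.

## Mixed-effects layer

Endpoint values (not difference scores — pairwise device differences are
read off the contrasts, which is what a least-squares-means table reports)
are modelled as

    value ~ device * task + age,   random intercept per subject,  REML.

Type-III tests use sum-to-zero contrasts enforced internally regardless of
input coding; each term is tested with a Wald F using the REML covariance.
Degrees of freedom use the residual approximation (n_obs - p); a
Satterthwaite approximation is not available in the fitting backend, and at
this package's balanced designs the residual df is large (>100) so the two
are practically indistinguishable — calibration checks below confirm it.
Post-hoc least-squares-mean device contrasts are computed per task level at
the mean age, with t-based CIs; no multiplicity correction by default
(Holm available). Alpha is fixed at 0.05. A singular or non-converged fit
triggers a flagged refit with a constrained variance structure.

Calibration is verified by simulation at the endpoint level (the generative
process of the model itself, bypassing the signal pipeline): with no device
effect the device F-test rejects at ~5% (5.1% over 1000 replicates during
development; the shipped check uses 200), and the contrast CI covers an
injected -0.10 m/s chest bias ~95% of the time.

Paired t-tests compare per-subject, visit-averaged bout statistics between
devices, with exact-tie handling (all-zero differences give t = 0, p = 1).

## What the synthetic data does not show

The generator contains no turning, no double-support dynamics, no soft
tissue artefact, no pathological gait, and its non-gait segments are
simple (quiet sitting and aperiodic noise bursts). Passing tests therefore
demonstrate internal consistency — the estimator inverts the assumed model
correctly, the statistics match their definitions, and the whole chain is
deterministic — not field accuracy on human data. In particular the
near-perfect end-to-end recovery (<1% error) is a property of the matched
model pair and should not be read as an expected real-world error.

## Problem sizes and tolerances

The shipped checks use: 20 seeds x 20 s walks for event detection
(match tolerance 50 ms); a 20-subject x 2-visit x 3-speed study at 0.02 g
noise for recovery and location equivalence; 100 random 20x2 fixtures for
oracle equivalence at 1e-10; 200 replicates each for type-I error and CI
coverage; and a 5-subject demo for byte-level determinism. Fixture sizes
were chosen so the whole suite runs in a few minutes on one core.
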