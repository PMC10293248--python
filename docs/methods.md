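# Methods

This note documents the models, conventions and numerical choices behind
`spiraldx`, in the order data flows through the package.

## Coordinate and unit conventions

Recordings are multivariate time series (t, x, y, force). The package fixes
coordinates in centimetres with the origin at the spiral centre and y up;
timestamps in seconds from the first sample; force dimensionless with 1 equal
to an average pen input. The acquisition format of the original tablet
application is not modelled — whether a device exports points or centimetres
is a property of the export pipeline, and the centimetre convention here is a
package choice that every downstream quantity (distances in cm, velocities in
cm/s) depends on.

## Spiral geometry and the distance series

The template is the Archimedean spiral r(θ) = b·θ with b = R/(2π·L) chosen so
that after L = 4 loops the radius is exactly R = 3.75 cm. A drawn trajectory
is reduced to the **signed radial deviation** d_i = r_i − b·θ_i, where r_i is
the sample's distance to the centre and θ_i its unwrapped polar angle. This
is deliberately *not* the nearest-point Euclidean distance: the signed radial
form is what makes "inside the template" negative, and is the only
definition under which an inward deviation and an outward deviation of equal
size are symmetric around zero. Tracing the template exactly yields the
all-zero series to machine precision, and a purely radial perturbation
A·sin(2πft) is recovered in d exactly — both are enforced by tests.

**Centre singularity.** The polar angle is numerically meaningless at the
origin. Samples within 0.5 mm of the centre take their measured atan2 angle
snapped to the 2π-branch nearest the last reliable unwrapped angle, and do
not advance that reference. For clean data this is exact (so the
zero-distance fixed point survives); for noisy data it bounds the error a
centre crossing can inject to one branch width instead of letting it seed
spurious whole turns.

**Orientation.** Spirals must run centre → outwards. The check compares the
mean radius over the first versus last 10 % of samples (robust to start/end
jitter); an inward recording is reversed with timestamps t'_i = t_last −
t_{n−1−i}, which preserves every inter-sample duration and therefore every
velocity. The operation is idempotent (property-tested).

## Artefact filtering

Two rules, applied in a fixed, logged order (reversal check → distance series
→ filtering → per-repetition features → repetition mean → arm selection):

* **Time-dependent series** (velocity, force, coordinate sequences, the FFT
  input) drop the first and last floor(0.10·n) samples — pen drop and lift
  dominate the variance at the edges.
* **Time-independent summaries** (max/mean/std of the distance series)
  instead remove the floor(0.05·n) values with the largest |d| — magnitude
  ranking treats inward and outward pen slips symmetrically.

floor() is used for both counts because it never over-removes on short
recordings. Repetitions within an arm are combined by their arithmetic mean
(a single repetition passes through); the arm whose clipped distance series
has the larger population standard deviation — the stronger affected side —
supplies the motor features. Ties break deterministically to the right arm.
Whether the original assessment averaged repetitions before or after arm
selection is ambiguous; this package always averages within arm first, then
selects the arm, and documents that as its fixed convention.

## Features

Fourteen model inputs per participant:

| group | features |
|---|---|
| non-motor | QYes — count of yes answers on the 30-item PDNMS |
| precision | F1c DistanceFFT, F2 MaxDistance, F3 MeanDistance, F4 StdDevDistance, F5 ChangeOfRadiusDirection, F6/F7 ChangesOfDirectionX/Y |
| force | F8 MeanForce, F9 StDevForce, F10 MedianForce |
| time | F11 TimeOfDrawing, F12 MeanVelocity, F13 StdDevVelocity |

Conventions worth stating:

* **F1c** is the only feature consuming both arms: per side, the clipped
  distance series is linearly resampled onto a uniform 240 Hz grid (an FFT
  requires uniform sampling; real timestamps jitter), transformed with a real
  FFT, the amplitude spectrum restricted to 3–15 Hz is averaged within 20
  equal-width bins (0.6 Hz each), and the population std over the 20 bin
  values is taken; F1c is the absolute between-side difference of that std —
  a laterality measure. Note the direction of the effect: a single dominant
  tremor line produces a *high* std across bins (one outlier bin), so a
  strongly lateralized tremor gives a large F1c.
* **F2/F3** are max/mean of |d| (deviation magnitudes); **F4** is the std of
  the signed series (sign-invariant anyway).
* **F5–F7** count sign changes in consecutive nonzero differences of the
  radius/x/y sequences; zero differences are skipped so plateaus do not
  create phantom reversals. For a tremor-dominated trace F5 grows roughly
  like 2 × tremor frequency × duration, which is why it discriminates slower
  PD tremor from faster tremor of other disorders.
* **Velocity** follows the discrete difference quotient with v_0 defined as
  0. The velocity series is computed on the full recording and then clipped
  10 % per end, so the artificial v_0 never enters F12/F13. All variances in
  the package are population (divide-by-N) variances; F13 is the square root
  of one.
* **F11** is the total drawing time of the unclipped recording.
* The **log transform** log(v + 1e−9) exists for visualization only
  (boxplots); features enter the classifier untransformed.

## Univariate statistics

Task labels are encoded 0/1 with the disease group positive, so a positive
Spearman rho means the feature rises with disease. Mann–Whitney-U tests are
two-sided (conservative; sidedness is a convention): exact enumeration when
both groups have ≤ 12 members and the pooled values are tie-free, otherwise
the tie-corrected normal approximation; the two branches agree to |Δp| ≤ 0.01
at the crossover (tested). If all pooled values are identical the test is
degenerate and p = 1 is reported. With 14 features the Bonferroni-corrected
level is 0.05/14 ≈ 0.0036, and the annotation ladder is
ns > 0.05/c ≥ * > 0.01/c ≥ ** > 0.001/c ≥ *** > 0.0001/c ≥ ****.

## Classification

Each task is evaluated by stratified fivefold cross-validation (fold class
proportions within one participant of the global ones, seeded and
deterministic). Per training fold, the 13 tablet features are standardized
and reduced by PCA retaining 95 % of variance; **QYes is standardized but not
passed through PCA** — dimensionality reduction is a treatment of the
correlated drawing features, and folding the single questionnaire count into
it would smear its signal across components. Scaler and PCA are refitted on
every training fold; a regression test asserts that a deliberately leaky
variant (preprocessing fitted on all data) changes the predictions. The
learner is an XGBoost gradient-boosted tree ensemble at library defaults,
single-threaded for bitwise reproducibility; class assignment thresholds the
positive-class probability at 0.5. Reported metrics are accuracy, precision,
recall and F1 of the positive (disease) class, averaged over folds. The
majority-class dummy baseline is evaluated under the same stratified CV; at
the default cohort sizes (27/24/26) it gives 0.53 / 0.65 / 0.52 for the
three tasks. The ablation suite compares dummy, questionnaire-only,
tablet-only and integrated feature sets per task.

## Shapley-value importances

Feature importances must be attributable to named features, but the fitted
pipeline predicts from PCA components. Per fold, a companion booster with
identical hyperparameters is therefore trained on the standardized,
*unreduced* training features and explained instead; the CV metrics always
come from the PCA pipeline.

Attributions are **exact interventional Shapley values** computed by full
coalition enumeration: with p ≤ 14 features there are at most 2^14 = 16 384
coalitions, so the Shapley sum is evaluated exactly in float64 against a
seeded background of 8 training rows, on the log-odds scale. Exactness buys
two things: the additivity identity Σφ + base = model output holds to
machine precision (tested at 1e−6, observed ~1e−15), and there is no
sampling noise in the importances. The implementation is validated against
the closed-form Shapley values of a linear model. Features are *ranked* by
the mean |φ| over test samples (signed means cancel for features whose
effect is symmetric across classes); the signed per-fold means are what the
importance boxplots display, one distribution over the five folds per
feature.

## Error analysis

Pooled out-of-fold predictions define the misclassified subgroups: false
positives and false negatives per task, with Task 2's false negatives split
by true subgroup (PD/DD). Per subgroup the report carries count, mean age,
female count, mean QYes and the mean Hoehn–Yahr stage over members with a
defined stage; empty subgroups report count 0 and blank statistics.

## Synthetic cohort generator

The generator defines the study conditions under which the pipeline is
tested; it emulates statistical structure, not biomechanics.

**Drawing model.** The sweep angle follows θ(t) = θ_max·√(t/T) — the
constant-linear-speed parametrization of an Archimedean spiral — over a
duration T sampled per participant. Three disturbances act on the radius:
a tremor component A_side·sin(2πft + φ); band-limited motion noise (white
Gaussian noise smoothed with a 25 ms kernel, ≈ 6 Hz low-pass, rescaled to
the participant's level); and 3× noise over the first/last 8 % of samples
standing in for pen placement and lift. Band-limited noise is a deliberate
modelling decision: white per-sample noise would flip the sign of nearly
every consecutive difference, turning the direction-change counts F5–F7 into
pure noise counters and erasing the tremor-frequency signal they are meant
to carry. Each participant's noise levels are drawn lognormally (σ = 0.3)
around the group level — without between-subject spread the std-type
features would be near-constant within a group and degenerate into perfect
class separators. Timestamps tick at 240 Hz with ±3 % jitter; force is the
participant's level plus smoothed noise, clipped at 0.

**Laterality.** The configured tremor power splits between sides:
A_side = A·√(2s), with s the affected side's power share (0.5 = symmetric).

**Phenotypes** (defaults; per-participant values sampled around them):

| parameter | CG | PD | DD |
|---|---|---|---|
| tremor frequency (Hz) | 4–12 (irrelevant) | 4–6 | 5–10 |
| tremor amplitude (cm) | 0.025 ± 0.015 | 0.10 ± 0.05, floor 0.03 | 0.10 ± 0.05, floor 0.03 |
| power share, affected side | 0.5 | 0.8 | 0.5 |
| draw duration (s) | 25 ± 5 | 32 ± 7 | 28 ± 6 |
| force level | 1.00 ± 0.12 | 0.90 ± 0.20 | 0.95 ± 0.18 |
| motion noise sd (cm) | 0.05 | 0.05 | 0.05 |
| PDNMS yes-probabilities | 0.02–0.18 (mean 0.10) | 0.20–0.60 (mean 0.40) | same as PD |
| age (years) | 58 ± 10 | 68 ± 8 | 58 ± 9 |
| female probability | 0.37 | 0.667 | 0.541 |

PD's slower, strongly lateralized tremor and longer draw encode rest tremor
and bradykinesia; DD mixes faster, essentially bilateral tremor (essential
tremor and related phenotypes) with the *same* elevated non-motor profile as
PD, so the questionnaire separates disease from control (Tasks 1–2) but not
PD from DD (Task 3) — the structure the three tasks assume. PD participants
receive a Hoehn–Yahr stage drawn from a fixed stage distribution
(1:3, 2:4, 2.5:5, 3:7, 4:3, 5:2 per 24). One integer seed determines every
byte of a cohort.

**What the generator does not model** — and hence what passing tests do not
show about recorded data: pen lifts and stroke re-joins (edges are only
noisier, never missing), tremor that is non-sinusoidal or non-stationary,
amplitude–frequency coupling, correlated answers within questionnaire
domains, medication state, and any age–phenotype dependence. Classifier
accuracies on synthetic cohorts characterize the pipeline under its own
assumptions; they are not estimates of clinical performance.

## Problem sizes and determinism

Default test and acceptance computations use the default cohort (77
participants, ~25–32 s recordings at 240 Hz), 100 simulations for the
parameter-recovery rates, and 20 cohort seeds for the ablation-ordering
property; the acceptance script averages the ablation table over 5 cohorts.
Every stochastic component threads a single `numpy.random.default_rng` seed;
CV fold assignment, the learner and the Shapley background subsample are
seeded from the model config, so identical configs give identical CSV/JSON
artifacts byte for byte.

## Known limitations

* The signed radial distance is an interpretation; a nearest-point metric
  would differ for strongly non-radial deviations (e.g. along-track lag).
* Feature naming follows the feature-group definitions (F9 StDevForce,
  F13 StdDevVelocity); summary tables in related literature occasionally
  swap these two labels.
* Exact Shapley enumeration scales as 2^p and is capped at p = 16; the
  package's feature set (14) is within the cap by construction.
* With fewer than ~13 training samples per class, PCA retaining 95 %
  variance can keep more components than the folds can support; the CV
  refuses classes smaller than the fold count rather than silently
  degrading.
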