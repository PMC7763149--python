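# Methods

This note documents the models, conventions and design choices behind
`finbeat`, in the order the pipeline runs.

## Signal model of the synthetic sessions

Real validation datasets for this problem pair a 10 Hz, ±2 g tri-axial
accelerometer stream from a tagged benthic shark with a video-coded
behaviour track. No such dataset is publicly deposited, so the package
ships a generator whose output carries the statistical signatures the
analysis depends on, and nothing more.

Each session is a sequence of single-behaviour events. Labels are drawn
from stationary relative frequencies with self-transitions excluded
(the previous label's weight is set to zero and the rest renormalised);
dwell times are uniform per behaviour; the last event is truncated at
the session end. Within an event the signal on each axis is

    a(t) = g·u  +  A sin(2π f (t − t_event))·e_axis  +  ε(t),

a constant gravity posture `u` (unit vector, device frame), an optional
sinusoid of amplitude `A` (g) and frequency `f` (Hz) on one axis with
phase restarting at the event boundary, and white Gaussian noise of
standard deviation σ (g), all clipped to ±2 g (clipping is logged).

Default regime parameters (all artifact choices — the source study
reports no quantitative amplitudes or frequencies — fixed once to
reproduce the qualitative ordering of dynamic body acceleration:
vertical swim ≫ swim ≫ rest):

| behaviour     | posture u  | axis | f (Hz) | A (g) | σ (g) | dwell (s) | weight |
|---------------|-----------|------|--------|-------|-------|-----------|--------|
| rest          | (0,0,−1)  | —    | —      | 0     | 0.01  | 10–60     | 0.30   |
| swim_column   | (0,0,−1)  | y    | 0.7    | 0.2   | 0.03  | 10–60     | 0.19   |
| swim_floor    | (0,0,−1)  | y    | 0.7    | 0.2   | 0.03  | 10–60     | 0.19   |
| vertical_swim | (−1,0,0)  | y    | 1.2    | 0.6   | 0.05  | 2–10      | 0.12   |
| chew          | (0,0,−1)  | x    | 3.0    | 0.1   | 0.02  | 2–5       | 0.20   |

The two swim labels are generated from identical parameter blocks on
purpose: the swim-merge test then has a true-null instance. The
vertical-swim posture moves gravity from the −z to the −x device axis,
i.e. a ~90° pitch shift, its defining signature. Chewing is small fast
x-axis pulses on a resting posture.

Dwell times and weights were set so that, at the default study size
(4 sessions × 600 s), every behaviour yields enough events for an
event-level 80/20 split and enough epochs per class for stratified
10-fold cross-validation at both epoch lengths. Chew bouts are kept the
shortest behaviour (2–5 s) but long enough that whole 2 s windows fit
inside them; with sub-2 s bouts the four-class analysis would be
impossible at the 2 s epoch even though the reference study reports it.
Optional `other` / `out_of_camera` regimes (off by default) exercise the
exclusion rules.

What the generator deliberately does not emulate: tailbeat kinematics
beyond a sinusoid, tag slippage, inter-individual variation, gradual
transitions, autocorrelated sensor noise, or any overlap between regime
distributions. Consequently the classifiers separate the synthetic
classes almost perfectly; passing pipeline tests demonstrates the
machinery (splitting, resampling, tuning, scoring) is correct, not that
real shark behaviours are this separable — the published real-data
comparison peaked at 89% accuracy.

## Derived channels

Static (gravity/posture) acceleration is a centred 5-sample moving
average of each raw axis; each window is averaged independently (no
running-sum drift), and at the stream edges the window truncates to the
samples available within the half-width. A centred window was chosen
over a trailing one to avoid phase lag at 10 Hz; 5 samples (0.5 s)
matches the reference protocol. Dynamic acceleration is raw − static,
so raw = static + dynamic holds to machine precision by construction.

Per sample: ODBA = |x_d|+|y_d|+|z_d|, VeDBA = √(x_d²+y_d²+z_d²) (hence
VeDBA ≤ ODBA ≤ √3·VeDBA); movement variation = |Δx|+|Δy|+|Δz| of the raw
axes, aligned by forward difference with the final sample repeating its
predecessor (a single-sample stream gets 0); energy = √(x²+y²+z²) of the
raw axes; pitch = atan(−x_s/√(y_s²+z_s²))·180/π ∈ [−90°, 90°] and
roll = atan2(y_s, z_s)·180/π ∈ (−180°, 180°], both from the static axes.

Open conventions resolved here: posture angles use the static axes
(posture is a gravity property; the dynamic residual carries no
orientation), while energy and movement variation summarise the raw
signal. The energy definition is configurable (`energy_form`:
`magnitude`, the default, or `squared` = x²+y²+z²) because either
reading is defensible; nothing downstream depends on the choice since
epoch statistics are computed per channel. Degenerate posture
(y_s = z_s = 0) yields pitch ±90° by the sign of −x_s and roll 0,
logged.

## Epochs and the 66 features

Within each event, non-overlapping windows of 1 s (10 samples) or 2 s
(20 samples) are anchored at the event start; the trailing remainder is
discarded and no window crosses an event boundary, so each epoch is
single-behaviour by construction. Disjoint tiling was chosen over
overlapping windows: overlap would multiply near-duplicate rows and
leak information across resampling boundaries. A `stride` option exists
for sensitivity analysis.

Per epoch, 9 channels (raw x, y, z + the six derived) × 6 statistics
(mean, SD, min, max, skewness, kurtosis) + 2 percentiles (Q10, Q90) for
the six derived channels = 66 features. Conventions: SD uses the n−1
denominator; skewness is the moment coefficient m₃/m₂^1.5 and kurtosis
the excess m₄/m₂² − 3 (the defaults of mainstream statistical
environments); a constant channel gets sd = skew = kurt = 0 exactly;
percentiles interpolate linearly between order statistics. Raw axes are
summarised unsmoothed — only ODBA/VeDBA are defined on the dynamic
components.

## Ethogram: exclusion and the swim merge

Rows labelled `other` or `out_of_camera` are dropped before modelling.
Whether the two swim labels merge is decided by Welch (unequal-variance)
two-sample t-tests on four epoch-level features: mean and SD of ODBA,
SD and max of VeDBA. Welch was preferred to the pooled-variance test as
the safer default. The decision is **merge iff every p ≥ α** (default
α = 0.05): the classes are combined exactly when no feature shows
evidence of a difference. The test runs on epoch-level rows (the
natural unit of the feature table); a missing or <2-row class forces
`keep_separate` with a flag. No multiple-testing correction is applied
across the four comparisons — with the merge-on-non-significance
logic, correcting would only make merging easier.

## Training protocol

* **Split.** The unit is the behaviour event: all epochs of an event go
  to one side, per class as close to 80/20 as rounding allows (≥1 event
  per side when a class has ≥2; a single-event class goes to train with
  a warning). Temporally adjacent epochs are strongly correlated, so an
  epoch-level split would overstate test performance.
* **Imbalance.** Minority classes are up-sampled with replacement to
  the majority count. Up-sampling is re-done inside each CV training
  fold — resampling before folding would place identical rows on both
  sides of a fold boundary and inflate CV scores — and once more on the
  full training set for the final refit. Test epochs are never
  resampled.
* **Tuning.** Exhaustive grid search scored by mean accuracy over
  repeated stratified k-fold CV (default 10 folds × 5 repeats; Cohen's
  kappa reported alongside; ties break to the earliest configuration in
  deterministic grid order). If any class has fewer rows than folds,
  the harness refuses with an error naming the class rather than
  silently degrading the stratification.
* **Models.** CART (cost-complexity pruned tree), RF, SVM (RBF kernel;
  C grid × kernel width from the median-of-squared-distances heuristic
  scaled by {0.5, 1, 2}), XGB, stochastic GBM (subsample 0.7), a
  boosted-trees stand-in for C5.0 (histogram gradient boosting, flagged
  `approximate` in all reports since no canonical C5.0 implementation
  exists in this ecosystem), a single-hidden-layer perceptron (NNET),
  and AVNNET — five such perceptrons differing only in initialisation
  seed, predicting by mean class probability. Features are
  standardised (training-fold mean/SD) for the SVM and neural networks
  only; trees consume raw features. Grids are package choices (the
  reference study's tuned values are not public). A reduced profile
  (`fast_specs`: 1–3 configurations per model, one CV repeat) is used
  by the examples, the bundled demonstration pipeline and the
  acceptance run to keep a full 8-model × 2-epoch comparison around
  five minutes on one core; `default_specs` is the full protocol.
* **Reproducibility.** One master seed drives stage seeds through a
  `SeedSequence` hierarchy (schedule vs noise in the generator; split,
  folds, resampling, model fits in the harness), so every output is
  bit-reproducible from config + seed.

## Evaluation

Confusion matrices are stored rows = predicted, columns = observed.
This orientation is the one under which the published per-class numbers
are internally consistent (sensitivity = TP over the *column* total,
precision = TP over the *row* total), and the package adopts it
throughout. Per class: sensitivity TP/(TP+FN), specificity TN/(FP+TN),
precision TP/(TP+FP), F = TP/(TP+½(FP+FN)) (the harmonic mean of
precision and sensitivity); overall: accuracy = trace/total, macro-F =
unweighted mean of defined class Fs, kappa = (p_o−p_e)/(1−p_e) with
p_e = Σ row_i·col_i/total². A class absent from both axes is reported
as missing and excluded from macro-F — silent zeros would distort the
average. Class metrics, accuracy and macro-F are reported as
percentages; kappa is unitless.

Feature importance is model-agnostic permutation importance on held-out
epochs: the mean test-accuracy drop over independent within-column
permutations (default 10 repeats), identical in definition for all
eight model types. Known limitation: with 66 strongly correlated
features and near-saturated classifiers, permuting any single column
barely moves accuracy, so importances on the default synthetic data are
small and nearly tied; the measure is informative when features carry
non-redundant signal, and the tests exercise it on such a fixture.

## Published reference matrices

The six test-set confusion matrices (SVM/RF/XGB × 1 s/2 s, 82 epochs
each) printed by the published captive validation study ship as package
fixtures. They pin the evaluation layer: recomputing every printed
sensitivity, specificity, precision, F-measure, accuracy and macro-F
cell from the counts reproduces the printed value to the precision it
was printed at. The study's raw accelerometer data were never
deposited, so its headline accuracies on real sharks are not
reproducible end-to-end; the synthetic pipeline plus these pinned
matrices are the substitute, and the tests treat them exactly that way.

Two counts printed in the study are knowingly not reproduction targets:
the captured-data-point totals per epoch length (the counting unit is
not stated and is inconsistent with disjoint tiling of one recording),
and the 82-epoch test-set size (an event-level split does not generally
produce equal test sizes at both epoch lengths).

## Problem sizes

Defaults used by the bundled runs: 4 sessions × 600 s at 10 Hz
(~24,000 labelled samples, ≈1,150 two-second epochs), reduced tuning
profile, 10-fold CV. These sizes give stable class counts while keeping
a full comparison in minutes; both the generator scale and the tuning
profile are configurable upward.
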