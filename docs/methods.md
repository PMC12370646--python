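# Methods

This note documents the models and procedures implemented in
`gaitbench`, the assumptions behind them, the defaults and why they were
chosen, and what the synthetic benchmarks do and do not establish.

## Assessment and signal model

The instrumented assessment is three consecutive shuttle-walk trials:
walk a 3.6 m path, execute a 180° turn, walk back, turn again. Ten IMUs
(waist/L5, chest/sternum, both wrists, thighs, shanks, feet) record
3-axis acceleration (m/s²) and angular rate (deg/s) at 100 Hz. Analysis
uses three derived signal families:

* **Tilt angles.** Sagittal and coronal tilt of each sensor relative to
  the gravity vertical, in degrees, backward positive / forward
  negative. Estimated by a complementary filter: the accelerometer tilt
  (`atan2` of the gravity projection) is blended with the integrated
  gyroscope rate, weight 0.98 to the gyro path. At 100 Hz this gives a
  crossover time constant of about 0.5 s — fast enough to reject
  accelerometer transients during steps, slow enough to cancel gyro
  drift. A full quaternion filter is unnecessary for tilt/heading at
  walking intensities and would be harder to validate against the
  generator's ground truth (estimator RMSE on noise-free synthetic input
  is below 1° for every sensor).
* **Heading.** Cumulative trapezoidal integral of the vertical-axis
  angular rate, unwrapped by construction. Pure integration drifts, so a
  linear ramp is removed using the protocol constraint that the net
  rotation of a completed assessment is a whole multiple of 180°; only
  the linear term is touched, preserving the peak structure segmentation
  needs.
* **Filtered channels.** All channels pass a 4th-order zero-phase
  (forward–backward) Butterworth low-pass at 12 Hz before any use. Gait
  content lives below ~10 Hz; 12 Hz keeps the sharp IC/TC transients
  reasonably crisp while removing broadband sensor noise. Zero-phase
  filtering is essential because event *timing* is the product.

## Segmentation

Turns are found on the smoothed absolute heading rate (Gaussian
smoothing, σ ≈ 0.075 s): each 180° turn produces one prominent rate peak
(`find_peaks`, prominence 30 deg/s, minimum separation 1 s), and the
turn's onset/completion are the samples where the rate crosses 15 % of
that peak's height. Heading itself is monotone during a turn; its rate
carries the peak structure, so the four crossings per trial play the role
of the four "rotation-curve peaks" bounding the two turns. Crossing
pairs closer than 1.5 s are merged into one turn: a freezing episode can
halt rotation mid-turn and split the rate peak, yet it is still a single
turn. Trials are located beforehand as contiguous active-movement
intervals of the smoothed shank angular-velocity envelope (activity
threshold 5 % of the maximum, sub-second lulls closed), with the trial
edges refined on a narrow (σ = 0.05 s) envelope because the coarse one
blurs the first and last strides. The straight-walk sections are the
active remainder before, between and after the turns: SW, T, SW, T per
trial, indexed SW1..SW6 / T1..T6 chronologically.

A trial that does not expose two turns raises a segmentation failure
rather than guessing; cohort extraction reports such participants and
gives them an all-missing feature row.

## Gait events

During walking the shank sagittal angular velocity shows one large
positive lobe per stride (swing). Swing peaks are detected per
straight-walk section (`find_peaks`: height ≥ 30 deg/s, prominence ≥ 50
deg/s, separation ≥ 0.4 s); the first local minimum strictly before a
peak is TC (toe-off) and the first strictly after is IC (heel strike).
Which flanking minimum is which is a convention taken from the
shank-gyroscope gait literature; the generator and detector share it, and
it is exposed in configuration for hardware with a different axis
convention. A local minimum is a sample strictly below its left
neighbour whose next differing right neighbour is larger; plateaus
resolve to their leftmost sample — a deterministic tie-break that an
exhaustive scan reproduces exactly (property-tested). A valley shared by
two swings serves as IC of the first and TC of the second. Cycles are
maximal IC → TC → IC triples per side; consecutive cycles share the
boundary IC. Cycles are never assembled inside turns; turn step counts
instead count IC events detected within the turn with the same operator.

## Feature catalog and construction

Three categories, ~17 base parameters (the in-text catalog; an extension
registry accepts new definitions without touching construction code):

* cycle-based (straight walks only, per-cycle values averaged within
  each section): gait speed (path length / section duration, m/s — the
  3.6 m protocol constant makes this drift-free, unlike double
  integration), cadence (120 / mean stride time, steps/min — computed
  from cycle durations, immune to partial strides at section edges),
  step length (path length / IC count), stride time (s), double support
  (% of cycle with both feet in stance, from bilateral IC/TC), shank
  swing RoM (time-integral of shank sagittal angular velocity over
  TC→IC, deg), trunk max sagittal angular velocity (deg/s);
* per-section: lumbar sagittal-sway difference (end − start of each SW),
  straight-walk duration, trunk forward-sway maximum (most negative
  sagittal tilt), turn duration, turn steps, turn max/mean angular
  velocity (waist heading rate), turn trunk sagittal mean sway;
* whole-assessment: trunk coronal-sway difference, effective trial
  duration (sum of all section durations — the natural reading of
  "time spent actively walking"), total turn duration.

Construction step 1 replaces each per-section base by max, min, mean and
`diff_mean` over its six applicable sections. `diff_mean` is the mean
*absolute* consecutive-section difference — a section-to-section
variability measure; the signed alternative telescopes to
(last − first)/(n − 1) and is available behind a flag. The float mean of
identical values can drift an ulp below the min, so the mean is clamped
into [min, max] to keep the ordering invariant exact. Step 2 collapses
every L/R pair per aggregate into (max), (min) and (diff) = |L − R|;
central-sensor features pass through. Names follow the
`Base—agg (pair)` convention (`Shank—Swing RoM—mean (max)`). The default
catalog yields 87 constructed features per participant. Missing values
(e.g. a section with no cycles) are *not* imputed at construction time;
median imputation happens inside the modeling stage, fit on training
folds only.

## Ordinal models

* **Split.** Repeated random 80/20 draws until (a) every observed score
  level of every item appears in training and (b) no demographic
  imbalance: Mann–Whitney p > 0.05 for age and disease duration,
  chi-square p > 0.05 for sex. The published protocol reports only
  p-values of unspecified tests; these are the standard nonparametric
  choices for a skewed age/duration distribution and a 2×2 sex table.
* **Level merging.** Any score level with ≤ 5 training participants
  (counted on the original training histogram) is folded into the
  adjacent lower level, cascading; a sparse lowest level folds upward.
  The identical map is applied verbatim to test scores. An item whose
  levels all collapse is reported as not modelable — expected below
  roughly 50 participants.
* **Ranking.** All features are ordered by total Gain of one reference
  XGBoost fit on the full training set (η = 0.1, depth 3, γ = 0.1,
  λ = 3 — the lowest grid corner, fixed and documented), ties broken by
  name. Ranking once before LOOCV mirrors the published design and
  carries a known optimistic bias relative to per-fold re-ranking; the
  strict mode is a flag away but is not the default.
* **Search.** For every top-K ∈ {5, 10, …, 50} and every hyperparameter
  combination of both algorithms (XGBoost grid 24 combos, RBF-SVM grid
  16), leave-one-out CV on the training set. Within each fold the
  training subset is median-imputed and oversampled by SMOTE before
  fitting — the left-out row never participates in imputation or
  oversampling (asserted structurally in tests). SMOTE uses k = 5
  within-class nearest neighbours, reduced to m − 1 for a class of
  m < 6, a singleton duplicated (SMOTE is undefined there). Fold
  predictions aggregate into one confusion matrix per configuration.
* **Selection and refit.** Highest LOOCV weighted F1 wins; ties break by
  exact accuracy, then smaller K, then gradient boosting before the SVM.
  The winner is refit on the full training set with the same SMOTE
  procedure and evaluated once on the held-out split.
* **Subscale.** The sum of the five item scores is predicted by LASSO on
  standardized, median-imputed features, penalty at the minimum mean
  10-fold-CV error; only non-zero coefficients are reported.

## Evaluation conventions

Per-class precision is UNDEFINED when a class is never predicted; recall
is 0 when the class occurs but is never hit and UNDEFINED when it never
occurs; F1 exists only when precision and recall are defined with a
positive sum. Weighted F1 treats an UNDEFINED class F1 as 0 while
keeping its support in the denominator; macro F1 averages only defined
classes. These two rules are not arbitrary: they are the unique pair
consistent with every published table row containing an NA, and the
package bundles those tables (`gaitbench/data/reference_tables.json`)
with a reconstruction oracle (`verify_reference_tables`) that re-derives
all 66 reconstructible values at printed precision. One printed cell
(item #3.13, test weighted F1 0.463) reconstructs to 0.462 from the
3-decimal per-class inputs — a rounding residue of aggregating rounded
values, within the half-ulp tolerance.

Weighted kappa uses quadratic disagreement weights
w_ij = ((i − j)/(M − 1))²; the published description ("higher weights to
greater disagreements") admits linear weights too, so real-data kappa
values are deliberately not reconstruction targets. ACC±1 is computed on
merged-level indices, not original 0–4 scores. MAE/RMSE/Spearman follow
the standard formulas, average ranks on ties.

## Synthetic cohorts: what they emulate, and what they do not

The generator is kinematics-first: it writes per-sensor angular
trajectories directly and derives accelerometers as the gravity
projection of the tilt, plus white Gaussian noise (defaults 1 deg/s and
0.05 m/s², roughly consumer-IMU class). Full rigid-body consistency
across segments is not attempted — the downstream pipeline consumes only
tilt, heading and the shank rate's peak/valley structure.

Five latent severities θ ∈ [0, 1] (chair, gait, freezing, stability,
posture) drive the kinematic targets monotonically: gait speed
1.25 − 0.80·θ_gait − 0.10·θ_stab m/s, cadence 112 − 30·θ_gait steps/min,
swing RoM 72 − 42·θ_gait deg, turn ramp 2.0 + 1.6·θ_stab + 1.2·θ_fog s,
turn steps 5 + 7·θ_fog + 3·θ_stab, trunk tilt −(2 + 16·θ_post) deg,
trunk sagittal angular velocity 28 − 14·θ_chair − 6·θ_gait deg/s. These
spans reflect typical clinic ranges (comfortable speed ≈ 1.2 m/s down to
severely impaired ≈ 0.4; turning in 4–6 quick steps vs 12–15 shuffling
ones). θ_fog > 0.6 additionally inserts a freezing episode at mid-turn:
the heading holds while both shanks oscillate at ≈ 2.2 steps/s with a
small range of motion, lengthening the turn and raising its step count —
the turn-initiation freeze that makes the freezing item clinically
legible in turn metrics. Item scores are clip(round(4·θ + ε), 0, 4) with
ε ~ N(0, σ_rater), σ_rater = 0.3 by default (about one rater
disagreement in three scores).

The shank stride template is a piecewise-sine with a positive swing lobe
whose integral equals the target swing RoM, flanked by dips at the TC/IC
instants, and a negative stance lobe sized so each stride nets zero
rotation (the shank pitch oscillates instead of drifting). Only complete
strides are rendered; edge gaps get a zero-integral sub-threshold wiggle
that keeps the activity envelope alive without creating detectable swing
peaks. Cohort severities share a common axial factor
(θ_i = clip(0.55·Beta(1.2, 2.5) + 0.55·Beta(1.2, 3.0))), skewing scores
toward the mild end so high scores are rare, as in clinic histograms.

What passing the synthetic benchmarks shows: the segmentation and event
operators recover the constructs they are defined on (boundaries within
0.25 s, events within 20 ms noise-free); the feature formulas hit the
generator's targets; the model search is leak-free and can recover
monotone severity–kinematics links through realistic label noise. What
it does not show: robustness to sensor misplacement, soft-tissue
artifact, arrhythmic or festinating gait outside the template family,
medication-state fluctuation, or any real-data effect size. The
published real-data accuracies are therefore anchored only through the
table-reconstruction oracle, never asserted of the synthetic pipeline.

## Problem sizes and numerical choices

The recovery benchmark runs n = 200 participants (160 train / 40 test),
rater noise SD 0.3, the reduced top-K sweep {5, 15, 25} and compact
hyperparameter sets (XGBoost at the reference combo; SVM γ ∈ {0.01, 0.1}
× C ∈ {1, 10}); the full grids remain the defaults and are exercised for
their exact contents in unit tests. XGBoost runs 100 trees,
single-thread `hist`, fixed seeds everywhere; per-fold SMOTE draws
derive from `SeedSequence(seed, K, fold)`, so every configuration of a
run is exactly reproducible. Boundary cases are pinned by tests:
sections are half-open `[start, end)` 0-based sample intervals; a
cutoff at or above Nyquist is a configuration error; an empty section
yields no events rather than an exception; degenerate kappa marginals
return UNDEFINED rather than NaN.

## Known limitations

* The feature catalog implements the named in-text parameters (~17 bases
  → 87 constructed features), not the full 240-parameter supplementary
  catalog; the registry is the extension point.
* Gain ranking before LOOCV (the published design) is optimistically
  biased; per-fold re-ranking is available but changes selected features.
* The generator's stride template cannot produce missing heel strikes,
  shuffling without swing peaks, or turn strategies other than a single
  smooth rotation with an optional mid-turn freeze.
* Demographic balance testing at α = 0.05 with small cohorts (< 40)
  rarely rejects, so "balanced" splits there are mostly unconstrained.
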