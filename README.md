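# gaitbench

Wearable-IMU shuttle-walk analysis and ordinal prediction of the five
MDS-UPDRS III gait/posture item scores.

## The problem

The gait and posture exam of Parkinson's disease — items #3.9 (arising
from chair), #3.10 (gait), #3.11 (freezing of gait), #3.12 (postural
stability) and #3.13 (posture), each rated 0–4 — is time-consuming and
subjective. A standardized instrumented walk offers an objective
alternative: the participant walks a 3.6 m path, turns 180°, walks back
and turns again, three times, wearing ten inertial sensors (waist, chest,
both wrists, thighs, shanks and feet; 3-axis accelerometer + gyroscope at
100 Hz). This package implements the full analysis chain from those raw
streams to item-level ordinal score prediction, for researchers in
digital movement biomarkers:

1. **Preprocessing** — zero-phase Butterworth low-pass (12 Hz) and
   complementary-filter orientation estimation (sagittal/coronal tilt
   relative to gravity, backward positive / forward negative; unwrapped
   heading from the vertical-axis angular rate).
2. **Segmentation** — peaks of the smoothed waist heading rate mark the
   turns; their onset/completion crossings split each trial into
   SW, T, SW, T, indexed SW1..SW6 / T1..T6 across the assessment.
3. **Gait events** — each prominent positive peak of the shank sagittal
   angular velocity is a swing; the first local minimum before it is
   terminal contact (TC, toe-off) and the first after it initial contact
   (IC, heel strike). A gait cycle is IC → TC → next IC of one side.
4. **Features** — a catalog of cycle-based (gait speed, cadence, step
   length, stride time, double support, shank swing RoM, trunk angular
   velocity), per-section (turn duration/steps/angular velocity, sway
   measures) and whole-assessment parameters, constructed in two steps:
   max/min/mean/diff_mean over the six applicable sections, then each
   left/right pair collapsed to (max), (min), (diff) = |L − R|.
5. **Models** — per item: an 80/20 split balanced on age, sex and disease
   duration; sparse score levels (training count ≤ 5) merged into the
   adjacent lower level; features ranked by total Gain of a reference
   XGBoost fit; a grid search over top-K ∈ {5,…,50}, XGBoost
   (η ∈ {0.05, 0.1}, depth ∈ {3, 4}, γ ∈ {0.1, 0.2}, λ ∈ {3, 4, 5}) and
   RBF-SVM (γ ∈ {0.001,…,1}, C ∈ {0.1,…,100}) under leave-one-out CV
   with SMOTE applied only inside each fold's training subset; the best
   configuration (weighted F1) refit on all training data. The subscale
   (sum of the five items) is predicted by LASSO at the minimum-CV-error
   penalty.
6. **Evaluation** — weighted/macro F1, exact and acceptable accuracy
   (ACC±0, ACC±1), quadratically weighted Cohen's κ and per-class
   precision/recall/F1 with explicit conventions for classes that are
   never predicted.

Because the underlying patient recordings are not public, the package
includes a first-class **synthetic cohort generator**: five latent
severities in [0, 1] drive the kinematics monotonically (speed, cadence
and shank swing fall with gait severity; turn duration and step count
rise with freezing/instability, freezing inserting a low-amplitude
high-step-rate episode inside turns; forward trunk lean grows with
posture severity), item scores are `clip(round(4·θ + ε), 0, 4)` with
Gaussian rater noise, and every stage's ground truth (sections, IC/TC
instants, kinematic targets) is returned alongside the signals.

## Worked example

```bash
python examples/04_synthetic_experiment.py
```

prints, for a 60-participant cohort (seed 3, rater noise SD 0.3):

```
train 48 / test 12 participants

item       algorithm                K levels          ACC+-0  ACC+-1    wF1
item_3_9   rbf_max_margin           5 0/1, 2/3/4       75.0%  100.0%  0.755
item_3_10  gradient_boosted_trees   5 0/1, 2/3/4       83.3%  100.0%  0.838
item_3_11  gradient_boosted_trees  15 0, 1, 2/3/4      75.0%  100.0%  0.756
item_3_12  gradient_boosted_trees   5 0, 1, 2/3/4      58.3%  100.0%  0.558
item_3_13  rbf_max_margin           5 0, 1, 2/3/4      66.7%  100.0%  0.692

subscale (sum of five items): MAE 1.03, RMSE 1.41, Spearman R 0.658 (moderate correlation)
LASSO kept 9 features at lambda 0.194
```

Every prediction lands within one merged level of the truth (ACC±1 =
100 %), exact accuracy varies with how well each item's driving
kinematics separate at this small cohort size, and the subscale
regression tracks overall severity. `examples/01`–`03` walk through
simulation, feature extraction and the metric-convention check
individually; larger cohorts (n = 200, as in `scripts/acceptance.py`)
reach ACC±1 ≥ 97 % per item and subscale Spearman ≈ 0.95.

The `gaitbench` CLI wraps the same pipeline
(`gaitbench run --seed 1 --out runs/demo`, `gaitbench verify-tables`).

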