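# Methods

This note documents the models, conventions and numerical choices behind
`sedmet`, in the spirit of a statistical package's methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## The measurement model

A minute of data from a thigh-worn 3-axis accelerometer (30 Hz, g) and an
8-channel rectified surface-EMG envelope (30 Hz, arbitrary device units;
channels = {right, left} × {forearm, upper arm, shoulder, lower back}) is
classified in two stages:

**Posture.** Under quasi-static conditions the accelerometer's y axis
(along the thigh, pointing up while standing) reads the gravity projection
y = −cos θ, where θ is the thigh's angle to the vertical: −1 g standing,
0 g horizontal. The fixed three-node tree is:

1. 5th percentile of y ≥ −0.774 g → **sitting**. Since
   arccos(0.774) ≈ 39°, this demands a thigh more horizontal than 39° for
   95% of the minute.
2. else, 5th percentile < −1.35 g → **walking** (per-step acceleration
   spikes below the standing band);
3. else, 95th percentile > −0.85 g → **walking** (per-step deceleration),
   otherwise **standing**.

The sitting threshold is a published quantity; the two walking thresholds
are configuration (`PostureThresholds`), fixed once from the synthetic
generator's quiet-standing band (standing y = −1 ± sway, so its 5th/95th
percentiles stay well inside (−1.35, −0.85), while the walking oscillation
leaves the band on both sides). The sign convention — quiet standing reads
−1 g — is itself a choice: it is the one under which the printed sitting
rule is satisfied by horizontal thighs and violated by vertical ones.

**MET.** Energy expenditure is expressed in METs relative to the person's
measured resting metabolic rate: RMR = median calorimeter output (kcal/min,
0.1 Hz) during the second five minutes of supine lying (the first five are
a settling period); each task's MET = median energy expenditure over the
final two minutes of the task divided by RMR; every minute of a task
inherits the task's MET. A minute is *inactive* iff MET ≤ 1.5 — the
boundary counts as inactive. Sitting and standing get separate binary
classifiers; walking minutes are excluded from MET classification.

Referencing to measured RMR rather than the 3.5 mL O₂/min/kg population
standard matters: with a measured resting oxygen uptake of 4.1 mL/min/kg,
standard-referenced MET values would be 17% higher
(`standard_met_inflation`), shifting minutes across the 1.5 threshold.

## Feature inventories

*Posture set* (10, y axis only): mean, median, 5th/95th percentile,
variance, IQR, kurtosis (Fisher excess), skewness, mean angle to vertical
and its variance. Shape statistics are defined as 0 for zero-variance
signals, where the usual estimators are undefined.

*MET set* (144 = 12 × 8 EMG + 16 × 3 accel): per channel six time-domain
features (standard deviation; 1 s-lag autocorrelation; number of prominent
peaks; sum of prominent-peak heights relative to the median; number of
median crossings; median time between adjacent crossings) and six
frequency-domain features (power-weighted mean frequency; frequency and
power of the first harmonic, i.e. the largest non-DC periodogram peak;
average signal power; band power above 0.5 Hz and above 5 Hz). The three
accelerometer axes additionally carry mean, median, and 5th/95th
percentile. **EMG channels deliberately have no absolute-amplitude
features**: without skin preparation or reference contractions, surface-EMG
amplitude varies too strongly between people to be comparable, so only
relative/dynamical features are used.

Conventions where the primitives are underdetermined (all exposed in
`FeatureConfig`):

* *Prominent peak*: local maximum with topographic prominence
  ≥ k × signal median (k = 1), minimum separation 1/6 s; when the median is
  non-positive (zero-mean accelerometer axes) the prominence constraint is
  dropped and only the distance constraint applies. The peak-sum feature is
  0 when the median is 0.
* *Median crossing*: strict sign change of (signal − median) between
  consecutive samples; touches do not count. Fewer than two crossings →
  inter-crossing time 0, keeping the feature totally ordered for tree
  splits.
* *Autocorrelation*: Pearson correlation of the signal with its 1 s-shifted
  copy over the overlap; 0 for zero-variance overlap.
* *Spectra*: one-shot periodogram of the mean-removed minute (no Welch
  averaging — the "first harmonic" should be a line, not a smoothed bump),
  spectrum scaling, resolution 1/60 Hz; DC excluded from all spectral
  features; zero signal → all six features 0.

Extraction is deterministic: identical input yields a bit-identical vector
in a fixed column order (`<stream>.<channel>.<feature>`).

## CART

`GiniTreeClassifier` is a greedy recursive partitioner: at each node an
exhaustive search over all features and all midpoints between consecutive
sorted distinct values, taking the split with the largest decrease of the
Gini diversity index 1 − Σ pₖ²; growth stops on purity, the minimum-leaf
bound, or maximum depth. Ties break toward the lower feature index, then
the lower threshold — any such rule is arbitrary, so it is documented and
tested (exact agreement with a brute-force enumerator on 100 random small
datasets). Samples with value < threshold go left. `predict_proba` returns
training-class fractions at the reached leaf; ROC analysis uses these leaf
scores. Default complexity limits for MET trees: max depth 5, min leaf 5 —
deliberately shallow, interpretable trees. Trees serialize to a readable
JSON so published models can ship as configuration.

## Calibration: LOPO + stepwise inclusion

Model validity is the pooled objective over hold-one-participant-out
cross-validation: one tree per participant, trained on everyone else,
scoring that participant's minutes exactly once; AUC (tie-corrected
Mann–Whitney concordance) or MCC is computed once over the pooled holdout
predictions (not averaged per participant). A leakage assertion runs on
every fold.

Feature inclusion is the greedy forward wrapper: train one model per
candidate feature, keep the best, try adding each remaining feature,
repeat until no candidate remains. Every pass's winner is recorded; the
final model maximizes objective − λ·(input features), λ = 10⁻³, so
equal-objective models resolve toward fewer inputs. Within a pass, ties
break toward the lexicographically smallest feature name; in the final
pick, toward fewer features. The fitted tree need not split on every input
feature (`used_features_ ⊆ best_features_`). Notes:

* `max_passes` caps the loop. The spirit of the procedure is to exhaust the
  candidates, and small candidate sets do; with 144 candidates the
  objective plateaus within a few passes while the cost grows
  quadratically, so calibration-study entry points default to small caps
  (the package's own choice of problem size; the per-pass structure is
  unchanged).
* Channel-restricted models (e.g. ≤ 3 EMG channels) are available two
  ways, since how the published restricted models were found is not
  documented: a constrained search that never visits a subset touching
  more channels (default), and a post-hoc filter over the recorded pass
  winners.
* A backward elimination variant (start full, drop one per pass) exists
  behind `direction="backward"`; it is the costlier alternative and not
  the default.
* Features of partially-missing channels (flagged by runs of ≥ 30
  consecutive exact zeros, i.e. 1 s at 30 Hz) participate normally; the
  wrapper is expected not to select them because they classify poorly.
  Signals are never cleaned or dropped.

OR-combination: two binary models combine on a trigger class — the minute
gets the trigger class iff either model predicts it. By set union this can
only raise the trigger class's sensitivity; the combined score is the
maximum of the component scores. `run_calibration_study` evaluates both
trigger directions for the AUC- and MCC-picked pair and keeps a
combination only when its fraction of correctly classified minutes beats
both components.

Metrics conventions: the positive class is *inactive* (SB) throughout;
MCC of a matrix with a zero marginal is 0 (a holdout participant may lack
a class); rates with zero denominators are reported as absent, never 0.
Individual-level summaries are per-participant medians with percentile
bootstrap 95% CIs (2000 resamples, seeded); participants with only one
true class are skipped and reported.

## The synthetic study generator

`generate_study` emulates the calibration protocol: 25 participants by
default, each doing seven randomized 5-min task blocks — four mandatory
(typing sitting, typing standing, video sitting, walking), always within
the first six blocks — followed by a 10-min lying block. Per-task MET is
drawn once per participant from a normal distribution with the median and
IQR of the task-level MET table the generator is calibrated to (video
1.09 (0.22) sitting … deskwork 1.47 (0.39) standing, walking 2.87 (0.74)),
floored at 1.0 (walking at 1.6, keeping it always active); all minutes of
a task share the draw, and ground-truth categories come from the drawn
MET, not from the noisy calorimeter, so recovery tests have a clean truth.

* **Accelerometer**: sitting draws a thigh angle from N(75°, 8°) clipped to
  [55°, 100°] (well past the 39° threshold); lying is near-horizontal
  (N(90°, 3°)); standing reads −1 g with 0.02 g sway; walking adds a
  sinusoid at the participant's gait frequency (N(1.8, 0.15) Hz) with
  0.8 g amplitude. White measurement noise, σ = 0.02 g.
* **EMG**: Poisson-arriving Gaussian-enveloped bursts (width 0.15 s) on a
  half-normal baseline (σ = 0.05 device units) — the simplest process with
  independently tunable rate and amplitude and a realistic envelope
  spectrum. Burst rate = 2.0 · (MET − 1) · wₖ bursts/s and burst amplitude
  = 0.8 · (0.5 + (MET − 1)) per channel k, both strictly increasing in
  MET. Task-specific channel weights wₖ (typing/mouse dominated by
  forearms, walking by the lower back, mouse lateralized to the right) are
  normalized to a constant sum, so the MET excess — not the task identity —
  sets the total activity volume. Each participant carries lognormal(0,
  0.4) per-channel gains, emulating the large inter-personal amplitude
  variability that motivates gain-robust features. The study path
  synthesizes the 30 Hz envelope directly; an equivalent raw path at
  1 kHz exists to exercise the analog front end (high-pass 1.8 Hz,
  full-wave rectification, low-pass 110 Hz, resampling to 30 Hz — 4th-order
  Butterworth applied forward-backward, output clipped at 0).
* **Calorimeter**: rmr × MET multiplier at 0.1 Hz with Gaussian noise
  (σ = 3% of RMR) and an exponential settling transient (amplitude 0.3,
  τ = 60 s) at the start of lying. RMR ~ N(1.4, 0.2) kcal/min
  (≈ 2000 kcal/day).
* **Presets**: the defaults make posture perfectly separable by the fixed
  tree (a property the test suite asserts); the `hard` preset (larger
  noise, flatter sitting angles, weaker gait oscillation, degraded EMG
  signal-to-noise) deliberately breaks that, guarding the suite against
  only ever seeing trivially separable data.

One seed fixes the full dataset bit-reproducibly (participants use
independent child streams of the master seed).

**What passing tests do and do not show.** The generator reproduces the
*statistical skeleton* the classifiers assume — posture-dependent gravity
projections, MET-monotone muscular activity, per-task MET mixtures,
inter-personal gain variability, partial channel dropout. It does not
model motor-unit physiology, electrode-skin artifacts, crosstalk between
muscles, fidgeting, posture transitions within a minute, or ambient
conditions. Perfect posture accuracy and high MET performance on the
default preset therefore validate the pipeline's mechanics and the
calibration machinery, not field performance on real recordings.

## Problem sizes and runtime choices

The shipped tests and the acceptance script use the package's own
desk-scale defaults: the end-to-end study runs 25 participants × 7 tasks
(≈ 1100 minutes, ≈ 160 000 feature values) with stepwise selection capped
at 3 passes per objective; smaller structural tests use 4–8 participants.
Channel-recovery and coverage properties use 20–50 seeded replicates.
Bootstrap CIs default to 2000 resamples.

## Known limitations

* The walk-node thresholds are calibration constants, not published
  values; on real data they should be re-fit (`GiniTreeClassifier` on
  posture features reproduces the structure).
* One MET label per task ignores within-task variation; minutes near the
  1.5 boundary are genuinely ambiguous and dominate the residual error of
  the synthetic MET models.
* Lying is not part of the posture vocabulary; a horizontal thigh while
  lying classifies as sitting, which is correct for the SB definition
  (reclining counts) but means the lying block must be annotated, not
  detected.
* CSV column layout is a declared convention (comma separator, dot
  decimal, one header row); real device exports may need remapping.
* No pruning, surrogate splits, missing-value handling inside trees, or
  ensemble methods — simplicity and interpretability are the point.
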