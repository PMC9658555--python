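# Methods

## Problem and data model

The task is binary detection of ongoing physical activity at each CGM
registration of a person with type 1 diabetes. Two kinds of source data
are supported, mirrored by the two ingest dialects:

* **Ohio-style**: per-subject XML archives with glucose (mg/dL, 5-min),
  heart-rate events (bpm, 5-min), self-reported exercise episodes (start,
  duration in minutes, subjective intensity 1–10) and a single body
  weight. Exercise labels are self-reports: a registration is positive iff
  it falls in `[start, start + duration)` of an episode with intensity ≥ 2
  (lower intensities are treated as non-exercise). The interval is
  half-open by our convention: "flag is set while the episode is in
  progress" fixes no boundary behavior on its own, and half-openness
  makes boundaries unambiguous.
* **D1namo-style**: per-subject folders with glucose registrations in
  mmol/L (CGM and manual finger sticks, the latter tagged and excluded
  from the grid) and a 1 Hz heart-rate/activity sensor summary. The 1 Hz
  channels are averaged over the half-open interval `(t_{i-1}, t_i]`
  between consecutive registrations (≈300 samples at 1 Hz; the first
  registration collects the nominal 5 minutes preceding it — the source
  aggregation rule names no assignment convention, so we fixed this one).
  A registration is positive iff its mean activity level strictly exceeds
  0.2, the sensor's mild-activity threshold. Means are rounded to 9
  decimals before the strict comparison so float accumulation cannot flip
  a value sitting exactly on the threshold. Aggregated heart rate is
  stored as the nearest integer, matching the integer HR of the record
  structure.

Glucose is converted to mg/dL at ingest (×18.0182) so both cohorts share
one scale; a flag disables the conversion. All downstream math uses
minutes and mg/dL.

Analysis is restricted to midnight-to-midnight **day blocks** in which
(a) CGM coverage ≥ 90% of the nominal daily grid with no gap (including
the margins to midnight) longer than 7.5 min (1.5 sampling intervals),
(b) at least one registration is labeled positive, and (c) when heart
rate is required, every registration carries one. Days without any
reported activity are excluded because self-reporting is unreliable:
exercise likely happened on many unlabeled days, and keeping them would
poison the negative class. The coverage and gap thresholds are our own
quantification of what "CGM signal present for the whole day" should
mean; both are configurable, and tightening either can only shrink the
result.

## Features

Each registration is described by its 15-record causal window (70 min of
history, Δt = 5 min): end-to-end difference d, consecutive differences
dp(0..13), three 5-record mini-window differences dpp(0..2), the
corresponding rates v, vp, vpp, second-order terms
ap(i) = (bg(i+2) − bg(i))/(2Δt)², body weight w, and — in FS2 — the heart
rate at the newest registration and its last consecutive difference.
These features are deliberately redundant (Σ dp = d; vp·Δt = dp); the
point is to expose differences, velocities and accelerations explicitly
to learners with different inductive biases. The ap denominator is the
squared time span exactly as defined, although it mixes a first
difference with a squared time — fidelity over dimensional tidiness.

Design choices the source leaves open, fixed here:

* **Label alignment**: the row's label is the exercise flag of the
  *newest* window record — the window is the causal history of the moment
  being classified, so no future information leaks into a row.
* **hr/hrp indexing**: evaluated at the window's newest registration; the
  alternative reading of hrp (last minus first 1 Hz sample within the
  inter-registration interval) was considered and not taken, since the
  defining formula is a difference of consecutive registration-level
  values.
* **Warm-up**: the first 14 rows of a stream (and of each day block —
  windows never cross block boundaries) are emitted with all
  window-derived features zero and the weight kept, so a deployed model
  can answer from the first registration; trustworthy output starts once
  15 registrations exist, i.e. 75 min after initiation. Training matrices
  keep the zero-padded rows by default (`warmup_policy="zero"`); dropping
  them is one flag away. Rows whose window would span a cleaned-out gap
  (non-uniform spacing) are likewise zero-padded and flagged.

## Classifier suite and training protocol

Fourteen scikit-learn configurations, fixed a priori: logistic regression
(L2, ≤1000 iterations), AdaBoost (50 trees), k-d-tree KNN (k = 5),
depth-unlimited decision tree, Gaussian naive Bayes, SVMs with rbf,
sigmoid and polynomial (degree 3/5/10) kernels capped at 1000 iterations,
a 100-tree random forest, and MLPs with hidden layers (100, 150, 100, 50)
and logistic/ReLU/tanh activations (≤1000 iterations). Scores for ROC are
positive-class probabilities where available and decision-function
margins for the SVMs; hard predictions use each learner's default
operating point.

Training defaults: **no feature scaling** (the SVM/MLP rows behave
accordingly — their within-cohort results are visibly weaker than the
tree ensembles, consistent with unscaled inputs) and **seeded random
undersampling of the training majority class to 1:1** (positives are
~5% of registrations; without balancing, several learners collapse to
the majority class). Both are single flags, recorded in each trained
model's metadata, because the original protocol documents neither. All
learner seeds derive from the run seed; fit/score is deterministic.

## Evaluation

ACC, TPR, TNR, PPV, FPR and F1 are computed from exact integer confusion
counts; a zero-denominator ratio is reported as 0 and flagged
"degenerate" rather than NaN. ROC thresholds sweep the distinct scores
(ties grouped); AUC is the trapezoidal area, which equals the
Mann–Whitney pairwise concordance probability — the test suite checks
that equality against a brute-force pair count.

Use-cases 1–4 split one cohort 75/25. The default split is
**chronological per subject** (earliest 75% train): adjacent windows
share 14 of 15 records, so a random row split would leak near-duplicates
of test rows into training; the random stratified split is kept as an
option since the source protocol does not specify the mode. Use-case 5
trains on all of one cohort and tests on all of another. Use-cases pool
all subjects into one matrix.

## Synthetic cohorts

The simulator generates what the analysis assumes about real data:
per-subject baseline glucose (140 ± 20 mg/dL) with a slow mean-reverting
wander (OU, reversion 0.005/min, diffusion 0.4 mg/dL/√min), ~3 meals/day
(linear rise to 30–80 mg/dL over 30 min, exponential decay, τ = 90 min),
exercise episodes (~1.2/day, 10–90 min, intensity 3–8, whole-minute
starts/durations at self-report resolution, non-overlapping by rejection
sampling), a lagged glycemic response (decline of 0.2 mg/dL/min per unit
intensity starting 12 min after onset, recovering exponentially with
τ = 60 min after the episode, floored at 40 mg/dL), a first-order
heart-rate response (rest 70 ± 6 bpm, gain 7 bpm per unit intensity,
τ = 2 min), an activity channel (rest 0.05, gain 0.08 per unit intensity,
so mid-intensity exercise clears the 0.2 threshold and rest does not),
additive Gaussian sensor noise (CGM 5 mg/dL, HR 3 bpm, activity 0.02),
CGM dropouts (0.2/day, 15–120 min), and a 10% chance that an episode is
never reported. Where the source material gives only qualitative
guidance (it quantifies neither effect sizes nor noise), these defaults
were chosen once as physiologically plausible values and are not tuned.

Each stochastic ingredient draws from its own seeded substream keyed by
(seed, subject, ingredient), so changing one knob — e.g. the CGM noise —
leaves episode times, meals and weights bit-identical; mechanism tests
exploit this.

What the simulator does **not** emulate: insulin and carbohydrate
pharmacokinetics, circadian glucose patterns, heart-rate variability
structure, cardiac autonomic neuropathy (which can blunt the HR response
in long-standing diabetes), sensor drift/compression artifacts, or
correlated multi-day behavior. Passing tests therefore demonstrate that
the pipeline implements its specification and that the method detects a
lagged-glucose + prompt-HR signature when one exists — not that the
absolute AUCs would be attained on clinical data.

## Problem sizes and numerics

The bundled experiments use cohorts of 10 subjects × 7 days (within- and
feature-set comparisons, 10 seeds) and 8 × 5 vs 5 × 3 subjects·days for
the cross-cohort transfer — large enough for ~500+ positive
registrations per cohort, small enough that the full suite runs in
minutes on one CPU. Window spacing is validated to a 1e-6 relative
tolerance before feature extraction; feature formulas are checked against
a loop-based evaluator at 1e-12. Iteration-capped learners (SVM, MLP,
LR) may stop before convergence by design; convergence warnings are
suppressed during fitting.

## Known limitations

* The real study datasets are access-restricted, so their printed
  per-cohort tables cannot be regenerated here; the pipeline reproduces
  the protocols and the qualitative ordering (FS2 > FS1; transfer works),
  not the published numbers.
* The exercise-intensity scale is subjective in the source data; the
  simulator treats it as a linear multiplier on both glucose decline and
  HR gain, which is a first-order idealization.
* Zero-padded warm-up rows carry real labels with zeroed features; with
  ~5% of rows padded this slightly depresses measured TPR when an episode
  touches a block start.
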