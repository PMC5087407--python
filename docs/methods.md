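# Methods

## Model

OCKRA is a bagging-style ensemble for one-class classification.  Each of the
`N` members sees a random feature subspace: `n` indices drawn uniformly with
replacement from `{1..n}` and deduplicated, so the expected retained
fraction is `1 − (1 − 1/n)^n` (63.93% for the 26-feature band schema, and
→ 1 − 1/e ≈ 63.2% for large `n`).  The member clusters the projected
training data with k-means++ and summarizes normality by its `k` centroids
plus a scale parameter `δ`, the mean pairwise Euclidean distance among
training rows subsampled at 60-second spacing.  A query's member similarity
is the Gaussian kernel `exp(−½ (d_min/δ)²)` of its nearest-centroid distance
`d_min`, and the ensemble score is the members' mean — a similarity in
`[0, 1]`, with 1 attained exactly when the query coincides with a centroid
in every member.

Assumptions worth stating explicitly:

- **Raw Euclidean distance, no feature scaling.**  Distances are computed on
  features in their native units, so channels with large numeric ranges
  (pace in ms/m, speed in cm/s) dominate `δ` and `d_min` in members that
  select them.  Random subspacing mitigates this: members that happen to
  exclude the large-range channels are sensitive to smaller-scale structure
  such as heart rate.  This is a property of the method as specified, not an
  oversight; adding standardization would change the classifier family.
- **Per-second feature vectors are treated as exchangeable.**  No temporal
  model links consecutive windows; detection is purely per observation.
- **Training data are all-normal.**  Labels, when present in an input table,
  are used only to filter rows out of training and as evaluation ground
  truth; no training operation reads them.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `n_members` | 100 | ensemble size; more members reduce score variance at linear cost |
| `k` | 10 | centroids per member; kept small so the model (1000 centres) fits a phone-class device |
| `δ` subsample spacing | 60 s | reduces `m` rows to ≈ `m/60` before the O(m²) pairwise mean |
| kernel | `exp(−½ (d/δ)²)` | the only parse of the printed member-similarity expression consistent with both published operating bounds (> 0.6 inside `δ`, < 0.02 beyond `3δ`) |
| `master_seed` | — | every member derives an independent child RNG via `SeedSequence(master_seed).spawn`, so training is reproducible and member-order independent |

Baselines: the Parzen window uses every training row with width `h` equal to
OCKRA's `δ` rule on unprojected data; k-means1/k-means2 replace the rows by
`k = 10` k-means++ centres and score by the nearest centre or the mean over
all centres.  The published kernel form for these baselines is not printed
anywhere we could find, so all distance-based methods share OCKRA's Gaussian
kernel; this makes the family relationships exact (`k = m` reduces k-means2
to Parzen; `kmeans2 ≤ kmeans1` pointwise) and is tested as such.  The
one-class SVM is deliberately an adapter over scikit-learn's `OneClassSVM`
(RBF, `γ = 0.038`, `ν = 0.5`, the LibSVM-style defaults of the original
comparison), not a re-implementation.

## Preprocessing

Feature extraction uses one-second windows and three rules: sub-second
channels contribute window mean and sample standard deviation (`ddof = 1`;
a single sample gives std 0); 1 Hz channels contribute the raw value; slower
channels contribute the last observed value carried forward.  Cumulative
counters (steps, distance, calories) contribute per-window increments.  The
26-field layout is three tri-axial 8 Hz blocks — the gyroscope event's
acceleration stream, gyroscope angular velocity, and the accelerometer —
summarized by mean and std per axis (18 fields), heart rate, skin
temperature, pace, speed and the ordinal UV level encoded 0–4 (5 fields),
and the three counter deltas.

Decisions the window rules do not determine by themselves:

- A second with no high-rate motion sample emits **no** vector: recharge
  gaps are real absences, not zeros.
- The counter-delta reference resets at the start of a contiguous segment
  and after any gap longer than 120 s, so a recharge gap never yields one
  huge spurious increment; within a contiguous segment the deltas telescope
  to (last − first).
- A 1 Hz or slower channel missing from an emitted window is carried
  forward; before its first observation it is back-filled from that first
  observation; a channel absent from the entire log contributes 0.0.  All
  three choices keep vectors complete and deterministic.
- Cross-validation folds are contiguous temporal blocks of near-equal size,
  not a random shuffle — the data are a time series, and shuffling would
  leak near-duplicate neighboring seconds between train and test.  Each of
  the five repetitions tests on one held-out normal block joined with the
  full anomaly table; anomaly scores are therefore pooled five times (once
  per trained model) into the per-subject curve.

## Numerical choices

- k-means++: seeding exactly as published (first centre uniform, subsequent
  centres ∝ squared distance to the nearest chosen centre), then Lloyd
  iterations to a centroid shift below 1e−6 or 100 iterations.  An emptied
  cluster is re-seeded with the point farthest from its assigned centroid.
  With fewer distinct rows than `k`, `k′ = #distinct` centroids are fitted
  instead of failing.  Nearest-centroid ties resolve to the lowest index.
- `δ` falls back to the full projected matrix when the 60-s subsample keeps
  fewer than two rows, and to a floor of 1e−12 when the data are constant
  (so identical queries still score 1 and anything else ≈ 0).
- ROC construction is a single ascending sort of the similarity scores with
  one operating point per distinct score (ties collapse), anomaly as the
  positive class, and a query called positive when its score is ≤ the
  threshold; AUC is the trapezoidal area, which equals the normalized
  Mann–Whitney U statistic and is tested against it to 1e−9.  The PR sweep
  stops once full recall is first reached (recall is constant and precision
  only decays beyond that point).  Population curves average the dependent
  coordinate on a fixed 101-point grid (mean and sample std per grid point).
- Wilcoxon signed-rank is two-sided and paired, zero differences dropped;
  identical vectors return p = 1 by convention.  Both rank tests delegate to
  scipy; a Kruskal–Wallis call on constant data returns (H = 0, p = 1)
  rather than the indeterminate tie-corrected form.

## Synthetic data

The generator emulates the *statistical structure* of week-long band logs,
not physiology: a hidden rest/walk/brisk Markov chain (stay probability
0.98/s) modulates motion variances, step and calorie rates and speed; heart
rate is a resting level plus a circadian sinusoid, a state shift and
Gaussian noise (sd 1.5 bpm); counters integrate per-state rates; skin
temperature and UV follow their slow schedules; a gap schedule deletes
readings outright.  Subject profiles (resting HR 55–75 bpm, stride
60–90 cm, activity scale 0.8–1.2) are drawn per subject from the master
seed.

The five staged anomaly scenarios are produced by the *same* generative
core with an effect overlay: multiplicative variance terms amplify the
current state, additive terms impose the absolute intensity of the staged
activity (a sprint is vigorous regardless of what preceded it), falls add
impact spikes (> 3 g with a rotation burst every few seconds, locomotion
stopped), and breath-holding has a still hold phase with a bradycardia dip
followed by a struggle phase with involuntary-movement bursts and a
post-release tachycardia rebound.  Every effect interpolates linearly with
`effect_scale`, so at 0 the anomaly process is *identical in distribution*
to normal behavior — the null used for calibration — and at 1 the default
effects are separable by a working detector (tested at AUC > 95%).

What the generator does **not** reproduce: real inter-channel correlation
structure, sensor artifacts and dropouts other than scheduled gaps,
demographic heterogeneity beyond the profile ranges, and the original
study's record counts.  Passing tests on synthetic data therefore validate
the algorithmic machinery and its calibration, not field performance on
real band data, whose published per-subject AUC benchmark ships with the
package only for comparison arithmetic.

Null-calibration variance deserves a note: an anomaly log is a handful of
short scenario segments, so its hidden-state draw is effectively a few
Bernoulli trials and single-seed null AUC is noisy by construction.  The
calibration check is therefore on the mean over ten generator seeds
(within 0.5 ± 0.05 for every classifier), not on each seed alone.

## Problem sizes

The test suite trains on simulated logs of 20–60 minutes per subject
(1,200–3,600 per-second vectors) with the full 100-member, `k = 10`
configuration, the size at which the whole suite completes in a couple of
minutes on one core; the acceptance script's Monte-Carlo retention estimate
uses 100,000 draws.  These sizes are the package's own desk-scale defaults;
nothing in the implementation assumes them.

## Known limitations

- No temporal smoothing of scores; a production alarm would hysteresis or
  debounce the per-second similarity.
- The number of members and `k` are taken as given; optimizing them is
  explicitly out of scope.
- The ocSVM adapter exposes a decision score on scikit-learn's scale, not a
  `[0, 1]` similarity; it participates in ranking-based evaluation only and
  is not serialized to the JSON model format.
- Pooling anomaly scores across the five folds weights each anomaly row
  five times in the per-subject curve; per-fold averaging is a defensible
  alternative the evaluation does not implement.
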