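# Methods

`dbsnet` analyses task-EEG functional connectivity in Parkinson's disease
patients treated with subthalamic deep brain stimulation (STN-DBS). The
package covers the analysis chain from source-space ROI time series to a
pre-operative responder classifier, and ships a synthetic-cohort generator
so that every stage is testable without patient data.

## Connectivity estimation

ROI activity (90 AAL cerebral regions, 1 kHz) recorded during a
three-stimulus visual oddball task (30 targets, 140 frequent, 30
distractors; 200 ms stimuli, 4 s inter-stimulus interval, 14 min total) is
processed per DBS condition (ON/OFF):

1. **Stimulator-line removal** (`fft_line_filter`): spectral bins within
   ±0.5 Hz (configurable) of each artifact line are zeroed on the continuous
   signal. The same line set is applied to both conditions of a subject. At
   most five lines are expected per recording; more triggers a warning.
2. **Band filtering** (`bandpass`): zero-phase (forward–backward) order-2
   Butterworth into six bands — delta 0.1–4, theta 4–8, alpha 8–12, beta
   12–30, low gamma 30–50, high gamma 50–100 Hz. Filtering always precedes
   epoching; second-order-sections keep narrow low bands stable at 1 kHz.
3. **Epoching** (`epoch`): 3 s trials from −1 s to +2 s around target-stimulus
   onsets; trials without full support are dropped and logged; fewer than 20
   target trials triggers a warning.
4. **Windowing** (`crop_window`): the 200–600 ms post-stimulus window.
   Conventions are 0-based and half-open: at 1 kHz this is samples
   1200..1599 of a 3000-sample trial with onset at sample 1000.
5. **Phase-lag index** (`pli`): with instantaneous phases φ from the
   analytic signal, PLI(i,j) = |mean_t sign(wrap(φ_i−φ_j))|, the difference
   wrapped into (−π, π] and sign(0) = 0, so zero-lag (volume-conducted)
   coupling is discounted. The analytic signal is computed on the full 3 s
   filtered trial and cropped afterwards, keeping Hilbert edge artifacts
   outside the analysis window. Per-trial matrices are averaged per subject,
   band, and condition (`average_fc`).

A caveat the test suite makes explicit: the expectation of PLI between
*independent* channels is governed by the number of effectively independent
phase-difference stretches in the window (≈ window × bandwidth), not by the
number of samples. The folded-normal bound √(2/(π·400)) ≈ 0.04 applies to
fast-mixing phases; for the 50 Hz wide high-gamma band the per-trial null
level is ≈ √(2/(π·20)) ≈ 0.18, and for delta/alpha the phase difference
barely moves within 400 ms, so per-trial null PLI is large (~0.4–0.5) and
trial averaging of the absolute statistic does not remove it. This inflated
narrowband null is a property of the PLI definition itself and is shared
with the real analysis; all inference is paired (ON vs OFF), which cancels
the bias.

## Statistical primitives

Self-contained in `dbsnet.stats`:

* **Wilcoxon signed-rank** (two-sided): zero differences are dropped before
  ranking (reported n is post-drop), tied absolute differences get
  mid-ranks. The null distribution is exact (sign-flip convolution) up to 25
  nonzero pairs and a normal approximation with continuity and tie
  correction above. All-zero differences give a flagged degenerate result
  with p = 1 rather than an exception.
* **Covariate adjustment for paired tests**: rank tests have no native
  covariate mechanism. The difference vector is regressed on centered
  covariates and only the fitted covariate contribution is removed — the
  grand mean (the paired effect) is retained — before testing the adjusted
  differences against zero. Removing the intercept too would annihilate the
  effect under test. Gender enters as a 0/1 indicator.
* **Spearman partial correlation**: x and y are rank-transformed
  (mid-ranks), residualized on the covariates plus intercept, and the
  Pearson correlation of the residuals is referred to a t distribution with
  n − 2 − k degrees of freedom. With no covariates this is plain Spearman.
* **FDR**: Benjamini–Hochberg step-up at q = 0.05 throughout.
* **Confusion metrics**: PPV, NPV, sensitivity, specificity; a
  zero-denominator metric is returned as NaN and excluded from averages,
  never imputed as 0.

## Motor subnetwork

The bilateral motor subnetwork comprises 14 AAL ROIs (precentral, SMA,
postcentral, caudate, putamen, pallidum, thalamus, both hemispheres; the STN
itself is below the reach of scalp source reconstruction). Its 91
within-subnetwork connections per subject and condition are summarized by
the **first eigenvariate**: ON and OFF rows of all subjects are pooled into
one subjects·conditions × 91 matrix per band, columns are mean-centered (not
variance-standardized — PLI edges share a scale), and the first right
singular vector supplies a common loading basis; subject scores are row
projections. Pooling keeps ON and OFF scores directly comparable; the sign
is fixed so the mean loading is non-negative, and variance explained is
s₁²/Σs². Loading matrices are reported in the cortical-first ROI ordering
(precentral, SMA, postcentral, then caudate, putamen, pallidum, thalamus).

Per band, ON vs OFF scores are compared with the covariate-adjusted
signed-rank test, FDR across the six bands. In bands surviving FDR,
per-region **seed connectivity** (mean of a region's 13 within-subnetwork
edges) is tested ON vs OFF with FDR across the 14 regions, and the OFF-state
eigenvariate scores are correlated with motor improvement
(UPDRS_diff = MDS-UPDRS III ON − OFF; more negative = larger benefit) by
Spearman partial correlation with age and gender as covariates. Additional
covariate columns (disease duration, stimulation duration, severity,
levodopa-equivalent dose) can be appended for sensitivity analyses.

## Whole-brain patterns

Edge vectors are the row-major upper triangle of the 90×90 matrix (4005
edges). Edgewise ON/OFF differences use the paired signed-rank test with FDR
across all 4005 edges within a band — deliberately conservative; with weak
diffuse effects nothing survives, which is the expected outcome.

Connectivity patterns are principal components of the ON-state edge vectors
across subjects (column-centered SVD, components in descending eigenvalue
order). The number of retained components per band comes from a repeated
randomized elbow rule on the scree values: 1-D k-means with random
initialization for k = 1, 2, …, the elbow being the smallest k whose
within-cluster variance reduction relative to k = 1 reaches 95%; the
repetition's answer is the size of the cluster containing the largest scree
value, and the mode over 100 repetitions (ties toward fewer components) is
used. Pattern scores are then correlated with the five neuropsychological
T-scores (digit span, two word-list recalls, Stroop interference, Mattis
total) by Spearman partial correlation; FDR spans the full component × test
grid per band. Missing T-scores are dropped pairwise, never imputed.

## Responder classification

A subject is an *optimal responder* at threshold t when UPDRS_diff < t (the
operating point of interest is t = −18). The **connectivity profile** of a
possibly-optimal subset is, per band, the set of edges whose subset-mean
ON−OFF difference deviates at least four population SDs from the band's
mean edge difference; each retained edge carries the sign of its difference.
Classification features are the stimulation-OFF PLI values of the profile's
edges, ordered band-major.

The nested leave-one-out procedure: the outer loop holds out one test
subject; the inner loop runs a second leave-one-out over the remainder,
sweeping every distinct observed UPDRS_diff value as a candidate threshold —
thresholds leaving fewer than two subjects in either class are skipped, as
are thresholds with empty profiles. Per threshold, the profile is rebuilt
from the inner-training possibly-optimal subjects, features are standardized
with inner-training statistics, a linear SVM (C = 1, balanced class weights)
is trained, and the held-out inner subject is classified; confusion counts
aggregate across inner folds and each threshold is scored by the mean of its
defined metrics (harmonic mean and Youden's J are available as alternative
criteria). The winning threshold — ties broken uniformly at random from a
stream keyed only by (seed, repetition, fold), never by the data — is used to
rebuild profile and SVM on all non-test subjects and classify the test
subject against the label that threshold induces. Folds whose chosen
threshold yields an empty profile or a single-class training set are
recorded as unclassifiable and excluded from the counts.

Confusion counts aggregate across outer folds within a repetition; the four
metrics are averaged over repetitions (undefined values skipped). The
repetition count defaults to 100; since data, folds, and sweep are
deterministic, repetition variability stems solely from the seeded random
tie-breaking. The most frequent threshold across all folds and repetitions
fixes the final reported profile, extracted from the full cohort. The
held-out subject never influences profile extraction, threshold choice,
feature standardization, or SVM fitting in its own fold; the test suite
enforces this with a poisoning probe.

## Synthetic cohorts

`CohortSpec` defaults are the study conditions: 43 subjects, 90 ROIs, six
bands, UPDRS_diff uniform over integers [−41, −9] (so ~70% of subjects fall
below the −18 operating point), ages N(61, 7), 14/43 female, UPDRS_OFF
uniform over [30, 70] raised where needed so UPDRS_ON stays non-negative.
Baseline edges are Beta(2, 5) draws (right-skewed sparse coupling; the real
null edge distribution is unknown). All planting is additive with clipping
to [0, 1]; clipping above 20% of edges is logged.

Planted structure, each with a ground-truth record that no analysis stage
reads:

* **OFF-state motor pattern** — a fixed unit-norm loading over the 91 motor
  connections (0.15 on cortico-cortical links, 1.0 elsewhere: the low
  within-cortical / high subcortical two-module layout), added to both
  conditions of the high-gamma band scaled by `motor_effect_size` (default
  2.0, i.e. per-edge shifts up to ≈0.2) times the subject's normalized
  improvement. This makes better responders express the pattern more
  strongly even with the stimulator off, which is what
  `correlate_off_with_updrs` must recover.
* **ON-state motor increase** — `on_motor_increase` (default 0.01) added
  uniformly to the motor subnetwork in the ON condition of the high-gamma
  band: the group-level stimulation effect detected by the band-wise test.
  The generator needs this knob because the responder profile alone affects
  only the optimal subgroup and cannot produce a cohort-wide paired effect.
* **Responder profile** — ten fixed (band, edge, direction) entries outside
  delta. For optimal responders only, the ON−OFF difference at these edges
  shifts by direction × `profile_effect_size` (default 0.15 ≈ 6 band-SDs
  for typical subset sizes) and the OFF values shift by direction ×
  `profile_off_effect` (default 0.1). The OFF shift is what makes
  pre-stimulation classification possible at all: were only the ON−OFF
  difference planted, the OFF features would carry no label information and
  the classifier could only perform at chance.
* **Cognition pattern** — a unit-norm random whole-brain edge pattern whose
  per-subject ON-state expression (SD `cognition_pattern_sd` = 2.5, enough
  for the pattern to dominate the ON-state scree) correlates at
  `cognition_effect_size` = 0.7 with the Stroop-interference T-score; the
  other four T-scores are pure noise, emulating a single true
  cognition–connectivity association.
* **Coupled oscillators** (`generate_coupled_timeseries`) — narrowband
  phase-diffusing oscillators for signal-level fixtures: listed edges share
  a generator with a constant phase offset, all other channels have
  independent phase trajectories, plus white noise at 1/snr.

Effect-size defaults were set by power reasoning at design time (eigenvector
signal-to-noise against the Beta baseline edge SD ≈ 0.16, 4-SD rule
feasibility against band SDs) so that the planted effects are detectable at
n = 43 with ≥90% power — the generator emulates a clearly positive study,
not a marginal one. What the generator does **not** emulate: volume
conduction and field spread, inter-regional correlation structure of real
PLI matrices (baseline edges are independent), sensor-level artifacts, and
realistic effect sizes, which the source study does not report. Passing
recovery tests therefore demonstrate correctness of the estimators and the
absence of information leakage — not expected performance on real EEG.

A single integer seed drives everything through counter-based sub-streams
(subject × purpose), so cohorts are reproducible bit-for-bit and extensible
without reshuffling history.

## Numerical and design choices

* Exact signed-rank null up to n = 25; beyond that the normal approximation
  error is far below the discreteness of the statistic.
* Eigenvariate scores are computed as explicit projections of the centered
  rows onto the loading vector, so identical ON/OFF matrices yield exactly
  degenerate paired tests instead of 1e−16 noise.
* The elbow rule's mapping from cluster count to "number of components" —
  the size of the cluster containing the largest scree value — is one of
  several defensible readings of the cited k-means elbow utility; it is
  deterministic given the seed and covered by an exhaustive two-cluster
  oracle in the tests.
* Threshold grid for the responder sweep = distinct observed UPDRS_diff
  values of the inner-training set; the reported threshold is therefore a
  grid value, and two grid values separating the same subjects denote the
  same classifier.
* Problem sizes in the test suite and acceptance script (Monte-Carlo over
  100 cohorts at n = 43 with 90 ROIs; 500 null cohorts at 30 ROIs for
  p-value calibration, where parcellation size is irrelevant; classifier
  checks at n = 43 with 36–45 ROIs, where only the classification mechanics
  are under test) are the package's chosen desk-scale operating points.

## Known limitations

* The inner sweep trains O(n² · thresholds) SVMs per repetition; at n = 43
  a repetition takes on the order of a minute. The procedure is exactly the
  specified one; for large repetition counts, run it once per cohort and
  persist the report.
* With perfectly separable data, several thresholds tie at the maximal inner
  score and the random tie-break occasionally selects a threshold whose
  induced label for the single held-out subject differs from the planted
  boundary; a few such boundary folds are the irreducible error floor of
  the procedure itself.
* Under a true global null the 4-SD rule selects almost no edges (that is
  what 4 SDs of an approximately Gaussian difference field means), so most
  folds are unclassifiable; chance-level behavior is therefore verified with
  permuted clinical scores, which preserve the connectivity structure while
  destroying every label–feature link.
* On label-permuted data the procedure performs *below* chance
  (sens + spec well under 1). This is the leave-one-out anti-learning
  artifact: removing the held-out subject from its own training fold
  subtracts its (feature-cluster, label) pair from the alignment the SVM
  learns, and with a true correlation of zero the classifier amplifies that
  small negative bias into a sign flip. The identity sens + spec = 1 holds
  only for predictions independent of training composition; the meaningful
  null guarantee — which the tests assert — is one-sided: no positive skill.
  Information leakage would violate it in the opposite direction.
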