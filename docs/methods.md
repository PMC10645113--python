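# Methods

This note documents the models, conventions and numerical choices behind
`hyenatrack`, in the order data flows through the pipeline, and states
what the synthetic-data generator does and does not emulate.

## Units, time and conventions

Acceleration is in g with gravity magnitude 1; axes are surge
(front–back), sway (side–side) and heave (up–down) on a collar-mounted
tag. Timestamps are tz-naive UTC; "days" and "hours of day" are
local-time calendar units under a fixed configurable UTC offset
(`utc_offset_h`, default +3 h for East Africa). Partial days at
deployment edges are excluded from every statistic: an hour counts as
covered only when all of its 3 s windows are present, and a daily curve
is complete only when all 24 hours are.

## Preprocessing

- **Downsampling** is block-mean decimation (each output sample is the
  mean of `rate/target_rate` consecutive inputs). The alternative —
  naive sample-picking — aliases high-frequency gait energy; averaging
  preserves dynamic-body-acceleration energy better. The factor must be
  an integer.
- **GPS speed filter**: per-fix speed is displacement from the previous
  valid fix divided by elapsed time; fixes above a percentile of the
  speed distribution (default 99.95) are invalidated. The percentile is
  computed per individual by default; `pooled_speed_threshold` supports
  a pooled cut-off across a population, and a fixed threshold can be
  passed explicitly (which also makes the filter idempotent).
- **Gap interpolation**: a gap bounded by valid fixes is filled linearly
  iff its duration is under 5 s *or* its endpoint displacement under
  5 m (an OR rule: brief dropouts are benign even when fast, and long
  dropouts are benign when the animal plainly did not move).
  Leading/trailing gaps are never filled and valid fixes never altered.
- Latitude/longitude inputs are projected to a local equirectangular
  plane about the track centroid before any distance computation; at
  the ~50 km scale of a single clan's range the projection error is
  negligible relative to GPS noise.

## VeDBA and activity levels

Per-sample VeDBA uses a sliding window (default 1 s) *centred* on the
sample with edge truncation — centring treats behaviour onsets and
offsets symmetrically. Within the window the per-axis mean is removed
(static/gravity component) and the Euclidean norms of the residual
vectors are *summed* across the window. Summation (not averaging) is
deliberate; a mean-VeDBA variant is a one-line change but the summed
form is the package's convention and all thresholds refer to it.

Log-mean VeDBA is the natural log of the mean per-sample VeDBA over
non-overlapping 3 s intervals (75 samples at 25 Hz), floored at 1e-12
before the log so all-zero intervals stay finite. Trailing partial
intervals are dropped.

Activity levels come from the empirical distribution of log-mean VeDBA:
a Gaussian KDE (Scott bandwidth) on a 1024-point grid, interior local
minima ranked by the prominence of the inverted density, and the top
`n_modes - 1` minima taken as thresholds. Prominence ranking matters
because the high-activity mode is rare (galloping is a small fraction of
windows) and a raw density ranking would discard it. A fixed preset
`(-3.4, 0)` is available for data whose units match the published cut
points; level assignment is strict below (`low` means x < t₁, so a value
exactly on a cut point belongs to the level above).

## Classification

Features are {min, max, mean, variance} per channel; variance is the
population variance (divide by n) — the convention is pinned by a test
against an enumerated ramp. Windows that straddle an audit state change,
or are only partially audited, are dropped rather than majority-labelled:
with 3 s windows the data loss is negligible and label noise is avoided.

Classifiers are scikit-learn estimators at library defaults (random
forest: 100 trees, Gini, unlimited depth; SVM: RBF kernel, C = 1;
k-NN: k = 5, Euclidean). The SVM and k-NN receive a `StandardScaler`
fitted on training folds only (leakage-safe); `scaling=False` reproduces
the raw-feature variant. Class imbalance is left as-is. The three
validation schemes share one report format: overall accuracy plus a
row-normalized confusion matrix (rows = true states; unoccupied rows are
NaN). Grouped folds whose training set lacks a test-set class still
predict; the condition is recorded in the report notes.

## Activity curves and daily fractions

An activity curve is the percentage of each local hour's windows in WALK
or LOPE. The daily activity fraction is the percentage over the whole
(fully covered) day; with equal windows per hour it equals the plain
mean of the 24 hourly values, and in general it is their
coverage-weighted mean. For figure-style summaries a pooled per-hour
percentage across days is provided; all statistics use per-day curves.

## Compensation regressions

Consecutive-day pairs (xᵢ = day i, yᵢ = day i+1) are built only across
truly consecutive dates; a date gap breaks pairing. Trailing m-day mean
predictors require the full m+1-day run present (no partial means).
Fits are ordinary least squares via the standard closed-form
(`scipy.stats.linregress`); a zero-variance predictor yields an
explicitly undefined (NaN) slope rather than an error. Regressions are
per individual; a pooled option exists but is off by default since
between-individual level differences would confound the within-animal
question.

## Individuality test

Curve-pair variability is the sum of squared hourly differences
(squared-percent units). The statistic is mean across-individual minus
mean within-individual variability over different-day pairs only;
same-date cross-individual pairs are excluded by default (an inclusion
flag exists for sensitivity). The null reshuffles, independently per
permutation and per calendar date, the assignment of that date's curves
among the individuals holding data that date — preserving per-individual
curve counts and per-date curve multisets exactly (asserted in tests).
The one-tailed p is the fraction of null statistics ≥ observed, reported
as "< 1/N" at zero exceedances; an add-one convention is available by
flag. The per-individual follow-up compares each animal's within
variability to the overall different-day variability under the same
null; animals with above-average day-to-day noise get negative
statistics and p near 1.

## Synchrony and proximity

The synchronization score is cosine similarity between two hour-by-hour
activity series over jointly observed hours, with a small epsilon
(1e-6) guarding zero vectors; it is bounded in [0, 1] and exactly 1 for
self-pairs. Cosine was chosen as the bounded similarity consistent with
self-pairs scoring 1; Pearson correlation is available via
`method="pearson"` for sensitivity. Because all individuals share the
daily rhythm, raw scores are uniformly high; significance comes from the
day-shuffle null — each permutation independently permutes each
individual's day order while preserving within-day hour structure, which
absorbs the shared rhythm by construction. A pair is synchronized iff
the observed score is strictly greater than 95% of the null scores.

Proximity weights are fractions of *jointly valid* seconds within a
distance threshold (strict <). Thresholds 50/100/200/300/500 m probe
robustness; weights are nested-monotone in the threshold by
construction. The synchrony-versus-proximity comparison is deliberately
qualitative (a tidy table with a `violation` flag for synchronized
low-proximity pairs); no formal network test is attempted at n = 5.

## The synthetic generator

The generator emulates the statistical structure the downstream analyses
assume, not hyena biomechanics:

- **Rhythm**: hourly active-state probability follows a two-bump
  von-Mises-like template on the 24 h circle (default peaks 19:00 and
  05:00 local, concentration 2.5), scaled between a baseline (0.05) and
  peak (0.55) active probability by `rhythm_amplitude` (default 0.8).
  Defaults mirror a crepuscular-nocturnal clan of five animals tracked
  ~40 days.
- **Idiosyncrasy**: a fixed per-individual hour-of-day offset curve,
  N(0, `idiosyncrasy_sd`) per hour (default 0.06 on the probability
  scale).
- **Coupling**: `coupling_matrix` is the target correlation of both the
  hour-level latent fluctuations (scale `latent_sd`, default 0.08) and
  the day-level AR(1) innovations, realised by multiplying independent
  per-individual standard-normal substreams by the (semidefinite-safe)
  Cholesky factor. Lower-triangular mixing plus per-individual seed
  substreams means appending an individual never perturbs existing
  ones; a perfectly coupled pair shares streams exactly.
- **Day effects**: an AR(1) multiplier with coefficient `day_autocorr`
  and stationary sd `day_effect_sd` (default 0.15) scales each day's
  probabilities — the ground truth the compensation regression
  estimates.
- **State draws**: windows follow "sticky" refresh chains (copy the
  previous window with probability `persistence`, else redraw at the
  current hourly probability), giving behavioural bouts while keeping
  hourly marginals. Active bouts mix WALK:LOPE 4:1 with their own
  persistence (0.92); resting bouts mix LYING:STAND:LYUP 55:25:20 with
  high persistence (0.997) because postures are long-lived — and
  because each posture change is a gravity-orientation jump that
  registers as a VeDBA spike.
- **Accelerometer rendering**: per window, the state's unit gravity
  orientation plus a per-axis sinusoid at the state's frequency (fresh
  random phase per window) plus white noise. Gravity is cross-faded over
  ~2 s at state boundaries so posture changes do not masquerade as
  sustained high dynamic acceleration. Signature defaults are
  placeholders tuned only for separability, with the dynamic scale
  chosen so the three log-mean-VeDBA modes bracket the (-3.4, 0) preset;
  they are not a gait model.
- **GPS**: Ornstein–Uhlenbeck ranging around per-individual home centres
  (sd `ranging_sd` = 150 m, relaxation 10 min), with innovations shrunk
  4× while inactive, plus a slow shared drift (sd 2×`ranging_sd`,
  relaxation 1 h) whose cross-individual correlation is again the
  coupling matrix — so time-in-proximity rises with coupling. Drift is
  generated at 60 s resolution and held constant within the minute.

What the generator does **not** emulate — and what passing tests
therefore cannot show about field data: realistic gait harmonics and
collar rotation, terrain/habitat structure, GPS fix loss patterns,
behaviour-dependent posture sequences, or observation effort varying
across individuals. Calibration results (type-I error of the
permutation tests, classifier accuracy ordering) are statements about
the pipeline's correctness under exchangeable or separable conditions,
not about achievable field accuracy.

## Problem sizes and test conditions

Chosen to keep every check sharp but cheap:

- Classifier benchmark: 4 individuals × 3 audits × 10 min at 25 Hz
  (2400 labelled windows), seed 17; per-audit bias injection at 0.2 g
  (comparable to between-posture gravity contrasts) for the
  random-split-versus-audit-wise comparison.
- Permutation-test calibration: 200 replicates of 5 individuals × 8
  days (individuality, 500 permutations) and of rhythm-only pairs × 10
  days (synchrony, 100 permutations).
- Day-autocorrelation recovery: 50 replicates of 3 individuals × 300
  days with `day_autocorr = -0.5`, `day_effect_sd = 0.25`,
  `latent_sd = 0`, `persistence = 0.9`; the replicate estimate is the
  population-mean slope. Averaging across individuals is what the
  per-animal OLS sampling error (sd ≈ √((1-φ²)/n) ≈ 0.05 at 300 days)
  requires for a ±0.1 recovery band to be a reliable check; the reduced
  measurement-noise settings isolate the day-level signal the regression
  is meant to estimate.
- Fixture-dataset IO tests run at 1–5 Hz; sample-count arithmetic is
  rate-proportional, so the check is the same.

## Known limitations

- The KDE threshold detector assumes the low/medium/high structure is
  present; heavily skewed or unimodal data trigger a warning and a
  best-effort result rather than a hard failure.
- The pseudo-individual null requires at least two individuals sharing
  dates; single-curve dates contribute no shuffling (allowed, but they
  weaken the null).
- Hourly activity series treat hours as exchangeable units within a
  day-shuffle; sub-hourly synchrony is out of scope.
- `BehaviorSequence` assumes a regular, gap-free window grid; recording
  dropouts must be handled by splitting sequences upstream.
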