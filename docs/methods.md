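# Methods

`pinchtest` implements the analysis pipeline of a smartphone "pinching
test": a 30-second task in which a person squeezes as many on-screen tomato
shapes as possible with two fingers of the tested hand while the other hand
holds the device. The pipeline turns raw touch/inertial event logs into 37
per-run features and evaluates their psychometric properties. Because no
raw dataset of this kind is publicly deposited, the package ships an
event-level cohort simulator that reproduces the statistical structure the
analyses assume; everything downstream of the simulator is the same code
that would run on real logs.

## Segmentation and success rule

A *pinch attempt* is a maximal interval during which at least one finger is
on the screen, bounded by all-fingers-up gaps; an attempt is assigned to
the shape whose lifetime (appearance to next appearance) contains its
start. The app's internal success criterion is not published, so the
package defines one and uses it consistently in both the simulator and the
segmenter: an attempt succeeds when exactly two concurrently-down fingers
first touch within `capture_radius` (default 1.5) shape radii of the shape
center and close to at most `squeeze_fraction` (default 0.5, boundary
inclusive) of their initial separation. Attempts with more than two
concurrent fingers count as performed but never as two-finger.

## Preprocessing

Touch coordinate channels are linearly resampled to a uniform 60 Hz grid
(grid anchored at each track's first sample; interpolation is done in
relative time, making the result exactly invariant under time translation)
and low-pass filtered with a zero-phase fourth-order Butterworth filter
before any path or velocity feature is computed. The configured cutoff of
fs/2 sits exactly at the Nyquist frequency, where a low-pass filter is
degenerate; the effective cutoff is therefore clamped to 0.99x Nyquist.
Zero-phase (forward-backward) filtering is used so that filtering cannot
shift timing landmarks; timing landmarks themselves (touch-down/lift
times) are always taken from the raw events, never from the filtered
trace.

The inertial stream is trimmed by 2 s at each end (dropping the set-up and
wind-down phases), its acceleration-magnitude and inclination channels are
resampled to a 20 ms period, and each channel is smoothed with a 10-sample
moving Blackman window normalized to unit sum ("same"-length output,
reflect-padded edges, so a constant channel passes through unchanged).
Streams shorter than twice the trim are unprocessable; their runs carry
missing inertial features and fail the validity check.

## Features

Thirteen pinching features: number of performed and successful pinches,
fraction of successful and of two-finger attempts, and — per two-finger
attempt, summarized across attempts by the within-run aggregate (median by
default; configurable to mean) — pinch time, gap time (attempt start minus
target-shape appearance; the first shape appears at t = 0), double touch
and double lift asynchrony, inter-finger distance at first contact and at
lift, finger path length (both fingers' polyline lengths summed, on the
filtered trace), finger velocity (path length / pinch time), and finger
path ratio (path length / summed straight-line displacements; >= 1, with
1 = perfectly straight movement). Per-attempt quantities use *all*
two-finger attempts, not only successful ones; the source description does
not fix this choice, and using all attempts keeps the estimate defined in
runs without successes.

Eleven inertial features from the stabilizing hand: mean, SD and excess
kurtosis of the acceleration magnitude over three windows — inside attempt
intervals ("pinch duration"), their complement ("pinch gaps"), and the
whole trimmed test — plus *horizontalness* (mean |cos(inclination)|; 1 =
device flat) and *orientation stability* (negative SD of inclination;
higher = steadier, so that worse hand function correlates negatively).
Kurtosis is the population excess kurtosis (normal = 0) and needs at least
4 samples in its window.

Thirteen fatigability features: for each pinching feature, its value on
the second half of the test minus the first half, attempts assigned to
halves by start time relative to duration/2 (boundary in the second half),
each half summarized with the same within-run aggregate. Count features
difference per-half counts. No preprocessing beyond the pinching chain is
applied. A half without the needed attempts yields a missing value.

## Validity, retention, aggregation

Runs performed with the device lying flat (e.g. on a table) are invalid.
The detector uses the stabilizing-hand stream: invalid iff the
acceleration-magnitude SD falls strictly below `min_acc_sd` (default
0.005 g) *and* the mean inclination is below `max_flat_inclination`
(default 0.1 rad) — a still but propped-up device is not flagged. The
thresholds sit an order of magnitude above accelerometer noise and an
order of magnitude below hand-tremor levels, so on the simulator the
detector separates the two classes with no overlap. Runs without a
processable inertial stream are invalid (`no_imu`).

Participants contribute at least 20 valid runs (per analyzed hand,
dominant by default) to be retained. Features are aggregated per
participant over consecutive 14-day windows anchored at the participant's
first valid run (calendar alignment is not specified in the source;
per-participant anchoring avoids empty leading windows), each window
requiring at least 3 valid runs — and at least 3 non-missing values per
feature — and over the whole study. The aggregate is the median for all
features, plus the SD (sample SD, ddof = 1) additionally for fatigability
features, whose day-to-day scatter is itself informative. Clinical anchors
are averaged over the available clinic visits (up to 3); a missing visit
is simply ignored.

## Psychometric analyses

**Test-retest reliability** is ICC(2,1): two-way random effects (subject +
window + residual), absolute agreement, single measurement, over the
2-week-window medians. On balanced data the classical ANOVA formula is
used. On unbalanced data the variance components are estimated by
Henderson's method III: the sequential sums of squares
SS(subject | mean, window), SS(window | mean) and SSE are equated to their
exact expectations (computed from projector traces) and the 3x3 linear
system is solved. Component estimates are *not* truncated at zero, so the
balanced case reproduces the textbook ICC(2,1) formula exactly; the final
ratio is clamped to [-1, 1]. Confidence intervals are percentile
bootstrap over subjects (200 replicates by default). Bands: poor < 0.5,
moderate 0.5-0.74, good 0.75-0.9, excellent > 0.9.

**Convergent validity** is the age- and sex-adjusted Spearman correlation:
both variables are residualized on an intercept + age + sex by least
squares, and the Spearman correlation of the residual pairs is reported
with a case-resampling bootstrap CI. A variable lying in the covariate
span to numerical precision has nothing left to correlate; its adjusted
correlation is reported as exactly 0 rather than as the rank correlation
of floating-point noise. The partial variant residualizes x, y and the
conditioning variable z on the covariates, rank-transforms all three, and
reports the partial Pearson correlation of the ranked x and y given ranked
z. Strength bands: uncorrelated |r| < 0.25, fair 0.25-0.49,
moderate-to-good 0.50-0.75, good-to-excellent > 0.75.

**Known-groups validity** compares healthy controls with the two
MS subgroups (MS-Normal: baseline dominant-hand 9HPT time strictly below
22.15 s; MS-Abnormal: the rest) and, for fatigability features, fatigued
(FSMC total >= 43) with non-fatigued MS. How "age- and sex-adjusted" was
operationalized for a rank test is not stated in the source; here values
are residualized on age and sex before testing. Each feature category
(pinching; inertial; fatigability by median; fatigability by SD) gets its
own Benjamini-Hochberg correction of the two-sided Mann-Whitney p-values.
Effect sizes are Cohen d on the residuals (pooled SD; Hedges correction
off) and the AUC = U/(n1 n2) with the midrank tie convention, reported
oriented >= 0.5 with the raw direction retained.

**Feature structure** uses window-level median aggregates (run-level rows
are configurable): the repeated-measures correlation (common-slope ANCOVA
with per-subject intercepts; r is the signed square root of
SS_x/(SS_x+SS_error), df = N - n_subjects - 1; subjects with constant x
are dropped with a warning), PCA as the eigendecomposition of the
correlation matrix of z-scored complete cases (constant columns dropped),
and principal-axis factoring (communalities iterated from squared multiple
correlations) with varimax rotation. Factoring is implemented in-package
and validated by simulate-and-recover tests (congruence >= 0.95 against
injected two-factor structure).

## The synthetic cohort

Each participant carries a latent disability score d >= 0 (truncated
normal; HC mean 0.25, SD 0.15; MS mean 1.0, SD 0.55) and a latent fatigue
trait with configurable correlation to d (default 0.6). Day-level noise
(SD 0.15) and a nondominant-hand penalty (0.15) perturb the effective
score per run. Within a run, shapes appear sequentially (a new shape
0.05 s after each success); each attempt draws a reaction latency, an
attempt duration, touch/lift asynchronies, a success indicator
(logistic in d) and an attempt geometry: two minimum-jerk straight-line
finger paths converging on the shape, with AR(1) tremor noise (SD linear
in d) on interior samples — endpoints are noise-free so that the
simulator's drawn success labels and the segmenter's classification agree
exactly. Failures either miss the shape or under-squeeze. The inertial
stream is gravity at a tilted orientation plus AR(1) inclination wobble
and acceleration noise, both increasing with d; with probability 0.05 a
run is generated "flat on the table" (near-zero acceleration variance,
inclination ~ 0) for the validity filter to catch. Attempts starting in
the second half are slowed in proportion to the day's fatigue level; with
the fatigue slope at 0 the halves are exchangeable and fatigability
features are centered on zero.

Clinical anchors are monotone functions of d (or of the fatigue trait for
the fatigue questionnaire) plus visit noise, three visits each, on
plausible scales (9HPT ~ 17.5 + 4.5 d s; EDSS on the 0-5.5 half-point
grid; SDMT decreasing in d; FSMC ~ 22 + 36 x fatigue). EDSS, functional
system scores and the arm-item questionnaire are emitted for the MS group
only. The cohort default is 18 controls and 67 MS participants followed
for 168 days with two runs per day, alternating hands.

Only signs and orderings are calibrated — the simulator makes no attempt
to match the source study's effect sizes, so passing tests demonstrate
that the pipeline recovers injected structure, not that it reproduces any
clinical effect magnitude. Real data differ in ways the generator does not
emulate: missing days and uneven adherence, device heterogeneity,
palm-touch artifacts, learning effects over weeks, and anchor
distributions with floor/ceiling effects.

## Problem sizes and numerical choices

The validation suite runs the full pipeline on a simulated cohort of 100
MS + 12 HC participants over 56 days (two runs per day; ~12,500 runs),
enough for every participant to clear the 20-valid-run retention rule
with margin; the ICC recovery experiments use 100 subjects x 6 windows,
averaged over 10 replicate cohorts so the check isolates estimator bias
from single-draw Monte-Carlo noise. Bootstrap replicates default to 200
(50 or fewer in the validation suite, where only point estimates are
asserted). Exact-identity checks (AUC vs pair counting, BH vs step-up,
aggregation vs two-pass statistics, balanced ICC vs ANOVA) are asserted
at 1e-12 to 1e-6; analytic filter-response checks at 1%.

Degenerate inputs: zero-variance variables raise; windows with fewer than
4 samples yield missing kurtosis; runs with zero two-finger attempts emit
counts but missing per-attempt features; boundary values are inclusive
where documented (squeeze fraction, FSMC cut) and exclusive where
documented (9HPT cut: strictly below = normal; validity SD: strictly
below = invalid).

## Known limitations

* The run-log schema and the success rule are reconstructions; the
  original app's internals are unpublished.
* The ICC bootstrap resamples subjects only, ignoring window-level
  dependence within subjects.
* The fatigability ICC and the fatigue-split contrasts are exercised on
  simulated fatigue dynamics only.
* No longitudinal progression modelling and no multivariate classifiers
  over the feature space; the analyses are per-feature.
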