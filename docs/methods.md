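# Methods

`mwgaze` detects mind wandering (MW) — attention drifting from an ongoing
audio-visual task to task-unrelated thought — from binocular eye tracking
alone, in the setting of a seated viewer 1.8 m from a projection wall
listening to an audio guide while a 120 Hz head-mounted tracker reports
left-, right- and combined-eye gaze in wall-pixel coordinates.  This note
records the models, conventions and design choices the package commits to,
and what its synthetic validation does and does not establish.

## Coordinate, unit and geometry conventions

All timestamps are seconds from recording start; coordinates are 0-based
wall pixels with y growing downward.  Durations become milliseconds only
inside feature values.  Visual angle converts to on-wall length by the
exact chord formula

    px = pixels_per_metre · 2 · d · tan(θ / 2),

with `d` the viewer distance (default 1.8 m) and `pixels_per_metre`
defaulting to 1000 px/m; the inverse is exact, so the conversion
round-trips to machine precision.  The combined gaze signal is taken from
the log when present and otherwise recomputed as the mean of the left and
right points (which of the two the original recordings used is not
knowable; both are supported).

## Oculomotor event detection

Fixations are detected with the dispersion-threshold algorithm (I-DT) on
the combined signal.  A window of consecutive valid samples grows while its
dispersion — the Salvucci–Goldberg sum of x- and y-ranges — stays at or
below the pixel equivalent of the angular threshold (default 1.0°, the
detection threshold; the tracker-accuracy value of 0.5° is available by
configuration).  A maximal window spanning at least 100 ms becomes a
fixation carrying its centroid, sample count and minimal-enclosing-circle
(MEC) radius; otherwise the start pointer advances one sample.  Invalid
samples are skipped, and a gap between consecutive valid samples longer
than `gap_tolerance_ms` (default 75 ms) terminates the window: blinks and
track loss are indistinguishable in this signal, so short outages are
bridged and long ones split events.  The detector is implemented as an
incremental state machine; the batch function feeds a whole recording
through it, which is what makes streaming replay exactly reproducible (see
below).  Its segmentation is verified in the tests against an exhaustive
brute-force reference that re-measures every candidate window, and the MEC
radius against a combinatorial search over all pair- and triple-defined
circles.

Saccades are derived from consecutive fixation pairs with an inter-fixation
gap of at most 200 ms (longer gaps are treated as track loss, not
saccades); duration is the gap, length the centroid distance, amplitude its
visual angle, velocity amplitude/duration.

## Windowed features

Recordings are segmented per trial into non-overlapping 1-s windows
anchored at the trial start, the trailing partial window discarded.  Every
window yields 37 features — 11 fixation, 22 saccade, 4 vergence — in a
fixed documented order (`mwgaze.features.FEATURE_NAMES`):

* seven summary statistics (mean, min, max, median, sample SD, moment
  skewness g1, excess kurtosis g2) of fixation duration (ms), saccade
  duration (ms), saccade length (px) and saccade velocity (deg/s);
* numbers of fixations and saccades per second;
* percentage of fixation duration, the fixation/saccade duration ratio,
  and the mean MEC radius of the window's fixations;
* mean and SD of per-sample binocular disparity (left–right distance, px)
  and of the per-fixation distance between left-eye and right-eye sample
  centroids.

Events belong to a window by temporal overlap.  Duration *statistics* use
full unclipped durations (a 3-s fixation overlapping the window contributes
3000 ms); the bounded *percentage* and *ratio* features clip event time to
the window, and the ratio's denominator is floored at one sample period
(1/120 s) so saccade-free windows stay finite.  Moments that are undefined
at the window's sample size — SD below n=2, skewness below n=3, kurtosis
below n=4 — are reported as 0, as are all features of event-free windows,
which carry an explicit flag; zero-filling rather than dropping keeps the
streaming contract total.  Windows whose valid-sample fraction falls below
`min_valid_fraction` (default 0.5; tracking-loss rates vary by setup, so
this is a configurable convention) are dropped in batch extraction and reported as
`unknown` by the stream.  "Centroid distance of gaze point sets" is read
per fixation (binocular centroids of one fixation's samples); this is a
documented choice where the original description is ambiguous, as is
collapsing the MEC radii to their window mean.

Deliberately excluded: blink features (not
separable from mapping failures or track loss), fixation dispersion beyond
the MEC radius, and any within-participant normalisation (the detector is
meant to generalise to unseen users).

## Annotation from the fade-out probe

During long trials the audio volume fades linearly at 5 percentage
points/s (fast mode; medium 2.5, slow 1.67; speech-speed fades at 9/4.5/3
wpm/s are modelled but not the study default) down to a 0.01 % floor until
a keypress restores it.  With the calibrated mean reaction time r = 3.59 s
(SD 1.56 s), each fade with onset `e` and keypress `k` contributes:

* if `k − r > e`: an MW span [e, k − r] and an excluded-reaction span
  [k − r, k] (the listener was reacting, not necessarily wandering — this
  data trains nothing);
* otherwise only the excluded span [e, k].

Short trials under explicit attention instructions are focused in full.  A
1-s window inherits a label only when *fully contained* in a span of that
label (an overlap mode exists behind a flag); everything else stays
unlabelled and out of training.  Containment prevents label bleed across
the window grid and makes MW-window counts monotone non-increasing in the
assumed reaction time.

## The session simulator

The generator exists because the human recordings are not public; it
emulates the protocol well enough to exercise every pipeline stage and to
state quantitative expectations the tests check.

Attention is a two-state semi-Markov process: focused dwells are
exponential with hazard 1/30 s⁻¹, MW dwells log-normal with mean 15 s
(log-sd 0.6), giving a long-run MW occupancy of one third, in line with
the ~31 % MW share such fine-grained labelling yields on human sessions.  Gaze alternates fixations
and saccadic transitions: focused fixation durations are log-normal with
median 250 ms and log-sd 0.4 at ~3 fixations/s (typical scene-viewing
statistics), targets hop by log-normal amplitudes
(median 4°) in random directions across a 5 m × 3 m wall.  The MW state
multiplies fixation durations (default 2.0), divides the fixation rate
(default 0.5 — the inter-fixation gap is solved so the rate target holds
given the inflated durations), inflates within-fixation jitter (default
1.5) and shifts binocular disparity (default +6 px): fewer, longer, more
dispersed fixations, the reported oculomotor signature of MW.

Tracker noise is modelled in two parts: accuracy (0.5°) acts as a
per-fixation systematic offset, while sample-to-sample jitter uses the much
smaller precision scale (default 0.1°, SD = half its pixel equivalent).
Collapsing both into per-sample noise at the accuracy scale would exceed
the I-DT dispersion threshold for any full window and no fixation would
ever be detected; separating them is standard tracker physics and keeps the
generator and detector mutually consistent, which a test verifies (detected
mean fixation duration within 10 % of the generative mean).  Track loss
appears as Poisson bursts (0.1/s, 50–150 ms) of invalid samples.

Fade onsets follow each other at U(15, 30) s gaps (pushed past a pending
keypress when an MW episode delays it).  The keypress latency is a
truncated-normal draw (bounds 0.5–15 s) around the 3.59 s mean when the
viewer is focused at onset, and the MW-episode remainder plus such a draw
otherwise — so annotation recovers spans lying mostly inside true MW
episodes, which a test quantifies (≥ 80 % with small reaction spread).
Each long trial ends with a critical-sentence span whose quiz response is
correct with probability decreasing in the span's true MW fraction.  One
seed fans out to per-trial generators via `SeedSequence.spawn`; identical
seeds give byte-identical session files.

The default protocol mirrors a full session (eight 30-s focused clips,
four 600-s long clips).  The test suite and the acceptance script run a
deliberately scaled-down cohort — 12 participants, two short clips and one
180-s long clip each — chosen so the end-to-end checks (two cohorts, two
5×3 cross-validation sweeps, a streaming replay) complete in minutes while
keeping several hundred labelled windows per cohort.

What the simulator does **not** reproduce: head movement, saccade
main-sequence kinematics, calibration drift, content-driven gaze (areas of
interest), or any audio.  Passing tests therefore demonstrate that the
pipeline recovers the statistical structure this generator encodes — they
do not certify classifier performance on human data, and the published
human-data results are not reproduction targets here.

## Classification and evaluation

Four families with the published hyperparameters: random forest (100
trees), SVM (polynomial kernel, C = 20, probability estimates enabled),
gradient-boosted trees (learning rate 0.1, max depth 10) and a multilayer
perceptron (two hidden layers of 20, SGD with learning-rate 0.5 under
inverse-scaling decay, momentum 0.3; the hidden width is a free choice,
set near the common (features + classes)/2 heuristic).  No rebalancing,
no feature scaling.

Evaluation is five iterations of 3-fold cross-validation over
*participants* (leave-9-of-27-out at full scale; 4-of-12 on the test
cohort), partition redrawn each iteration, models trained only on
out-of-fold participants — absence of leakage is asserted structurally on
every fold.  The 15 fold results aggregate to mean (SD) of rank AUC,
support-weighted F1, and the MW-positive false-positive rate, precision and
recall at a 0.5 probability threshold (a configurable
convention).  AUC is checked in the tests against
exhaustive pair counting.  Hyperparameter tuning picks, per fold, the grid
point with the best AUC and returns the modal winner across the 15 trials,
ties resolving toward the earliest grid entry so published values stay
preferred.  Test-phase seeds are derived separately from tuning seeds.

Null calibration permutes labels *globally but afresh in every CV
iteration* (`modeling.null_calibration`).  A single fixed permutation
leaves a chance alignment between each participant's feature profile and
their shuffled base rate that does not average out on a 12-participant
cohort (measured drift up to ~0.57); permuting within participants is
biased the other way, because a participant's true MW occupancy shapes both
their base rate and their feature distribution.  Fresh per-iteration
permutations make the pooled mean concentrate at 0.5 (measured 0.496–0.505
across seeds).

Feature ranking follows the information-gain attribute evaluation:
supervised discretisation by recursive entropy minimisation with the MDL
stopping criterion (entropies in bits), then IG = H(class) − H(class |
bins), descending, ties alphabetical; a feature whose every candidate cut
fails the MDL test scores 0.  Ranking SVM features by primal weights is not
implemented — with a polynomial kernel there are no primal weights to rank.
Ablation re-runs cross-validation with identical folds and seeds on the
reduced feature set and reports per-metric deltas.

## Streaming classification

The stream classifier replays the batch pipeline incrementally.  Samples
feed the same I-DT state machine; second `k` (window [k, k+1) anchored at
the trial start) is finalised as soon as every event that can overlap it is
closed — the open I-DT window must start at or after k+1, and a pending
saccade that could reach back before k+1 must be resolved.  A final flush
closes the last window at end of stream.  Because the events and feature
arithmetic are byte-for-byte those of the batch path, streamed and batch
per-second labels are identical, which is the invariant the tests enforce.
The price is latency: typically one saccade plus the ongoing fixation
(a fraction of a second), but an unusually long stable fixation delays the
seconds it covers until it ends.  A hard one-second emission deadline was
considered and rejected — it cannot coexist with exact batch equivalence,
and exactness is the more valuable contract (approximate real-time output
remains available by flushing, and per-window compute is far below one
second on one CPU).

Seconds with a valid-sample fraction below threshold emit `unknown`.  The
percent-MW measure over a critical sentence is 100 × (MW seconds) /
(classified seconds), counting a second when its window start lies inside
the span; `unknown` seconds leave both numerator and denominator, and the
measure is undefined (reported missing) when nothing in the span was
classified.

## Validation statistics

Quiz responses encode to 1 iff the chosen option equals the correct one;
"I am not sure" and every wrong option encode to 0; missing responses are
excluded with a logged count.

The repeated-measures correlation of x and y over participants is the
ANCOVA common-slope correlation: removing each participant's means from
both variables and correlating the residuals, with the sign taken from the
common slope and df = N − k − 1 for N observations from k participants.
Binary variables enter as 0/1 numerics.  p-values use the t transform of r
at that df; 95 % confidence intervals use Fisher's z with
SE = 1/√(df − 1) — at r = 0.49 and df = 377 this prints the interval
[0.41, 0.56], matching the published convention.  The implementation is
verified against an explicit dummy-coded ANCOVA oracle (to 1e-9) and
against `pingouin.rm_corr` (r, df and p agree to numerical precision).
The point-biserial companion averages within participants first and reports
the Pearson correlation of the k aggregates with df = k − 2 and a Fisher
CI with SE = 1/√(k − 3).  A covariate or response with no within-participant
variance is an error; participants with a single observation contribute no
within-participant information and trigger a warning.

## Degenerate inputs and numerical conventions

Empty gaze series yield empty event lists; all-invalid windows are
`unknown`/dropped; an empty feature-matrix write produces a header-only
file that reads back empty.  Moment ratios whose variance underflows to
zero (denormal spreads) are reported by the undefined-moment convention
(0) rather than NaN.  Gaze logs are written at 9-decimal precision
(sub-nanosecond in time, sub-micron on the wall), which bounds round-trip
error at 1e-9 while keeping files byte-stable across identical runs.
Malformed log rows are rejected and counted, never imputed — imputation
would corrupt event detection downstream.

## Known limitations

Synthetic validation only (see the simulator section); single-threaded
reference implementation of I-DT (linear-time typical case, no attempt at
SIMD); the fade envelope models volume in percentage points with a hard
floor and does not model perceptual loudness; quiz difficulty is a noisy
companion of correctness in the simulator rather than an independent
construct; and the streaming classifier assumes per-trial streams with
monotone timestamps (time regressions are an error, not a resync).
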