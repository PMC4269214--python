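# Methods

This note documents the models, numerical choices and known limitations
of stresspipe, and what the synthetic-data generator does and does not
emulate.

## Signal chain

One subject-day pairs (a) the phone events logged between 8:00 and 20:00
local time, (b) the RR-interval session recorded the following night, and
(c) the end-of-day self-reported stress score in [0, 1]. Timestamps are
ISO-8601 with timezone; "a day" is the subject's local civil date. Days
without an HRV night are excluded from all models (day alignment), so the
three models are always evaluated on the same days.

## HRV features

**Artifact filter.** RR intervals deviating more than 20 % from the
previously *retained* interval are discarded; comparing against the last
retained beat (not the raw predecessor) means an isolated ectopic spike
costs one beat, not two. The first interval anchors the chain. A corrupted
anchor (the night's first beat itself ectopic) would invert the filter —
it then retains the artifacts and rejects the normal beats — so when fewer
than half the beats survive, the filter re-anchors on the first beat
within 20 % of the series median. The beat-time axis is rebuilt from the
retained intervals; the Lomb–Scargle estimator tolerates the resulting
uneven sampling, which is why it is used for the spectrum.

**Conventions** (fixed so that independent oracles are unambiguous):
SDNN uses the n−1 denominator; Poincaré SD1/SD2 use population variance;
pNN50 is a percentage of the number of successive differences; the RR
histogram for the geometric measures uses 1/128-s bins aligned to zero;
TINN is the base width of the least-squares triangle whose apex sits at
the modal bin, with the two base points searched over the bin edges;
ApEn uses m = 2, r = 0.2·SDNN, Chebyshev distance, self-matches included
(a constant series has r = 0 and ApEn 0 by convention). Normalized band
powers exclude VLF from the denominator: LF_nu = LF/(LF+HF). Sleep
duration is the sum of retained intervals, not wall clock. All of these
are configurable through `PipelineConfig`.

**Spectrum.** The classical Lomb–Scargle periodogram (with the
per-frequency time offset τ) is evaluated on a regular grid over
0.01–0.4 Hz with spacing 1/(4T) (oversampling 4). Two routes compute the
identical statistic: direct sums (scipy, chunked over frequencies) and a
Press–Rybicki extirpolation-FFT evaluation used for full-night series,
where the direct route would need a minute per night and gigabytes of
intermediates. With 8-point Lagrange extirpolation on a mesh oversampled
8× beyond the output Nyquist, the FFT route matches the direct sums to
~1e-11 of the spectral peak; the test suite checks both routes against a
plain-sum oracle and, on evenly spaced input, against the classical
periodogram. Band powers are trapezoidal integrals over VLF 0.01–0.04,
LF 0.04–0.15, HF 0.15–0.4 Hz.

**ApEn at scale.** Template counts use a KD-tree with per-point neighbour
queries under the Chebyshev metric — exact, and the only O(N log N)-ish
part of an otherwise O(N²) statistic; a 25k-beat night takes ~0.5 s.

## Phone features

Call, calendar, contacts-delta, battery, accelerometer, GPS and audio
features follow the definitions in the API docstrings. Choices worth
noting: the incoming/outgoing ratio is #incoming / #outgoing; call and
acceleration variances use the population denominator; calendar note size
is counted in characters; audio features (length, RMS energy) are averaged
over the day's voice responses; every division-by-zero situation yields an
explicit missing value, never an exception. DBSCAN over haversine distance
(eps 100 m, minPts 5 by default) counts visited locations, noise excluded.

Anonymization mirrors what a collection app does before upload. Audio is
chunk-permuted within each second (50-ms chunks by default, seeded), which
conserves the sample multiset, duration and RMS energy exactly. GPS tracks
are shifted so the centroid of the visited-location centroids becomes the
origin; longitude offsets are additionally scaled by cos(centroid
latitude) into the local equirectangular frame, because a plain
translation toward the equator would stretch east–west distances by
1/cos(lat) — with the scaling, day-scale pairwise distances are preserved
to first order (checked to 0.1 %). Tracks straddling the antimeridian are
not handled.

## Stress model

The multinomial logit uses reference class 0. The fit maximises the mean
log-likelihood minus a ridge penalty (default 1e-4) on the standardised
slopes; intercepts are never penalised, so the fitted mean class
probabilities reproduce the empirical class frequencies exactly, and the
penalty keeps the optimum finite on separable data — routine for
user-specific fits with ten-odd nights. The penalty is on the
per-observation scale, so duplicating every row leaves the fit unchanged.
Optimisation is L-BFGS with analytic gradient from a zero start
(deterministic); standard errors come from the analytic observed
information, back-transformed to the raw feature scale. Ties in every
argmax (classification and fusion) break toward the lower class. A class
absent from training is flagged and receives probability zero.

Two α symbols exist and are distinct config keys: `filter_alpha` (0.1,
the long-term filter coefficient, equal to the maximum day-to-day LTS
change) and `slider_alpha` (0.75, the relative-slider gain: a full swing
travels 75 % of the remaining distance toward 0 or 1). The day's overall
self-report is the mean of the absolute answer and the two transformed
relative answers; missing relatives are dropped from the mean, and the
last-week reference is the mean of the last 7 available daily scores.
Fusion weights are the normalized per-modality accuracies, computed
per user when at least 10 labeled days exist per modality, else globally;
the common (all-features) model is preferred whenever both modalities are
present in training and prediction.

## Selection and evaluation

Correlation reduction pools all users: of each pair with |r| ≥ 0.8 and
p < 0.01 (both configurable; the thresholds echo the significance marking
convention of pairwise feature correlation tables in this literature),
the member with the larger mean absolute correlation to the remaining
features is dropped until no flagged pair remains — greedy, deterministic
and idempotent. Constant features have undefined correlations and are
kept with a warning.

Sequential forward selection runs per user on the reduced set with
seeded, stratified 10-fold CV (folds capped by the smallest class count).
It stops when the best accuracy gain is ≤ `min_improvement` (default 0) —
i.e. a tie does not justify adding a feature — and records the gain at
addition as the feature's importance. Selection happens once per user,
then cross-validation re-uses the chosen subset; this two-stage order is
optimistic (no nested selection) and is kept deliberately as the protocol
under study.

Leave-one-day-out (per user, one fold per labeled day) measures the
user-specific models; leave-one-participant-out (one fold per user,
accuracy pooled over held-out days) measures the general model, whose
feature subset aggregates the per-user selections by mean importance.
Across users, LODO accuracies are averaged unweighted. Folds whose
training labels miss a class are still evaluated, with the fold flagged.
Under a uniform self-report distribution the class prior is
(0.3, 0.4, 0.3), so chance accuracy is 40 %.

## Synthetic data

The generator emulates the study's data shapes with controllable
statistical structure; all randomness derives from one seed through
`SeedSequence` spawning, so cohorts are byte-reproducible.

*Nights*: RR_k = mean + A_LF sin(2π f_LF t_k) + A_HF sin(2π f_HF t_k) +
white noise, with t_k the cumulative beat time and ectopic beats injected
as ±40 % multiplicative spikes at rate 0.01. Beat-time (not wall-time)
modulation is adequate for band-dominance and filter-recall checks but is
not a physiological model: no sleep stages, no respiratory coupling, no
circadian drift. *Days*: Poisson calls with log-normal durations, Poisson
calendar events, contact snapshots with small drift, a monotone battery
discharge with one charging block, 30-s accelerometer windows around 1 g
on the duty cycle, GPS dwell points around two cluster centres, and
white-noise audio of known RMS (low-rate synthetic audio; only length and
energy matter downstream).

*Cohorts*: per user-day the generator draws four driving feature values —
sleep duration N(6.0, 0.8) h clipped to the 4.2–9.5 h range, mean RR
N(950, 70) ms, call count Poisson(6), audio length N(20, 6) s —
standardises them with those nominal moments, pushes them through a
ground-truth reference-class logit, samples the class, and draws the
self-report uniformly inside that class's score band (so the mapped label
equals the sampled class exactly; label noise is a separate knob, default
off). The default effect directions encode higher stress with shorter
sleep, faster heart rate, more calls and shorter voice answers; the
default magnitude (slopes ±2.5 and ±5.0 per standardised feature for the
two non-reference classes, intercepts 0 and −4) was fixed once, at design
time, to make the cohort's within-population Bayes accuracy ≈ 0.82 with
class shares ≈ (0.50, 0.29, 0.21) — a "strong but not trivial" recovery
problem. Because the drivers are recovered almost exactly by extraction
(the call count exactly, durations to ~1 %), passing recovery tests shows
the modeling and evaluation chain works; it does not show that real
phone/HRV data carry this much signal.

Problem sizes used by the test suite and the acceptance script — a
10 × 30 cohort through the full raw-file pipeline, 20 nights each for the
filter and band-dominance rates, 20 selection replicates at n = 300 — were
chosen to keep every quantity's Monte-Carlo error well below its margin
while a full run stays in the minutes range on one CPU.

## Known limitations

- The 20 % artifact rule is a heuristic; it does not classify ectopic
  beats, and bursts of consecutive artifacts can still pass once the
  chain re-anchors.
- TINN on very sparse histograms (few beats) is dominated by bin
  granularity; its degenerate single-bin value is one bin width.
- The LOPO "general model" aggregates per-user selections; with no
  eligible users it falls back to the reduced feature sets.
- The logit treats classes as nominal; the ordinal structure of the
  stress levels is deliberately not exploited, and accuracy is the only
  evaluation metric.
- Missing single features drop the affected rows per model; no imputation
  is attempted.
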