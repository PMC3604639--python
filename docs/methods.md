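# Methods

## The deviation trace and fingerprint

A scale run is 15 note onsets t₀…t₁₄ (ms). We regress tᵢ on the temporal
index i (0…14, the order of playing) by ordinary least squares and keep the
residuals dᵢ = tᵢ − (â + b̂·i). The slope is free per run, so the overall
tempo and any local tempo drift are absorbed; the intercept absorbs the
starting time. The metronome is deliberately not used as the reference —
only the internal microstructure of the run remains. Traces are always
indexed by playing order; for cross-hand comparisons an optional *space*
alignment re-sorts both traces into keyboard (ascending-pitch) order, which
reverses descending-sounding traces.

Runs are averaged element-wise per hand × movement direction (unweighted
over that condition's runs), and the four averaged traces form the
2 (hands) × 2 (directions) × 15 (notes) fingerprint of a pianist-session.
Direction is body-centered: right-hand ascending = outward, left-hand
ascending = inward.

Unevenness (SD-IKI) of a run is the sample SD (n−1 denominator; the
convention for n = 14 intervals) of its 14 inter-keystroke intervals; a
session's score is the median over runs. Because differencing removes the
nominal grid, unevenness depends only on the successive differences of the
deviations.

## Run validation

A candidate run is accepted only where a window of 15 consecutive events
exactly reproduces the expected C-major pitch sequence for the hand and
direction; matches never overlap. A window whose neighbouring event repeats
the run's first or last pitch is rejected as containing a surplus note (a
doubled boundary keystroke). Rejected stretches are classified (wrong pitch,
surplus note, missing note, incomplete run) and logged, mirroring the
discard accounting of a recording session. No minimum gap between runs is
required — exact sequence match is the criterion. One consequence: streams
that butt an ascending run against a descending run sharing the pivot note
should be extracted per direction, and the shared-boundary run is rejected
as ambiguous.

## Identification and evaluation

The temporal distance between traces is √(Σ(aᵢ−bᵢ)²/n) — an RMS, i.e. a
scaled Euclidean norm, so the metric axioms hold. The correlation metric is
Pearson r over the paired values, compared on the Fisher-z scale; z(±1) is
capped at atanh(1−10⁻¹⁵) so self-comparisons stay finite and maximal. Exact
score ties resolve to the lexicographically smallest database label (with a
warning) for reproducibility.

Identification assigns each query independently to its nearest database
entry — not an optimal one-to-one assignment, deliberately: the point is
that the simplest possible matcher suffices. Evaluation uses the exact
binomial tail P(X ≥ k | chance = 1/|database|) (one-sided: the claim is
directional) and the Clopper–Pearson (beta-quantile) two-sided 95% interval
for the success proportion. The bootstrap draws 10,000 subsamples of eight
distinct pianists without replacement, classifies within the subsample, and
reports the mean, SD (n−1), and 2.5/97.5 percentile interval of the rate.

Grouped contrasts compare cross-session distances for: like-for-like cells
(self vs. other pianist); within-pianist cross-hand cell pairs grouped by
same movement (inward–inward, outward–outward) vs. same sound
(inward–outward); and same-direction cross-hand pairs within vs. between
pianists. All contrast comparisons are computed across the two sessions in
both orders, in time alignment by default.

## Stimulus rendering

A stimulus scale places note i at lead-in + i·125 ms + factor·dᵢ, where 125
ms is the nominal interval (120 BPM, four notes per beat). Two metronome
clicks (MIDI note 96) precede each scale 500 ms apart, and the first scale
note falls one click interval after the second click, continuing the pulse
(the gap is not otherwise constrained by the design, so the pulse-continuing
choice is ours). All notes last 137.5 ms at fixed velocity 64, removing
articulation and loudness cues. In paired stimuli the second scale's first
note starts 3.5 s after the first scale's first note (onset-to-onset;
configurable). Files are written at 480 PPQ with a single tempo event, so
quantization error is below 0.53 ms; the render → ingest → fit round trip
recovers factor·d to well under 1 ms.

The recognition set crosses 6 labeled pairs × {veridical, magnified ×5} ×
2 presentation orders into 24 distinct stimuli, each presented 6 times: 144
trials, shuffled per seed, in 4 blocks of 36, balanced 72 self / 72 other.

## Adaptive threshold procedure

The grid holds 500 midpoints linearly spaced over factors 0–5 crossed with
false-alarm rates {0, .1, .2, .3, .4}, slope fixed at 4: 2,500 curves
p(yes) = a + (1−a)/(1+exp(−k(x−m))). After each response the likelihood of
the full history is evaluated per curve (kept incrementally; a naive
recomputation oracle is tested against it) and the next stimulus sits at the
64%-response point of the maximum-likelihood curve, clipped to [0, 5]. The
block threshold is the midpoint of the final ML curve, without
interpolation. Numerical choices: per-trial probabilities are floored at
10⁻⁹ so a = 0 hypotheses stay comparable after a spurious "yes"; all
likelihood ties (including the empty history) resolve to the lowest grid
index (smallest a, then smallest m); if the ML curve's a exceeds 0.64 the
64% point is unattainable and the grid maximum is presented with a warning.

A 36-trial block embeds six factor-0 catch trials — two uniformly placed in
trials 1–12, four in trials 13–36 — leaving 30 adaptive trials. Catch
responses never enter the likelihood (they are validity checks); a block
whose catch "yes" ratio exceeds 30% is flagged invalid. A configuration flag
(`catch_included_in_total=False`) instead appends the six catches to a full
complement of adaptive trials.

d′ is Φ⁻¹(hit rate) − Φ⁻¹(false-alarm rate); rates of exactly 0 or 1 are
replaced by 1/(2n) and 1−1/(2n) given the per-class trial count.

Factor thresholds convert to ms as unevenness(factor · base trace) =
factor × unevenness(base trace) — linear because magnification scales every
interval deviation equally. For observers whose true decision variable is
unevenness in ms, the recovered ms threshold is a property of the observer,
not of the probe trace, while factor thresholds vary inversely with the
probe's base unevenness.

### Known limitation: high-false-alarm observers

With a 40% false-alarm observer and 30 adaptive trials, the estimate can
stick at low midpoints: chance "yes" responses at low levels anchor
low-midpoint curves, and placements then stay where the responses remain
ambiguous. Simulations show mean recovery error within 0.5 factor units for
a ≤ 0.2 everywhere and for a = 0.4 with midpoints up to ≈ 2, but growing to
≈ 0.9 at a = 0.4, m = 4. Including catch trials in the likelihood or
forcing a suprathreshold first trial does not cure this; it is a trial-count
limitation of the procedure. In practice such blocks are almost always
rejected by the 30% catch rule anyway.

## Synthetic generator

Per note j of cell (hand h, direction d) of a pianist:

    latent[h,d,j] = s·(√ec·P_j + √mc·M_{d,j} + √(1−ec−mc)·U_{h,d,j})

with all components standard normal and independent across notes: P shared
by all four cells (effector coupling ec), M_d shared by same-movement cells
(movement coupling mc), U unique. Every cell's marginal per-note SD is s
regardless of the couplings. A session adds one per-note per-cell shift (SD
`session_sd`), optionally a latent drift (SD `drift_sd`, for long retest
intervals; a single free knob, not fitted to anything); each run adds iid
keystroke noise (SD `keystroke_sd`) on the 125 ms grid. Noise is Gaussian
throughout. A `magnitude_matched` flag rescales each cell's latent to a
common RMS, producing populations that differ in trace shape only; an
optional left-hand noise multiplier (off by default) reproduces the
left-hand disadvantage.

Defaults were moment-matched once to the regime of professional scale
playing and then verified by simulation (never adjusted afterwards):
`between_sd` 4.85 ms, `session_sd` 2.5 ms, `keystroke_sd` 2.5 ms, 12 runs
per session, mc = 0.25, ec = 0.10. The moment math accounts for the OLS
residual projection, which shrinks iid per-note noise by √(13/15): predicted
between-pianist trace distance ≈ 7.2 ms, within-pianist cross-session
distance ≈ 3.4 ms, unevenness ≈ 8–9 ms. The couplings order the contrasts
(same movement < same sound; cross-hand self < other) without changing
within-cell distances.

What the generator does *not* emulate: systematic hand/direction asymmetries
(off by default), non-Gaussian or serially correlated motor noise,
note-position effects (real deviations concentrate at specific transitions,
e.g. thumb passage), error/correction behaviour, and tempo drift beyond the
linear term. Passing tests therefore show that the pipeline's inferences are
correct under the assumed statistical structure, not that real pianists
satisfy that structure.

Simulated listeners: `ObserverModel` responds "irregular" with probability
given by its true psychometric curve in either the factor or the
unevenness-in-ms domain. The same/different `RecognitionObserver` hears a
scale's deviations only if its unevenness exceeds a detection threshold
(default 10.22 ms), then responds "different" when the RMS distance between
perceived traces plus internal noise exceeds a criterion; it lapses
(guesses) on a fixed fraction of trials. This observer is a minimal model
built to link the threshold test to the recognition test — veridical pairs
are sub-threshold and yield d′ ≈ 0, magnified pairs are separable — not a
fitted model of human listeners.

## Problem sizes

The test suite and acceptance script use the cohort sizes of the designs
they emulate (8, 18, and 20 pianists; 12 runs per session; 36-trial blocks;
10,000-rep bootstrap) and check seed-level properties over 200-seed
ensembles for identification and contrast orderings and 100-block ensembles
per observer setting for threshold recovery.
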