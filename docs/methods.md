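# Methods

## Stimulus model

Stimuli are four-bar 4/4 melodies at 70 bpm built from four one-bar
rhythmic phrases, one per note-pair type (eighth-eighth, eighth-quarter,
quarter-eighth, quarter-quarter). Each phrase opens with its defining note
pair directly after the bar line, uses only eighth and quarter values, and
closes with a rest. The exact filler rhythms inside each bar are a
reconstruction under those constraints (the pair durations — 1, 1.5, 1.5
and 2 beats — are fixed; the fillers are this package's choice, defined in
`score_model.DEFAULT_PHRASES` and replaceable via the `phrases` argument).

Pitches come from one of nine candidate five-note windows of the C-major
scale, whose lowest notes run from C4 to D5 (so all pitches lie between C4
and A5). A melody's pitch sequence is a constrained random walk: the first
pitch is uniform over the window; each subsequent pitch is uniform over the
admissible neighbours of the previous one — at most one scale position away,
repetition allowed, clipped at the window boundary (where the neighbour set
shrinks to two). The default battery is 4 sets × 12 melodies with one
pitch range drawn per set; a `numpy.random.SeedSequence` split per set and
per melody makes the battery bit-reproducible from one master seed.

AOIs (2.24 × 2.11 cm) sit at the bar lines of bars 2–4, vertically centred
on the staff; bar 1 is previewed during the count-in and carries no AOI.
The published layout fixes the staff (27.3 cm wide, 1.3 cm clef block,
6.5 cm bars, centred on a 49.92 × 28.08 cm / 1920 × 1080 px image at 60 cm
viewing distance) but not the AOI pixel origins; anchoring each AOI's left
edge at its bar line is this package's convention, derived from the
geometry. The valid area (32.23 × 5.98 cm) is centred on the staff.

## Scoring

Quantization maps onset *t* to grid index ⌊*t*/Δ + ½⌋ with Δ the grid step
(214.29 ms for sixteenths at 70 bpm). A tie at exactly half a grid step
rounds up; this is a convention, chosen as the least surprising one, and is
exercised by a dedicated test. Onsets earlier than −Δ/2 clamp to index 0
with a warning; the grid extends one bar past the last stimulus onset so
trailing extras still quantize to bounded indices.

Onset matching is greedy in raw-onset order with single claiming: when two
performed notes quantize to the same stimulus position, the earlier one is
onset-correct and the later is not. This keeps each stimulus note matched
at most once, so accuracies cannot exceed 1.

Accuracy orientation: onset accuracy = onset-correct / performed; pitch
accuracy = pitch-correct / onset-correct. An empty denominator yields an
undefined (missing) value, never 0 or 1 — a melody with no onset-correct
notes has no pitch accuracy. Note-pair accuracy applies the same formulas
restricted to the two stimulus notes of each coded pair (denominator 2 for
onsets).

The recordings' time zero defaults to the end of the two-bar count-in
(`anchor="count_in_end"`), i.e. 0 ms is the first beat of the performance,
which is the frame the sixteenth grid presupposes; `file_start` and
`first_note` anchors cover recordings trimmed differently.

## Rhythm-error taxonomy

Performed notes are labelled correct/added/early/late; stimulus notes are
matched/skipped or paired early/late. After onset matching, each unmatched
stimulus note may be paired with one unmatched performed note within a
radius (default one beat). The pairing minimizes the total absolute grid
distance among maximum-cardinality pairings, computed as a rectangular
linear-sum assignment with a prohibitive cost on beyond-radius pairs. A
left-to-right greedy nearest-neighbour rule was considered and rejected: it
can pair non-optimally when errors cluster (stimulus grids {4, 6} with
performed {2, 5} is the smallest counterexample), whereas the assignment
formulation agrees with exhaustive enumeration whenever the optimum is
unique — a property the test suite checks directly. When several pairings
tie, the assignment solver's deterministic choice stands.

Early/late pairs carry onset deviation in beats (signed grid distance /
grid division; negative = early, |deviation| ≥ one grid step by
construction) and pitch deviation in semitones, which gives incorrect-onset
notes a reference pitch as well. Unpaired performed notes are *added*;
unpaired stimulus notes are *skipped*. The strict skip reading — both
neighbouring stimulus notes performed with correct onsets — is reported
separately as `skipped_strict`, because the two definitions disagree on
clustered errors; the radius-based label is total (every note gets exactly
one), the strict flag is diagnostic.

## Gaze QC and AOI measures

Trial-level criteria (any violation excludes the trial, all violations are
recorded): fixation count < 4 or > 40; total gaze duration < 4,571 ms or
> 13,714 ms (the overall reading time); more than 5 fixations outside the
valid area. A negative outside-area count is impossible for a computed
count and is treated as a data-integrity failure (corrupt record ⇒
excluded); it can only fire when the count is supplied externally.
Criteria are mutually independent, so the flags are order-independent.

Data-point criteria blank single measures while keeping the trial: saccade
measures when fewer than 3 saccades were detected, the summed forward
(progressive, i.e. rightward) saccade distance is under 13 cm, or fixation
and saccade counts differ by more than 8 — the signature of corrupted
saccade detection on noisy data. AOI records with more than 6 fixations or
over 4,000 ms of gaze are marked missing, as are AOIs no fixation entered.

AOI membership is point-in-rectangle with left/top edges inclusive and
right/bottom exclusive (every point belongs to at most one AOI; overlapping
AOIs are rejected at configuration time). A *visit* is a maximal run of
consecutive fixations inside the AOI; the first visit is the first pass and
the next re-entry the second pass — the standard reading-research
convention, adopted here because the measures themselves do not pin down a
definition. One intervening outside fixation suffices to end a visit.
Coordinates are handled in cm, with px↔cm converters at the display's
1920 px / 49.92 cm scale. Visual angle θ at distance *d* converts to screen
extent 2·*d*·tan(θ/2): 2° ≈ 2.1 cm and 1.5° ≈ 1.57 cm at 60 cm.

## Synthetic data

The performer model emulates exactly the error structure the measures
assume: per stimulus note, a skip with probability `p_skip`; otherwise an
onset displaced by a systematic delay plus zero-mean Gaussian jitter
(truncated so onsets stay non-negative — the simplest defensible motor-noise
model) and a pitch substituted with probability `p_pitch_error` by a
uniform nonzero offset within ±2 semitones; plus, per inter-onset gap, an
extra note at the gap midpoint with probability `p_add`, its pitch drawn
from the melody's five-note range as a hand-position slip would produce.
Defaults (40 ms jitter, 5 % rates) describe a competent performer whose
jitter stays well under half a grid step. The gaze model emits a
left-to-right scan (Poisson count at four fixations per bar, ~850 ms
durations, 20 % regressions, 0.3 cm positional noise), which reproduces the
scale of real melody reading (≈16 fixations per melody) without claiming
cognitive realism.

What the simulations do not emulate: expressive timing covariance between
notes, tempo drift, pedalling, hand-repositioning, fixation-detection noise
correlated across events, or memory-load effects. Passing
parameter-recovery tests therefore shows the estimators are consistent for
the generating model, not that real performances satisfy that model.

## Problem sizes and numerical choices

The test suite and the acceptance script run on generated data only:
melody-invariant checks sweep 1,000 generator seeds; quantization is
verified against a brute-force nearest-grid argmin on 10,000 random onsets;
the pairing oracle enumerates all assignments on instances of up to 6 + 6
notes; skip-rate recovery uses ≥ 10,000 simulated stimulus notes (3
binomial standard errors); jitter monotonicity uses 12 melodies × 3
repetitions per jitter level. These sizes put every stochastic check's
sampling error well inside its asserted tolerance while keeping the whole
suite to a few seconds.

Known limitations: no duration scoring (recorded durations are unreliable
without pedal control and are carried through unscored); no dynamic-time-
warping alignment (the grid-quantization method is the point); fixation
detection is upstream (inputs are pre-detected events); the statistical
modelling of the resulting tables is out of scope — the package emits
analysis-ready CSVs instead.
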