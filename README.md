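# sightscore

Tools for music sight-reading experiments that pair MIDI performance
scoring with eye-tracking quality control. The package targets researchers
who record piano performances of short notated melodies (together with eye
movements over the score) and need objective, note-level accuracy measures:
it generates the constrained-random stimulus battery, scores recorded
performances against the stimulus, classifies rhythm errors, and applies
trial/data-point exclusion rules and AOI (area-of-interest) aggregation to
fixation/saccade event tables.

## The scoring model

A stimulus melody defines note onsets on a metric grid. With tempo *T* (bpm)
and grid division *g* (subdivisions per beat; *g* = 4 gives sixteenth
notes), the grid step is Δ = 60000/(*T*·*g*) ms — 214.29 ms at 70 bpm.
Scoring proceeds in three steps:

1. **Quantization.** Each performed onset *t* is snapped to grid index
   *k* = ⌊*t*/Δ + ½⌋ (ties round up), i.e. to the nearest grid onset *k*Δ.
2. **Onset matching.** A performed note is *onset-correct* iff its grid
   index equals a stimulus note's metric position not already claimed by an
   earlier performed note. Onset accuracy = onset-correct / performed.
3. **Pitch scoring.** Only onset-correct notes have an unambiguous
   reference pitch; for those, pitch is compared by exact MIDI number.
   Pitch accuracy = pitch-correct / onset-correct (undefined when no onset
   is correct).

Beyond the binary flags, rhythm errors are classified into four types:
**added** (surplus performed notes), **skipped** (unperformed stimulus
notes), and **early**/**late** (an unmatched performed note paired to an
unmatched stimulus position by grid distance, via a minimum-total-deviation
assignment within a one-beat radius). Early/late pairs carry continuous
deviations: onset deviation in beats (negative = early) and pitch deviation
in semitones.

The gaze side implements the standard two-tier screen: trial-level
exclusions (fixation count outside 4–40, total gaze duration outside
4,571–13,714 ms, > 5 fixations outside the valid area), data-point
exclusions (saccade measures blanked when < 3 saccades, forward distance
< 13 cm, or fixation/saccade counts differ by > 8; AOI records blanked at
> 6 fixations or > 4,000 ms gaze), first/second-pass decomposition of AOI
visits, and visual-angle arithmetic (*s* = 2·*d*·tan(θ/2)).

## Worked example

Score a 4-note performance against a stimulus of four quarter notes
C4–E4–G4–C5 at 70 bpm (stimulus grid positions {0, 4, 8, 12}):

```python
from sightscore import (PerformanceNote, PerformanceRecord, TimingConfig,
                        quantize, score_performance)
from sightscore.score_model import (PAIR_TYPES, DiatonicPitch, StimulusMelody,
                                    StimulusNote, c_major_range)

timing = TimingConfig(tempo_bpm=70, grid_division=4)
print(quantize(840.0, timing).grid_index,          # -> 4
      round(quantize(840.0, timing).quantized_onset_ms))  # -> 857

stimulus = StimulusMelody(
    "demo", 0, tuple(PAIR_TYPES), c_major_range("C4"),
    tuple(StimulusNote(float(i), 1.0, DiatonicPitch.from_name(n))
          for i, n in enumerate(["C4", "E4", "G4", "C5"])), {})
performance = PerformanceRecord(
    "trial", "demo",
    tuple(PerformanceNote(o, p, 200.0)
          for o, p in [(10, 60), (880, 65), (1300, 67), (2400, 72)]),
    anchor="file_start")
scores, melody_score = score_performance(performance, stimulus, timing)
print(melody_score.onset_accuracy, melody_score.pitch_accuracy)  # -> 0.5 0.5
```

The notes at 10 ms and 880 ms quantize to grids 0 and 4 (both stimulus
positions, so onset-correct); 1300 ms and 2400 ms land on grids 6 and 11
(no stimulus note there). Of the two onset-correct notes, the first has the
right pitch (C4) and the second does not (F4 for E4) — so onset accuracy
and pitch accuracy are both 0.50.

The same pipeline is available from the shell:

```sh
sightscore generate-stimuli --seed 1 --out stimuli    # 48 melodies + manifest
sightscore score --performance stimuli/set0_mel00.mid \
    --stimulus-seed 1 --melody-id set0_mel00 --anchor file_start
sightscore gaze-qc --fixations fixations.csv --saccades saccades.csv
```

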