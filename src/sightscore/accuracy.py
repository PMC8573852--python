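"""Performance scoring against a stimulus melody.

The scoring pipeline has three steps: (1) every performed note onset is
quantized to the nearest point of the metric grid (sixteenth notes by
default — at 70 bpm one grid step is 214.29 ms, so a note played at 840 ms
snaps to grid index 4, i.e. 857 ms); (2) a quantized note is onset-correct
iff its grid index coincides with a stimulus note's metric position not
already claimed by an earlier performed note; (3) pitch is scored only for
onset-correct notes, by exact MIDI-number comparison with the stimulus
pitch at that position — only those notes have an unambiguous reference
pitch.  Per-melody onset accuracy is the fraction of performed notes with a
correct onset; pitch accuracy is the fraction of onset-correct notes with
the correct pitch (undefined when no onset is correct).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

from .midi_io import PerformanceNote, PerformanceRecord
from .score_model import StimulusMelody, TimingConfig

__all__ = [
    "QuantizedNote",
    "NoteScore",
    "MelodyScore",
    "PairScore",
    "quantize",
    "quantize_performance",
    "stimulus_grid",
    "match_onsets",
    "score_pitch",
    "score_performance",
    "melody_accuracy",
    "pair_accuracy",
]


@dataclass(frozen=True)
class QuantizedNote:
    source: PerformanceNote
    grid_index: int
    quantized_onset_ms: float


@dataclass(frozen=True)
class NoteScore:
    """Correctness flags for one performed note.

    ``pitch_correct`` is None exactly when the onset is incorrect: without a
    correct onset there is no reference pitch to compare against.
    """

    quantized: QuantizedNote
    onset_correct: bool
    pitch_correct: bool | None

    def __post_init__(self) -> None:
        if (self.pitch_correct is None) != (not self.onset_correct):
            raise ValueError("pitch_correct must be defined iff onset_correct")


@dataclass(frozen=True)
class MelodyScore:
    n_performed: int
    n_onset_correct: int
    n_pitch_correct: int

    @property
    def onset_accuracy(self) -> float | None:
        if self.n_performed == 0:
            return None
        return self.n_onset_correct / self.n_performed

    @property
    def pitch_accuracy(self) -> float | None:
        if self.n_onset_correct == 0:
            return None
        return self.n_pitch_correct / self.n_onset_correct


@dataclass(frozen=True)
class PairScore:
    """Accuracy restricted to the two stimulus notes of one coded note pair."""

    aoi_index: int
    pair_type: str
    n_onset_correct: int
    n_pitch_correct: int
    n_stimulus: int = 2

    @property
    def onset_accuracy(self) -> float:
        return self.n_onset_correct / self.n_stimulus

    @property
    def pitch_accuracy(self) -> float | None:
        if self.n_onset_correct == 0:
            return None
        return self.n_pitch_correct / self.n_onset_correct


def quantize(onset_ms: float, timing: TimingConfig, max_grid_index: int | None = None) -> QuantizedNote:
    """Snap one onset to the nearest grid position.

    A tie at exactly half a grid step rounds up to the later index.  Onsets
    earlier than half a grid step before zero are clamped to index 0 with a
    warning; ``max_grid_index`` (if given) bounds trailing extras.
    """
    if not math.isfinite(onset_ms):
        raise ValueError("onset must be finite")
    step = timing.grid_step_ms
    index = math.floor(onset_ms / step + 0.5)  # round half up
    if index < 0:
        warnings.warn(
            f"onset {onset_ms:.1f} ms more than half a grid step before zero; clamped",
            stacklevel=2,
        )
        index = 0
    if max_grid_index is not None and index > max_grid_index:
        index = max_grid_index
    return QuantizedNote(
        source=PerformanceNote(onset_ms, 60, 1.0),
        grid_index=index,
        quantized_onset_ms=index * step,
    )


def quantize_performance(
    record: PerformanceRecord, timing: TimingConfig, melody: StimulusMelody | None = None
) -> list[QuantizedNote]:
    """Quantize every note of a record; grid bounded to the melody span + 1 bar."""
    max_index = None
    if melody is not None and melody.notes:
        last_beats = melody.notes[-1].onset_beats + 4.0
        max_index = round(last_beats * timing.grid_division)
    out = []
    for note in record.notes:
        q = quantize(note.onset_ms, timing, max_index)
        out.append(QuantizedNote(note, q.grid_index, q.quantized_onset_ms))
    return out


def stimulus_grid(melody: StimulusMelody, timing: TimingConfig) -> dict[int, int]:
    """Map grid index -> stimulus MIDI pitch (stimulus onsets lie on the grid)."""
    grid = {}
    for note in melody.notes:
        pos = note.onset_beats * timing.grid_division
        index = round(pos)
        if not math.isclose(pos, index, abs_tol=1e-9):
            raise ValueError(
                f"stimulus onset {note.onset_beats} beats is off the "
                f"1/{timing.grid_division}-beat grid"
            )
        grid[index] = note.pitch.midi_number
    return grid


def match_onsets(
    quantized: Sequence[QuantizedNote], melody: StimulusMelody, timing: TimingConfig
) -> list[bool]:
    """Onset-correct flags: grid index equals an unclaimed stimulus position.

    Performed notes are processed in raw-onset order; when two quantize to
    the same stimulus position the earlier claims it, so each stimulus note
    is matched at most once and accuracies stay bounded by 1.
    """
    grid = stimulus_grid(melody, timing)
    claimed: set[int] = set()
    flags = []
    for q in quantized:
        ok = q.grid_index in grid and q.grid_index not in claimed
        if ok:
            claimed.add(q.grid_index)
        flags.append(ok)
    return flags


def score_pitch(
    quantized: Sequence[QuantizedNote],
    onset_flags: Sequence[bool],
    melody: StimulusMelody,
    timing: TimingConfig,
) -> list[NoteScore]:
    """Exact-MIDI pitch comparison for onset-correct notes (octave errors count)."""
    grid = stimulus_grid(melody, timing)
    scores = []
    for q, ok in zip(quantized, onset_flags):
        pitch_ok = (q.source.pitch == grid[q.grid_index]) if ok else None
        scores.append(NoteScore(q, ok, pitch_ok))
    return scores


def melody_accuracy(scores: Sequence[NoteScore]) -> MelodyScore:
    n_onset = sum(s.onset_correct for s in scores)
    n_pitch = sum(bool(s.pitch_correct) for s in scores)
    return MelodyScore(len(scores), n_onset, n_pitch)


def score_performance(
    record: PerformanceRecord, melody: StimulusMelody, timing: TimingConfig | None = None
) -> tuple[list[NoteScore], MelodyScore]:
    """Full pipeline: quantize, match onsets, score pitch, aggregate."""
    timing = timing or TimingConfig()
    quantized = quantize_performance(record, timing, melody)
    flags = match_onsets(quantized, melody, timing)
    scores = score_pitch(quantized, flags, melody, timing)
    return scores, melody_accuracy(scores)


def pair_accuracy(
    scores: Sequence[NoteScore], melody: StimulusMelody, timing: TimingConfig | None = None
) -> list[PairScore]:
    """Per-AOI accuracy over the two notes of each coded note pair.

    The pair of AOI *k* comprises the first two stimulus notes of bar k+2
    (the pair opens the bar).  Onset accuracy uses the pair's two stimulus
    notes as denominator; pitch accuracy conditions on the matched ones.
    """
    timing = timing or TimingConfig()
    by_grid = {s.quantized.grid_index: s for s in scores if s.onset_correct}
    out = []
    for aoi, ptype in sorted(melody.aoi_note_pairs.items()):
        bar_start = (aoi + 1) * 4.0
        pair_notes = [n for n in melody.notes if n.onset_beats >= bar_start][:2]
        if len(pair_notes) < 2:
            warnings.warn(f"AOI {aoi}: fewer than two stimulus notes in bar", stacklevel=2)
            continue
        n_onset = n_pitch = 0
        for note in pair_notes:
            s = by_grid.get(round(note.onset_beats * timing.grid_division))
            if s is not None:
                n_onset += 1
                n_pitch += bool(s.pitch_correct)
        out.append(PairScore(aoi, ptype, n_onset, n_pitch))
    return out
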