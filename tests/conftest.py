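import numpy as np
import pytest

from sightscore import PerformanceNote, PerformanceRecord, TimingConfig
from sightscore.score_model import (
    PAIR_TYPES,
    DiatonicPitch,
    StimulusMelody,
    StimulusNote,
    c_major_range,
)


@pytest.fixture
def timing() -> TimingConfig:
    return TimingConfig()  # 70 bpm, sixteenth grid


def make_melody(pitch_names, onsets_beats, durations_beats=None, melody_id="custom"):
    """A hand-built stimulus melody (bypasses the battery generator)."""
    durations_beats = durations_beats or [1.0] * len(onsets_beats)
    notes = tuple(
        StimulusNote(float(o), float(d), DiatonicPitch.from_name(p))
        for p, o, d in zip(pitch_names, onsets_beats, durations_beats)
    )
    return StimulusMelody(
        melody_id=melody_id,
        set_index=0,
        phrase_order=tuple(PAIR_TYPES),
        pitch_range=c_major_range("C4"),
        notes=notes,
        aoi_note_pairs={},
    )


def make_record(onset_pitch_pairs, melody_id="custom", duration_ms=200.0):
    notes = tuple(
        PerformanceNote(float(o), int(p), duration_ms) for o, p in onset_pitch_pairs
    )
    return PerformanceRecord("trial", melody_id, notes, anchor="file_start")


@pytest.fixture
def quarter_melody():
    """Four quarter notes C4 E4 G4 C5 at beats 0-3 (grid {0,4,8,12})."""
    return make_melody(["C4", "E4", "G4", "C5"], [0, 1, 2, 3])


@pytest.fixture
def worked_performance():
    """A worked 4-note performance: 2 correct onsets, 1 correct pitch."""
    return make_record([(10, 60), (880, 65), (1300, 67), (2400, 72)])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
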