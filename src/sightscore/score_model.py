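"""Stimulus melodies and the sight-reading stimulus battery.

The experimental stimuli are four-bar 4/4 melodies at 70 bpm, built by
randomly ordering four one-bar rhythmic phrases (one per note-pair type:
eighth-eighth, eighth-quarter, quarter-eighth, quarter-quarter) and walking
pitches stepwise through a five-note diatonic window of the C-major scale
between C4 and A5.  This module defines the domain types, the pitch-range
enumeration, the constrained random pitch walk, battery generation, the
screen/AOI geometry of the display, and beat <-> millisecond arithmetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "DiatonicPitch",
    "PhraseEvent",
    "RhythmicPhrase",
    "StimulusNote",
    "StimulusMelody",
    "ScreenGeometry",
    "TimingConfig",
    "PAIR_TYPES",
    "DEFAULT_PHRASES",
    "c_major_range",
    "enumerate_pitch_ranges",
    "generate_melody",
    "generate_battery",
    "battery_manifest",
    "beats_to_ms",
    "render_stimulus",
    "aoi_rectangles",
]

# C-major scale positions: white keys, semitone offsets within an octave.
_WHITE_OFFSETS = (0, 2, 4, 5, 7, 9, 11)
_WHITE_NAMES = ("C", "D", "E", "F", "G", "A", "B")

PAIR_TYPES = ("eighth-eighth", "eighth-quarter", "quarter-eighth", "quarter-quarter")


@dataclass(frozen=True)
class DiatonicPitch:
    """A white-key (C-major) pitch with its MIDI number and scale position.

    ``scale_degree_index`` counts C-major scale steps from C0, so adjacent
    white keys differ by exactly 1 and octaves by 7; it is the coordinate in
    which the "at most one position away" melody constraint is expressed.
    """

    name: str
    midi_number: int
    scale_degree_index: int

    @staticmethod
    def from_name(name: str) -> "DiatonicPitch":
        letter, octave_s = name[0].upper(), name[1:]
        if letter not in _WHITE_NAMES or not octave_s.lstrip("-").isdigit():
            raise ValueError(f"not a C-major (white-key) pitch name: {name!r}")
        octave = int(octave_s)
        li = _WHITE_NAMES.index(letter)
        midi = 12 * (octave + 1) + _WHITE_OFFSETS[li]
        return DiatonicPitch(f"{letter}{octave}", midi, 7 * octave + li)

    @staticmethod
    def from_scale_degree(index: int) -> "DiatonicPitch":
        octave, li = divmod(index, 7)
        return DiatonicPitch(
            f"{_WHITE_NAMES[li]}{octave}",
            12 * (octave + 1) + _WHITE_OFFSETS[li],
            index,
        )

    def step(self, n: int) -> "DiatonicPitch":
        """The pitch ``n`` scale positions away (n may be negative)."""
        return DiatonicPitch.from_scale_degree(self.scale_degree_index + n)


@dataclass(frozen=True)
class PhraseEvent:
    """One rhythmic event within a phrase: (onset, duration) in beats."""

    onset_beats: float
    duration_beats: float
    is_rest: bool = False


@dataclass(frozen=True)
class RhythmicPhrase:
    """A one-bar (4-beat) rhythmic phrase opening with its defining note pair.

    Invariants: the first two sounding events start at beat 0 and form the
    pair named by ``pair_type``; the final event is a rest; only eighth (0.5)
    and quarter (1.0) values occur; events tile exactly 4 beats.
    """

    pair_type: str
    events: tuple[PhraseEvent, ...]

    def __post_init__(self) -> None:
        if self.pair_type not in PAIR_TYPES:
            raise ValueError(f"unknown pair type {self.pair_type!r}")
        evs = self.events
        if not evs or not evs[-1].is_rest:
            raise ValueError("phrase must end with a rest")
        pos = 0.0
        for ev in evs:
            if not math.isclose(ev.onset_beats, pos):
                raise ValueError("phrase events must tile the bar contiguously")
            if ev.duration_beats not in (0.5, 1.0):
                raise ValueError("only eighth and quarter values are allowed")
            pos += ev.duration_beats
        if not math.isclose(pos, 4.0):
            raise ValueError("phrase must span exactly 4 beats")
        sounding = [ev for ev in evs if not ev.is_rest]
        if len(sounding) < 2 or sounding[0].onset_beats != 0.0:
            raise ValueError("the defining note pair must start at beat 0")
        want = {"eighth": 0.5, "quarter": 1.0}
        d1, d2 = (want[w] for w in self.pair_type.split("-"))
        if (sounding[0].duration_beats, sounding[1].duration_beats) != (d1, d2):
            raise ValueError(f"first two notes do not form a {self.pair_type} pair")

    @property
    def notes(self) -> tuple[PhraseEvent, ...]:
        return tuple(ev for ev in self.events if not ev.is_rest)


def _phrase(pair_type: str, spans: Sequence[tuple[float, bool]]) -> RhythmicPhrase:
    events, pos = [], 0.0
    for dur, is_rest in spans:
        events.append(PhraseEvent(pos, dur, is_rest))
        pos += dur
    return RhythmicPhrase(pair_type, tuple(events))


# Reconstructed one-bar phrases: the defining pair opens the bar, fillers use
# only eighth/quarter values, and each bar closes with a rest.
DEFAULT_PHRASES: dict[str, RhythmicPhrase] = {
    "eighth-eighth": _phrase(
        "eighth-eighth",
        [(0.5, False), (0.5, False), (1.0, False), (1.0, False), (0.5, False), (0.5, True)],
    ),
    "eighth-quarter": _phrase(
        "eighth-quarter",
        [(0.5, False), (1.0, False), (0.5, False), (1.0, False), (0.5, False), (0.5, True)],
    ),
    "quarter-eighth": _phrase(
        "quarter-eighth",
        [(1.0, False), (0.5, False), (0.5, False), (1.0, False), (1.0, True)],
    ),
    "quarter-quarter": _phrase(
        "quarter-quarter",
        [(1.0, False), (1.0, False), (1.0, False), (1.0, True)],
    ),
}


@dataclass(frozen=True)
class StimulusNote:
    onset_beats: float
    duration_beats: float
    pitch: DiatonicPitch


@dataclass(frozen=True)
class StimulusMelody:
    """A four-bar stimulus melody: ordered notes plus design metadata.

    ``aoi_note_pairs`` maps AOI index (0..2, covering the note pairs opening
    bars 2-4) to the pair type found there; bar 1 carries no AOI because its
    preview makes it no true first-sight reading.
    """

    melody_id: str
    set_index: int
    phrase_order: tuple[str, ...]
    pitch_range: tuple[DiatonicPitch, ...]
    notes: tuple[StimulusNote, ...]
    aoi_note_pairs: dict[int, str] = field(default_factory=dict)

    def validate(self) -> None:
        if sorted(self.phrase_order) != sorted(PAIR_TYPES):
            raise ValueError("each phrase type must appear exactly once")
        if len(self.pitch_range) != 5:
            raise ValueError("pitch range must contain 5 notes")
        degrees = {p.scale_degree_index for p in self.pitch_range}
        for n in self.notes:
            if n.pitch.scale_degree_index not in degrees:
                raise ValueError(f"pitch {n.pitch.name} outside the melody's range")
        for a, b in zip(self.notes, self.notes[1:]):
            if abs(b.pitch.scale_degree_index - a.pitch.scale_degree_index) > 1:
                raise ValueError("consecutive pitches more than one position apart")
            if b.onset_beats <= a.onset_beats:
                raise ValueError("note onsets must be strictly increasing")
        if self.notes and self.notes[-1].onset_beats + self.notes[-1].duration_beats > 16.0 + 1e-9:
            raise ValueError("melody exceeds 16 beats")

    @property
    def total_beats(self) -> float:
        return 16.0


@dataclass(frozen=True)
class ScreenGeometry:
    """Physical layout of the stimulus display, all lengths in cm.

    Defaults reproduce the experimental display: a 27.3 cm staff centred on a
    49.92 x 28.08 cm (1920 x 1080 px) image viewed from 60 cm, with a
    32.23 x 5.98 cm valid area around the staff and 2.24 x 2.11 cm AOIs.
    """

    staff_width_cm: float = 27.3
    clef_block_cm: float = 1.3
    bar_width_cm: float = 6.5
    staff_height_cm: float = 0.78
    aoi_width_cm: float = 2.24
    aoi_height_cm: float = 2.11
    valid_width_cm: float = 32.23
    valid_height_cm: float = 5.98
    image_px: tuple[int, int] = (1920, 1080)
    image_cm: tuple[float, float] = (49.92, 28.08)
    viewing_distance_cm: float = 60.0

    def __post_init__(self) -> None:
        # AOIs must not fall below the 1.5-degree foveal minimum.
        min_cm = 2 * self.viewing_distance_cm * math.tan(math.radians(1.5) / 2)
        if min(self.aoi_width_cm, self.aoi_height_cm) < min_cm - 1e-9:
            raise ValueError(
                f"AOI side below the 1.5-degree minimum ({min_cm:.2f} cm at "
                f"{self.viewing_distance_cm:g} cm viewing distance)"
            )

    @property
    def px_per_cm(self) -> float:
        return self.image_px[0] / self.image_cm[0]

    def cm_to_px(self, cm: float) -> float:
        return cm * self.px_per_cm

    def px_to_cm(self, px: float) -> float:
        return px / self.px_per_cm

    @property
    def staff_left_cm(self) -> float:
        return (self.image_cm[0] - self.staff_width_cm) / 2

    @property
    def staff_center_y_cm(self) -> float:
        return self.image_cm[1] / 2

    @property
    def valid_area_cm(self) -> tuple[float, float, float, float]:
        """(left, top, right, bottom) of the valid area, centred on the staff."""
        cx = self.image_cm[0] / 2
        cy = self.staff_center_y_cm
        return (
            cx - self.valid_width_cm / 2,
            cy - self.valid_height_cm / 2,
            cx + self.valid_width_cm / 2,
            cy + self.valid_height_cm / 2,
        )


def aoi_rectangles(geometry: ScreenGeometry) -> list[tuple[float, float, float, float]]:
    """AOI rectangles (left, top, right, bottom) in cm, for bars 2-4.

    Each AOI starts at its bar line (where the note pair appears) and is
    vertically centred on the staff.  Bar 1 has no AOI.
    """
    rects = []
    top = geometry.staff_center_y_cm - geometry.aoi_height_cm / 2
    for bar in (2, 3, 4):
        left = geometry.staff_left_cm + geometry.clef_block_cm + (bar - 1) * geometry.bar_width_cm
        rects.append((left, top, left + geometry.aoi_width_cm, top + geometry.aoi_height_cm))
    return rects


@dataclass(frozen=True)
class TimingConfig:
    """Tempo and metric-grid settings shared by scoring and rendering."""

    tempo_bpm: float = 70.0
    grid_division: int = 4  # subdivisions per beat; 4 = sixteenth notes
    count_in_bars: int = 2
    performance_bars: int = 4
    beats_per_bar: int = 4

    def __post_init__(self) -> None:
        if self.tempo_bpm <= 0:
            raise ValueError("tempo must be positive")
        if self.grid_division not in (1, 2, 4, 8):
            raise ValueError("grid_division must be one of 1, 2, 4, 8")

    @property
    def beat_ms(self) -> float:
        return 60000.0 / self.tempo_bpm

    @property
    def grid_step_ms(self) -> float:
        return self.beat_ms / self.grid_division

    @property
    def count_in_ms(self) -> float:
        return beats_to_ms(self.count_in_bars * self.beats_per_bar, self.tempo_bpm)

    @property
    def performance_ms(self) -> float:
        return beats_to_ms(self.performance_bars * self.beats_per_bar, self.tempo_bpm)


def beats_to_ms(beats: float, tempo_bpm: float) -> float:
    """Convert beats to milliseconds at the given tempo (exact, unrounded).

    Four 4/4 bars at 70 bpm give 13714.29 ms; round only when reporting.
    """
    if tempo_bpm <= 0:
        raise ValueError("tempo must be positive")
    if beats < 0:
        raise ValueError("beats must be non-negative")
    return beats * 60000.0 / tempo_bpm


def c_major_range(start: DiatonicPitch | str, n: int = 5) -> tuple[DiatonicPitch, ...]:
    """``n`` adjacent C-major scale notes ascending from ``start``."""
    if isinstance(start, str):
        start = DiatonicPitch.from_name(start)
    return tuple(start.step(i) for i in range(n))


def enumerate_pitch_ranges(
    low_start: DiatonicPitch | str = "C4",
    high_start: DiatonicPitch | str = "D5",
) -> list[tuple[DiatonicPitch, ...]]:
    """All five-note diatonic windows whose lowest note lies in [low, high].

    With the default bounds C4..D5 this yields the nine candidate ranges
    C4-D4-E4-F4-G4 through D5-E5-F5-G5-A5.
    """
    if isinstance(low_start, str):
        low_start = DiatonicPitch.from_name(low_start)
    if isinstance(high_start, str):
        high_start = DiatonicPitch.from_name(high_start)
    if low_start.scale_degree_index > high_start.scale_degree_index:
        raise ValueError("low_start must not be above high_start")
    return [
        c_major_range(low_start.step(i))
        for i in range(high_start.scale_degree_index - low_start.scale_degree_index + 1)
    ]


def generate_melody(
    rng: np.random.Generator,
    pitch_range: Sequence[DiatonicPitch],
    phrases: dict[str, RhythmicPhrase] | None = None,
    melody_id: str = "melody",
    set_index: int = 0,
) -> StimulusMelody:
    """Draw one stimulus melody: random phrase order + stepwise pitch walk.

    The first pitch is uniform over the range; every following pitch is
    uniform over the admissible neighbours of the previous one (at most one
    scale position away, staying allowed, clipped to the range).
    """
    phrases = dict(phrases or DEFAULT_PHRASES)
    if len(pitch_range) != 5:
        raise ValueError("pitch range must contain 5 notes")
    order = tuple(rng.permutation(list(phrases)))
    degrees = sorted(p.scale_degree_index for p in pitch_range)
    by_degree = {p.scale_degree_index: p for p in pitch_range}

    rhythm: list[tuple[float, float]] = []
    for bar, ptype in enumerate(order):
        for ev in phrases[ptype].notes:
            rhythm.append((bar * 4.0 + ev.onset_beats, ev.duration_beats))

    cur = int(rng.choice(degrees))
    notes = []
    for onset, dur in rhythm:
        notes.append(StimulusNote(onset, dur, by_degree[cur]))
        nbrs = [d for d in (cur - 1, cur, cur + 1) if d in by_degree]
        cur = int(rng.choice(nbrs))

    melody = StimulusMelody(
        melody_id=melody_id,
        set_index=set_index,
        phrase_order=order,
        pitch_range=tuple(pitch_range),
        notes=tuple(notes),
        aoi_note_pairs={i: order[i + 1] for i in range(3)},
    )
    melody.validate()
    return melody


def generate_battery(
    master_seed: int,
    n_sets: int = 4,
    melodies_per_set: int = 12,
    phrases: dict[str, RhythmicPhrase] | None = None,
) -> list[StimulusMelody]:
    """The full stimulus battery: ``n_sets`` x ``melodies_per_set`` melodies.

    One pitch range is drawn per set from the nine candidates; a seed
    sequence split per set and per melody makes the battery exactly
    reproducible from the master seed.
    """
    candidates = enumerate_pitch_ranges()
    ss = np.random.SeedSequence(master_seed)
    battery = []
    for set_idx, set_ss in enumerate(ss.spawn(n_sets)):
        streams = set_ss.spawn(melodies_per_set + 1)
        set_rng = np.random.default_rng(streams[0])
        pitch_range = candidates[int(set_rng.integers(len(candidates)))]
        for m_idx in range(melodies_per_set):
            battery.append(
                generate_melody(
                    np.random.default_rng(streams[m_idx + 1]),
                    pitch_range,
                    phrases,
                    melody_id=f"set{set_idx}_mel{m_idx:02d}",
                    set_index=set_idx,
                )
            )
    return battery


def battery_manifest(battery: Sequence[StimulusMelody]):
    """The battery coding table: which AOI holds which pair type per melody."""
    import pandas as pd

    rows = []
    for m in battery:
        row = {
            "melody_id": m.melody_id,
            "set": m.set_index,
            "phrase_order": "|".join(m.phrase_order),
            "pitch_range": "-".join(p.name for p in m.pitch_range),
        }
        for aoi, ptype in sorted(m.aoi_note_pairs.items()):
            row[f"aoi{aoi}_pair"] = ptype
        rows.append(row)
    return pd.DataFrame(rows)


def render_stimulus(melody: StimulusMelody, timing: TimingConfig):
    """The melody as a millisecond note table: (onset_ms, pitch, duration_ms).

    Returns a list of dicts matching the performance-note CSV dialect; use
    :func:`sightscore.midi_io.write_performance` to emit an SMF.
    """
    import warnings

    if not melody.notes:
        warnings.warn(f"melody {melody.melody_id} has no notes", stacklevel=2)
    return [
        {
            "onset_ms": beats_to_ms(n.onset_beats, timing.tempo_bpm),
            "pitch": n.pitch.midi_number,
            "duration_ms": beats_to_ms(n.duration_beats, timing.tempo_bpm),
            "velocity": 64,
        }
        for n in melody.notes
    ]
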