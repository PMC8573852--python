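"""Performance I/O: canonical note lists in absolute milliseconds.

Recordings arrive either as Standard MIDI Files or as CSV note tables
(columns ``onset_ms, pitch_midi, duration_ms, velocity``).  Both are read
into a :class:`PerformanceRecord` whose time zero is a configurable anchor:
the file start, the end of the two-bar count-in (the scoring frame, where
0 ms is the first beat of bar 1 of the performance), or the first note.
Result tables are written as plain CSV.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import pandas as pd

from . import smf
from .score_model import TimingConfig

__all__ = [
    "PerformanceNote",
    "PerformanceRecord",
    "read_performance",
    "write_performance",
    "notes_from_table",
    "write_results",
]

Anchor = Literal["file_start", "count_in_end", "first_note"]

CSV_COLUMNS = ("onset_ms", "pitch_midi", "duration_ms", "velocity")


@dataclass(frozen=True)
class PerformanceNote:
    """One recorded note event, times in absolute milliseconds."""

    onset_ms: float
    pitch: int
    duration_ms: float
    velocity: int = 64

    def __post_init__(self) -> None:
        if not 0 <= self.pitch <= 127:
            raise ValueError(f"pitch {self.pitch} outside MIDI range 0-127")
        if self.duration_ms <= 0:
            raise ValueError("duration must be positive")


@dataclass
class PerformanceRecord:
    trial_id: str
    melody_id: str
    notes: tuple[PerformanceNote, ...]
    anchor: Anchor = "count_in_end"

    def __post_init__(self) -> None:
        self.notes = tuple(sorted(self.notes, key=lambda n: (n.onset_ms, n.pitch)))


def _apply_anchor(
    notes: list[PerformanceNote], anchor: Anchor, timing: TimingConfig
) -> list[PerformanceNote]:
    if anchor == "file_start" or not notes:
        offset = 0.0
    elif anchor == "count_in_end":
        offset = timing.count_in_ms
    elif anchor == "first_note":
        offset = min(n.onset_ms for n in notes)
    else:
        raise ValueError(f"unknown anchor {anchor!r}")
    return [
        PerformanceNote(n.onset_ms - offset, n.pitch, n.duration_ms, n.velocity)
        for n in notes
    ]


def notes_from_table(df: pd.DataFrame) -> list[PerformanceNote]:
    """Build notes from a CSV-dialect table, dropping out-of-range pitches."""
    missing = [c for c in CSV_COLUMNS[:3] if c not in df.columns]
    if missing:
        raise ValueError(f"note table missing columns: {missing}")
    notes = []
    for idx, row in df.iterrows():
        pitch = int(row["pitch_midi"])
        if not 0 <= pitch <= 127:
            warnings.warn(f"row {idx}: pitch {pitch} outside 0-127, dropped", stacklevel=2)
            continue
        notes.append(
            PerformanceNote(
                float(row["onset_ms"]),
                pitch,
                float(row["duration_ms"]),
                int(row.get("velocity", 64)) if "velocity" in df.columns else 64,
            )
        )
    return notes


def read_performance(
    path: str | os.PathLike,
    timing: TimingConfig | None = None,
    anchor: Anchor = "count_in_end",
    trial_id: str | None = None,
    melody_id: str = "",
) -> PerformanceRecord:
    """Read an SMF (``.mid``/``.midi``) or CSV note table into a record.

    SMF tick times are converted to ms through the file's tempo map; CSV
    times are taken verbatim.  The anchor offset is subtracted exactly once.
    """
    timing = timing or TimingConfig()
    path = os.fspath(path)
    if path.lower().endswith((".mid", ".midi", ".smf")):
        raw, _ = smf.read_smf(path)
        notes = [PerformanceNote(n.onset_ms, n.pitch, n.duration_ms, n.velocity) for n in raw]
    else:
        notes = notes_from_table(pd.read_csv(path))
    return PerformanceRecord(
        trial_id=trial_id or os.path.splitext(os.path.basename(path))[0],
        melody_id=melody_id,
        notes=tuple(_apply_anchor(notes, anchor, timing)),
        anchor=anchor,
    )


def write_performance(
    path: str | os.PathLike,
    notes: Iterable[PerformanceNote | dict],
    timing: TimingConfig | None = None,
) -> None:
    """Write notes as SMF (``.mid``) or CSV, by file extension."""
    timing = timing or TimingConfig()
    norm = [
        n if isinstance(n, PerformanceNote) else PerformanceNote(
            n["onset_ms"], n["pitch"], n["duration_ms"], n.get("velocity", 64)
        )
        for n in notes
    ]
    path = os.fspath(path)
    if path.lower().endswith((".mid", ".midi", ".smf")):
        smf.write_smf(
            path,
            [smf.SmfNote(n.onset_ms, n.pitch, n.duration_ms, n.velocity) for n in norm],
            timing.tempo_bpm,
        )
    else:
        pd.DataFrame(
            [
                {
                    "onset_ms": n.onset_ms,
                    "pitch_midi": n.pitch,
                    "duration_ms": n.duration_ms,
                    "velocity": n.velocity,
                }
                for n in norm
            ],
            columns=list(CSV_COLUMNS),
        ).to_csv(path, index=False)


def write_results(
    out_dir: str | os.PathLike,
    note_rows: Sequence[dict] = (),
    melody_rows: Sequence[dict] = (),
    error_rows: Sequence[dict] = (),
) -> dict[str, str]:
    """Write notes.csv / melodies.csv / errors.csv; header-only when empty."""
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    schemas = {
        "notes.csv": (
            note_rows,
            [
                "trial_id", "melody_id", "note_index", "onset_ms", "pitch_midi",
                "grid_index", "quantized_onset_ms", "onset_correct", "pitch_correct",
            ],
        ),
        "melodies.csv": (
            melody_rows,
            [
                "trial_id", "melody_id", "n_performed", "n_onset_correct",
                "n_pitch_correct", "onset_accuracy", "pitch_accuracy",
            ],
        ),
        "errors.csv": (
            error_rows,
            [
                "trial_id", "melody_id", "note_index", "role", "label",
                "skipped_strict", "onset_deviation_beats",
                "pitch_deviation_semitones", "paired_note_index",
            ],
        ),
    }
    paths = {}
    for name, (rows, columns) in schemas.items():
        df = pd.DataFrame(list(rows))
        for col in columns:
            if col not in df.columns:
                df[col] = pd.Series(dtype=object)
        path = os.path.join(out_dir, name)
        df[columns].to_csv(path, index=False)
        paths[name] = path
    return paths
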