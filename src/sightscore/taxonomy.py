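"""Rhythm-error taxonomy: added, skipped, early and late notes.

Beyond the binary onset/pitch flags, rhythm errors are classified into four
types.  Onset-matched notes are *correct*.  Each unmatched stimulus note is
paired with an unmatched performed note by grid distance — the pairing is
the minimum-total-deviation assignment over all maximum-cardinality
pairings within a radius (default one beat) — and the performed partner is
labelled *early* or *late* by the sign of its onset deviation.  Performed
notes left unpaired are *added*; stimulus notes left unpaired are
*skipped*.  Early/late pairs carry continuous deviations: onset deviation
in beats (negative = early) and pitch deviation in semitones, which gives
incorrect-onset notes a reference pitch too.

The strict reading of a skip — the neighbouring stimulus notes were both
performed with correct onsets — is reported separately as
``skipped_strict``, since it diverges from the radius-based label when
errors cluster.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .accuracy import NoteScore
from .score_model import StimulusMelody, TimingConfig

__all__ = [
    "PerformedLabel",
    "StimulusLabel",
    "ErrorClassification",
    "classify_errors",
    "error_summary",
]

_FORBIDDEN = 1e9  # assignment cost for pairs beyond the radius


@dataclass(frozen=True)
class PerformedLabel:
    """Label for one performed note: correct, added, early or late."""

    note_index: int
    label: str  # correct | added | early | late
    onset_deviation_beats: float | None = None
    pitch_deviation_semitones: int | None = None
    paired_stimulus_index: int | None = None


@dataclass(frozen=True)
class StimulusLabel:
    """Status of one stimulus note: matched, skipped, or paired early/late."""

    note_index: int
    status: str  # matched | skipped | early | late
    skipped_strict: bool = False
    paired_performed_index: int | None = None


@dataclass
class ErrorClassification:
    performed: list[PerformedLabel]
    stimulus: list[StimulusLabel]


def _optimal_pairing(
    stim_grids: Sequence[int], perf_grids: Sequence[int], radius_steps: float
) -> list[tuple[int, int]]:
    """Min-total-|grid distance| assignment of maximum cardinality.

    Pairs farther apart than ``radius_steps`` are forbidden.  Implemented as
    a rectangular linear-sum assignment with a large finite cost on
    forbidden pairs (any number of real pairings is cheaper than one
    forbidden one), then dropping forbidden picks.
    """
    if not stim_grids or not perf_grids:
        return []
    cost = np.abs(
        np.asarray(stim_grids, dtype=float)[:, None] - np.asarray(perf_grids, dtype=float)[None, :]
    )
    cost[cost > radius_steps] = _FORBIDDEN
    rows, cols = linear_sum_assignment(cost)
    return [(int(i), int(j)) for i, j in zip(rows, cols) if cost[i, j] < _FORBIDDEN]


def classify_errors(
    scores: Sequence[NoteScore],
    melody: StimulusMelody,
    timing: TimingConfig | None = None,
    pairing_radius_beats: float = 1.0,
) -> ErrorClassification:
    """Classify every performed and every stimulus note (total classification)."""
    timing = timing or TimingConfig()
    div = timing.grid_division

    stim_grids = [round(n.onset_beats * div) for n in melody.notes]
    stim_pitch = [n.pitch.midi_number for n in melody.notes]

    # Which stimulus notes were matched (claimed) by onset-correct notes.
    matched_stim: dict[int, int] = {}  # stimulus index -> performed index
    for p_idx, s in enumerate(scores):
        if s.onset_correct:
            matched_stim[stim_grids.index(s.quantized.grid_index)] = p_idx

    un_stim = [i for i in range(len(stim_grids)) if i not in matched_stim]
    un_perf = [i for i, s in enumerate(scores) if not s.onset_correct]

    pairs = _optimal_pairing(
        [stim_grids[i] for i in un_stim],
        [scores[j].quantized.grid_index for j in un_perf],
        pairing_radius_beats * div,
    )
    pair_of_stim = {un_stim[i]: un_perf[j] for i, j in pairs}
    pair_of_perf = {un_perf[j]: un_stim[i] for i, j in pairs}

    performed: list[PerformedLabel] = []
    for p_idx, s in enumerate(scores):
        if s.onset_correct:
            performed.append(PerformedLabel(p_idx, "correct"))
            continue
        s_idx = pair_of_perf.get(p_idx)
        if s_idx is None:
            performed.append(PerformedLabel(p_idx, "added"))
            continue
        dev_steps = s.quantized.grid_index - stim_grids[s_idx]
        performed.append(
            PerformedLabel(
                p_idx,
                "early" if dev_steps < 0 else "late",
                onset_deviation_beats=dev_steps / div,
                pitch_deviation_semitones=s.quantized.source.pitch - stim_pitch[s_idx],
                paired_stimulus_index=s_idx,
            )
        )

    stimulus: list[StimulusLabel] = []
    for s_idx in range(len(stim_grids)):
        if s_idx in matched_stim:
            stimulus.append(StimulusLabel(s_idx, "matched"))
            continue
        strict = (s_idx - 1 < 0 or s_idx - 1 in matched_stim) and (
            s_idx + 1 >= len(stim_grids) or s_idx + 1 in matched_stim
        )
        p_idx = pair_of_stim.get(s_idx)
        if p_idx is None:
            stimulus.append(StimulusLabel(s_idx, "skipped", skipped_strict=strict))
        else:
            dev = scores[p_idx].quantized.grid_index - stim_grids[s_idx]
            stimulus.append(
                StimulusLabel(
                    s_idx,
                    "early" if dev < 0 else "late",
                    skipped_strict=False,
                    paired_performed_index=p_idx,
                )
            )
    return ErrorClassification(performed, stimulus)


def error_summary(classification: ErrorClassification) -> dict[str, float]:
    """Counts per label plus mean absolute deviations over early/late pairs."""
    counts = {label: 0 for label in ("correct", "added", "early", "late")}
    for p in classification.performed:
        counts[p.label] += 1
    counts["skipped"] = sum(s.status == "skipped" for s in classification.stimulus)
    counts["skipped_strict"] = sum(s.skipped_strict for s in classification.stimulus)
    devs_onset = [
        abs(p.onset_deviation_beats)
        for p in classification.performed
        if p.onset_deviation_beats is not None
    ]
    devs_pitch = [
        abs(p.pitch_deviation_semitones)
        for p in classification.performed
        if p.pitch_deviation_semitones is not None
    ]
    summary: dict[str, float] = dict(counts)
    summary["mean_abs_onset_deviation_beats"] = float(np.mean(devs_onset)) if devs_onset else float("nan")
    summary["mean_abs_pitch_deviation_semitones"] = float(np.mean(devs_pitch)) if devs_pitch else float("nan")
    return summary
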