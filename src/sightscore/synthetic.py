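"""Synthetic performances and gaze records with known ground truth.

A parameterised performer model turns a stimulus melody into a recording:
each stimulus note is skipped with probability ``p_skip``, otherwise played
with a systematic delay plus truncated-Gaussian onset jitter, its pitch
substituted with probability ``p_pitch_error`` (a uniform nonzero semitone
offset); extra notes are inserted between onsets with probability ``p_add``
per gap, their pitch drawn from the melody's range as a hand-position slip
would produce.  A parameterised reader model emits a left-to-right fixation
scan over the staff with occasional regressions and Gaussian positional
noise.  Both record their ground truth, so accuracy scores and taxonomy
counts can be checked against the rates that generated them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .gaze import FixationEvent, SaccadeEvent, TrialGaze
from .midi_io import PerformanceNote, PerformanceRecord
from .score_model import ScreenGeometry, StimulusMelody, TimingConfig, beats_to_ms

__all__ = [
    "PerformerParams",
    "GazeParams",
    "simulate_performance",
    "simulate_gaze",
    "recovery_experiment",
]


@dataclass(frozen=True)
class PerformerParams:
    """Error structure of a simulated performer.

    Defaults describe a competent but imperfect sight-reader: 40 ms onset
    jitter (well under half a sixteenth at 70 bpm), no systematic delay, and
    5 % pitch-substitution, skip and addition rates.
    """

    onset_jitter_sd_ms: float = 40.0
    systematic_delay_ms: float = 0.0
    p_pitch_error: float = 0.05
    p_skip: float = 0.05
    p_add: float = 0.05
    pitch_error_range_semitones: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.onset_jitter_sd_ms < 0:
            raise ValueError("jitter must be non-negative")
        for p in (self.p_pitch_error, self.p_skip, self.p_add):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class GazeParams:
    """Reading-behaviour parameters for the simulated gaze scan.

    Defaults target the scale of real melody reading: about four fixations
    per bar (sixteen per melody) of roughly 850 ms, with a 20 % regression
    rate.
    """

    fixations_per_bar: float = 4.0
    fixation_duration_mean_ms: float = 850.0
    fixation_duration_sd_ms: float = 250.0
    p_regression: float = 0.2
    noise_sd_cm: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fixations_per_bar <= 0 or self.fixation_duration_mean_ms <= 0:
            raise ValueError("means must be positive")
        if not 0 <= self.p_regression <= 1:
            raise ValueError("p_regression must lie in [0, 1]")


def simulate_performance(
    melody: StimulusMelody,
    timing: TimingConfig,
    params: PerformerParams,
    rng: np.random.Generator | None = None,
    trial_id: str = "synthetic",
) -> tuple[PerformanceRecord, pd.DataFrame]:
    """Simulate one recorded performance plus its ground-truth label table.

    Returns (record, truth) where ``truth`` has one row per event:
    ``stimulus_index`` (or -1 for inserted notes), ``status`` in
    {played, skipped, added}, ``pitch_substituted``, and the true onset.
    """
    rng = rng or np.random.default_rng(params.seed)
    beat_ms = timing.beat_ms
    pitch_pool = [p.midi_number for p in melody.pitch_range]

    notes: list[PerformanceNote] = []
    truth_rows: list[dict] = []
    onsets_ms = [beats_to_ms(n.onset_beats, timing.tempo_bpm) for n in melody.notes]

    for i, stim in enumerate(melody.notes):
        if rng.random() < params.p_skip:
            truth_rows.append(
                {"stimulus_index": i, "status": "skipped", "pitch_substituted": False,
                 "true_onset_ms": onsets_ms[i]}
            )
            continue
        onset = onsets_ms[i] + params.systematic_delay_ms
        if params.onset_jitter_sd_ms > 0:
            jitter = rng.normal(0.0, params.onset_jitter_sd_ms)
            onset = max(0.0, onset + jitter)
        pitch = stim.pitch.midi_number
        substituted = rng.random() < params.p_pitch_error
        if substituted:
            r = params.pitch_error_range_semitones
            offsets = [o for o in range(-r, r + 1) if o != 0]
            pitch = int(np.clip(pitch + rng.choice(offsets), 0, 127))
        dur = beats_to_ms(stim.duration_beats, timing.tempo_bpm) * 0.9
        notes.append(PerformanceNote(onset, pitch, dur, 64))
        truth_rows.append(
            {"stimulus_index": i, "status": "played", "pitch_substituted": substituted,
             "true_onset_ms": onsets_ms[i]}
        )

    # Insertions: one candidate per inter-onset gap, placed at the midpoint.
    for i in range(len(onsets_ms) - 1):
        if rng.random() < params.p_add:
            mid = (onsets_ms[i] + onsets_ms[i + 1]) / 2
            pitch = int(rng.choice(pitch_pool))
            notes.append(PerformanceNote(mid, pitch, beat_ms * 0.25, 64))
            truth_rows.append(
                {"stimulus_index": -1, "status": "added", "pitch_substituted": False,
                 "true_onset_ms": mid}
            )

    record = PerformanceRecord(
        trial_id=trial_id, melody_id=melody.melody_id, notes=tuple(notes)
    )
    return record, pd.DataFrame(
        truth_rows, columns=["stimulus_index", "status", "pitch_substituted", "true_onset_ms"]
    )


def simulate_gaze(
    melody: StimulusMelody,
    geometry: ScreenGeometry,
    params: GazeParams,
    rng: np.random.Generator | None = None,
    trial_id: str = "synthetic",
    n_bars: int = 4,
) -> TrialGaze:
    """Simulate a left-to-right scan of the staff with regressions.

    Fixation landing points progress across the staff width; with
    probability ``p_regression`` a fixation jumps back toward earlier
    material.  Saccades are derived from consecutive landing points.
    """
    rng = rng or np.random.default_rng(params.seed)
    n_fix = max(1, int(rng.poisson(params.fixations_per_bar * n_bars)))
    x0 = geometry.staff_left_cm + geometry.clef_block_cm
    span = geometry.staff_width_cm - geometry.clef_block_cm
    y0 = geometry.staff_center_y_cm

    targets = np.linspace(x0, x0 + span, n_fix)
    xs: list[float] = []
    pos = 0
    for _ in range(n_fix):
        if xs and rng.random() < params.p_regression:
            pos = max(0, pos - int(rng.integers(1, 4)))
        xs.append(float(targets[pos]))
        pos = min(n_fix - 1, pos + 1)

    fixations: list[FixationEvent] = []
    t = 0.0
    for x in xs:
        dur = max(30.0, rng.normal(params.fixation_duration_mean_ms, params.fixation_duration_sd_ms))
        nx = x + (rng.normal(0.0, params.noise_sd_cm) if params.noise_sd_cm > 0 else 0.0)
        ny = y0 + (rng.normal(0.0, params.noise_sd_cm) if params.noise_sd_cm > 0 else 0.0)
        fixations.append(FixationEvent(trial_id, t, dur, nx, ny))
        t += dur + 30.0

    saccades: list[SaccadeEvent] = []
    for a, b in zip(fixations, fixations[1:]):
        dx = b.x_cm - a.x_cm
        if abs(dx) < 1e-9:
            continue
        saccades.append(
            SaccadeEvent(
                trial_id,
                a.onset_ms + a.duration_ms,
                abs(dx),
                "progressive" if dx > 0 else "regressive",
            )
        )
    return TrialGaze(trial_id, melody.melody_id, fixations, saccades)


def recovery_experiment(
    melodies: Sequence[StimulusMelody],
    timing: TimingConfig,
    param_grid: Sequence[PerformerParams],
    n_reps: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Score simulated performances across a parameter grid.

    For each cell: mean onset/pitch accuracy from the scoring pipeline and
    mean taxonomy counts, next to the generating rates — the table a
    parameter-recovery check reads.
    """
    from .accuracy import score_performance
    from .taxonomy import classify_errors, error_summary

    rng = np.random.default_rng(seed)
    rows = []
    for cell, params in enumerate(param_grid):
        accs, paccs, counts = [], [], []
        n_stim = n_skip_true = 0
        for rep in range(n_reps):
            for melody in melodies:
                rec, truth = simulate_performance(melody, timing, params, rng)
                scores, mscore = score_performance(rec, melody, timing)
                summary = error_summary(classify_errors(scores, melody, timing))
                if mscore.onset_accuracy is not None:
                    accs.append(mscore.onset_accuracy)
                if mscore.pitch_accuracy is not None:
                    paccs.append(mscore.pitch_accuracy)
                counts.append(summary)
                n_stim += len(melody.notes)
                n_skip_true += int((truth["status"] == "skipped").sum())
        rows.append(
            {
                "cell": cell,
                "onset_jitter_sd_ms": params.onset_jitter_sd_ms,
                "p_skip": params.p_skip,
                "p_add": params.p_add,
                "p_pitch_error": params.p_pitch_error,
                "true_skip_fraction": n_skip_true / n_stim if n_stim else float("nan"),
                "mean_onset_accuracy": float(np.mean(accs)) if accs else float("nan"),
                "mean_pitch_accuracy": float(np.mean(paccs)) if paccs else float("nan"),
                "est_skip_fraction": float(np.sum([c["skipped"] for c in counts])) / n_stim,
                "mean_added": float(np.mean([c["added"] for c in counts])),
                "mean_early": float(np.mean([c["early"] for c in counts])),
                "mean_late": float(np.mean([c["late"] for c in counts])),
            }
        )
    return pd.DataFrame(rows)
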