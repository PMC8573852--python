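"""Eye-movement quality control and AOI aggregation.

Pre-detected fixation and saccade events for one melody-reading trial are
screened in two tiers.  Trial-level criteria exclude the whole trial
(fixation count outside 4-40, total gaze duration outside 4,571-13,714 ms,
more than 5 fixations outside the valid area, or a corrupt negative
outside-area count).  Data-point criteria keep the trial but blank single
measures: saccade measures when fewer than 3 saccades were detected, the
forward-saccade distance is under 13 cm, or fixation and saccade counts
differ by more than 8; AOI records with more than 6 fixations or over
4,000 ms of gaze.  Retained fixations are assigned to AOI rectangles and
aggregated into per-AOI counts and gaze durations, split into first-pass
(the gaze's first visit) and second-pass (the first return visit)
fixations.  An AOI no fixation ever entered is marked missing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

__all__ = [
    "FixationEvent",
    "SaccadeEvent",
    "TrialGaze",
    "QCThresholds",
    "AOIMetrics",
    "apply_trial_exclusions",
    "apply_datapoint_exclusions",
    "assign_fixations_to_aois",
    "visual_angle_to_cm",
    "cm_to_visual_angle",
]

Rect = tuple[float, float, float, float]  # (left, top, right, bottom), cm


@dataclass(frozen=True)
class FixationEvent:
    trial_id: str
    onset_ms: float
    duration_ms: float
    x_cm: float
    y_cm: float

    def __post_init__(self) -> None:
        if self.duration_ms <= 0:
            raise ValueError("fixation duration must be positive")
        if not (math.isfinite(self.x_cm) and math.isfinite(self.y_cm)):
            raise ValueError("fixation coordinates must be finite")


@dataclass(frozen=True)
class SaccadeEvent:
    trial_id: str
    onset_ms: float
    amplitude_cm: float
    direction: str  # progressive (rightward) | regressive (leftward)

    def __post_init__(self) -> None:
        if self.amplitude_cm <= 0:
            raise ValueError("saccade amplitude must be positive")
        if self.direction not in ("progressive", "regressive"):
            raise ValueError(f"unknown saccade direction {self.direction!r}")


@dataclass
class TrialGaze:
    trial_id: str
    melody_id: str
    fixations: list[FixationEvent]
    saccades: list[SaccadeEvent]
    excluded: bool = False
    exclusion_reasons: list[str] = field(default_factory=list)
    # Optional externally supplied count; None -> computed from fixations.
    n_outside_valid_area: int | None = None
    missing_measures: set[str] = field(default_factory=set)


@dataclass(frozen=True)
class QCThresholds:
    """Exclusion thresholds; defaults are the study's criteria."""

    min_fixations: int = 4
    max_fixations: int = 40
    min_total_gaze_ms: float = 4571.0
    max_total_gaze_ms: float = 13714.0
    max_outside_valid_area: int = 5
    min_saccades: int = 3
    min_forward_saccade_distance_cm: float = 13.0
    max_fix_saccade_count_diff: int = 8
    max_aoi_fixations: int = 6
    max_aoi_gaze_ms: float = 4000.0


@dataclass
class AOIMetrics:
    aoi_index: int
    pair_type: str | None
    n_fixations: int
    n_first_pass: int
    n_second_pass: int
    gaze_duration_ms: float
    first_pass_duration_ms: float
    second_pass_duration_ms: float
    missing: bool


def _in_rect(f: FixationEvent, rect: Rect) -> bool:
    # Left/top edges inclusive, right/bottom exclusive.
    left, top, right, bottom = rect
    return left <= f.x_cm < right and top <= f.y_cm < bottom


def count_outside_valid_area(trial: TrialGaze, valid_area: Rect) -> int:
    if trial.n_outside_valid_area is not None:
        return trial.n_outside_valid_area
    return sum(not _in_rect(f, valid_area) for f in trial.fixations)


def apply_trial_exclusions(
    trial: TrialGaze, valid_area: Rect, thresholds: QCThresholds | None = None
) -> TrialGaze:
    """Flag the trial with every violated trial-level criterion.

    Criteria are independent, so the resulting flags do not depend on the
    order of evaluation.  A negative outside-area count cannot arise from
    counting and marks a corrupt record.
    """
    th = thresholds or QCThresholds()
    reasons = []
    n_fix = len(trial.fixations)
    total_gaze = sum(f.duration_ms for f in trial.fixations)
    n_outside = count_outside_valid_area(trial, valid_area)
    if n_fix < th.min_fixations:
        reasons.append(f"n_fixations<{th.min_fixations}")
    if n_fix > th.max_fixations:
        reasons.append(f"n_fixations>{th.max_fixations}")
    if total_gaze < th.min_total_gaze_ms:
        reasons.append(f"total_gaze<{th.min_total_gaze_ms:g}")
    if total_gaze > th.max_total_gaze_ms:
        reasons.append(f"total_gaze>{th.max_total_gaze_ms:g}")
    if n_outside > th.max_outside_valid_area:
        reasons.append(f"outside_valid_area>{th.max_outside_valid_area}")
    if n_outside < 0:
        reasons.append("outside_valid_area_negative_corrupt")
    trial.exclusion_reasons = reasons
    trial.excluded = bool(reasons)
    return trial


def apply_datapoint_exclusions(
    trial: TrialGaze, thresholds: QCThresholds | None = None
) -> TrialGaze:
    """Blank saccade measures that violate data-point criteria; keep the trial."""
    th = thresholds or QCThresholds()
    missing = set(trial.missing_measures)
    n_sacc = len(trial.saccades)
    forward_cm = sum(s.amplitude_cm for s in trial.saccades if s.direction == "progressive")
    if n_sacc < th.min_saccades:
        missing.add("saccades")
    if forward_cm < th.min_forward_saccade_distance_cm:
        missing.add("saccades")
    if abs(len(trial.fixations) - n_sacc) > th.max_fix_saccade_count_diff:
        missing.add("saccades")
    trial.missing_measures = missing
    return trial


def _validate_aois(aois: Sequence[Rect]) -> None:
    for i, a in enumerate(aois):
        for j, b in enumerate(aois[i + 1 :], start=i + 1):
            if a[0] < b[2] and b[0] < a[2] and a[1] < b[3] and b[1] < a[3]:
                raise ValueError(f"AOIs {i} and {j} overlap")


def assign_fixations_to_aois(
    fixations: Sequence[FixationEvent],
    aois: Sequence[Rect],
    pair_types: dict[int, str] | None = None,
    thresholds: QCThresholds | None = None,
) -> list[AOIMetrics]:
    """Per-AOI fixation counts and gaze durations with pass decomposition.

    A *visit* is a maximal run of consecutive fixations inside the AOI; the
    first visit is the first pass, the next re-entry the second pass.  AOI
    records exceeding the fixation-count or gaze-duration data-point
    criteria are marked missing, as are AOIs with no fixations at all.
    """
    th = thresholds or QCThresholds()
    _validate_aois(aois)
    pair_types = pair_types or {}
    out = []
    for idx, rect in enumerate(aois):
        visits: list[list[FixationEvent]] = []
        inside_prev = False
        for f in fixations:
            inside = _in_rect(f, rect)
            if inside:
                if not inside_prev:
                    visits.append([])
                visits[-1].append(f)
            inside_prev = inside
        n_fix = sum(len(v) for v in visits)
        dur = sum(f.duration_ms for v in visits for f in v)
        first = visits[0] if visits else []
        second = visits[1] if len(visits) > 1 else []
        noisy = n_fix > th.max_aoi_fixations or dur > th.max_aoi_gaze_ms
        out.append(
            AOIMetrics(
                aoi_index=idx,
                pair_type=pair_types.get(idx),
                n_fixations=n_fix,
                n_first_pass=len(first),
                n_second_pass=len(second),
                gaze_duration_ms=dur,
                first_pass_duration_ms=sum(f.duration_ms for f in first),
                second_pass_duration_ms=sum(f.duration_ms for f in second),
                missing=n_fix == 0 or noisy,
            )
        )
    return out


def visual_angle_to_cm(angle_deg: float, distance_cm: float) -> float:
    """Screen extent subtending ``angle_deg`` at ``distance_cm``: 2 d tan(a/2).

    2 degrees at 60 cm is about 2.1 cm — the foveal high-acuity window of
    the display.
    """
    if distance_cm <= 0:
        raise ValueError("viewing distance must be positive")
    if not 0 <= angle_deg < 180:
        raise ValueError("angle must be in [0, 180) degrees")
    return 2 * distance_cm * math.tan(math.radians(angle_deg) / 2)


def cm_to_visual_angle(size_cm: float, distance_cm: float) -> float:
    """Inverse of :func:`visual_angle_to_cm`."""
    if distance_cm <= 0:
        raise ValueError("viewing distance must be positive")
    if size_cm < 0:
        raise ValueError("size must be non-negative")
    return math.degrees(2 * math.atan(size_cm / (2 * distance_cm)))
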