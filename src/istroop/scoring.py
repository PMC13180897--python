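"""ROI dwell-time scoring: the test's continuous accuracy metric.

A rectangular region of interest (ROI) is placed over the correct option of
each trial.  The trial score is the raw percentage of viewing time spent
inside that ROI during the 7-s presentation window; per-trial percentages
are averaged into condition scores and a total score in [0, 100].  Unlike a
dichotomous correct/incorrect outcome, the percentage captures intermediate
states — hesitation, partial interference — in a single continuous number.

"Viewing time" is measured over *tracked* time: the denominator is the
count of valid samples in the window (configurable to the full expected
sample budget for sensitivity analyses).  Trials with too little valid data
fail QC and are dropped from the averages rather than imputed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .gaze import GazeRecording, GazeSample, TrialWindowSamples, segment_trials
from .schedule import Condition, Corner, TaskSchedule, TrialSpec, validate_schedule, ScheduleError

__all__ = [
    "RegionOfInterest",
    "LayoutConfig",
    "ScoringConfig",
    "TrialScore",
    "ParticipantETScore",
    "roi_for_trial",
    "hit_test",
    "score_trial",
    "score_participant",
]


@dataclass(frozen=True)
class RegionOfInterest:
    """Axis-aligned rect in normalized screen units, half-open containment."""

    corner: Corner
    x0: float
    y0: float
    x1: float
    y1: float

    def __post_init__(self) -> None:
        if not (self.x0 < self.x1 and self.y0 < self.y1):
            raise ValueError(f"degenerate ROI rect {(self.x0, self.y0, self.x1, self.y1)}")

    @property
    def rect(self) -> tuple[float, float, float, float]:
        return (self.x0, self.y0, self.x1, self.y1)

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Vectorized half-open point-in-rect test (NaN-safe: NaN is outside)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x >= self.x0) & (x < self.x1) & (y >= self.y0) & (y < self.y1)


@dataclass(frozen=True)
class LayoutConfig:
    """Corner-ROI geometry: each ROI is a width×height fraction of the
    screen anchored in its corner (default 0.4 × 0.4)."""

    roi_width: float = 0.4
    roi_height: float = 0.4

    def __post_init__(self) -> None:
        if not (0 < self.roi_width <= 0.5 and 0 < self.roi_height <= 0.5):
            raise ValueError("ROI fractions must lie in (0, 0.5] so corner ROIs stay disjoint")


@dataclass(frozen=True)
class ScoringConfig:
    layout: LayoutConfig = field(default_factory=LayoutConfig)
    #: denominator for the percentage: tracked samples ("valid") or the full
    #: expected sample budget ("window", duration × nominal rate)
    denominator: str = "valid"
    #: a trial passes QC when n_valid / expected_samples ≥ this fraction
    min_valid_fraction: float = 0.5
    #: participant flagged unusable when more than this many trials fail QC
    max_failed_trials: int = 8

    def __post_init__(self) -> None:
        if self.denominator not in ("valid", "window"):
            raise ValueError("denominator must be 'valid' or 'window'")
        if not 0 <= self.min_valid_fraction <= 1:
            raise ValueError("min_valid_fraction must be in [0, 1]")


@dataclass(frozen=True)
class TrialScore:
    trial_index: int
    condition: Condition
    n_total: int
    n_valid: int
    n_hit: int
    pct: float  # NaN when the denominator is zero
    qc_pass: bool

    @property
    def missing(self) -> bool:
        return math.isnan(self.pct)


@dataclass(frozen=True)
class ParticipantETScore:
    participant_id: str
    trial_scores: tuple[TrialScore, ...]
    condition_scores: dict[Condition, float]  # NaN when no scored trial
    total_score: float
    n_qc_failed: int
    usable: bool

    def to_dict(self) -> dict:
        return {
            "participant_id": self.participant_id,
            "total_score": self.total_score,
            "condition_scores": {c.value: self.condition_scores[c] for c in Condition},
            "n_qc_failed": self.n_qc_failed,
            "usable": self.usable,
            "trials": [
                {
                    "trial_index": s.trial_index,
                    "condition": s.condition.value,
                    "n_total": s.n_total,
                    "n_valid": s.n_valid,
                    "n_hit": s.n_hit,
                    "pct": None if s.missing else s.pct,
                    "qc_pass": s.qc_pass,
                }
                for s in self.trial_scores
            ],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


_ANCHORS = {
    Corner.TOP_LEFT: (0.0, 0.0),
    Corner.TOP_RIGHT: (1.0, 0.0),
    Corner.BOTTOM_LEFT: (0.0, 1.0),
    Corner.BOTTOM_RIGHT: (1.0, 1.0),
}


def roi_for_corner(corner: Corner, layout: LayoutConfig | None = None) -> RegionOfInterest:
    """ROI rect for a corner: a layout-fraction rectangle anchored there."""
    lay = layout or LayoutConfig()
    ax, ay = _ANCHORS[corner]
    x0 = ax * (1.0 - lay.roi_width)
    y0 = ay * (1.0 - lay.roi_height)
    return RegionOfInterest(corner, x0, y0, x0 + lay.roi_width, y0 + lay.roi_height)


def roi_for_trial(trial: TrialSpec, layout: LayoutConfig | None = None) -> RegionOfInterest:
    """ROI over the trial's correct option."""
    return roi_for_corner(trial.correct_corner, layout)


def hit_test(sample: GazeSample, roi: RegionOfInterest) -> bool:
    """True iff the sample is valid and its point lies in the half-open rect."""
    if not sample.valid:
        return False
    return bool(roi.contains(sample.x, sample.y))


def score_trial(
    window: TrialWindowSamples,
    roi: RegionOfInterest,
    config: ScoringConfig | None = None,
    *,
    condition: Condition = Condition.WORD,
    expected_samples: int | None = None,
    duration: float = 7.0,
    nominal_rate: float = 50.0,
) -> TrialScore:
    """Score one trial window against its correct-option ROI.

    ``pct`` is 100 × hits / denominator; a zero denominator yields a missing
    (NaN) score with ``qc_pass=False`` rather than an error.
    """
    cfg = config or ScoringConfig()
    if expected_samples is None:
        expected_samples = int(round(duration * nominal_rate))
    n_total = len(window)
    n_valid = int(window.valid.sum())
    n_hit = int((window.valid & roi.contains(window.x, window.y)).sum())
    denom = n_valid if cfg.denominator == "valid" else expected_samples
    pct = 100.0 * n_hit / denom if denom > 0 else float("nan")
    qc_pass = (
        expected_samples > 0
        and n_valid / expected_samples >= cfg.min_valid_fraction
        and not math.isnan(pct)
    )
    return TrialScore(
        trial_index=window.trial_index,
        condition=condition,
        n_total=n_total,
        n_valid=n_valid,
        n_hit=n_hit,
        pct=pct,
        qc_pass=qc_pass,
    )


def _mean_or_nan(values: list[float]) -> float:
    return float(np.mean(values)) if values else float("nan")


def score_participant(
    rec: GazeRecording,
    sched: TaskSchedule,
    config: ScoringConfig | None = None,
    alignment_offset: float = 0.0,
) -> ParticipantETScore:
    """Full per-participant scoring: segment, score 16 trials, average.

    The total score is the arithmetic mean of per-trial percentages over
    trials passing QC; condition scores average each condition's scored
    trials.  Trials failing QC are dropped from the means, and the
    participant is flagged unusable when more than ``max_failed_trials``
    fail.
    """
    cfg = config or ScoringConfig()
    violations = validate_schedule(sched)
    if violations:
        raise ScheduleError("invalid schedule: " + "; ".join(violations))
    windows = segment_trials(rec, sched, alignment_offset)
    trial_scores = []
    for window, trial in zip(windows, sched.trials):
        roi = roi_for_trial(trial, cfg.layout)
        trial_scores.append(
            score_trial(
                window,
                roi,
                cfg,
                condition=trial.condition,
                duration=trial.duration,
                nominal_rate=rec.nominal_rate,
            )
        )
    included = [s.pct for s in trial_scores if s.qc_pass]
    condition_scores = {
        c: _mean_or_nan([s.pct for s in trial_scores if s.qc_pass and s.condition == c])
        for c in Condition
    }
    n_failed = sum(1 for s in trial_scores if not s.qc_pass)
    return ParticipantETScore(
        participant_id=rec.participant_id,
        trial_scores=tuple(trial_scores),
        condition_scores=condition_scores,
        total_score=_mean_or_nan(included),
        n_qc_failed=n_failed,
        usable=n_failed <= cfg.max_failed_trials,
    )
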