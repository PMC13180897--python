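"""Stimulus-program generation for the matching-format Stroop task.

The task is a 16-trial movie with four blocked conditions — word, reverse
Stroop, color, and Stroop — four trials each.  Every trial shows an
instruction stimulus in the screen center and four answer options, one per
corner; exactly one option is correct.  Within each condition the four
correct colors are a permutation of the palette (no color repeats as the
answer), and each corner holds the correct option exactly once, so scores
carry no spatial bias.

Condition semantics (matching format):

* ``word`` — a color word in neutral ink; options are color patches; the
  correct patch matches the word's *meaning*.
* ``reverse_stroop`` — a color word printed in an incongruent ink; options
  are color patches; correct = the word's *meaning* (ink must be ignored).
* ``color`` — a color patch; options are color words in neutral ink;
  correct = the word naming the patch.
* ``stroop`` — a color word printed in an incongruent ink; options are
  color patches; correct = the *ink* color (meaning must be ignored).

Timing: each trial lasts 7 s with a 1 s inter-trial interval; a 2 s
instruction slide separates blocks.  Coordinates are normalized screen
units, origin top-left, y increasing downward.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "Condition",
    "Corner",
    "TrialSpec",
    "TaskSchedule",
    "ScheduleConfig",
    "ScheduleError",
    "generate_schedule",
    "validate_schedule",
    "schedule_timeline",
]

DEFAULT_PALETTE = ("red", "blue", "green", "yellow")

SCHEMA_VERSION = 1


class ScheduleError(ValueError):
    """Raised for invalid schedule configuration or an invalid schedule."""


class Condition(str, Enum):
    WORD = "word"
    REVERSE_STROOP = "reverse_stroop"
    COLOR = "color"
    STROOP = "stroop"


class Corner(str, Enum):
    TOP_LEFT = "top_left"
    TOP_RIGHT = "top_right"
    BOTTOM_LEFT = "bottom_left"
    BOTTOM_RIGHT = "bottom_right"


#: conditions whose options are color patches (vs. printed color words)
PATCH_OPTION_CONDITIONS = frozenset(
    {Condition.WORD, Condition.REVERSE_STROOP, Condition.STROOP}
)
#: conditions with an incongruent word/ink pairing in the center stimulus
INCONGRUENT_CONDITIONS = frozenset({Condition.REVERSE_STROOP, Condition.STROOP})

DEFAULT_BLOCK_ORDER = (
    Condition.WORD,
    Condition.REVERSE_STROOP,
    Condition.COLOR,
    Condition.STROOP,
)


@dataclass(frozen=True)
class TrialSpec:
    """One 7-s trial: center stimulus, corner options, correct answer, timing."""

    index: int
    condition: Condition
    stimulus_word: str | None
    stimulus_ink: str | None
    options: dict[Corner, str]
    correct_corner: Corner
    onset: float
    duration: float = 7.0

    @property
    def correct_color(self) -> str:
        return self.options[self.correct_corner]


@dataclass(frozen=True)
class ScheduleConfig:
    palette: tuple[str, ...] = DEFAULT_PALETTE
    block_order: tuple[Condition, ...] = DEFAULT_BLOCK_ORDER
    trial_duration: float = 7.0
    inter_trial_interval: float = 1.0
    block_instruction_duration: float = 2.0

    def __post_init__(self) -> None:
        if len(self.palette) != 4 or len(set(self.palette)) != 4:
            raise ScheduleError(
                f"palette must hold exactly 4 distinct colors, got {self.palette!r}"
            )
        if sorted(c.value for c in self.block_order) != sorted(c.value for c in Condition):
            raise ScheduleError(
                f"block_order must be a permutation of the 4 conditions, got {self.block_order!r}"
            )
        if self.trial_duration <= 0:
            raise ScheduleError("trial_duration must be positive")
        if self.inter_trial_interval < 0 or self.block_instruction_duration < 0:
            raise ScheduleError("intervals must be non-negative")


@dataclass(frozen=True)
class TaskSchedule:
    trials: tuple[TrialSpec, ...]
    palette: tuple[str, ...]
    block_order: tuple[Condition, ...]
    inter_trial_interval: float
    block_instruction_duration: float
    seed: int

    @property
    def duration(self) -> float:
        last = self.trials[-1]
        return last.onset + last.duration

    # -- JSON serialization (round-trips bit-exact) --------------------------

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "seed": self.seed,
            "palette": list(self.palette),
            "block_order": [c.value for c in self.block_order],
            "inter_trial_interval": self.inter_trial_interval,
            "block_instruction_duration": self.block_instruction_duration,
            "trials": [
                {
                    "index": t.index,
                    "condition": t.condition.value,
                    "stimulus_word": t.stimulus_word,
                    "stimulus_ink": t.stimulus_ink,
                    "options": {c.value: t.options[c] for c in Corner},
                    "correct_corner": t.correct_corner.value,
                    "onset": t.onset,
                    "duration": t.duration,
                }
                for t in self.trials
            ],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "TaskSchedule":
        trials = tuple(
            TrialSpec(
                index=t["index"],
                condition=Condition(t["condition"]),
                stimulus_word=t["stimulus_word"],
                stimulus_ink=t["stimulus_ink"],
                options={Corner(k): v for k, v in t["options"].items()},
                correct_corner=Corner(t["correct_corner"]),
                onset=t["onset"],
                duration=t["duration"],
            )
            for t in d["trials"]
        )
        return cls(
            trials=trials,
            palette=tuple(d["palette"]),
            block_order=tuple(Condition(c) for c in d["block_order"]),
            inter_trial_interval=d["inter_trial_interval"],
            block_instruction_duration=d["block_instruction_duration"],
            seed=d["seed"],
        )

    @classmethod
    def from_json(cls, s: str) -> "TaskSchedule":
        return cls.from_dict(json.loads(s))

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "TaskSchedule":
        with open(path, encoding="utf-8") as fh:
            return cls.from_json(fh.read())


def generate_schedule(seed: int, config: ScheduleConfig | None = None) -> TaskSchedule:
    """Generate a valid 16-trial blocked schedule, deterministic in ``seed``.

    Per condition: the four correct colors are a seeded permutation of the
    palette and the four correct corners a seeded permutation of the corners
    (Latin-square balance — each corner is correct exactly once per block,
    hence four times over the full schedule).
    """
    cfg = config or ScheduleConfig()
    rng = np.random.default_rng(seed)
    corners = list(Corner)
    trials: list[TrialSpec] = []
    onset = 0.0
    index = 0
    for block_i, condition in enumerate(cfg.block_order):
        if block_i > 0:
            onset += cfg.block_instruction_duration
        correct_colors = [str(c) for c in rng.permutation(cfg.palette)]
        correct_corners = [corners[i] for i in rng.permutation(4)]
        for k in range(4):
            correct = correct_colors[k]
            distractors = [c for c in cfg.palette if c != correct]
            rng.shuffle(distractors)
            corner_cycle = corners[corners.index(correct_corners[k]):] + corners[: corners.index(correct_corners[k])]
            options = {corner_cycle[0]: correct}
            for corner, color in zip(corner_cycle[1:], distractors):
                options[corner] = color
            if condition in INCONGRUENT_CONDITIONS:
                other = [c for c in cfg.palette if c != correct]
                incong = other[int(rng.integers(len(other)))]
                if condition is Condition.STROOP:
                    word, ink = incong, correct  # answer = ink color
                else:
                    word, ink = correct, incong  # answer = word meaning
            elif condition is Condition.WORD:
                word, ink = correct, None  # neutral ink
            else:  # COLOR: center patch, options are words
                word, ink = None, correct
            trials.append(
                TrialSpec(
                    index=index,
                    condition=condition,
                    stimulus_word=word,
                    stimulus_ink=ink,
                    options=options,
                    correct_corner=correct_corners[k],
                    onset=onset,
                    duration=cfg.trial_duration,
                )
            )
            index += 1
            onset += cfg.trial_duration + cfg.inter_trial_interval
    return TaskSchedule(
        trials=tuple(trials),
        palette=tuple(cfg.palette),
        block_order=tuple(cfg.block_order),
        inter_trial_interval=cfg.inter_trial_interval,
        block_instruction_duration=cfg.block_instruction_duration,
        seed=seed,
    )


def validate_schedule(s: TaskSchedule) -> list[str]:
    """Check every schedule invariant; return human-readable violations.

    Returns an empty list iff the schedule is valid.  Never raises.
    """
    v: list[str] = []
    if len(s.trials) != 16:
        v.append(f"schedule: expected 16 trials, found {len(s.trials)}")
    if len(s.palette) != 4 or len(set(s.palette)) != 4:
        v.append(f"schedule: palette must hold 4 distinct colors, got {s.palette!r}")

    by_condition: dict[Condition, list[TrialSpec]] = {c: [] for c in Condition}
    for t in s.trials:
        by_condition[t.condition].append(t)

    for cond, ts in by_condition.items():
        if len(ts) != 4:
            v.append(f"condition {cond.value}: expected 4 trials, found {len(ts)}")

    # blocked: each condition's trials occupy contiguous indices
    seq = [t.condition for t in s.trials]
    seen: set[Condition] = set()
    prev: Condition | None = None
    for t_i, cond in enumerate(seq):
        if cond != prev:
            if cond in seen:
                v.append(f"trial {t_i}: condition {cond.value} re-opens a block (not blocked)")
            seen.add(cond)
            prev = cond

    for cond, ts in by_condition.items():
        if len(ts) == 4:
            correct = sorted(t.correct_color for t in ts)
            if correct != sorted(s.palette):
                v.append(
                    f"condition {cond.value}: correct colors {correct} are not a "
                    f"permutation of the palette"
                )

    for t in s.trials:
        if len(t.options) != 4 or set(t.options) != set(Corner):
            v.append(f"trial {t.index}: options must cover all 4 corners")
            continue
        if len(set(t.options.values())) != 4:
            v.append(f"trial {t.index}: option colors are not 4 distinct colors")
        if t.correct_corner not in t.options:
            v.append(f"trial {t.index}: correct corner missing from options")
        if t.condition in INCONGRUENT_CONDITIONS:
            if t.stimulus_word is None or t.stimulus_ink is None:
                v.append(f"trial {t.index}: {t.condition.value} requires word and ink")
            elif t.stimulus_word == t.stimulus_ink:
                v.append(
                    f"trial {t.index}: {t.condition.value} stimulus must be "
                    f"incongruent (word == ink == {t.stimulus_word!r})"
                )
        if t.duration <= 0:
            v.append(f"trial {t.index}: non-positive duration")

    onsets = [t.onset for t in s.trials]
    if any(b <= a for a, b in zip(onsets, onsets[1:])):
        v.append("schedule: onsets are not strictly increasing")
    else:
        for a, b in zip(s.trials, s.trials[1:]):
            gap = b.onset - (a.onset + a.duration)
            expected = s.inter_trial_interval
            if a.condition != b.condition:
                expected += s.block_instruction_duration
            if abs(gap - expected) > 1e-9:
                v.append(
                    f"trial {b.index}: onset gap {gap:g}s, expected {expected:g}s"
                )
    return v


def schedule_timeline(s: TaskSchedule) -> list[tuple[int, float, float]]:
    """Half-open presentation windows ``(trial_index, start_s, end_s)``.

    Raises :class:`ScheduleError` if the schedule is invalid.
    """
    violations = validate_schedule(s)
    if violations:
        raise ScheduleError("invalid schedule: " + "; ".join(violations))
    return [(t.index, t.onset, t.onset + t.duration) for t in s.trials]
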