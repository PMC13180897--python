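"""Gaze-stream containers, CSV I/O, and trial segmentation.

A recording is a timestamped stream of gaze points nominally sampled at
50 Hz by a corneal-reflection eye tracker.  Samples carry a validity flag:
when the device loses the eye (blink, head motion) the flag is false and
the coordinates are missing.  Coordinates are normalized screen units in
[0, 1], origin top-left; off-screen samples are kept (they simply fall in
no region of interest).

The CSV dialect is ``time_s,x,y,valid`` — comma-separated, UTF-8, ``.``
decimal, coordinates written to 6 decimals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .schedule import TaskSchedule, schedule_timeline

__all__ = [
    "GazeSample",
    "GazeRecording",
    "TrialWindowSamples",
    "GazeFormatError",
    "read_gaze_csv",
    "write_gaze_csv",
    "segment_trials",
]

logger = logging.getLogger(__name__)

CSV_COLUMNS = ("time_s", "x", "y", "valid")
CSV_PRECISION = 6


class GazeFormatError(ValueError):
    """Raised when a gaze CSV is unreadable or structurally wrong."""


class GazeSample(NamedTuple):
    """A single gaze point; ``x``/``y`` are NaN when the sample is invalid."""

    t: float
    x: float
    y: float
    valid: bool


@dataclass
class GazeRecording:
    """A participant's gaze stream, stored columnar for vectorized scoring."""

    participant_id: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray
    nominal_rate: float = 50.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.t)
        if not (len(self.x) == len(self.y) == len(self.valid) == n):
            raise ValueError("t, x, y, valid must have equal length")
        if n and np.any(np.diff(self.t) < 0):
            raise ValueError("timestamps must be non-decreasing")
        if n and self.t[0] < 0:
            raise ValueError("timestamps must be non-negative")
        if self.nominal_rate <= 0:
            raise ValueError("nominal_rate must be positive")
        # validity contract: a tracked sample has coordinates
        bad = self.valid & (np.isnan(self.x) | np.isnan(self.y))
        if np.any(bad):
            raise ValueError(
                f"{int(bad.sum())} samples flagged valid but missing coordinates"
            )

    def __len__(self) -> int:
        return len(self.t)

    def sample(self, i: int) -> GazeSample:
        return GazeSample(
            float(self.t[i]), float(self.x[i]), float(self.y[i]), bool(self.valid[i])
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.t,
                "x": self.x,
                "y": self.y,
                "valid": self.valid.astype(int),
            }
        )


@dataclass
class TrialWindowSamples:
    """Samples restricted to one trial's half-open window [onset, onset+dur)."""

    trial_index: int
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray

    def __len__(self) -> int:
        return len(self.t)


def read_gaze_csv(path, participant_id: str | None = None) -> GazeRecording:
    """Read a ``time_s,x,y,valid`` CSV into a :class:`GazeRecording`.

    Rows whose ``time_s`` cannot be parsed are dropped (counted in the log);
    rows with unparseable or missing coordinates are retained with
    ``valid=False``.  Samples are sorted by time on read if needed.
    """
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise GazeFormatError(f"{path}: empty gaze file") from None
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise GazeFormatError(f"{path}: missing columns {missing}")

    t = pd.to_numeric(df["time_s"], errors="coerce")
    x = pd.to_numeric(df["x"], errors="coerce")
    y = pd.to_numeric(df["y"], errors="coerce")
    valid_raw = pd.to_numeric(df["valid"], errors="coerce")

    keep = t.notna() & valid_raw.notna()
    n_malformed = int((~keep).sum())
    if n_malformed:
        logger.warning("%s: dropped %d malformed rows", path, n_malformed)
    t, x, y = t[keep].to_numpy(), x[keep].to_numpy(), y[keep].to_numpy()
    valid = valid_raw[keep].to_numpy() != 0
    # a "valid" row lacking coordinates is demoted to invalid
    valid &= ~(np.isnan(x) | np.isnan(y))

    order = np.argsort(t, kind="stable")
    if np.any(np.diff(t) < 0):
        logger.warning("%s: timestamps unsorted; sorting on read", path)
        t, x, y, valid = t[order], x[order], y[order], valid[order]

    pid = participant_id if participant_id is not None else str(path)
    return GazeRecording(participant_id=pid, t=t, x=x, y=y, valid=valid)


def write_gaze_csv(rec: GazeRecording, path) -> None:
    """Write a recording in the package CSV dialect (6-decimal coordinates)."""
    if len(rec) == 0:
        raise ValueError("refusing to write a recording with no samples")
    df = rec.to_frame()
    df.to_csv(path, index=False, float_format=f"%.{CSV_PRECISION}f")


def segment_trials(
    rec: GazeRecording,
    sched: TaskSchedule,
    alignment_offset: float = 0.0,
) -> list[TrialWindowSamples]:
    """Split a recording into the 16 per-trial windows of a schedule.

    Windows are half-open ``[onset, onset + duration)`` in schedule time, so
    the windows partition trial-time samples with no double counting; a
    sample landing exactly on a window end belongs to the next interval.
    Inter-trial and block-instruction samples are discarded.

    ``alignment_offset`` is the recording time of schedule time zero
    (default 0: recording clock starts with the schedule).
    """
    t_sched = rec.t - alignment_offset
    windows = []
    for trial_index, start, end in schedule_timeline(sched):
        lo = int(np.searchsorted(t_sched, start, side="left"))
        hi = int(np.searchsorted(t_sched, end, side="left"))
        windows.append(
            TrialWindowSamples(
                trial_index=trial_index,
                t=rec.t[lo:hi],
                x=rec.x[lo:hi],
                y=rec.y[lo:hi],
                valid=rec.valid[lo:hi],
            )
        )
    return windows
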