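"""Conventional neuropsychological instruments and cutoff classifications.

Holds per-participant scores for the standard memory-clinic battery —
MMSE (global cognition, 0–30), FAB (frontal lobe battery, 0–18), TMT-A/B
(completion time in seconds, longer = worse), CDR (clinical dementia
rating) and the paper-and-pencil matching Stroop test (correct responses
per condition in 40 s) — plus the cutoff-based group labels used for
diagnostic validation:

* MMSE: 28–30 cognitively normal, 24–27 suspected MCI, ≤23 suspected
  dementia.
* FAB: ≤11/18 frontal lobe dysfunction.
* CDR: 0 normal, 0.5 MCI, ≥1 dementia.
* TMT: abnormal when completion time exceeds a configured cutoff (cutoffs
  are published age-normed values from prior work; the defaults here,
  A = 90 s and B = 180 s, are this package's own working defaults and must
  be reviewed for any real cohort).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "NeuropsychProfile",
    "TmtCutoffs",
    "classify_mmse",
    "classify_fab",
    "classify_cdr",
    "classify_tmt",
    "paper_stroop_total",
    "read_cohort_csv",
    "write_cohort_csv",
]

PAPER_STROOP_CONDITIONS = ("word", "reverse_stroop", "color", "stroop")
VALID_CDR = (0.0, 0.5, 1.0, 2.0, 3.0)


def _is_missing(v) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v))


@dataclass(frozen=True)
class NeuropsychProfile:
    """One participant's conventional-instrument scores; None = missing."""

    participant_id: str
    age: float | None = None
    sex: str | None = None
    mmse: int | None = None
    fab: int | None = None
    tmt_a_s: float | None = None
    tmt_b_s: float | None = None
    cdr: float | None = None
    paper_stroop: dict[str, int | None] = field(
        default_factory=lambda: {c: None for c in PAPER_STROOP_CONDITIONS}
    )

    def __post_init__(self) -> None:
        if self.mmse is not None and not 0 <= self.mmse <= 30:
            raise ValueError(f"MMSE {self.mmse} outside 0–30")
        if self.fab is not None and not 0 <= self.fab <= 18:
            raise ValueError(f"FAB {self.fab} outside 0–18")
        for part, v in (("A", self.tmt_a_s), ("B", self.tmt_b_s)):
            if v is not None and v <= 0:
                raise ValueError(f"TMT-{part} time must be positive, got {v}")
        if self.cdr is not None and self.cdr not in VALID_CDR:
            raise ValueError(f"CDR must be one of {VALID_CDR}, got {self.cdr}")
        for cond in PAPER_STROOP_CONDITIONS:
            v = self.paper_stroop.get(cond)
            if v is not None and v < 0:
                raise ValueError(f"paper Stroop count for {cond} must be ≥ 0")


@dataclass(frozen=True)
class TmtCutoffs:
    """Completion-time cutoffs (seconds) above which TMT is abnormal."""

    a_s: float = 90.0
    b_s: float = 180.0


def classify_mmse(mmse: int) -> str:
    """MMSE three-group screen: CN (28–30), suspected MCI (24–27),
    suspected dementia (≤23)."""
    if not 0 <= mmse <= 30:
        raise ValueError(f"MMSE {mmse} outside 0–30")
    if mmse >= 28:
        return "CN"
    if mmse >= 24:
        return "suspected_MCI"
    return "suspected_dementia"


def classify_fab(fab: int) -> str:
    """FAB frontal-lobe-dysfunction cutoff: ≤11/18 → dysfunction."""
    if not 0 <= fab <= 18:
        raise ValueError(f"FAB {fab} outside 0–18")
    return "dysfunction" if fab <= 11 else "normal"


def classify_cdr(cdr: float) -> str:
    """CDR groups: 0 → CN, 0.5 → MCI, ≥1 → dementia."""
    if cdr not in VALID_CDR:
        raise ValueError(f"CDR must be one of {VALID_CDR}, got {cdr}")
    if cdr == 0:
        return "CN"
    if cdr == 0.5:
        return "MCI"
    return "dementia"


def classify_tmt(time_s: float | None, part: str, cutoffs: TmtCutoffs | None = None) -> str | None:
    """TMT-A/B label: abnormal iff time strictly exceeds the part's cutoff.

    Missing time yields None (excluded downstream).
    """
    if cutoffs is None:
        raise ValueError("TMT cutoffs must be configured")
    if part not in ("A", "B"):
        raise ValueError(f"TMT part must be 'A' or 'B', got {part!r}")
    if time_s is None or _is_missing(time_s):
        return None
    if time_s <= 0:
        raise ValueError(f"TMT time must be positive, got {time_s}")
    cutoff = cutoffs.a_s if part == "A" else cutoffs.b_s
    return "abnormal" if time_s > cutoff else "normal"


def paper_stroop_total(profile: NeuropsychProfile) -> int | None:
    """Total paper-Stroop score: sum of the four condition counts.

    Returns None when any condition count is missing.
    """
    counts = [profile.paper_stroop.get(c) for c in PAPER_STROOP_CONDITIONS]
    if any(_is_missing(c) for c in counts):
        return None
    return int(sum(counts))


# ---------------------------------------------------------------------------
# cohort CSV: one row per participant, missing cells empty

_COLUMNS = [
    "participant_id",
    "age",
    "sex",
    "mmse",
    "fab",
    "tmt_a_s",
    "tmt_b_s",
    "cdr",
    "paper_stroop_word",
    "paper_stroop_reverse_stroop",
    "paper_stroop_color",
    "paper_stroop_stroop",
]


def write_cohort_csv(profiles: list[NeuropsychProfile], path) -> None:
    rows = []
    for p in profiles:
        row = {
            "participant_id": p.participant_id,
            "age": p.age,
            "sex": p.sex,
            "mmse": p.mmse,
            "fab": p.fab,
            "tmt_a_s": p.tmt_a_s,
            "tmt_b_s": p.tmt_b_s,
            "cdr": p.cdr,
        }
        for c in PAPER_STROOP_CONDITIONS:
            row[f"paper_stroop_{c}"] = p.paper_stroop.get(c)
        rows.append(row)
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, index=False)


def _opt_int(v) -> int | None:
    return None if pd.isna(v) else int(v)


def _opt_float(v) -> float | None:
    return None if pd.isna(v) else float(v)


def read_cohort_csv(path) -> list[NeuropsychProfile]:
    df = pd.read_csv(path)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing cohort columns {missing}")
    profiles = []
    for _, r in df.iterrows():
        profiles.append(
            NeuropsychProfile(
                participant_id=str(r["participant_id"]),
                age=_opt_float(r["age"]),
                sex=None if pd.isna(r["sex"]) else str(r["sex"]),
                mmse=_opt_int(r["mmse"]),
                fab=_opt_int(r["fab"]),
                tmt_a_s=_opt_float(r["tmt_a_s"]),
                tmt_b_s=_opt_float(r["tmt_b_s"]),
                cdr=_opt_float(r["cdr"]),
                paper_stroop={
                    c: _opt_int(r[f"paper_stroop_{c}"]) for c in PAPER_STROOP_CONDITIONS
                },
            )
        )
    return profiles
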