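"""End-to-end orchestration: simulate/load → score → validate → report.

Produces a :class:`CohortReport` mirroring the standard validation battery
for the eye-tracking score:

* concurrent validity — Spearman correlations of the eye-tracking total
  and per-condition scores against the paper-based Stroop counterparts;
* construct validity — correlations against FAB, TMT-A/B and MMSE, and
  Mann–Whitney comparisons across cutoff-defined groups;
* diagnostic accuracy — ROC/AUC for FAB-defined frontal lobe dysfunction,
  MMSE-defined dementia and MCI+dementia screening, and CDR-defined
  dementia.

Every entry carries the n actually used (missing instrument values are
deleted per-analysis); analyses that cannot run (a missing group, a
constant score) are reported as missing rather than silently dropped.
Report serialization is deterministic (sorted keys) so identical inputs
reproduce identical bytes.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .clinical import (
    NeuropsychProfile,
    PAPER_STROOP_CONDITIONS,
    TmtCutoffs,
    classify_cdr,
    classify_fab,
    classify_mmse,
    classify_tmt,
    paper_stroop_total,
    read_cohort_csv,
)
from .gaze import read_gaze_csv
from .schedule import Condition, TaskSchedule
from .scoring import ParticipantETScore, ScoringConfig, score_participant
from .simulate import SimulatedParticipant, SimulationConfig, simulate_cohort
from .stats import mann_whitney_u, roc_auc, spearman

__all__ = [
    "CohortReport",
    "AnalysisConfig",
    "build_cohort_frame",
    "analyze_cohort",
    "run_pipeline",
    "subgroup_filter",
]

logger = logging.getLogger(__name__)

MIN_PARTICIPANTS = 10


@dataclass(frozen=True)
class AnalysisConfig:
    tmt_cutoffs: TmtCutoffs = field(default_factory=TmtCutoffs)
    ci_method: str = "delong"
    ci_seed: int = 0
    #: require at least this many complete pairs / group members per analysis
    min_n: int = 3


@dataclass
class CohortReport:
    n_cohort: int
    n_excluded: int
    correlations: dict[str, dict]
    group_comparisons: dict[str, dict]
    rocs: dict[str, dict]
    subgroup: str | None = None

    def to_dict(self) -> dict:
        return {
            "n_cohort": self.n_cohort,
            "n_excluded": self.n_excluded,
            "subgroup": self.subgroup,
            "correlations": self.correlations,
            "group_comparisons": self.group_comparisons,
            "rocs": self.rocs,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def save(self, path) -> None:
        Path(path).write_text(self.to_json(), encoding="utf-8")

    def to_frame(self) -> pd.DataFrame:
        """Flat one-row-per-analysis table for CSV export."""
        rows = []
        for family, entries in (
            ("correlation", self.correlations),
            ("group_comparison", self.group_comparisons),
            ("roc", self.rocs),
        ):
            for name, d in sorted(entries.items()):
                row = {"family": family, "analysis": name}
                row.update({k: v for k, v in d.items() if not isinstance(v, (list, dict))})
                rows.append(row)
        return pd.DataFrame(rows)


def build_cohort_frame(
    profiles: list[NeuropsychProfile],
    et_scores: dict[str, ParticipantETScore],
    tmt_cutoffs: TmtCutoffs | None = None,
) -> pd.DataFrame:
    """One row per participant joining instrument scores, derived group
    labels and eye-tracking scores.  Participants without a usable
    eye-tracking score are excluded (logged with a count)."""
    cutoffs = tmt_cutoffs or TmtCutoffs()
    rows = []
    n_excluded = 0
    for p in profiles:
        s = et_scores.get(p.participant_id)
        if s is None or not s.usable or math.isnan(s.total_score):
            n_excluded += 1
            continue
        row = {
            "participant_id": p.participant_id,
            "age": p.age,
            "sex": p.sex,
            "mmse": p.mmse,
            "fab": p.fab,
            "tmt_a_s": p.tmt_a_s,
            "tmt_b_s": p.tmt_b_s,
            "cdr": p.cdr,
            "paper_total": paper_stroop_total(p),
            "mmse_group": classify_mmse(p.mmse) if p.mmse is not None else None,
            "fab_group": classify_fab(p.fab) if p.fab is not None else None,
            "cdr_group": classify_cdr(p.cdr) if p.cdr is not None else None,
            "tmt_a_group": classify_tmt(p.tmt_a_s, "A", cutoffs),
            "tmt_b_group": classify_tmt(p.tmt_b_s, "B", cutoffs),
            "et_total": s.total_score,
            "n_qc_failed": s.n_qc_failed,
        }
        for c in PAPER_STROOP_CONDITIONS:
            row[f"paper_{c}"] = p.paper_stroop.get(c)
            cs = s.condition_scores[Condition(c)]
            row[f"et_{c}"] = None if math.isnan(cs) else cs
        rows.append(row)
    if n_excluded:
        logger.warning("excluded %d participants without usable ET scores", n_excluded)
    df = pd.DataFrame(rows)
    df.attrs["n_excluded"] = n_excluded
    return df


def _corr_entry(df: pd.DataFrame, xcol: str, ycol: str, min_n: int) -> dict:
    x = pd.to_numeric(df[xcol], errors="coerce").to_numpy(dtype=float)
    y = pd.to_numeric(df[ycol], errors="coerce").to_numpy(dtype=float)
    n = int((~(np.isnan(x) | np.isnan(y))).sum())
    if n < max(3, min_n):
        return {"missing": f"only {n} complete pairs", "n": n}
    return spearman(x, y).to_dict()


def _split(df: pd.DataFrame, col: str, positive: Callable[[object], bool]):
    sub = df[df[col].notna()]
    mask = sub[col].map(positive).astype(bool)
    scores = pd.to_numeric(sub["et_total"]).to_numpy(dtype=float)
    return scores[mask.to_numpy()], scores[~mask.to_numpy()], sub, mask


def _comparison_entry(df, col, positive, min_n) -> dict:
    a, b, _, _ = _split(df, col, positive)
    if len(a) < min_n or len(b) < min_n:
        return {"missing": f"group sizes {len(a)}/{len(b)} too small", "n": len(a) + len(b)}
    d = mann_whitney_u(a, b).to_dict()
    d["n"] = d["n1"] + d["n2"]
    return d


def _roc_entry(df, col, positive, cfg: AnalysisConfig) -> dict:
    a, b, sub, mask = _split(df, col, positive)
    if len(a) < cfg.min_n or len(b) < cfg.min_n:
        return {"missing": f"group sizes {len(a)}/{len(b)} too small", "n": len(a) + len(b)}
    scores = pd.to_numeric(sub["et_total"]).to_numpy(dtype=float)
    labels = mask.to_numpy().astype(int)
    if np.nanstd(scores) == 0:
        return {"missing": "constant score", "n": len(scores)}
    res = roc_auc(
        scores, labels, direction="lower", ci_method=cfg.ci_method, seed=cfg.ci_seed
    )
    return res.to_dict()


def analyze_cohort(df: pd.DataFrame, config: AnalysisConfig | None = None) -> CohortReport:
    """Run the full validation battery on a joined cohort frame."""
    cfg = config or AnalysisConfig()
    correlations = {
        "et_total_vs_paper_total": _corr_entry(df, "et_total", "paper_total", cfg.min_n),
        "et_total_vs_fab": _corr_entry(df, "et_total", "fab", cfg.min_n),
        "et_total_vs_tmt_a": _corr_entry(df, "et_total", "tmt_a_s", cfg.min_n),
        "et_total_vs_tmt_b": _corr_entry(df, "et_total", "tmt_b_s", cfg.min_n),
        "et_total_vs_mmse": _corr_entry(df, "et_total", "mmse", cfg.min_n),
    }
    for c in PAPER_STROOP_CONDITIONS:
        correlations[f"et_{c}_vs_paper_{c}"] = _corr_entry(df, f"et_{c}", f"paper_{c}", cfg.min_n)

    group_comparisons = {
        "fab_low_vs_high": _comparison_entry(
            df, "fab_group", lambda v: v == "dysfunction", cfg.min_n
        ),
        "tmt_a_abnormal_vs_normal": _comparison_entry(
            df, "tmt_a_group", lambda v: v == "abnormal", cfg.min_n
        ),
        "tmt_b_abnormal_vs_normal": _comparison_entry(
            df, "tmt_b_group", lambda v: v == "abnormal", cfg.min_n
        ),
        "mmse_dementia_vs_rest": _comparison_entry(
            df, "mmse_group", lambda v: v == "suspected_dementia", cfg.min_n
        ),
        "mmse_mci_dementia_vs_cn": _comparison_entry(
            df, "mmse_group", lambda v: v != "CN", cfg.min_n
        ),
        "cdr_dementia_vs_rest": _comparison_entry(
            df, "cdr_group", lambda v: v == "dementia", cfg.min_n
        ),
    }

    rocs = {
        "fab_dysfunction": _roc_entry(df, "fab_group", lambda v: v == "dysfunction", cfg),
        "mmse_dementia_vs_rest": _roc_entry(
            df, "mmse_group", lambda v: v == "suspected_dementia", cfg
        ),
        "mmse_mci_dementia_vs_cn": _roc_entry(df, "mmse_group", lambda v: v != "CN", cfg),
        "cdr_dementia_vs_rest": _roc_entry(df, "cdr_group", lambda v: v == "dementia", cfg),
    }

    return CohortReport(
        n_cohort=len(df),
        n_excluded=int(df.attrs.get("n_excluded", 0)),
        correlations=correlations,
        group_comparisons=group_comparisons,
        rocs=rocs,
        subgroup=df.attrs.get("subgroup"),
    )


def subgroup_filter(
    df: pd.DataFrame,
    predicate: Callable[[pd.DataFrame], pd.Series],
    label: str,
) -> pd.DataFrame | None:
    """Subset a cohort frame for stratified re-analysis (e.g. by age decade).

    The subset carries a provenance label into any report built from it.
    Returns None (with a warning) when the predicate selects nobody.
    """
    mask = predicate(df).astype(bool)
    sub = df[mask].reset_index(drop=True)
    if len(sub) == 0:
        logger.warning("subgroup %r is empty; analysis skipped", label)
        return None
    sub.attrs["n_excluded"] = 0
    sub.attrs["subgroup"] = label
    return sub


def score_simulated_cohort(
    participants: list[SimulatedParticipant],
    schedule: TaskSchedule,
    scoring_config: ScoringConfig | None = None,
) -> dict[str, ParticipantETScore]:
    return {
        p.participant_id: score_participant(p.recording, schedule, scoring_config)
        for p in participants
    }


def load_cohort_dir(
    cohort_dir, schedule: TaskSchedule, scoring_config: ScoringConfig | None = None
) -> tuple[list[NeuropsychProfile], dict[str, ParticipantETScore]]:
    """Load a cohort directory: ``cohort.csv`` + ``gaze/<pid>.csv``.

    Participants whose gaze file is missing or unreadable are logged and
    excluded."""
    cohort_dir = Path(cohort_dir)
    profiles = read_cohort_csv(cohort_dir / "cohort.csv")
    scores: dict[str, ParticipantETScore] = {}
    n_unresolvable = 0
    for p in profiles:
        gpath = cohort_dir / "gaze" / f"{p.participant_id}.csv"
        if not gpath.exists():
            n_unresolvable += 1
            logger.warning("no gaze file for %s; excluded", p.participant_id)
            continue
        rec = read_gaze_csv(gpath, participant_id=p.participant_id)
        scores[p.participant_id] = score_participant(rec, schedule, scoring_config)
    if n_unresolvable:
        logger.warning("%d participants unresolvable (no gaze data)", n_unresolvable)
    return profiles, scores


def run_pipeline(
    schedule: TaskSchedule,
    cohort_dir=None,
    sim_config: SimulationConfig | None = None,
    seed: int = 0,
    scoring_config: ScoringConfig | None = None,
    analysis_config: AnalysisConfig | None = None,
    subgroup: tuple[str, Callable[[pd.DataFrame], pd.Series]] | None = None,
) -> CohortReport:
    """Full pipeline: simulate (or load) a cohort, score it, run the battery.

    Exactly one of ``cohort_dir`` / ``sim_config`` selects the input.
    Deterministic for fixed inputs and seed.
    """
    if (cohort_dir is None) == (sim_config is None):
        raise ValueError("provide exactly one of cohort_dir or sim_config")
    acfg = analysis_config or AnalysisConfig()
    if sim_config is not None:
        participants = simulate_cohort(sim_config, schedule, seed)
        profiles = [p.profile for p in participants]
        scores = score_simulated_cohort(participants, schedule, scoring_config)
    else:
        profiles, scores = load_cohort_dir(cohort_dir, schedule, scoring_config)
    if len(scores) < MIN_PARTICIPANTS:
        raise ValueError(
            f"pipeline needs at least {MIN_PARTICIPANTS} resolvable participants, "
            f"got {len(scores)}"
        )
    df = build_cohort_frame(profiles, scores, acfg.tmt_cutoffs)
    if subgroup is not None:
        label, predicate = subgroup
        sub = subgroup_filter(df, predicate, label)
        if sub is None:
            raise ValueError(f"subgroup {label!r} selected no participants")
        df = sub
    return analyze_cohort(df, acfg)
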