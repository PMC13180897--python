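"""Generative model of a memory-clinic cohort and its gaze behavior.

No cohort data accompany the task design, so validation runs on synthetic
participants drawn from an explicit behavioral model whose effect sizes are
controllable:

* Two correlated latent traits per participant — frontal/executive
  function φ and global cognition g, bivariate standard normal with
  correlation ρ — drive everything else.
* Instrument scores are noisy affine functions of the latents, anchored to
  the moments of a typical memory-clinic cohort (MMSE mean 24.1 SD 4.4,
  FAB mean 12.4 SD 3.0, age mean 76.4 SD 7.1, TMT-A ≈ 77 s, TMT-B ≈ 153 s)
  and clamped to instrument ranges.  TMT values are missing more often for
  impaired participants, mimicking test discontinuation.
* Gaze in a trial is a two-phase process.  A *search* phase of lognormal
  duration (longer for low φ and for interference conditions) hops among
  the screen center and the four option regions; a *decision* phase then
  fixates a chosen option — the correct one with probability
  ``logistic(β·φ − penalty(condition))`` — with per-sample stay probability
  p_stay.  Samples drop out independently at the track-loss rate.

The analytic mean trial score under this model
(:func:`expected_trial_score`) serves as the simulator's calibration
oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit
from scipy.stats import norm

from .clinical import NeuropsychProfile, PAPER_STROOP_CONDITIONS
from .gaze import GazeRecording
from .schedule import Condition, Corner, TaskSchedule, TrialSpec
from .scoring import LayoutConfig, roi_for_corner

__all__ = [
    "SimulationConfig",
    "SimulatedParticipant",
    "simulate_cohort",
    "simulate_trial_gaze",
    "expected_trial_score",
]

#: interference penalty (logits) subtracted from the correct-choice log-odds
DEFAULT_PENALTIES = {
    Condition.WORD: 0.0,
    Condition.COLOR: 0.0,
    Condition.REVERSE_STROOP: 0.5,
    Condition.STROOP: 1.0,
}

#: central instruction region, disjoint from the default 0.4-fraction corner ROIs
CENTER_RECT = (0.4, 0.4, 0.6, 0.6)


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the cohort and gaze model; defaults are the study
    conditions the package is validated under."""

    n_participants: int = 97
    latent_correlation: float = 0.6  # corr(φ, g)
    discrimination: float = 1.5  # β: effect of φ on correct-choice log-odds
    penalties: dict[Condition, float] = field(
        default_factory=lambda: dict(DEFAULT_PENALTIES)
    )
    # search-phase duration: T_s ~ LogNormal(μ0 − slope·φ + 0.2·penalty, spread), capped at 7 s
    search_mu0: float = math.log(2.0)
    search_spread: float = 0.5
    search_phi_slope: float = 0.3
    search_penalty_slope: float = 0.2
    mean_hop_s: float = 0.25  # mean dwell per search hop
    p_stay: float = 0.9  # per-sample prob of remaining on the chosen option
    track_loss_rate: float = 0.05
    sample_rate_hz: float = 50.0
    # instrument noise scales (score units)
    mmse_noise: float = 1.5
    fab_noise: float = 1.0
    tmt_a_noise: float = 0.35  # log-scale
    tmt_b_noise: float = 0.40
    cdr_noise: float = 0.3
    # missingness (FAB: administrative; TMT: impairment-linked discontinuation)
    fab_missing_rate: float = 3 / 97
    tmt_a_missing_intercept: float = -2.2
    tmt_b_missing_intercept: float = -1.3
    tmt_missing_phi_slope: float = -1.0

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("need at least 2 participants")
        if not -1 <= self.latent_correlation <= 1:
            raise ValueError("latent_correlation must be in [-1, 1]")
        for p in (self.p_stay, self.track_loss_rate, self.fab_missing_rate):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if any(v < 0 for v in self.penalties.values()):
            raise ValueError("penalties must be non-negative")
        if self.search_spread <= 0 or self.mean_hop_s <= 0 or self.sample_rate_hz <= 0:
            raise ValueError("search_spread, mean_hop_s, sample_rate_hz must be positive")

    def penalty(self, condition: Condition) -> float:
        return self.penalties.get(condition, 0.0)


@dataclass
class SimulatedParticipant:
    participant_id: str
    phi: float
    g: float
    profile: NeuropsychProfile
    recording: GazeRecording
    chosen_corners: list[Corner]  # ground-truth decision per trial
    chose_correct: list[bool]


def _regions(layout: LayoutConfig) -> list[tuple[float, float, float, float]]:
    """Five candidate gaze regions: center + four corner option ROIs."""
    rects = [CENTER_RECT]
    for corner in Corner:
        roi = roi_for_corner(corner, layout)
        rects.append(roi.rect)
    return rects


def _uniform_in_rects(rects, idx: np.ndarray, rng) -> tuple[np.ndarray, np.ndarray]:
    arr = np.asarray(rects, dtype=float)
    x0, y0, x1, y1 = arr[idx, 0], arr[idx, 1], arr[idx, 2], arr[idx, 3]
    u, v = rng.random(len(idx)), rng.random(len(idx))
    return x0 + u * (x1 - x0), y0 + v * (y1 - y0)


def simulate_trial_gaze(
    trial: TrialSpec,
    phi: float,
    config: SimulationConfig,
    rng: np.random.Generator,
    layout: LayoutConfig | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, Corner]:
    """Simulate one trial's gaze: ``(t_rel, x, y, valid, chosen_corner)``.

    ``t_rel`` are sample times relative to trial onset at the configured
    rate.  Search-phase hops pick among the five regions uniformly (so each
    region's expected occupancy share is 1/5); the decision phase puts each
    sample on the chosen option with probability p_stay, else uniformly on
    one of the other four regions.
    """
    lay = layout or LayoutConfig()
    rate = config.sample_rate_hz
    n = int(round(trial.duration * rate))
    t_rel = np.arange(n) / rate

    pen = config.penalty(trial.condition)
    mu = config.search_mu0 - config.search_phi_slope * phi + config.search_penalty_slope * pen
    t_search = min(float(rng.lognormal(mu, config.search_spread)), trial.duration)
    n_search = min(int(round(t_search * rate)), n)

    corners = list(Corner)
    correct_i = corners.index(trial.correct_corner)
    region_idx = np.empty(n, dtype=np.intp)

    if n_search > 0:
        p_hop = min(1.0, 1.0 / (config.mean_hop_s * rate))
        # draw enough geometric hop lengths to cover the search phase
        n_hops = max(8, int(2 * n_search * p_hop) + 8)
        while True:
            lengths = rng.geometric(p_hop, size=n_hops)
            if lengths.sum() >= n_search:
                break
            n_hops *= 2
        targets = rng.integers(0, 5, size=n_hops)
        region_idx[:n_search] = np.repeat(targets, lengths)[:n_search]

    q = float(expit(config.discrimination * phi - pen))
    if rng.random() < q:
        chosen = trial.correct_corner
    else:
        wrong = [c for c in corners if c is not trial.correct_corner]
        chosen = wrong[int(rng.integers(3))]
    chosen_region = 1 + corners.index(chosen)  # region 0 is the center

    n_dec = n - n_search
    if n_dec > 0:
        stay = rng.random(n_dec) < config.p_stay
        others = np.array([r for r in range(5) if r != chosen_region])
        dec_regions = np.where(
            stay, chosen_region, others[rng.integers(0, 4, size=n_dec)]
        )
        region_idx[n_search:] = dec_regions

    x, y = _uniform_in_rects(_regions(lay), region_idx, rng)
    valid = rng.random(n) >= config.track_loss_rate
    x = np.where(valid, x, np.nan)
    y = np.where(valid, y, np.nan)
    return t_rel, x, y, valid, chosen


def _lognormal_capped_mean(mu: float, sigma: float, cap: float) -> float:
    """E[min(X, cap)] for X ~ LogNormal(mu, sigma), in closed form."""
    if cap <= 0:
        return 0.0
    lc = math.log(cap)
    partial = math.exp(mu + sigma**2 / 2) * norm.cdf((lc - mu - sigma**2) / sigma)
    tail = cap * norm.sf((lc - mu) / sigma)
    return partial + tail


def expected_trial_score(
    phi: float, condition: Condition, config: SimulationConfig | None = None
) -> float:
    """Analytic expected trial percentage under the gaze model.

    Search samples land in the correct region with probability 1/5;
    decision samples with probability ``q·p_stay + (1 − q)(1 − p_stay)/4``
    where ``q = logistic(β·φ − penalty)``.  The expected search share is
    ``E[min(T_s, 7)] / 7`` via the closed-form capped-lognormal mean.
    Track loss cancels from the tracked-time percentage.
    """
    cfg = config or SimulationConfig()
    pen = cfg.penalty(condition)
    duration = 7.0
    mu = cfg.search_mu0 - cfg.search_phi_slope * phi + cfg.search_penalty_slope * pen
    share_search = _lognormal_capped_mean(mu, cfg.search_spread, duration) / duration
    q = float(expit(cfg.discrimination * phi - pen))
    p_dec = q * cfg.p_stay + (1.0 - q) * (1.0 - cfg.p_stay) / 4.0
    return 100.0 * (share_search / 5.0 + (1.0 - share_search) * p_dec)


def _clamp_round(v: float, lo: int, hi: int) -> int:
    return int(min(max(round(v), lo), hi))


def _simulate_profile(
    pid: str, phi: float, g: float, cfg: SimulationConfig, rng: np.random.Generator
) -> NeuropsychProfile:
    mmse = _clamp_round(24.1 + 4.4 * g + cfg.mmse_noise * rng.standard_normal(), 0, 30)
    fab: int | None = _clamp_round(
        12.4 + 3.0 * phi + cfg.fab_noise * rng.standard_normal(), 0, 18
    )
    if rng.random() < cfg.fab_missing_rate:
        fab = None
    tmt_a: float | None = float(
        np.exp(4.25 - 0.35 * phi + cfg.tmt_a_noise * rng.standard_normal())
    )
    if rng.random() < expit(cfg.tmt_a_missing_intercept + cfg.tmt_missing_phi_slope * phi):
        tmt_a = None
    tmt_b: float | None = float(
        np.exp(4.90 - 0.50 * phi + cfg.tmt_b_noise * rng.standard_normal())
    )
    if rng.random() < expit(cfg.tmt_b_missing_intercept + cfg.tmt_missing_phi_slope * phi):
        tmt_b = None
    c_latent = g + cfg.cdr_noise * rng.standard_normal()
    if c_latent >= 0.45:
        cdr = 0.0
    elif c_latent >= -0.25:
        cdr = 0.5
    elif c_latent >= -1.3:
        cdr = 1.0
    else:
        cdr = 2.0
    paper = {}
    for cond_name in PAPER_STROOP_CONDITIONS:
        pen = cfg.penalty(Condition(cond_name))
        lam = math.exp(math.log(10.0) + 0.35 * phi - 0.3 * pen)
        paper[cond_name] = int(rng.poisson(lam))
    age = float(min(max(round(76.4 - 2.0 * g + 6.8 * rng.standard_normal()), 51), 89))
    sex = "F" if rng.random() < 56 / 97 else "M"
    return NeuropsychProfile(
        participant_id=pid,
        age=age,
        sex=sex,
        mmse=mmse,
        fab=fab,
        tmt_a_s=tmt_a,
        tmt_b_s=tmt_b,
        cdr=cdr,
        paper_stroop=paper,
    )


def simulate_participant(
    pid: str,
    schedule: TaskSchedule,
    config: SimulationConfig,
    rng: np.random.Generator,
    layout: LayoutConfig | None = None,
) -> SimulatedParticipant:
    z1, z2 = rng.standard_normal(2)
    rho = config.latent_correlation
    phi = float(z1)
    g = float(rho * z1 + math.sqrt(1.0 - rho**2) * z2)
    profile = _simulate_profile(pid, phi, g, config, rng)

    ts, xs, ys, vs = [], [], [], []
    chosen_corners: list[Corner] = []
    chose_correct: list[bool] = []
    for trial in schedule.trials:
        t_rel, x, y, valid, chosen = simulate_trial_gaze(trial, phi, config, rng, layout)
        ts.append(trial.onset + t_rel)
        xs.append(x)
        ys.append(y)
        vs.append(valid)
        chosen_corners.append(chosen)
        chose_correct.append(chosen is trial.correct_corner)
    recording = GazeRecording(
        participant_id=pid,
        t=np.concatenate(ts),
        x=np.concatenate(xs),
        y=np.concatenate(ys),
        valid=np.concatenate(vs),
        nominal_rate=config.sample_rate_hz,
    )
    return SimulatedParticipant(
        participant_id=pid,
        phi=phi,
        g=g,
        profile=profile,
        recording=recording,
        chosen_corners=chosen_corners,
        chose_correct=chose_correct,
    )


def simulate_cohort(
    config: SimulationConfig,
    schedule: TaskSchedule,
    seed: int,
    layout: LayoutConfig | None = None,
) -> list[SimulatedParticipant]:
    """Simulate a full cohort, reproducible from ``seed``.

    Each participant draws from an independent substream spawned from the
    master seed, so cohorts are identical across runs and participant k is
    unaffected by how many others are simulated after it.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(config.n_participants)
    width = len(str(config.n_participants))
    return [
        simulate_participant(
            f"sim{str(i + 1).zfill(width)}",
            schedule,
            config,
            np.random.default_rng(child),
            layout,
        )
        for i, child in enumerate(children)
    ]
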