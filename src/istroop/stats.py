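"""Diagnostic-validation statistics: Spearman, Mann–Whitney U, ROC/AUC.

The validation battery for a continuous screening score against reference
instruments and cutoff-defined groups:

* tie-corrected Spearman rank correlation (midranks, two-sided
  t-approximation p) with pairwise deletion of missing values;
* Mann–Whitney U with ``U = Σ 1[a > b] + ½·1[a == b]``, exact permutation
  p for small samples and a tie- and continuity-corrected normal
  approximation otherwise;
* ROC curve and trapezoidal AUC — identical by construction to the
  pairwise-probability estimator U/(n₁·n₂) — with a DeLong 95% CI
  (covariance of the placement values) and a stratified-bootstrap
  alternative.

All tests are two-sided.  Each result carries the n actually used so
per-analysis missingness is visible.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sps
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "CorrelationResult",
    "GroupComparison",
    "ROCResult",
    "spearman",
    "mann_whitney_u",
    "roc_auc",
    "auc_ci",
]

logger = logging.getLogger(__name__)

#: exact Mann–Whitney enumeration up to this combined sample size
EXACT_MWU_MAX_N = 12


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int
    undefined: bool = False

    def to_dict(self) -> dict:
        return {
            "method": "spearman",
            "r": None if self.undefined else self.r,
            "p": None if self.undefined else self.p,
            "n": self.n,
            "undefined": self.undefined,
        }


@dataclass(frozen=True)
class GroupComparison:
    u_statistic: float
    p: float
    n1: int
    n2: int
    median1: float
    median2: float
    iqr1: tuple[float, float]
    iqr2: tuple[float, float]
    method: str  # "exact" or "normal_approx"

    def to_dict(self) -> dict:
        return {
            "method": f"mann_whitney_u_{self.method}",
            "u": self.u_statistic,
            "p": self.p,
            "n1": self.n1,
            "n2": self.n2,
            "median1": self.median1,
            "median2": self.median2,
            "iqr1": list(self.iqr1),
            "iqr2": list(self.iqr2),
        }


@dataclass(frozen=True)
class ROCResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    ci95: tuple[float, float]
    direction: str  # "lower" or "higher": which scores indicate the positive class
    n_pos: int
    n_neg: int
    ci_method: str = "delong"

    @property
    def points(self) -> list[tuple[float, float]]:
        return list(zip(self.fpr.tolist(), self.tpr.tolist()))

    def to_dict(self) -> dict:
        return {
            "method": "roc_auc",
            "auc": self.auc,
            "ci95": list(self.ci95),
            "ci_method": self.ci_method,
            "direction": self.direction,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "n": self.n_pos + self.n_neg,
        }


def _clean_pairs(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    return x[keep], y[keep]


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation with midranks for ties.

    Missing pairs are deleted pairwise.  r is the Pearson correlation of
    the midranks; p is the two-sided t-approximation.  A constant input
    vector leaves r undefined (flagged, not raised).
    """
    xc, yc = _clean_pairs(x, y)
    n = len(xc)
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, got {n}")
    if np.all(xc == xc[0]) or np.all(yc == yc[0]):
        return CorrelationResult(r=float("nan"), p=float("nan"), n=n, undefined=True)
    res = sps.spearmanr(xc, yc)
    return CorrelationResult(r=float(res.statistic), p=float(res.pvalue), n=n)


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U = Σ over pairs of 1[a > b] + ½·1[a == b], via midranks (O(n log n))."""
    n1, n2 = len(a), len(b)
    ranks = sps.rankdata(np.concatenate([a, b]))
    r1 = ranks[:n1].sum()
    return float(r1 - n1 * (n1 + 1) / 2)


def _exact_mwu_p(a: np.ndarray, b: np.ndarray, u_obs: float) -> float:
    """Two-sided exact p by full enumeration of group labelings (handles ties).

    p = min(1, 2·min(P(U ≤ u), P(U ≥ u))) over all C(n1+n2, n1) relabelings.
    """
    pooled = np.concatenate([a, b])
    n = len(pooled)
    n1 = len(a)
    ranks = sps.rankdata(pooled)
    offset = n1 * (n1 + 1) / 2
    us = np.array(
        [ranks[list(idx)].sum() - offset for idx in combinations(range(n), n1)]
    )
    eps = 1e-9
    p_le = np.mean(us <= u_obs + eps)
    p_ge = np.mean(us >= u_obs - eps)
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def _normal_mwu_p(a: np.ndarray, b: np.ndarray, u_obs: float) -> float:
    """Two-sided normal approximation with tie correction and continuity
    correction."""
    n1, n2 = len(a), len(b)
    n = n1 + n2
    mu = n1 * n2 / 2
    pooled = np.concatenate([a, b])
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (n * (n - 1))
    var = n1 * n2 / 12 * ((n + 1) - tie_term)
    if var <= 0:  # all values tied
        return 1.0
    z = (abs(u_obs - mu) - 0.5) / math.sqrt(var)
    z = max(z, 0.0)
    return float(2 * sps.norm.sf(z))


def mann_whitney_u(a, b, *, exact_max_n: int = EXACT_MWU_MAX_N) -> GroupComparison:
    """Two-sided Mann–Whitney U comparison of two independent samples.

    The p-value is exact (full enumeration over group labelings, valid
    under ties) when n1 + n2 ≤ ``exact_max_n``, otherwise a tie-corrected,
    continuity-corrected normal approximation.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    u = _u_statistic(a, b)
    if len(a) + len(b) <= exact_max_n:
        p = _exact_mwu_p(a, b, u)
        method = "exact"
    else:
        p = _normal_mwu_p(a, b, u)
        method = "normal_approx"
    q1a, q3a = np.percentile(a, [25, 75])
    q1b, q3b = np.percentile(b, [25, 75])
    return GroupComparison(
        u_statistic=u,
        p=p,
        n1=len(a),
        n2=len(b),
        median1=float(np.median(a)),
        median2=float(np.median(b)),
        iqr1=(float(q1a), float(q3a)),
        iqr2=(float(q1b), float(q3b)),
        method=method,
    )


def _orient(scores: np.ndarray, direction: str) -> np.ndarray:
    if direction == "lower":
        return -scores
    if direction == "higher":
        return scores
    raise ValueError("direction must be 'lower' or 'higher'")


def roc_auc(
    scores,
    labels,
    direction: str = "lower",
    ci_method: str = "delong",
    n_boot: int = 2000,
    seed: int = 0,
) -> ROCResult:
    """ROC curve and AUC for a continuous score against binary labels.

    ``direction`` says which end of the score scale indicates the positive
    (impaired) class; with ``direction='lower'`` (the default for dwell-time
    scores, where impairment lowers the score) scores are negated before
    thresholding so an informative score yields AUC ≥ 0.5.  The AUC is the
    trapezoidal area over all thresholds, which equals the tie-adjusted
    pairwise estimator U/(n₁·n₂) exactly.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    keep = ~np.isnan(scores)
    scores, labels = scores[keep], labels[keep].astype(int)
    classes = np.unique(labels)
    if not np.array_equal(classes, [0, 1]):
        raise ValueError(f"labels must contain both classes 0 and 1, got {classes}")
    oriented = _orient(scores, direction)
    fpr, tpr, thr = _sk_roc_curve(labels, oriented, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    result = ROCResult(
        fpr=fpr,
        tpr=tpr,
        thresholds=thr,
        auc=auc,
        ci95=(float("nan"), float("nan")),
        direction=direction,
        n_pos=int((labels == 1).sum()),
        n_neg=int((labels == 0).sum()),
    )
    low, high, used = _auc_ci_impl(result, scores, labels, ci_method, n_boot, seed)
    return ROCResult(
        fpr=fpr,
        tpr=tpr,
        thresholds=thr,
        auc=auc,
        ci95=(low, high),
        direction=direction,
        n_pos=result.n_pos,
        n_neg=result.n_neg,
        ci_method=used,
    )


def _delong_variance(pos: np.ndarray, neg: np.ndarray) -> float:
    """DeLong variance of the AUC from placement values."""
    m, n = len(pos), len(neg)
    # ψ(X_i, Y_j) = 1 if X_i > Y_j, ½ if equal
    psi = (pos[:, None] > neg[None, :]) + 0.5 * (pos[:, None] == neg[None, :])
    v10 = psi.mean(axis=1)  # per-positive placements
    v01 = psi.mean(axis=0)  # per-negative placements
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(s10 / m + s01 / n)


def _bootstrap_ci(
    scores: np.ndarray, labels: np.ndarray, direction: str, n_boot: int, seed: int
) -> tuple[float, float]:
    """Stratified percentile bootstrap of the AUC."""
    rng = np.random.default_rng(seed)
    oriented = _orient(scores, direction)
    pos = oriented[labels == 1]
    neg = oriented[labels == 0]
    aucs = np.empty(n_boot)
    for i in range(n_boot):
        p = rng.choice(pos, size=len(pos), replace=True)
        q = rng.choice(neg, size=len(neg), replace=True)
        psi = (p[:, None] > q[None, :]) + 0.5 * (p[:, None] == q[None, :])
        aucs[i] = psi.mean()
    low, high = np.percentile(aucs, [2.5, 97.5])
    return float(low), float(high)


def _auc_ci_impl(
    result: ROCResult,
    scores: np.ndarray,
    labels: np.ndarray,
    method: str,
    n_boot: int,
    seed: int,
) -> tuple[float, float, str]:
    if method not in ("delong", "bootstrap"):
        raise ValueError("ci_method must be 'delong' or 'bootstrap'")
    if method == "delong":
        oriented = _orient(scores, result.direction)
        var = _delong_variance(oriented[labels == 1], oriented[labels == 0])
        if var > 0:
            half = 1.959963984540054 * math.sqrt(var)
            return (
                max(0.0, result.auc - half),
                min(1.0, result.auc + half),
                "delong",
            )
        logger.warning("degenerate DeLong variance; falling back to bootstrap CI")
        method = "bootstrap"
    low, high = _bootstrap_ci(scores, labels, result.direction, n_boot, seed)
    return max(0.0, min(low, result.auc)), min(1.0, max(high, result.auc)), "bootstrap"


def auc_ci(
    result: ROCResult,
    scores,
    labels,
    method: str = "delong",
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[float, float]:
    """95% CI for an ROC AUC: DeLong by default, seeded stratified bootstrap
    as an alternative; falls back to bootstrap when the DeLong variance is
    degenerate.  The interval is clipped to [0, 1] and contains the point
    AUC."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    keep = ~np.isnan(scores)
    scores, labels = scores[keep], labels[keep].astype(int)
    low, high, _ = _auc_ci_impl(result, scores, labels, method, n_boot, seed)
    return low, high
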