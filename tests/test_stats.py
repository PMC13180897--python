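"""Rank statistics and ROC analysis against independent brute-force oracles."""

import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import rankdata

from istroop.stats import (
    auc_ci,
    mann_whitney_u,
    roc_auc,
    spearman,
)


# ---------------------------------------------------------------------------
# independent oracles

def oracle_spearman_r(x, y):
    """Midrank-then-Pearson, straight from the definition."""
    rx, ry = rankdata(x), rankdata(y)
    return np.corrcoef(rx, ry)[0, 1]


def oracle_u(a, b):
    """Pairwise count: U = Σ 1[a > b] + ½·1[a == b]."""
    return sum(1.0 if ai > bj else 0.5 if ai == bj else 0.0 for ai in a for bj in b)


def oracle_exact_p(a, b):
    """Two-sided exact p over all C(n1+n2, n1) relabelings."""
    pooled = list(a) + list(b)
    n1 = len(a)
    u_obs = oracle_u(a, b)
    us = []
    for idx in combinations(range(len(pooled)), n1):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        us.append(oracle_u(ga, gb))
    us = np.array(us)
    eps = 1e-9
    return min(1.0, 2 * min(np.mean(us <= u_obs + eps), np.mean(us >= u_obs - eps)))


# ---------------------------------------------------------------------------
# Spearman

class TestSpearman:
    def test_perfect_monotone(self):
        assert spearman([1, 2, 3, 4], [10, 20, 30, 40]).r == pytest.approx(1.0)

    def test_perfect_antimonotone(self):
        assert spearman([1, 2, 3, 4], [4, 3, 2, 1]).r == pytest.approx(-1.0)

    def test_matches_midrank_oracle_with_ties(self, rng):
        for _ in range(50):
            x = rng.integers(0, 5, size=8).astype(float)
            y = rng.integers(0, 5, size=8).astype(float)
            if np.all(x == x[0]) or np.all(y == y[0]):
                continue
            res = spearman(x, y)
            assert res.r == pytest.approx(oracle_spearman_r(x, y), abs=1e-12)
            assert res.n == 8

    def test_pairwise_deletion_of_missing(self):
        x = [1, 2, np.nan, 4, 5]
        y = [2, 4, 6, np.nan, 10]
        res = spearman(x, y)
        assert res.n == 3
        assert res.r == pytest.approx(1.0)

    def test_constant_vector_flagged_undefined(self):
        res = spearman([1.0, 1.0, 1.0, 1.0], [1, 2, 3, 4])
        assert res.undefined and math.isnan(res.r)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 2], [3, 4])

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(
        st.lists(st.floats(-100, 100), min_size=5, max_size=15, unique=True),
        st.sampled_from(["exp", "cube", "affine"]),
    )
    def test_invariance_under_strictly_monotone_transform(self, xs, transform):
        rng = np.random.default_rng(len(xs))
        y = rng.random(len(xs))
        x = np.array(xs)
        f = {"exp": np.exp, "cube": lambda v: v**3, "affine": lambda v: 3 * v + 1}[transform]
        fx = f(x / 100)
        if np.all(np.isfinite(fx)) and len(np.unique(fx)) == len(fx):
            assert spearman(fx, y).r == pytest.approx(spearman(x, y).r, abs=1e-9)


# ---------------------------------------------------------------------------
# Mann-Whitney U

class TestMannWhitney:
    def test_complete_separation(self):
        res = mann_whitney_u([1, 2], [3, 4])
        assert res.u_statistic == 0.0

    def test_identical_groups_give_half_u(self):
        a = [1.0, 2.0, 3.0, 4.0]
        res = mann_whitney_u(a, a)
        assert res.u_statistic == pytest.approx(len(a) ** 2 / 2)
        assert res.p == pytest.approx(1.0)

    def test_u_bounded_by_n1n2(self, rng):
        for _ in range(20):
            a = rng.integers(0, 10, size=rng.integers(2, 8)).astype(float)
            b = rng.integers(0, 10, size=rng.integers(2, 8)).astype(float)
            res = mann_whitney_u(a, b)
            assert 0 <= res.u_statistic <= res.n1 * res.n2
            assert res.u_statistic == pytest.approx(oracle_u(a, b))

    def test_exact_p_matches_enumeration_oracle(self, rng):
        for _ in range(20):
            a = rng.integers(0, 6, size=4).astype(float)
            b = rng.integers(0, 6, size=4).astype(float)
            res = mann_whitney_u(a, b)
            assert res.method == "exact"
            assert res.p == pytest.approx(oracle_exact_p(a, b), abs=1e-12)

    def test_normal_approx_close_to_exact_for_small_n(self, rng):
        for _ in range(20):
            a = rng.normal(size=6)
            b = rng.normal(size=6)
            exact = mann_whitney_u(a, b).p
            approx = mann_whitney_u(a, b, exact_max_n=0).p
            assert abs(exact - approx) < 0.02

    def test_medians_and_iqrs_reported(self):
        res = mann_whitney_u([1, 2, 3, 4, 5], [10, 20, 30])
        assert res.median1 == 3 and res.median2 == 20
        assert res.iqr1[0] <= res.median1 <= res.iqr1[1]

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


# ---------------------------------------------------------------------------
# ROC / AUC

class TestRocAuc:
    def test_perfect_separation(self):
        scores = [10, 20, 30, 1, 2, 3]
        labels = [0, 0, 0, 1, 1, 1]  # impaired score lower
        res = roc_auc(scores, labels, direction="lower")
        assert res.auc == pytest.approx(1.0)
        assert res.ci95[1] == pytest.approx(1.0)

    def test_null_case_about_half(self, rng):
        scores = np.tile(np.arange(20.0), 2)
        labels = np.repeat([0, 1], 20)
        res = roc_auc(scores, labels)
        assert res.auc == pytest.approx(0.5)

    def test_curve_monotone_from_origin_to_one(self, rng):
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, size=40)
        if len(np.unique(labels)) < 2:
            labels[0], labels[1] = 0, 1
        res = roc_auc(scores, labels)
        assert res.fpr[0] == 0 and res.tpr[0] == 0
        assert res.fpr[-1] == 1 and res.tpr[-1] == 1
        assert np.all(np.diff(res.fpr) >= 0) and np.all(np.diff(res.tpr) >= 0)

    def test_auc_equals_u_over_n1n2(self, rng):
        for _ in range(30):
            n = int(rng.integers(8, 30))
            scores = rng.integers(0, 10, size=n).astype(float)  # ties likely
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            res = roc_auc(scores, labels, direction="lower")
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            # lower score indicates impairment: count neg ranking above pos
            u = oracle_u(neg, pos)
            assert res.auc == pytest.approx(u / (len(pos) * len(neg)), abs=1e-12)

    def test_direction_flip_mirrors_auc(self, rng):
        scores = rng.normal(size=30)
        labels = rng.integers(0, 2, size=30)
        labels[:2] = [0, 1]
        lo = roc_auc(scores, labels, direction="lower").auc
        hi = roc_auc(scores, labels, direction="higher").auc
        assert lo + hi == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2, 3], [1, 1, 1])


class TestAucCi:
    def _cohort_scores(self, rng, n=100):
        labels = np.repeat([0, 1], n // 2)
        scores = np.where(labels == 1, rng.normal(40, 15, n), rng.normal(55, 15, n))
        return scores, labels

    def test_ci_contains_point_auc(self, rng):
        scores, labels = self._cohort_scores(rng)
        res = roc_auc(scores, labels, direction="lower")
        low, high = res.ci95
        assert 0.0 <= low <= res.auc <= high <= 1.0

    def test_delong_and_bootstrap_agree(self, rng):
        scores, labels = self._cohort_scores(rng)
        res = roc_auc(scores, labels, direction="lower")
        dl = auc_ci(res, scores, labels, method="delong")
        bs = auc_ci(res, scores, labels, method="bootstrap", seed=11)
        mid_dl = (dl[0] + dl[1]) / 2
        mid_bs = (bs[0] + bs[1]) / 2
        assert abs(mid_dl - mid_bs) < 0.02

    def test_bootstrap_is_seed_deterministic(self, rng):
        scores, labels = self._cohort_scores(rng)
        res = roc_auc(scores, labels, direction="lower")
        assert auc_ci(res, scores, labels, "bootstrap", seed=5) == auc_ci(
            res, scores, labels, "bootstrap", seed=5
        )

    def test_degenerate_variance_falls_back_to_bootstrap(self, caplog):
        scores = np.array([1.0, 2, 3, 10, 11, 12])
        labels = np.array([1, 1, 1, 0, 0, 0])
        with caplog.at_level("WARNING"):
            res = roc_auc(scores, labels, direction="lower")
        assert res.ci_method == "bootstrap"
        assert res.ci95[1] == pytest.approx(1.0)
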