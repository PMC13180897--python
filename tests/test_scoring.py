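"""ROI geometry, hit testing, and the dwell-percentage score."""

import math

import numpy as np
import pytest

from istroop.gaze import GazeRecording, GazeSample, TrialWindowSamples
from istroop.scoring import (
    LayoutConfig,
    RegionOfInterest,
    ScoringConfig,
    hit_test,
    roi_for_corner,
    roi_for_trial,
    score_participant,
    score_trial,
)
from istroop.schedule import Corner


def window(t, x, y, valid, idx=0):
    return TrialWindowSamples(
        idx, np.asarray(t, float), np.asarray(x, float), np.asarray(y, float), np.asarray(valid, bool)
    )


class TestRoiGeometry:
    @pytest.mark.parametrize(
        "corner,rect",
        [
            (Corner.TOP_LEFT, (0.0, 0.0, 0.4, 0.4)),
            (Corner.TOP_RIGHT, (0.6, 0.0, 1.0, 0.4)),
            (Corner.BOTTOM_LEFT, (0.0, 0.6, 0.4, 1.0)),
            (Corner.BOTTOM_RIGHT, (0.6, 0.6, 1.0, 1.0)),
        ],
    )
    def test_default_corner_anchoring(self, corner, rect):
        assert roi_for_corner(corner).rect == pytest.approx(rect)

    def test_roi_follows_trial_correct_corner(self, default_schedule):
        for t in default_schedule.trials:
            assert roi_for_trial(t).corner is t.correct_corner

    def test_half_fraction_rois_tile_screen_disjointly(self, rng):
        lay = LayoutConfig(roi_width=0.5, roi_height=0.5)
        rois = [roi_for_corner(c, lay) for c in Corner]
        pts = rng.random((2000, 2))
        hits = np.stack([r.contains(pts[:, 0], pts[:, 1]) for r in rois])
        assert np.all(hits.sum(axis=0) == 1)  # exactly one ROI per on-screen point

    def test_default_rois_pairwise_disjoint(self, rng):
        rois = [roi_for_corner(c) for c in Corner]
        pts = rng.random((2000, 2))
        hits = np.stack([r.contains(pts[:, 0], pts[:, 1]) for r in rois])
        assert np.all(hits.sum(axis=0) <= 1)

    def test_degenerate_rect_rejected(self):
        with pytest.raises(ValueError):
            RegionOfInterest(Corner.TOP_LEFT, 0.4, 0.0, 0.4, 0.4)


class TestHitTest:
    roi = RegionOfInterest(Corner.TOP_LEFT, 0.0, 0.0, 0.4, 0.4)

    def test_interior_point_hits(self):
        assert hit_test(GazeSample(0.0, 0.1, 0.1, True), self.roi)

    def test_half_open_edge_misses(self):
        assert not hit_test(GazeSample(0.0, 0.4, 0.1, True), self.roi)
        assert hit_test(GazeSample(0.0, 0.0, 0.0, True), self.roi)

    def test_invalid_sample_never_hits(self):
        assert not hit_test(GazeSample(0.0, 0.1, 0.1, False), self.roi)

    def test_offscreen_point_misses_all_rois(self):
        s = GazeSample(0.0, 1.2, -0.1, True)
        assert not any(hit_test(s, roi_for_corner(c)) for c in Corner)


class TestScoreTrial:
    roi = RegionOfInterest(Corner.TOP_LEFT, 0.0, 0.0, 0.4, 0.4)

    def test_all_in_roi_gives_100(self):
        n = 350
        w = window(np.arange(n) / 50, np.full(n, 0.2), np.full(n, 0.2), np.ones(n))
        s = score_trial(w, self.roi)
        assert s.pct == 100.0 and s.qc_pass

    def test_none_in_roi_gives_0(self):
        n = 350
        w = window(np.arange(n) / 50, np.full(n, 0.9), np.full(n, 0.9), np.ones(n))
        assert score_trial(w, self.roi).pct == 0.0

    def test_half_hits_gives_50_and_matches_naive_scan(self):
        n = 350
        x = np.where(np.arange(n) < 175, 0.2, 0.9)
        w = window(np.arange(n) / 50, x, np.full(n, 0.2), np.ones(n))
        s = score_trial(w, self.roi)
        naive = sum(
            1
            for i in range(n)
            if w.valid[i] and 0 <= w.x[i] < 0.4 and 0 <= w.y[i] < 0.4
        )
        assert s.n_hit == naive == 175
        assert s.pct == 50.0

    def test_zero_valid_samples_marked_missing(self):
        n = 10
        w = window(np.arange(n) / 50, np.full(n, np.nan), np.full(n, np.nan), np.zeros(n))
        s = score_trial(w, self.roi)
        assert s.missing and not s.qc_pass

    def test_qc_fails_below_min_valid_fraction(self):
        n = 350
        valid = np.zeros(n, bool)
        valid[:100] = True  # 100/350 < 0.5
        x = np.where(valid, 0.2, np.nan)
        w = window(np.arange(n) / 50, x, x, valid)
        s = score_trial(w, self.roi)
        assert not s.qc_pass and s.pct == 100.0

    def test_window_denominator_config(self):
        n = 350
        valid = np.zeros(n, bool)
        valid[:175] = True
        x = np.where(valid, 0.2, np.nan)
        w = window(np.arange(n) / 50, x, x, valid)
        s = score_trial(w, self.roi, ScoringConfig(denominator="window"))
        assert s.pct == pytest.approx(100 * 175 / 350)

    def test_monotone_in_added_samples(self, rng):
        n = 100
        w = window(np.arange(n) / 50, rng.random(n), rng.random(n), np.ones(n))
        base = score_trial(w, self.roi)
        w_in = window(
            np.arange(n + 1) / 50,
            np.append(w.x, 0.2),
            np.append(w.y, 0.2),
            np.append(w.valid, True),
        )
        w_out = window(
            np.arange(n + 1) / 50,
            np.append(w.x, 0.9),
            np.append(w.y, 0.9),
            np.append(w.valid, True),
        )
        assert score_trial(w_in, self.roi).pct >= base.pct
        assert score_trial(w_out, self.roi).pct <= base.pct


class TestScoreParticipant:
    def _recording_gazing_at(self, sched, corner_of_trial, rate=50.0):
        ts, xs, ys = [], [], []
        for trial in sched.trials:
            n = int(round(trial.duration * rate))
            roi = roi_for_corner(corner_of_trial(trial))
            cx, cy = (roi.x0 + roi.x1) / 2, (roi.y0 + roi.y1) / 2
            ts.append(trial.onset + np.arange(n) / rate)
            xs.append(np.full(n, cx))
            ys.append(np.full(n, cy))
        t = np.concatenate(ts)
        return GazeRecording(
            "p", t, np.concatenate(xs), np.concatenate(ys), np.ones(len(t), bool), rate
        )

    def test_always_on_correct_option_scores_100(self, default_schedule):
        rec = self._recording_gazing_at(default_schedule, lambda t: t.correct_corner)
        res = score_participant(rec, default_schedule)
        assert res.total_score == pytest.approx(100.0)
        assert all(v == pytest.approx(100.0) for v in res.condition_scores.values())
        assert res.usable and res.n_qc_failed == 0

    def test_uniform_gaze_over_quadrants_scores_about_25(self, default_schedule, rng):
        lay = LayoutConfig(roi_width=0.5, roi_height=0.5)
        duration = default_schedule.duration
        t = np.arange(0, duration, 1 / 50)
        n = len(t)
        rec = GazeRecording("p", t, rng.random(n), rng.random(n), np.ones(n, bool))
        cfg = ScoringConfig(layout=lay)
        res = score_participant(rec, default_schedule, cfg)
        assert res.total_score == pytest.approx(25.0, abs=3.0)

    def test_missing_trial_dropped_from_mean(self, default_schedule):
        rec = self._recording_gazing_at(default_schedule, lambda t: t.correct_corner)
        # blank out trial 0's window: all samples invalid
        first = default_schedule.trials[0]
        mask = (rec.t >= first.onset) & (rec.t < first.onset + first.duration)
        valid = rec.valid.copy()
        valid[mask] = False
        x = rec.x.copy()
        y = rec.y.copy()
        x[mask] = np.nan
        y[mask] = np.nan
        rec2 = GazeRecording("p", rec.t, x, y, valid, rec.nominal_rate)
        res = score_participant(rec2, default_schedule)
        assert res.n_qc_failed == 1
        assert res.total_score == pytest.approx(100.0)

    def test_unusable_when_too_many_trials_fail(self, default_schedule):
        rec = self._recording_gazing_at(default_schedule, lambda t: t.correct_corner)
        valid = rec.valid.copy()
        cutoff = default_schedule.trials[9].onset  # kill 9 of 16 trials
        mask = rec.t < cutoff
        x, y = rec.x.copy(), rec.y.copy()
        valid[mask] = False
        x[mask] = np.nan
        y[mask] = np.nan
        rec2 = GazeRecording("p", rec.t, x, y, valid, rec.nominal_rate)
        res = score_participant(rec2, default_schedule)
        assert res.n_qc_failed == 9 and not res.usable

    def test_sampling_rate_invariance(self, default_schedule):
        # identical deterministic gaze path sampled at 50 vs 100 Hz
        res50 = score_participant(
            self._recording_gazing_at(default_schedule, lambda t: t.correct_corner, 50),
            default_schedule,
        )
        res100 = score_participant(
            self._recording_gazing_at(default_schedule, lambda t: t.correct_corner, 100),
            default_schedule,
        )
        assert abs(res50.total_score - res100.total_score) < 1.0

    def test_total_always_within_bounds(self, default_schedule, rng):
        duration = default_schedule.duration
        t = np.arange(0, duration, 1 / 50)
        n = len(t)
        valid = rng.random(n) > 0.3
        x = np.where(valid, rng.random(n) * 1.4 - 0.2, np.nan)  # partly off-screen
        y = np.where(valid, rng.random(n) * 1.4 - 0.2, np.nan)
        rec = GazeRecording("p", t, x, y, valid)
        res = score_participant(rec, default_schedule)
        assert 0.0 <= res.total_score <= 100.0
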