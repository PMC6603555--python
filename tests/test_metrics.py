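"""Evaluation statistics: confusion arithmetic, event-window matching,
ROC/TOC construction and presentation rounding."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from falldet import (ConfusionCounts, compute_metrics, j_index,
                     match_events_clip, match_events_continuous, roc_points,
                     toc_points)
from falldet.metrics import UndefinedMetricError, round_half_up


class TestJIndex:
    @pytest.mark.parametrize("sens, spec, expected", [
        (96.7, 96.4, 93.1),
        (89.4, 97.3, 86.7),
        (100.0, 100.0, 100.0),
        (50.0, 50.0, 0.0),
        (0.0, 100.0, 0.0),
        (40.0, 40.0, -20.0),
    ])
    def test_youden_identity(self, sens, spec, expected):
        assert j_index(sens, spec) == pytest.approx(expected)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            j_index(101.0, 50.0)

    @given(st.floats(0, 100), st.floats(0, 100))
    def test_matches_counts_route(self, sens, spec):
        # J from percentages equals J computed through compute_metrics on
        # counts realizing (approximately) those percentages
        tp = int(round(sens * 10))
        tn = int(round(spec * 10))
        counts = ConfusionCounts(tp=tp, fn=1000 - tp, fp=1000 - tn, tn=tn)
        rep = compute_metrics(counts)
        assert rep.j_index_pct == pytest.approx(
            j_index(rep.sensitivity_pct, rep.specificity_pct))


class TestComputeMetrics:
    def test_continuous_scoring_high_sensitivity_set(self):
        # 272 falls / 44.67 h of continuous wear: 259 hits, 24 false alarms
        rep = compute_metrics(
            ConfusionCounts(tp=259, fn=13, fp=24, tn=None), hours=44.67)
        r = rep.rounded()
        assert r["sensitivity_pct"] == 95.2
        assert r["precision_pct"] == 91.5
        assert r["f_score_pct"] == 93.3
        assert r["fa_per_day"] == 8.9
        assert rep.specificity_pct is None  # undefined on continuous data

    def test_continuous_scoring_low_sensitivity_set(self):
        rep = compute_metrics(
            ConfusionCounts(tp=220, fn=52, fp=1, tn=None), hours=44.67)
        r = rep.rounded()
        assert r["sensitivity_pct"] == 80.9
        assert r["precision_pct"] == 99.5
        assert r["fa_per_day"] == 0.4

    def test_undefined_sensitivity_raises(self):
        with pytest.raises(UndefinedMetricError):
            compute_metrics(ConfusionCounts(tp=0, fn=0, fp=1, tn=1))

    def test_fa_per_day_linearity(self):
        base = compute_metrics(ConfusionCounts(tp=1, fn=0, fp=6, tn=None),
                               hours=33.0)
        double_fp = compute_metrics(
            ConfusionCounts(tp=1, fn=0, fp=12, tn=None), hours=33.0)
        double_hours = compute_metrics(
            ConfusionCounts(tp=1, fn=0, fp=6, tn=None), hours=66.0)
        assert double_fp.fa_per_day == pytest.approx(2 * base.fa_per_day)
        assert double_hours.fa_per_day == pytest.approx(base.fa_per_day / 2)

    def test_day_hours_scaling(self):
        rep16 = compute_metrics(ConfusionCounts(tp=1, fn=0, fp=8, tn=None),
                                hours=44.67, day_hours=16.5)
        rep33 = compute_metrics(ConfusionCounts(tp=1, fn=0, fp=8, tn=None),
                                hours=44.67, day_hours=33.0)
        assert rep33.fa_per_day == pytest.approx(2 * rep16.fa_per_day)

    def test_rounding_half_up_at_presentation_only(self):
        assert round_half_up(8.85, 1) == 8.9
        assert round_half_up(8.84999, 1) == 8.8
        assert round_half_up(99.55, 1) == 99.6


class TestClipMatching:
    def test_per_type_accuracy_of_dominant_false_alarm_source(self):
        # 73 standing-quick-drop clips, 33 of which trigger the detector
        events = {f"c{i}": ([1] if i < 33 else []) for i in range(73)}
        labels = {f"c{i}": False for i in range(73)}
        c = match_events_clip(events, labels)
        assert (c.fp, c.tn) == (33, 40)
        acc = c.tn / (c.tn + c.fp) * 100
        assert round_half_up(acc, 1) == 54.8

    def test_fall_totals(self):
        events = {f"f{i}": ([1] if i < 970 else []) for i in range(1009)}
        labels = {f"f{i}": True for i in range(1009)}
        c = match_events_clip(events, labels)
        assert (c.tp, c.fn) == (970, 39)

    def test_empty_corpus(self):
        c = match_events_clip({}, {})
        assert (c.tp, c.fp, c.tn, c.fn) == (0, 0, 0, 0)

    def test_unlabeled_clip_rejected(self):
        with pytest.raises(KeyError):
            match_events_clip({"x": [1]}, {})


class TestContinuousMatching:
    def test_counts_windows_once_and_flags_strays(self):
        # 272 windows, 236 carrying at least one event, 5 stray events
        windows = [(i * 10_000, i * 10_000 + 2_000) for i in range(272)]
        events = [i * 10_000 + 500 for i in range(236)]
        events += [236 * 10_000 + 500] * 2  # doubled hits: not double-counted
        strays = [5_000_000_000 + i * 100_000 for i in range(5)]
        c = match_events_continuous(events + strays, windows, tolerance_s=0.0)
        assert (c.tp, c.fn, c.fp) == (237, 35, 5)
        assert c.tn is None

    def test_no_events(self):
        c = match_events_continuous([], [(0, 100), (500, 600)])
        assert (c.tp, c.fp, c.fn) == (0, 0, 2)

    def test_overlapping_windows_rejected(self):
        with pytest.raises(ValueError):
            match_events_continuous([], [(0, 100), (50, 200)])

    def test_event_conservation_at_zero_tolerance(self):
        rng = np.random.default_rng(1)
        windows = sorted((int(s), int(s) + 1000)
                         for s in rng.choice(10**6, 15, replace=False) * 50)
        windows = [w for i, w in enumerate(windows)
                   if i == 0 or w[0] > windows[i - 1][1]]
        events = list(rng.integers(0, 5 * 10**7, 60))
        c = match_events_continuous(events, windows, tolerance_s=0.0)
        in_any = sum(1 for t in events
                     if any(s <= t <= e for s, e in windows))
        assert c.tp + c.fp <= len(events)
        assert c.fp == len(events) - in_any

    def test_agrees_with_brute_force_interval_check(self):
        rng = np.random.default_rng(7)
        starts = np.sort(rng.choice(np.arange(100) * 10_000, 18,
                                    replace=False))
        windows = [(int(s), int(s) + 3_000) for s in starts]
        events = sorted(int(t) for t in rng.integers(0, 10**6, 40))
        tol = 2.0
        c = match_events_continuous(events, windows, tolerance_s=tol)
        # brute force over all event-window pairs
        tol_ms = int(tol * 1000)
        hit_w = set()
        fp = 0
        for t in events:
            match = [i for i, (s, e) in enumerate(windows)
                     if s - tol_ms <= t <= e + tol_ms]
            if match:
                hit_w.add(match[0])
            else:
                fp += 1
        assert (c.tp, c.fp, c.fn) == (len(hit_w), fp,
                                      len(windows) - len(hit_w))


class TestCurvePoints:
    def test_toc_from_hits_and_false_alarms(self):
        assert toc_points([(236, 5)]) == [(241, 236)]
        assert toc_points([(0, 0)]) == [(0, 0)]

    def test_roc_from_operating_point(self):
        (x, y), = roc_points([(95.0, 94.4)])
        assert x == pytest.approx(0.056)
        assert y == pytest.approx(0.950)

    def test_toc_y_never_exceeds_x(self):
        pts = toc_points([(10, 0), (5, 7), (0, 3)])
        assert all(y <= x for x, y in pts)

    def test_plots_render(self, tmp_path):
        import matplotlib
        matplotlib.use("Agg")
        from falldet.metrics import plot_roc, plot_toc
        ax = plot_roc(roc_points([(95.0, 94.4), (89.4, 97.3)]))
        assert ax.get_xlabel()
        ax2 = plot_toc(toc_points([(236, 5), (259, 24)]), total_falls=272)
        assert ax2.get_ylabel()
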