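"""Threshold-search pipeline: splits, undersampling, random draws, candidate
evaluation, ranking and sensitivity-level selection."""

import numpy as np
import pytest

from falldet import (DEFAULT_BOUNDS, CandidateResult, OptimizationConfig,
                     ThresholdBounds, ThresholdOptimizer, ThresholdSet,
                     make_ds1_corpus, select_levels)
from falldet.optimizer import (sample_threshold_sets, stratified_splits,
                               undersample_majority)
from falldet.state_machine import TUNABLE_FIELDS


def _labels(n_fall, n_nonfall):
    return np.array([True] * n_fall + [False] * n_nonfall)


class TestStratifiedSplits:
    def test_seventy_thirty_per_class(self):
        cfg = OptimizationConfig(n_splits=5)
        splits = stratified_splits(_labels(10, 10), cfg,
                                   np.random.default_rng(0))
        labels = _labels(10, 10)
        for train, test in splits:
            assert labels[train].sum() == 7
            assert (~labels[train]).sum() == 7
            assert len(train) + len(test) == 20
            assert set(train) & set(test) == set()

    def test_train_ratio_within_one_clip_of_global(self):
        labels = _labels(37, 91)
        cfg = OptimizationConfig(n_splits=10)
        for train, _ in stratified_splits(labels, cfg,
                                          np.random.default_rng(3)):
            frac = labels[train].mean()
            global_frac = labels.mean()
            assert abs(frac * len(train) - global_frac * len(train)) <= 1.0

    def test_deterministic_per_seed(self):
        labels = _labels(12, 30)
        cfg = OptimizationConfig(n_splits=4)
        a = stratified_splits(labels, cfg, np.random.default_rng(9))
        b = stratified_splits(labels, cfg, np.random.default_rng(9))
        for (ta, sa), (tb, sb) in zip(a, b):
            np.testing.assert_array_equal(ta, tb)
            np.testing.assert_array_equal(sa, sb)

    def test_tiny_class_rejected(self):
        with pytest.raises(ValueError):
            stratified_splits(_labels(1, 10), OptimizationConfig(),
                              np.random.default_rng(0))


class TestUndersampling:
    def test_majority_reduced_to_minority_count(self):
        labels = _labels(60, 100)
        idx = np.arange(160)
        out = undersample_majority(idx, labels, np.random.default_rng(0))
        assert labels[out].sum() == 60
        assert (~labels[out]).sum() == 60
        assert set(out) <= set(idx)

    def test_balanced_input_unchanged(self):
        labels = _labels(5, 5)
        idx = np.arange(10)
        out = undersample_majority(idx, labels, np.random.default_rng(0))
        np.testing.assert_array_equal(out, idx)


class TestThresholdSampling:
    def test_draws_within_bounds_and_fixed_fields_untouched(self):
        sets = sample_threshold_sets(DEFAULT_BOUNDS, 50,
                                     np.random.default_rng(5))
        assert len(sets) == 50
        for ts in sets:
            for name in TUNABLE_FIELDS:
                lo, hi = getattr(DEFAULT_BOUNDS, name)
                assert lo <= getattr(ts, name) <= hi
            assert ts.watcher_duration_s == 5.0

    def test_collapsed_bounds_give_identical_sets(self):
        b = ThresholdBounds(
            unstable_mag_dev=(0.2, 0.2), fall_ratio_min=(1.0, 1.0),
            impact_mag_min=(1.5, 1.5), impact_angle_min=(40.0, 40.0),
            watcher_move_dev=(0.3, 0.3))
        sets = sample_threshold_sets(b, 10, np.random.default_rng(0))
        assert len(set(sets)) == 1

    def test_same_seed_same_sets(self):
        a = sample_threshold_sets(DEFAULT_BOUNDS, 5, np.random.default_rng(2))
        b = sample_threshold_sets(DEFAULT_BOUNDS, 5, np.random.default_rng(2))
        assert a == b


@pytest.fixture(scope="module")
def small_corpus():
    # ~40 clips, both classes, mixed positions
    counts = {
        "Forward fall ending lying flat": 6,
        "Backward fall ending lying": 6,
        "Walk few meters and fall forward": 4,
        "Walk a few meters": 6,
        "While standing quickly drop sensor on the table": 6,
        "Forward Fall with recovery": 4,
        "Run a few meters": 4,
        "Sitting on a chair": 4,
    }
    return list(make_ds1_corpus(counts=counts, seed=21))


@pytest.fixture(scope="module")
def small_fit(small_corpus):
    cfg = OptimizationConfig(n_splits=3, n_undersamples=2, n_random_sets=8,
                             n_keep=5, seed=13, rate_hz=50)
    return ThresholdOptimizer(small_corpus, config=cfg).fit(), cfg


class TestEvaluateCandidate:
    def test_impossible_thresholds_fire_nothing(self, small_corpus):
        from falldet.optimizer import evaluate_candidate
        ts = ThresholdSet(unstable_mag_dev=50.0, fall_ratio_min=500.0,
                          impact_mag_min=50.0, impact_angle_min=179.0,
                          watcher_move_dev=50.0)
        c = evaluate_candidate(ts, small_corpus, rate_hz=50)
        assert c.tp == 0 and c.fp == 0
        assert c.fn == sum(1 for cl in small_corpus if cl.is_fall)
        assert c.tn == sum(1 for cl in small_corpus if not cl.is_fall)

    def test_reference_thresholds_separate_the_toy_corpus(self, small_corpus):
        from falldet import REFERENCE_THRESHOLDS
        from falldet.optimizer import evaluate_candidate
        c = evaluate_candidate(REFERENCE_THRESHOLDS, small_corpus, rate_hz=100)
        assert c.fn == 0 and c.fp == 0


class TestRunOptimization:
    def test_evaluation_counts_follow_loop_arithmetic(self, small_fit):
        res, cfg = small_fit
        assert res.n_train_evaluations == (
            cfg.n_splits * cfg.n_undersamples * cfg.n_random_sets)
        assert res.n_test_evaluations == (
            cfg.n_splits * cfg.n_undersamples
            * min(cfg.n_keep, cfg.n_random_sets))

    def test_leaderboard_sorted_by_test_j(self, small_fit):
        res, cfg = small_fit
        js = [c.test_j for c in res.candidates]
        assert js == sorted(js, reverse=True)
        assert len(res.candidates) <= cfg.n_keep

    def test_reproducible_from_seed(self, small_corpus):
        cfg = OptimizationConfig(n_splits=2, n_undersamples=2, n_random_sets=5,
                                 n_keep=3, seed=99, rate_hz=50)
        r1 = ThresholdOptimizer(small_corpus, config=cfg).fit()
        r2 = ThresholdOptimizer(small_corpus, config=cfg).fit()
        assert r1.candidates == r2.candidates
        assert r1.select_levels(3).to_dict() == r2.select_levels(3).to_dict()

    def test_best_candidate_separates_synthetic_corpus(self, small_fit):
        res, _ = small_fit
        assert res.candidates[0].test_j >= 90.0

    def test_summary_has_rank_and_threshold_columns(self, small_fit):
        res, _ = small_fit
        df = res.summary()
        assert list(df["rank"]) == list(range(1, len(df) + 1))
        for name in TUNABLE_FIELDS:
            assert name in df.columns


def _cand(sens, spec, i=0):
    ts = ThresholdSet(0.2 + i * 1e-3, 1.0, 1.5, 40.0, 0.3)
    return CandidateResult(thresholds=ts, train_j=0.0,
                           test_j=sens + spec - 100.0, test_sens=sens,
                           test_spec=spec, split_id=0, undersample_id=0)


class TestSelectLevels:
    def test_published_style_operating_points(self):
        pts = [_cand(89.4, 97.3, 0), _cand(95.0, 94.4, 1),
               _cand(96.4, 92.8, 2)]
        lv = select_levels(pts)
        assert lv.low is pts[0]      # highest specificity
        assert lv.medium is pts[1]   # highest J
        assert lv.high is pts[2]     # highest sensitivity
        assert lv.high.test_sens >= lv.medium.test_sens >= lv.low.test_sens

    def test_degenerate_repeated_point(self):
        pts = [_cand(90.0, 90.0)] * 10
        lv = select_levels(pts)
        assert lv.low is lv.medium is lv.high

    def test_matches_exhaustive_argmax(self):
        rng = np.random.default_rng(11)
        pts = [_cand(float(s), float(p), i)
               for i, (s, p) in enumerate(rng.uniform(50, 100, (10, 2)))]
        lv = select_levels(pts)
        assert lv.medium.test_j == max(c.test_j for c in pts)
        assert lv.low.test_spec == max(c.test_spec for c in pts)
        assert lv.high.test_sens == max(c.test_sens for c in pts)

    def test_too_few_candidates_rejected(self):
        with pytest.raises(ValueError):
            select_levels([_cand(90, 90), _cand(91, 89)])
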