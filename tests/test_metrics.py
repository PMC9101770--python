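"""Margin filter, confusion ratios, four-class segmentation, segment metrics."""

import math

import numpy as np
import pytest

from warmgait import metrics as mx


class TestMarginFilterMask:
    def test_no_change_points_all_true(self):
        assert mx.margin_filter_mask(np.zeros(40, int)).all()

    def test_single_change_point_excludes_25_samples(self):
        labels = np.array([0] * 50 + [1] * 50)
        mask = mx.margin_filter_mask(labels, change_margin=12)
        excluded = np.flatnonzero(~mask)
        # change point at index 50: indices 38..62 inclusive are masked out
        assert excluded.tolist() == list(range(38, 63))
        assert excluded.size == 25

    def test_change_point_near_start_truncated(self):
        labels = np.array([0] * 5 + [1] * 30)
        mask = mx.margin_filter_mask(labels, change_margin=12)
        assert np.flatnonzero(~mask).tolist() == list(range(0, 18))


class TestConfusion:
    def test_perfect_prediction(self):
        y = np.array([1, 1, 0, 0, 1])
        c = mx.confusion(y, y)
        assert (c.fp, c.fn) == (0, 0)
        assert (c.tp, c.tn) == (3, 2)

    def test_inverted_prediction(self):
        y = np.array([1, 0, 1, 0])
        c = mx.confusion(y, 1 - y)
        assert (c.tp, c.tn) == (0, 0)
        assert (c.fp, c.fn) == (2, 2)

    def test_hand_tally_ten_points(self):
        true_ = np.array([1, 1, 1, 0, 0, 0, 1, 0, 1, 0])
        pred_ = np.array([1, 0, 1, 1, 0, 0, 1, 1, 0, 0])
        c = mx.confusion(true_, pred_)
        assert (c.tp, c.fp, c.fn, c.tn) == (3, 2, 2, 3)

    def test_mask_restricts_counts(self):
        true_ = np.array([1, 1, 0, 0])
        pred_ = np.array([1, 0, 0, 1])
        mask = np.array([True, False, True, False])
        c = mx.confusion(true_, pred_, mask)
        assert (c.tp, c.fp, c.fn, c.tn) == (1, 0, 0, 1)

    def test_counts_sum_to_masked_in_points(self, rng):
        true_ = rng.integers(0, 2, 500)
        pred_ = rng.integers(0, 2, 500)
        mask = mx.margin_filter_mask(true_)
        c = mx.confusion(true_, pred_, mask)
        assert c.total == int(mask.sum())


class TestRatios:
    def test_worked_example(self):
        c = mx.ConfusionCounts(tp=8, fp=2, fn=1, tn=9)
        assert mx.precision(c) == pytest.approx(0.8)
        assert mx.accuracy(c) == pytest.approx(0.85)
        assert mx.detection_prevalence(c) == pytest.approx(0.5)
        assert mx.prevalence(c) == pytest.approx(0.45)

    def test_perfect_counts(self):
        c = mx.ConfusionCounts(tp=5, fp=0, fn=0, tn=5)
        assert mx.precision(c) == 1.0 and mx.accuracy(c) == 1.0

    def test_undefined_precision_is_nan_not_zero(self):
        c = mx.ConfusionCounts(tp=0, fp=0, fn=3, tn=7)
        assert math.isnan(mx.precision(c))

    def test_prevalences_agree_when_fp_equals_fn(self, rng):
        c = mx.ConfusionCounts(tp=13, fp=4, fn=4, tn=9)
        assert mx.prevalence(c) == mx.detection_prevalence(c)


class TestCombinedSegmentation:
    def test_perfect_prediction_only_tp_tn_segments(self):
        y = np.array([1, 1, 0, 0, 1, 1, 1, 0])
        segs = mx.combined_segmentation(y, y)
        assert [s.cls for s in segs] == ["TP", "TN", "TP", "TN"]

    def test_four_class_example(self):
        segs = mx.combined_segmentation([1, 1, 0, 0], [1, 0, 0, 1])
        assert [s.cls for s in segs] == ["TP", "FN", "TN", "FP"]
        assert [s.n_samples for s in segs] == [1, 1, 1, 1]

    def test_all_negative_single_tn_segment(self):
        segs = mx.combined_segmentation(np.zeros(9, int), np.zeros(9, int))
        assert len(segs) == 1 and segs[0].cls == "TN" and segs[0].n_samples == 9

    def test_masked_gap_joins_matching_runs(self):
        # TP run, masked gap, TP run again -> one segment
        true_ = np.array([1, 1, 1, 1, 1])
        pred_ = np.array([1, 1, 0, 1, 1])
        mask = np.array([True, True, False, True, True])
        segs = mx.combined_segmentation(true_, pred_, mask)
        assert len(segs) == 1
        assert segs[0].cls == "TP" and segs[0].n_samples == 4

    def test_masked_gap_keeps_distinct_runs_apart(self):
        true_ = np.array([1, 1, 0, 0, 0])
        pred_ = np.array([1, 1, 1, 0, 0])
        mask = np.array([True, True, False, True, True])
        segs = mx.combined_segmentation(true_, pred_, mask)
        assert [s.cls for s in segs] == ["TP", "TN"]

    def test_segments_partition_timeline(self, rng):
        true_ = rng.integers(0, 2, 300)
        pred_ = rng.integers(0, 2, 300)
        segs = mx.combined_segmentation(true_, pred_)
        assert sum(s.n_samples for s in segs) == 300
        for a, b in zip(segs, segs[1:]):
            assert a.end == b.start


class TestSegmentMetrics:
    def test_perfect_prediction_scores_one(self):
        y = np.array([1, 1, 0, 1, 0, 0, 1])
        sc = mx.segment_confusion(mx.combined_segmentation(y, y))
        assert mx.precision(sc) == 1.0 and mx.accuracy(sc) == 1.0

    def test_four_segment_example_ratios(self):
        segs = mx.combined_segmentation([1, 1, 0, 0], [1, 0, 0, 1])
        sc = mx.segment_confusion(segs)
        assert mx.precision(sc) == pytest.approx(0.5)  # 1 TP / (1 TP + 1 FP)
        assert mx.accuracy(sc) == pytest.approx(0.5)  # (1 + 1) / 4

    def test_segment_precision_diverges_from_timepoint_precision(self):
        # many short correct walking runs, one long spurious one:
        # the long FP segment counts once at segment level but dominates
        # the time-point counts... and vice versa.
        true_ = np.array([1, 0, 1, 0, 1, 0] + [0] * 30)
        pred_ = np.array([1, 0, 1, 0, 1, 0] + [1] * 30)
        c = mx.confusion(true_, pred_)
        sc = mx.segment_confusion(mx.combined_segmentation(true_, pred_))
        assert mx.precision(sc) > mx.precision(c)  # 3/(3+1) vs 3/(3+30)

    def test_weight_by_length_variant(self):
        true_ = np.array([1, 1, 1, 0, 0, 0])
        pred_ = np.array([1, 1, 1, 1, 0, 0])
        segs = mx.combined_segmentation(true_, pred_)
        unweighted = mx.segment_confusion(segs)
        weighted = mx.segment_confusion(segs, weight_by_length=True)
        assert (unweighted.tp, unweighted.fp, unweighted.tn) == (1, 1, 1)
        assert (weighted.tp, weighted.fp, weighted.tn) == (3, 1, 2)

    def test_empty_segmentation_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            mx.segment_confusion([])


def test_metrics_report_bundles_everything(rng):
    # run-structured labels so the margin filter leaves points to score
    true_ = np.repeat(rng.integers(0, 2, 8), 50)[:400]
    pred_ = np.repeat(rng.integers(0, 2, 8), 50)[:400]
    report = mx.metrics_report(true_, pred_)
    counts = report["counts"]
    assert sum(counts.values()) == report["n_masked_in"]
    assert 0 <= report["accuracy"] <= 1
    assert report["segment_counts"]["tp"] >= 0
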