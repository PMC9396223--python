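"""Metric stack: matching, P/R/F1, AP/mAP, counting, yield regression."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from litchidet.evaluation import (average_precision, count_fruits,
                                  density_stratum, evaluate, match, mean_ap,
                                  precision_recall_f1, yield_regression)
from litchidet.records import Box, Detection


def _det(x, y, w, h, conf, label="litchi"):
    return Detection(Box(x, y, x + w, y + h, label), conf)


class TestMatch:
    def test_perfect_one_to_one(self):
        gts = [Box(0, 0, 10, 10), Box(20, 20, 30, 30)]
        dets = [_det(0, 0, 10, 10, 0.9), _det(20, 20, 10, 10, 0.8)]
        res = match(dets, gts)
        assert res.tp == 2 and res.fp == 0 and res.fn == 0

    def test_double_detection_counts_one_fp(self):
        gts = [Box(0, 0, 10, 10)]
        dets = [_det(0, 0, 10, 10, 0.9), _det(1, 1, 9, 9, 0.8)]
        res = match(dets, gts)
        assert res.tp == 1 and res.fp == 1 and res.fn == 0

    def test_class_mismatch_is_fp(self):
        gts = [Box(0, 0, 10, 10, "litchi")]
        dets = [_det(0, 0, 10, 10, 0.9, "raw_litchi")]
        res = match(dets, gts)
        assert res.tp == 0 and res.fp == 1 and res.fn == 1

    @given(seed=st.integers(0, 40))
    def test_matches_independent_greedy_oracle(self, seed):
        rng = np.random.default_rng(seed)
        gts = [Box(x, y, x + w, y + h,
                   "litchi" if rng.uniform() < 0.5 else "raw_litchi")
               for x, y, w, h in rng.uniform(5, 40, (10, 4))]
        dets = [_det(*rng.uniform(5, 40, 4), float(rng.uniform(0, 1)),
                     "litchi" if rng.uniform() < 0.5 else "raw_litchi")
                for _ in range(10)]
        res = match(dets, gts, 0.5)

        # oracle: explicit re-walk of the greedy rule
        order = sorted(range(len(dets)), key=lambda i: -dets[i].confidence)
        used = set()
        tp = 0
        for i in order:
            cands = [(dets[i].box.iou(g), j) for j, g in enumerate(gts)
                     if j not in used and g.label == dets[i].label]
            cands = [(v, j) for v, j in cands if v >= 0.5]
            if cands:
                v, j = max(cands)
                used.add(j)
                tp += 1
        assert res.tp == tp and res.fn == len(gts) - tp

    def test_tp_bounded_by_min_of_sides(self):
        gts = [Box(0, 0, 10, 10)] * 3
        dets = [_det(0, 0, 10, 10, 0.9)]
        res = match(dets, gts)
        assert res.tp <= min(len(dets), len(gts))


class TestPrecisionRecallF1:
    def test_published_table_row_rounds_to_087(self):
        # P=87.6%, R=85.6% -> F1 = 2PR/(P+R) = 0.8659 -> 0.87 at 2 d.p.
        p, r = 0.876, 0.856
        f1 = 2 * p * r / (p + r)
        assert round(f1, 2) == 0.87

    def test_equal_p_r_gives_f1_equal_p(self):
        p, r, f1 = precision_recall_f1(30, 10, 10)
        assert p == r == f1 == 0.75

    def test_zero_tp_gives_zeros(self):
        assert precision_recall_f1(0, 5, 7) == (0.0, 0.0, 0.0)

    def test_empty_everything_flags_zero_not_nan(self):
        p, r, f1 = precision_recall_f1(0, 0, 0)
        assert (p, r, f1) == (0.0, 0.0, 0.0)


class TestAveragePrecision:
    def test_perfect_detector_has_ap_one(self):
        ap = average_precision([0.9, 0.8], [True, True], n_gt=2)
        assert ap == 1.0

    def test_three_detection_toy_by_threshold_enumeration(self):
        # confidences 0.9 TP, 0.8 FP, 0.7 TP over 2 gts.
        # PR points: (r=.5, p=1), (r=.5, p=.5), (r=1, p=2/3);
        # envelope integrates to 0.5*1 + 0.5*(2/3) = 5/6.
        ap = average_precision([0.9, 0.8, 0.7], [True, False, True], n_gt=2)
        assert ap == pytest.approx(5 / 6)

    def test_invariant_to_monotone_confidence_rescaling(self):
        conf = [0.9, 0.6, 0.4, 0.2]
        flags = [True, False, True, False]
        a = average_precision(conf, flags, 3)
        b = average_precision([c ** 3 for c in conf], flags, 3)
        assert a == pytest.approx(b)

    @given(seed=st.integers(0, 40))
    def test_removing_a_fp_never_decreases_ap(self, seed):
        rng = np.random.default_rng(seed)
        n = 12
        conf = rng.uniform(0, 1, n).tolist()
        flags = (rng.uniform(size=n) < 0.5).tolist()
        n_gt = int(sum(flags)) + 3
        base = average_precision(conf, flags, n_gt)
        fps = [i for i, f in enumerate(flags) if not f]
        if fps:
            i = fps[0]
            pruned = average_precision(conf[:i] + conf[i + 1:],
                                       flags[:i] + flags[i + 1:], n_gt)
            assert pruned >= base - 1e-12

    @given(seed=st.integers(0, 40))
    def test_adding_top_confidence_tp_never_decreases_ap(self, seed):
        rng = np.random.default_rng(seed)
        n = 10
        conf = rng.uniform(0, 0.9, n).tolist()
        flags = (rng.uniform(size=n) < 0.5).tolist()
        n_gt = int(sum(flags)) + 2
        base = average_precision(conf, flags, n_gt)
        more = average_precision(conf + [0.99], flags + [True], n_gt)
        assert more >= base - 1e-12

    def test_all_and_101_point_interpolations_agree_roughly(self, rng):
        conf = rng.uniform(0, 1, 50).tolist()
        flags = (rng.uniform(size=50) < 0.6).tolist()
        a = average_precision(conf, flags, 35, "all")
        b = average_precision(conf, flags, 35, "101")
        assert abs(a - b) < 0.05


class TestMeanAp:
    def test_published_class_aps_average_to_92_4(self):
        m = mean_ap({"litchi": 0.939, "raw_litchi": 0.908})
        assert round(100 * m + 1e-9, 1) == 92.4

    def test_single_class_map_is_ap(self):
        assert mean_ap([0.77]) == 0.77

    def test_permutation_invariant(self):
        assert mean_ap([0.2, 0.9, 0.5]) == mean_ap([0.9, 0.5, 0.2])


class TestEvaluate:
    def test_ground_truth_against_itself_is_all_ones(self, easy_pairs):
        gts = [rec.boxes for _, rec in easy_pairs]
        dets = [[Detection(b, 0.99) for b in boxes] for boxes in gts]
        rep = evaluate(dets, gts)
        assert rep.precision == rep.recall == rep.f1 == rep.map50 == 1.0
        for m in rep.per_class.values():
            assert m["ap"] == 1.0 or m["n_gt"] == 0

    def test_count_identities_per_class(self, easy_pairs):
        gts = [rec.boxes for _, rec in easy_pairs]
        dets = [[Detection(b, 0.9) for b in boxes[:-1]] for boxes in gts]
        rep = evaluate(dets, gts)
        for c, m in rep.per_class.items():
            assert m["tp"] + m["fn"] == m["n_gt"]
            n_dets = sum(1 for dd in dets for d in dd if d.label == c)
            assert m["tp"] + m["fp"] == n_dets
        assert 0 <= rep.map50 <= 1

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            evaluate([[]], [[], []])


class TestCounting:
    def test_empty_detections_light_stratum(self):
        c = count_fruits([])
        assert c["total"] == 0 and c["stratum"] == "light"

    def test_85_boxes_is_heavy(self):
        dets = [_det(i, 0, 2, 2, 0.9) for i in range(85)]
        assert count_fruits(dets)["stratum"] == "heavy"

    def test_boundary_40_is_moderate(self):
        assert density_stratum(40) == "moderate"
        assert density_stratum(39) == "light"
        assert density_stratum(80) == "moderate"
        assert density_stratum(81) == "heavy"

    def test_stratum_uses_gt_count_when_given(self):
        c = count_fruits([], gt_count=90)
        assert c["stratum"] == "heavy" and c["total"] == 0


class TestYieldRegression:
    def test_exact_prediction(self):
        out = yield_regression([10, 20, 30, 40], [10, 20, 30, 40])
        assert out["r2"] == pytest.approx(1.0)
        assert out["slope"] == pytest.approx(1.0)
        assert out["intercept"] == pytest.approx(0.0, abs=1e-9)

    def test_constant_prediction_r2_zero(self):
        out = yield_regression([25, 25, 25, 25], [10, 20, 30, 40])
        assert out["r2"] == 0.0

    def test_zero_variance_actual_flagged_undefined(self):
        out = yield_regression([1, 2, 3], [5, 5, 5])
        assert not out["defined"]

    def test_five_pairs_match_normal_equations(self):
        actual = np.array([12.0, 33.0, 47.0, 61.0, 88.0])
        predicted = np.array([10.0, 35.0, 44.0, 66.0, 83.0])
        out = yield_regression(predicted, actual)
        # closed form: slope = cov / var, intercept = mean residual
        slope = np.cov(actual, predicted, bias=True)[0, 1] / actual.var()
        intercept = predicted.mean() - slope * actual.mean()
        assert out["slope"] == pytest.approx(slope)
        assert out["intercept"] == pytest.approx(intercept)
        fitted = slope * actual + intercept
        r2 = 1 - ((predicted - fitted) ** 2).sum() / \
            ((predicted - predicted.mean()) ** 2).sum()
        assert out["r2"] == pytest.approx(r2)

    def test_too_few_points_error(self):
        with pytest.raises(ValueError):
            yield_regression([1, 2], [1, 2])
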