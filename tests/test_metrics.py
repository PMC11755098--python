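"""Metric suite checked against brute-force oracles: matching, AP envelope
integration, max-F1 threshold sweep, pooled mIoU and the filtered report."""

import numpy as np
import pytest

from alsseg.geometry import BBox, InstanceMask
from alsseg import metrics as M


def det(x0, y0, x1, y1, score=1.0, image_id=0, cls=0, mask=None):
    return M.Detection(image_id, cls, score, BBox(x0, y0, x1, y1), mask)


class TestIoU:
    def test_identical_boxes(self):
        assert M.iou(BBox(0, 0, 9, 9), BBox(0, 0, 9, 9)) == 1.0

    def test_disjoint_boxes(self):
        assert M.iou(BBox(0, 0, 4, 4), BBox(10, 10, 14, 14)) == 0.0

    def test_half_overlap_pixel_enumeration(self):
        # two 10x10 squares sharing 5 columns: 50 / 150
        a, b = BBox(0, 0, 9, 9), BBox(5, 0, 14, 9)
        grid = np.zeros((20, 20), int)
        grid[0:10, 0:10] += 1
        grid[0:10, 5:15] += 2
        inter = np.sum(grid == 3)
        union = np.sum(grid > 0)
        assert M.iou(a, b) == pytest.approx(inter / union) == pytest.approx(1 / 3)

    def test_mixed_kinds_rejected(self):
        with pytest.raises(TypeError):
            M.iou(BBox(0, 0, 1, 1), InstanceMask(np.ones((4, 4), bool)))

    def test_mask_iou(self):
        a = np.zeros((4, 4), bool)
        b = np.zeros((4, 4), bool)
        a[:2] = True
        b[1:3] = True
        assert M.iou(InstanceMask(a), InstanceMask(b)) == pytest.approx(4 / 12)


class TestMatch:
    def test_perfect_single(self):
        c, labels = M.match([det(0, 0, 9, 9)], [det(0, 0, 9, 9)])
        assert (c.tp, c.fp, c.fn) == (1, 0, 0) and labels == [True]

    def test_single_claim_rule(self):
        dets = [det(0, 0, 9, 9, 0.9), det(0, 0, 9, 9, 0.8)]
        c, labels = M.match(dets, [det(0, 0, 9, 9)])
        assert (c.tp, c.fp, c.fn) == (1, 1, 0)
        assert labels == [True, False]  # higher score claims the GT

    def test_cross_image_never_matches(self):
        c, _ = M.match([det(0, 0, 9, 9, image_id=1)], [det(0, 0, 9, 9, image_id=2)])
        assert (c.tp, c.fp, c.fn) == (0, 1, 1)

    def test_matches_exhaustive_oracle(self, rng):
        """20 random detections / 10 GT equal an independently coded greedy
        assignment under the same (score desc, best IoU) rule."""

        def rand_box(r):
            x0, y0 = r.integers(0, 30, 2)
            return BBox(x0, y0, x0 + r.integers(4, 15), y0 + r.integers(4, 15))

        gts = [M.Detection(0, 0, 1.0, rand_box(rng)) for _ in range(10)]
        dets = [M.Detection(0, 0, float(rng.random()), rand_box(rng)) for _ in range(20)]
        counts, labels = M.match(dets, gts, 0.5)
        # oracle
        taken = set()
        expect = [False] * 20
        for i in sorted(range(20), key=lambda i: (-dets[i].score, i)):
            ious = [
                (M.iou(dets[i].bbox, g.bbox), j)
                for j, g in enumerate(gts)
                if j not in taken
            ]
            ious = [(v, j) for v, j in ious if v >= 0.5]
            if ious:
                v, j = max(ious, key=lambda t: (t[0], -t[1]))
                taken.add(j)
                expect[i] = True
        assert labels == expect
        assert (counts.tp, counts.fp, counts.fn) == (sum(expect), 20 - sum(expect), 10 - len(taken))

    def test_tp_plus_fn_equals_gt_count(self, rng):
        gts = [det(0, 0, 5, 5), det(20, 20, 25, 25)]
        dets = [det(0, 0, 5, 5, 0.9), det(50, 50, 55, 55, 0.8)]
        c, _ = M.match(dets, gts)
        assert c.tp + c.fn == len(gts)


class TestPRF1:
    def test_p_r(self):
        p, r, _ = M.precision_recall_f1(M.MatchCounts(tp=9, fp=1, fn=0))
        assert (p, r) == (0.9, 1.0)

    def test_f1_formula(self):
        _, _, f1 = M.precision_recall_f1(M.MatchCounts(tp=36, fp=4, fn=9))
        # P=0.9, R=0.8 -> F1 = 1.44/1.7
        assert f1 == pytest.approx(1.44 / 1.7)

    def test_zero_over_zero_convention(self):
        assert M.precision_recall_f1(M.MatchCounts(0, 0, 0)) == (0.0, 0.0, 0.0)


class TestAveragePrecision:
    def test_all_tp_full_recall(self):
        curve = M.PRCurve(np.array([1.0, 1.0]), np.array([0.5, 1.0]))
        assert M.average_precision(curve) == pytest.approx(1.0)

    def test_hand_integrated_envelope(self):
        # labels (TP, FP, TP) over 2 GT: 0.5*1 + 0.5*(2/3)
        gts = [det(0, 0, 9, 9), det(100, 100, 109, 109)]
        dets = [
            det(0, 0, 9, 9, 0.9),
            det(50, 50, 59, 59, 0.8),
            det(100, 100, 109, 109, 0.7),
        ]
        curve = M.pr_curve(dets, gts)
        assert M.average_precision(curve) == pytest.approx(0.5 + 0.5 * 2 / 3)

    def test_all_fp_zero(self):
        gts = [det(0, 0, 9, 9)]
        dets = [det(50, 50, 59, 59, 0.9)]
        assert M.average_precision(M.pr_curve(dets, gts)) == 0.0

    def test_matches_bruteforce_envelope_on_random_sets(self, rng):
        """200 randomized detections: AP equals a literal envelope
        integration coded independently, to 1e-9."""
        for _ in range(5):
            n_gt = int(rng.integers(5, 30))
            labels = rng.random(200) < 0.35
            scores = rng.random(200)
            order = np.argsort(-scores)
            tp = labels[order].astype(float)
            cum_tp, cum_fp = np.cumsum(tp), np.cumsum(1 - tp)
            prec = cum_tp / (cum_tp + cum_fp)
            rec = np.minimum(cum_tp, n_gt) / n_gt
            curve = M.PRCurve(prec, rec)
            # oracle: walk recall increments, take max precision to the right
            ap = 0.0
            prev_r = 0.0
            for i in range(200):
                dr = rec[i] - prev_r
                if dr > 0:
                    ap += dr * prec[i:].max()
                    prev_r = rec[i]
            assert M.average_precision(curve) == pytest.approx(ap, abs=1e-9)


class TestMeanAP:
    def test_single_class(self):
        assert M.mean_ap([0.7]) == 0.7

    def test_two_classes(self):
        assert M.mean_ap([1.0, 0.5]) == 0.75

    def test_range_average_equals_independent_aps(self):
        gts = [det(0, 0, 9, 9), det(30, 30, 39, 39)]
        dets = [det(0, 0, 8, 9, 0.9), det(30, 30, 39, 39, 0.8)]
        thresholds = [0.5, 0.75]
        combined = M.ap_over_range(dets, gts, thresholds)
        individual = [
            M.average_precision(M.pr_curve(dets, gts, t)) for t in thresholds
        ]
        assert combined == pytest.approx(np.mean(individual))


class TestMIoU:
    def test_perfect(self):
        m = np.zeros((10, 10), bool)
        m[2:5, 2:5] = True
        assert M.miou({0: m}, {0: m.copy()}) == 1.0

    def test_empty_prediction_zero(self):
        g = np.zeros((10, 10), bool)
        g[0, 0] = True
        assert M.miou({0: np.zeros((10, 10), bool)}, {0: g}) == 0.0

    def test_two_class_toy(self):
        # class 0: IoU 1/3; class 1: IoU 1.0 -> mean 2/3
        p0 = np.zeros((10, 15), bool); p0[0:10, 0:10] = True
        g0 = np.zeros((10, 15), bool); g0[0:10, 5:15] = True
        p1 = np.zeros((10, 15), bool); p1[3:5, 3:5] = True
        assert M.miou({0: p0, 1: p1}, {0: g0, 1: p1.copy()}) == pytest.approx(
            (1 / 3 + 1.0) / 2
        )

    def test_absent_class_excluded(self):
        m = np.ones((4, 4), bool)
        empty = np.zeros((4, 4), bool)
        assert M.miou({0: m, 1: empty}, {0: m.copy(), 1: empty.copy()}) == 1.0


class TestMaxF1Threshold:
    def test_single_perfect_detection(self):
        gts = [det(0, 0, 9, 9)]
        t, f1 = M.max_f1_threshold([det(0, 0, 9, 9, 0.7)], gts)
        assert (t, f1) == (0.7, 1.0)

    def test_low_score_fp_excluded_by_threshold(self):
        gts = [det(0, 0, 9, 9)]
        dets = [det(0, 0, 9, 9, 0.7), det(50, 50, 59, 59, 0.1)]
        t, f1 = M.max_f1_threshold(dets, gts)
        assert f1 == 1.0 and t == 0.7

    def test_matches_exhaustive_sweep(self, rng):
        def rand_box(r):
            x0, y0 = r.integers(0, 40, 2)
            return BBox(x0, y0, x0 + r.integers(4, 12), y0 + r.integers(4, 12))

        gts = [M.Detection(0, 0, 1.0, rand_box(rng)) for _ in range(12)]
        dets = [M.Detection(0, 0, float(rng.random()), rand_box(rng)) for _ in range(30)]
        t, f1 = M.max_f1_threshold(dets, gts, 0.4)
        best = (-1.0, None)
        for cand in sorted({d.score for d in dets}):
            kept = [d for d in dets if d.score >= cand]
            c, _ = M.match(kept, gts, 0.4)
            _, _, v = M.precision_recall_f1(c)
            if v > best[0]:
                best = (v, cand)
        assert (t, f1) == (best[1], best[0])

    def test_no_detections_rejected(self):
        with pytest.raises(ValueError):
            M.max_f1_threshold([], [det(0, 0, 1, 1)])


class TestFilteredMIoU:
    def test_worked_example(self):
        mean, excl = M.filtered_miou_report([0.9, 0.8, 0.5], 0.75)
        assert mean == pytest.approx(0.85) and excl == 1

    def test_floor_zero_plain_mean(self):
        mean, excl = M.filtered_miou_report([0.9, 0.8, 0.5], 0.0)
        assert mean == pytest.approx(np.mean([0.9, 0.8, 0.5])) and excl == 0

    def test_all_excluded(self):
        mean, excl = M.filtered_miou_report([0.1, 0.2], 0.75)
        assert mean is None and excl == 2

    def test_matches_filter_then_mean_oracle(self, rng):
        vals = rng.random(100).tolist()
        mean, excl = M.filtered_miou_report(vals, 0.75)
        kept = [v for v in vals if v > 0.75]
        assert excl == 100 - len(kept)
        assert mean == pytest.approx(np.mean(kept))


class TestInvariantsAndReport:
    def test_perfect_predictions_all_ones(self):
        m = np.zeros((16, 16), bool)
        m[2:8, 2:8] = True
        gts = [det(2, 2, 7, 7, mask=InstanceMask(m))]
        dets = [det(2, 2, 7, 7, 0.9, mask=InstanceMask(m.copy()))]
        for kind in ("box", "mask"):
            rep = M.evaluate(dets, gts, kind=kind)
            assert rep.precision == rep.recall == rep.f1 == rep.ap == 1.0
            if kind == "mask":
                assert rep.miou == 1.0

    def test_removing_tp_never_increases_recall(self):
        gts = [det(0, 0, 9, 9), det(30, 30, 39, 39)]
        dets = [det(0, 0, 9, 9, 0.9), det(30, 30, 39, 39, 0.8)]
        c_full, _ = M.match(dets, gts)
        c_less, _ = M.match(dets[:1], gts)
        r_full = M.precision_recall_f1(c_full)[1]
        r_less = M.precision_recall_f1(c_less)[1]
        assert r_less <= r_full

    def test_adding_fp_never_increases_precision(self):
        gts = [det(0, 0, 9, 9)]
        dets = [det(0, 0, 9, 9, 0.9)]
        p0 = M.precision_recall_f1(M.match(dets, gts)[0])[0]
        dets_fp = dets + [det(50, 50, 59, 59, 0.95)]
        p1 = M.precision_recall_f1(M.match(dets_fp, gts)[0])[0]
        assert p1 <= p0
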