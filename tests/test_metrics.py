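"""Evaluation metrics against exhaustive reference implementations."""

import numpy as np
import pytest

from snoutnet.metrics import (average_precision, confusion_matrix, summarize,
                              t_confidence_interval)
from snoutnet.model import Detection
from snoutnet.types import NUM_CLASSES, BBox


def D(cid, conf, x1, y1, x2, y2):
    return Detection(BBox.from_xyxy(x1, y1, x2, y2), cid, conf)


def G(cid, x1, y1, x2, y2):
    return (cid, BBox.from_xyxy(x1, y1, x2, y2))


def _iou(a: BBox, b: BBox) -> float:
    ax1, ay1, ax2, ay2 = a.to_xyxy()
    bx1, by1, bx2, by2 = b.to_xyxy()
    ix = max(0.0, min(ax2, bx2) - max(ax1, bx1))
    iy = max(0.0, min(ay2, by2) - max(ay1, by1))
    inter = ix * iy
    union = (ax2 - ax1) * (ay2 - ay1) + (bx2 - bx1) * (by2 - by1) - inter
    return inter / union if union else 0.0


def reference_ap(detections, ground_truths, cid, iou_threshold):
    """Quadratic-time reference: greedy matching + all-point PR sweep,
    written independently of the library implementation."""
    dets = sorted(((i, d) for i, dd in enumerate(detections)
                   for d in dd if d.class_id == cid),
                  key=lambda t: -t[1].confidence)
    gts = {i: [b for c, b in gg if c == cid]
           for i, gg in enumerate(ground_truths)}
    n_gt = sum(len(v) for v in gts.values())
    if n_gt == 0:
        return 0.0
    taken = {i: set() for i in gts}
    flags = []
    for img, det in dets:
        best_j, best_iou = None, iou_threshold
        for j, g in enumerate(gts.get(img, [])):
            if j in taken[img]:
                continue
            iou = _iou(det.box, g)
            if iou >= best_iou:
                best_j, best_iou = j, iou
        if best_j is not None:
            taken[img].add(best_j)
            flags.append(True)
        else:
            flags.append(False)
    ap = 0.0
    tp = fp = 0
    prec, rec = [], []
    for f in flags:
        tp += f
        fp += not f
        prec.append(tp / (tp + fp))
        rec.append(tp / n_gt)
    for r in np.linspace(0, 1, 101):
        vals = [p for p, rr in zip(prec, rec) if rr >= r]
        ap += max(vals) if vals else 0.0
    return ap / 101.0


def random_fixture(rng, n_images=3, max_boxes=4):
    dets, gts = [], []
    for _ in range(n_images):
        dd, gg = [], []
        for _ in range(rng.integers(0, max_boxes + 1)):
            x, y = rng.uniform(0, 0.5, 2)
            w, h = rng.uniform(0.1, 0.4, 2)
            gg.append(G(int(rng.integers(0, 4)), x, y,
                        min(x + w, 1), min(y + h, 1)))
        for _ in range(rng.integers(0, max_boxes + 1)):
            x, y = rng.uniform(0, 0.5, 2)
            w, h = rng.uniform(0.1, 0.4, 2)
            dd.append(D(int(rng.integers(0, 4)), float(rng.uniform(0.05, 1)),
                        x, y, min(x + w, 1), min(y + h, 1)))
        dets.append(dd)
        gts.append(gg)
    return dets, gts


class TestAveragePrecision:
    def test_exact_match_gives_ap_one(self):
        gts = [[G(0, 0.1, 0.1, 0.5, 0.5)]]
        dets = [[D(0, 0.9, 0.1, 0.1, 0.5, 0.5)]]
        assert average_precision(dets, gts, 0.5)[0] == pytest.approx(1.0)

    def test_no_detections_gives_zero(self):
        gts = [[G(1, 0.1, 0.1, 0.5, 0.5)]]
        assert average_precision([[]], gts, 0.5)[1] == 0.0

    def test_three_detection_fixture_matches_hand_enumeration(self):
        # two GTs; detections ranked TP, FP, TP -> precision 1, 1/2, 2/3
        # at recalls 1/2, 1/2, 1: AP = (51*1 + 50*(2/3)) / 101
        gts = [[G(0, 0.05, 0.05, 0.35, 0.35), G(0, 0.6, 0.6, 0.9, 0.9)]]
        dets = [[D(0, 0.9, 0.05, 0.05, 0.35, 0.35),
                 D(0, 0.8, 0.4, 0.05, 0.55, 0.2),
                 D(0, 0.7, 0.6, 0.6, 0.9, 0.9)]]
        expect = (51 * 1.0 + 50 * (2 / 3)) / 101
        assert average_precision(dets, gts, 0.5)[0] == pytest.approx(expect)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_reference_on_random_fixtures(self, seed):
        rng = np.random.default_rng(seed)
        dets, gts = random_fixture(rng)
        for thr in (0.3, 0.5, 0.75):
            ap = average_precision(dets, gts, thr)
            for cid in range(NUM_CLASSES):
                assert ap[cid] == pytest.approx(
                    reference_ap(dets, gts, cid, thr), abs=1e-9)

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            average_precision([[]], [[]], 1.5)


class TestConfusion:
    def test_all_correct_diagonal(self):
        gts = [[G(c, 0.1, 0.1, 0.4, 0.4) for c in range(2)]]
        # separate the two boxes spatially
        gts = [[G(0, 0.05, 0.05, 0.3, 0.3), G(1, 0.6, 0.6, 0.9, 0.9)]]
        dets = [[D(0, 0.9, 0.05, 0.05, 0.3, 0.3), D(1, 0.8, 0.6, 0.6, 0.9, 0.9)]]
        cm = confusion_matrix(dets, gts, 0.5)
        assert cm[0, 0] == 1 and cm[1, 1] == 1
        off = cm.copy()
        np.fill_diagonal(off, 0)
        assert off.sum() == 0

    def test_cross_class_error_lands_in_cold_fever_cell(self):
        gts = [[G(1, 0.1, 0.1, 0.5, 0.5)]]           # Cold ground truth
        dets = [[D(3, 0.9, 0.1, 0.1, 0.5, 0.5)]]      # Fever prediction
        cm = confusion_matrix(dets, gts, 0.5)
        assert cm[1, 3] == 1

    def test_unmatched_rows_and_columns(self):
        gts = [[G(2, 0.1, 0.1, 0.4, 0.4)]]
        dets = [[D(0, 0.9, 0.6, 0.6, 0.9, 0.9)]]
        cm = confusion_matrix(dets, gts, 0.5)
        assert cm[2, NUM_CLASSES] == 1    # missed GT -> background column
        assert cm[NUM_CLASSES, 0] == 1    # spurious det -> background row

    @pytest.mark.parametrize("seed", range(5))
    def test_gt_marginals_conserved(self, seed):
        rng = np.random.default_rng(100 + seed)
        dets, gts = random_fixture(rng, n_images=4)
        cm = confusion_matrix(dets, gts, 0.5)
        for c in range(NUM_CLASSES):
            n_gt = sum(1 for gg in gts for cc, _ in gg if cc == c)
            assert cm[c].sum() == n_gt
        n_det = sum(len(dd) for dd in dets)
        assert cm[:, :NUM_CLASSES].sum() == n_det


class TestSummarize:
    def test_perfect_detector_scores_one_everywhere(self):
        rng = np.random.default_rng(7)
        gts = []
        dets = []
        for _ in range(4):
            gg = []
            for c in range(NUM_CLASSES):
                x = 0.05 + 0.24 * c
                gg.append(G(c, x, 0.1, x + 0.15, 0.4))
            gts.append(gg)
            dets.append([D(c, 0.95, *g[1].to_xyxy()) for c, g in
                         zip(range(NUM_CLASSES), gg)])
        rep = summarize(dets, gts)
        assert rep.map50 == pytest.approx(1.0)
        assert rep.map50_95 == pytest.approx(1.0)
        assert rep.precision == pytest.approx(1.0)
        assert rep.recall == pytest.approx(1.0)
        off = rep.confusion.copy()
        np.fill_diagonal(off, 0)
        assert off.sum() == 0

    @pytest.mark.parametrize("seed", range(4))
    def test_map5095_never_exceeds_map50(self, seed):
        rng = np.random.default_rng(200 + seed)
        dets, gts = random_fixture(rng, n_images=4)
        if all(len(g) == 0 for g in gts):
            pytest.skip("degenerate draw without ground truths")
        rep = summarize(dets, gts)
        assert rep.map50_95 <= rep.map50 + 1e-9

    def test_metric_ranges_and_determinism(self):
        rng = np.random.default_rng(300)
        dets, gts = random_fixture(rng, n_images=5)
        r1 = summarize(dets, gts)
        r2 = summarize(dets, gts)
        assert np.array_equal(r1.per_class_ap50, r2.per_class_ap50)
        assert np.array_equal(r1.confusion, r2.confusion)
        for v in [r1.map50, r1.map50_95, r1.precision, r1.recall,
                  *r1.per_class_ap50]:
            assert 0.0 <= v <= 1.0

    def test_empty_image_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            summarize([], [])


class TestTConfidenceInterval:
    def test_identical_values_zero_width(self):
        mean, half = t_confidence_interval([3.3, 3.3, 3.3])
        assert mean == pytest.approx(3.3)
        assert half == pytest.approx(0.0)

    def test_three_seed_example(self):
        # sd = 0.2, t_{0.975, df=2} = 4.303 -> half width 4.303*0.2/sqrt(3)
        mean, half = t_confidence_interval([95.5, 95.7, 95.9], 0.95)
        assert mean == pytest.approx(95.7)
        assert half == pytest.approx(0.497, abs=0.001)

    def test_half_width_monotone_in_level(self):
        vals = [1.0, 1.5, 2.2, 1.8]
        widths = [t_confidence_interval(vals, lv)[1]
                  for lv in (0.5, 0.8, 0.9, 0.95, 0.99)]
        assert all(a < b for a, b in zip(widths, widths[1:]))

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            t_confidence_interval([1.0])
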