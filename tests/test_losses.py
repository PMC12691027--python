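"""CIoU / DFL / smoothed-BCE losses and the center-prior assigner."""

import math

import numpy as np
import pytest

from snoutnet.losses import (assign_targets, ciou, cls_loss,
                             detection_loss, dfl)
from snoutnet.autodiff import Tensor


def iou_elementwise(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Plain IoU of paired xyxy boxes (row i of a vs row i of b)."""
    ix = np.clip(np.minimum(a[:, 2], b[:, 2]) - np.maximum(a[:, 0], b[:, 0]),
                 0, None)
    iy = np.clip(np.minimum(a[:, 3], b[:, 3]) - np.maximum(a[:, 1], b[:, 1]),
                 0, None)
    inter = ix * iy
    union = ((a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
             + (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1]) - inter)
    return inter / union


class TestCiou:
    def test_identical_boxes_score_one(self):
        b = np.array([1.0, 2.0, 5.0, 7.0])
        assert ciou(b, b) == pytest.approx(1.0)

    def test_hand_computed_offset_squares(self):
        # IoU 1/7, center distance^2 = 2, enclosing diagonal^2 = 18,
        # equal aspect ratios so the v-term vanishes
        a = np.array([0.0, 0.0, 2.0, 2.0])
        b = np.array([1.0, 1.0, 3.0, 3.0])
        assert ciou(a, b) == pytest.approx(1 / 7 - 1 / 9, abs=1e-9)

    def test_far_separated_boxes_negative(self):
        a = np.array([0.0, 0.0, 1.0, 1.0])
        b = np.array([50.0, 50.0, 51.0, 51.0])
        assert ciou(a, b) < 0

    def test_zero_area_box_rejected(self):
        with pytest.raises(ValueError, match="zero-area"):
            ciou(np.array([0, 0, 0, 1.0]), np.array([0, 0, 1.0, 1.0]))

    def test_ciou_never_exceeds_iou_on_random_pairs(self):
        rng = np.random.default_rng(10)
        xy = rng.uniform(0, 50, size=(10_000, 2, 2))
        wh = rng.uniform(0.1, 30, size=(10_000, 2, 2))
        a = np.concatenate([xy[:, 0], xy[:, 0] + wh[:, 0]], axis=1)
        b = np.concatenate([xy[:, 1], xy[:, 1] + wh[:, 1]], axis=1)
        c = ciou(a, b)
        iou = iou_elementwise(a, b)
        assert (c <= iou + 1e-9).all()

    def test_equality_with_iou_iff_centers_and_aspects_match(self):
        a = np.array([0.0, 0.0, 4.0, 2.0])
        b = np.array([-1.0, -0.5, 5.0, 2.5])  # same center, same 2:1 aspect
        assert ciou(a, b) == pytest.approx(
            float(iou_elementwise(a[None], b[None])[0]), abs=1e-9)


class TestDfl:
    def test_delta_on_integer_target_is_zero(self):
        p = np.zeros(16)
        p[3] = 1.0
        assert dfl(p, 3.0) == pytest.approx(0.0)

    def test_uniform_prediction_gives_log_bins(self):
        p = np.full(16, 1 / 16)
        assert dfl(p, 3.4) == pytest.approx(math.log(16), rel=1e-9)

    def test_out_of_range_target_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            dfl(np.full(16, 1 / 16), 15.5)

    def test_grid_search_confirms_interpolated_minimizer(self):
        # over all two-bin distributions on (3,4), the loss for target 3.4
        # is minimized at mass (0.6, 0.4)
        target = 3.4
        best_m, best_loss = None, np.inf
        for m in np.linspace(0.01, 0.99, 99):
            p = np.zeros(16)
            p[3], p[4] = m, 1 - m
            loss = dfl(p, target)
            if loss < best_loss:
                best_m, best_loss = m, loss
        assert best_m == pytest.approx(0.6, abs=0.011)
        # and the minimizing distribution has mean equal to the target
        assert 3 * best_m + 4 * (1 - best_m) == pytest.approx(target, abs=0.05)


class TestClsLoss:
    def test_perfect_confident_prediction_no_smoothing(self):
        assert cls_loss(np.array([1 - 1e-9]), np.array([1.0]), 0.0) \
            == pytest.approx(0.0, abs=1e-6)

    def test_smoothed_positive_example_value(self):
        val = cls_loss(np.array([0.95]), np.array([1.0]), 0.05)
        expect = -(0.95 * math.log(0.95) + 0.05 * math.log(0.05))
        assert val == pytest.approx(expect, rel=1e-6)

    def test_minimum_at_one_minus_epsilon(self):
        eps = 0.05
        ps = np.linspace(0.01, 0.999, 500)
        losses = [cls_loss(np.array([p]), np.array([1.0]), eps) for p in ps]
        assert ps[int(np.argmin(losses))] == pytest.approx(1 - eps, abs=0.005)

    def test_invalid_smoothing_rejected(self):
        with pytest.raises(ValueError):
            cls_loss(np.array([0.5]), np.array([1.0]), 0.6)


SHAPES = {3: (8, 8), 4: (4, 4), 5: (2, 2)}
STRIDES = {3: 8, 4: 16, 5: 32}


class TestAssigner:
    def test_no_ground_truths_all_background(self):
        a = assign_targets(SHAPES, STRIDES, np.zeros((0, 4)), np.zeros(0),
                           reg_max=16)
        assert a.num_matched == 0
        assert (a.gt_index == -1).all()

    def test_single_centered_gt_claims_nearby_p3_cells(self):
        box = np.array([[24.0, 24.0, 40.0, 40.0]])  # 16px box on P3
        a = assign_targets(SHAPES, STRIDES, box, np.array([2]), reg_max=16)
        assert a.num_matched > 0
        matched_levels = a.level_of[a.matched]
        assert set(matched_levels) == {3}
        # every matched center lies inside the box
        cc = a.centers[a.matched]
        assert ((cc > box[0, :2]) & (cc < box[0, 2:])).all()

    def test_nested_shared_center_resolves_to_smaller(self):
        big = [8.0, 8.0, 56.0, 56.0]
        small = [24.0, 24.0, 40.0, 40.0]
        a = assign_targets(SHAPES, STRIDES, np.array([big, small]),
                           np.array([0, 1]), reg_max=16)
        # locations claimed by both boxes go to the smaller one (index 1)
        inside_small = ((a.centers > np.array(small[:2]))
                        & (a.centers < np.array(small[2:]))).all(axis=1)
        both = inside_small & a.matched
        assert both.any()
        assert (a.gt_index[both & (a.level_of == 3)] == 1).all()

    def test_matches_brute_force_enumeration_on_small_grid(self):
        """Independent oracle: re-derive the assignment rule exhaustively."""
        shapes, strides = {3: (4, 4)}, {3: 8}
        rng = np.random.default_rng(11)
        for _ in range(20):
            n = rng.integers(1, 4)
            x1 = rng.uniform(0, 20, n)
            y1 = rng.uniform(0, 20, n)
            boxes = np.stack([x1, y1, x1 + rng.uniform(4, 12, n),
                              y1 + rng.uniform(4, 12, n)], axis=1)
            classes = rng.integers(0, 4, n)
            a = assign_targets(shapes, strides, boxes, classes,
                               reg_max=16, topk=3)
            # oracle: per gt, centers inside box sorted by center distance,
            # keep 3; conflicts -> smaller area then lower index
            centers = a.centers
            areas = (boxes[:, 2] - boxes[:, 0]) * (boxes[:, 3] - boxes[:, 1])
            claims = {}
            for m, b in enumerate(boxes):
                inside = [i for i in range(len(centers))
                          if b[0] < centers[i, 0] < b[2]
                          and b[1] < centers[i, 1] < b[3]]
                gc = ((b[0] + b[2]) / 2, (b[1] + b[3]) / 2)
                inside.sort(key=lambda i: math.hypot(centers[i, 0] - gc[0],
                                                     centers[i, 1] - gc[1]))
                for i in inside[:3]:
                    cur = claims.get(i)
                    if cur is None or areas[m] < areas[cur] - 1e-9 or (
                            abs(areas[m] - areas[cur]) <= 1e-9 and m < cur):
                        claims[i] = m
            expect = np.full(len(centers), -1)
            for i, m in claims.items():
                expect[i] = m
            assert np.array_equal(a.gt_index, expect)

    def test_bin_targets_within_dfl_range(self):
        box = np.array([[0.0, 0.0, 64.0, 64.0]])
        a = assign_targets(SHAPES, STRIDES, box, np.array([0]), reg_max=16)
        assert (a.ltrb_targets >= 0).all()
        assert (a.ltrb_targets <= 15).all()


class TestDetectionLoss:
    def _outputs(self, rng, n=2, nc=4, reg_max=8):
        out = {}
        for l, (h, w) in SHAPES.items():
            out[l] = (Tensor(rng.normal(size=(n, 4 * reg_max, h, w)).astype(np.float32)),
                      Tensor(rng.normal(size=(n, nc, h, w)).astype(np.float32)))
        return out

    def test_components_nonnegative_and_weighted_total(self):
        rng = np.random.default_rng(12)
        outputs = self._outputs(rng)
        gts = [(np.array([[10.0, 10.0, 40.0, 40.0]]), np.array([1])),
               (np.zeros((0, 4)), np.zeros(0, dtype=int))]
        total, bd = detection_loss(outputs, gts, reg_max=8, strides=STRIDES)
        assert bd.box >= 0 and bd.cls >= 0 and bd.dfl >= 0
        assert bd.total == pytest.approx(
            7.5 * bd.box + 0.5 * bd.cls + 1.5 * bd.dfl, rel=1e-5)

    def test_gradients_flow_to_both_branches(self):
        rng = np.random.default_rng(13)
        outputs = self._outputs(rng)
        for reg, cls in outputs.values():
            reg.requires_grad = True
            cls.requires_grad = True
        # a 30px box is assigned on P3 only: regression gradients flow
        # there, while classification (background BCE) reaches all levels
        gts = [(np.array([[10.0, 10.0, 40.0, 40.0]]), np.array([1]))] * 2
        total, _ = detection_loss(outputs, gts, reg_max=8, strides=STRIDES)
        total.backward()
        assert np.abs(outputs[3][0].grad).max() > 0
        for l, (reg, cls) in outputs.items():
            assert reg.grad is not None
            assert cls.grad is not None and np.abs(cls.grad).max() > 0
        # unmatched levels carry no regression signal for this geometry
        assert np.abs(outputs[5][0].grad).max() == 0
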