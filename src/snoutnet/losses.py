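"""Detection losses and target assignment.

The composite training objective is

    L = w_box * L_box + w_cls * L_cls + w_dfl * L_dfl

* **L_box** — 1 - CIoU over matched prediction/ground-truth pairs.  CIoU
  augments IoU with a normalized center-distance penalty and an
  aspect-ratio consistency term, so CIoU <= IoU always, with equality
  exactly when centers and aspect ratios coincide.
* **L_dfl** — distribution focal loss: each box-edge distance is predicted
  as a categorical distribution over ``reg_max`` bins and supervised by
  cross-entropy against the two integer bins bracketing the continuous
  target, weighted by linear interpolation.
* **L_cls** — per-class binary cross-entropy with label smoothing
  (targets 1 -> 1-eps, 0 -> eps), normalized by the number of assigned
  locations.

Assignment is an anchor-free center-prior rule: a location is a candidate
for a ground-truth box when its cell center lies inside the box and the
box's maximum edge distance falls in the location's level scale range;
the top-k candidates closest to the box center are matched, and a
location claimed by several boxes goes to the smallest-area one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

DEFAULT_LOSS_WEIGHTS = {"box": 7.5, "cls": 0.5, "dfl": 1.5}
DEFAULT_LABEL_SMOOTHING = 0.05


# ---------------------------------------------------------------------------
# reference (numpy) loss primitives
# ---------------------------------------------------------------------------

def ciou(box_a: np.ndarray, box_b: np.ndarray) -> np.ndarray:
    """Complete IoU of xyxy boxes; broadcasts over leading dimensions.

    CIoU = IoU - rho^2 / c^2 - alpha * v, where rho is the center
    distance, c the enclosing-box diagonal, and v the squared difference
    of arctan aspect ratios scaled by 4/pi^2.
    """
    a = np.asarray(box_a, dtype=np.float64)
    b = np.asarray(box_b, dtype=np.float64)
    aw, ah = a[..., 2] - a[..., 0], a[..., 3] - a[..., 1]
    bw, bh = b[..., 2] - b[..., 0], b[..., 3] - b[..., 1]
    if np.any(aw <= 0) or np.any(ah <= 0) or np.any(bw <= 0) or np.any(bh <= 0):
        raise ValueError("zero-area box passed to ciou")
    ix = np.clip(np.minimum(a[..., 2], b[..., 2]) - np.maximum(a[..., 0], b[..., 0]), 0, None)
    iy = np.clip(np.minimum(a[..., 3], b[..., 3]) - np.maximum(a[..., 1], b[..., 1]), 0, None)
    inter = ix * iy
    union = aw * ah + bw * bh - inter
    iou = inter / union
    rho2 = ((a[..., 0] + a[..., 2] - b[..., 0] - b[..., 2]) ** 2
            + (a[..., 1] + a[..., 3] - b[..., 1] - b[..., 3]) ** 2) / 4.0
    cw = np.maximum(a[..., 2], b[..., 2]) - np.minimum(a[..., 0], b[..., 0])
    ch = np.maximum(a[..., 3], b[..., 3]) - np.minimum(a[..., 1], b[..., 1])
    c2 = cw ** 2 + ch ** 2
    v = (4.0 / math.pi ** 2) * (np.arctan(aw / ah) - np.arctan(bw / bh)) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(v > 0, v / (1.0 - iou + v + 1e-12), 0.0)
    return iou - rho2 / c2 - alpha * v


def dfl(pred_bins: np.ndarray, target: float) -> float:
    """Distribution focal loss of one bin distribution against a target.

    Cross-entropy against the two integer bins bracketing ``target``,
    weighted by linear interpolation; zero for a point mass on an
    integer target.
    """
    p = np.asarray(pred_bins, dtype=np.float64)
    reg_max = p.size
    if not 0.0 <= target <= reg_max - 1:
        raise ValueError(f"target {target} outside [0, {reg_max - 1}]")
    if not np.isclose(p.sum(), 1.0, atol=1e-5):
        raise ValueError("pred_bins must sum to 1")
    lo = int(np.floor(target))
    hi = min(lo + 1, reg_max - 1)
    w_hi = target - lo
    w_lo = 1.0 - w_hi
    loss = 0.0
    if w_lo > 0:
        loss -= w_lo * np.log(max(p[lo], 1e-12))
    if w_hi > 0:
        loss -= w_hi * np.log(max(p[hi], 1e-12))
    return float(loss)


def cls_loss(pred_scores: np.ndarray, targets: np.ndarray,
             smoothing: float = DEFAULT_LABEL_SMOOTHING) -> float:
    """Smoothed binary cross-entropy, averaged over entries.

    Hard targets are mapped 1 -> 1-eps and 0 -> eps before the BCE.
    """
    if not 0.0 <= smoothing < 0.5:
        raise ValueError("smoothing must lie in [0, 0.5)")
    p = np.clip(np.asarray(pred_scores, dtype=np.float64), 1e-12, 1 - 1e-12)
    y = np.asarray(targets, dtype=np.float64)
    y = y * (1.0 - smoothing) + (1.0 - y) * smoothing
    return float(np.mean(-(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))))


# ---------------------------------------------------------------------------
# target assignment
# ---------------------------------------------------------------------------

@dataclass
class Assignment:
    """Per-location matching for one image, flattened across levels."""

    centers: np.ndarray        # (L, 2) pixel cell centers
    strides: np.ndarray        # (L,)
    level_of: np.ndarray       # (L,) pyramid level per location
    gt_index: np.ndarray       # (L,) matched ground-truth index, -1 = background
    ltrb_targets: np.ndarray   # (L, 4) edge distances in stride units (matched rows)
    gt_boxes: np.ndarray       # (M, 4) xyxy pixels
    gt_classes: np.ndarray     # (M,)

    @property
    def matched(self) -> np.ndarray:
        return self.gt_index >= 0

    @property
    def num_matched(self) -> int:
        return int(self.matched.sum())


def _flat_grid(shapes: Dict[int, Tuple[int, int]], strides: Dict[int, int]):
    centers, stride_flat, level_flat, offsets = [], [], [], {}
    total = 0
    for l in sorted(shapes):
        h, w = shapes[l]
        s = strides[l]
        cy, cx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        centers.append(np.stack([(cx.ravel() + 0.5) * s,
                                 (cy.ravel() + 0.5) * s], axis=1))
        stride_flat.append(np.full(h * w, s, dtype=np.float64))
        level_flat.append(np.full(h * w, l, dtype=np.int64))
        offsets[l] = (total, total + h * w)
        total += h * w
    return (np.concatenate(centers), np.concatenate(stride_flat),
            np.concatenate(level_flat), offsets)


def _scale_bounds(levels: Sequence[int], strides: Dict[int, int]
                  ) -> Dict[int, Tuple[float, float]]:
    """Per-level admissible range of a box's maximum edge distance (pixels).

    Level l covers (previous upper, 8 * stride_l], open-ended at the
    coarsest level, starting from 0 at the finest.
    """
    bounds = {}
    lower = 0.0
    ordered = sorted(levels)
    for i, l in enumerate(ordered):
        upper = math.inf if i == len(ordered) - 1 else 8.0 * strides[l]
        bounds[l] = (lower, upper)
        lower = upper
    return bounds


def assign_targets(shapes: Dict[int, Tuple[int, int]], strides: Dict[int, int],
                   gt_boxes: np.ndarray, gt_classes: np.ndarray,
                   reg_max: int, topk: int = 10) -> Assignment:
    """Center-prior top-k assignment of grid locations to ground truths."""
    centers, stride_flat, level_flat, _ = _flat_grid(shapes, strides)
    L = len(centers)
    gt_boxes = np.asarray(gt_boxes, dtype=np.float64).reshape(-1, 4)
    gt_classes = np.asarray(gt_classes, dtype=np.int64).reshape(-1)
    gt_index = np.full(L, -1, dtype=np.int64)
    ltrb_targets = np.zeros((L, 4), dtype=np.float64)
    if len(gt_boxes) == 0:
        return Assignment(centers, stride_flat, level_flat, gt_index,
                          ltrb_targets, gt_boxes, gt_classes)
    bounds = _scale_bounds(sorted(set(level_flat.tolist())), strides)
    lowers = np.array([bounds[l][0] for l in level_flat])
    uppers = np.array([bounds[l][1] for l in level_flat])
    areas = (gt_boxes[:, 2] - gt_boxes[:, 0]) * (gt_boxes[:, 3] - gt_boxes[:, 1])

    claimed_area = np.full(L, np.inf)
    claimed_gt = np.full(L, -1, dtype=np.int64)
    for m, box in enumerate(gt_boxes):
        ltrb = np.stack([centers[:, 0] - box[0], centers[:, 1] - box[1],
                         box[2] - centers[:, 0], box[3] - centers[:, 1]], axis=1)
        inside = ltrb.min(axis=1) > 0
        maxd = ltrb.max(axis=1)
        in_range = (maxd > lowers) & (maxd <= uppers)
        cand = np.flatnonzero(inside & in_range)
        if cand.size == 0:
            continue
        gcx, gcy = (box[0] + box[2]) / 2, (box[1] + box[3]) / 2
        dist = np.hypot(centers[cand, 0] - gcx, centers[cand, 1] - gcy)
        take = cand[np.argsort(dist, kind="stable")[:topk]]
        for i in take:
            # conflicts resolve to the smaller-area ground truth
            if areas[m] < claimed_area[i] - 1e-9 or (
                    abs(areas[m] - claimed_area[i]) <= 1e-9 and m < claimed_gt[i]):
                claimed_area[i] = areas[m]
                claimed_gt[i] = m
    matched = claimed_gt >= 0
    gt_index[matched] = claimed_gt[matched]
    if matched.any():
        mb = gt_boxes[gt_index[matched]]
        cc = centers[matched]
        ss = stride_flat[matched][:, None]
        ltrb = np.stack([cc[:, 0] - mb[:, 0], cc[:, 1] - mb[:, 1],
                         mb[:, 2] - cc[:, 0], mb[:, 3] - cc[:, 1]], axis=1) / ss
        ltrb_targets[matched] = np.clip(ltrb, 0.0, reg_max - 1 - 1e-3)
    return Assignment(centers, stride_flat, level_flat, gt_index,
                      ltrb_targets, gt_boxes, gt_classes)


# ---------------------------------------------------------------------------
# differentiable batch loss
# ---------------------------------------------------------------------------

@dataclass
class LossBreakdown:
    box: float
    cls: float
    dfl: float
    total: float
    weights: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_LOSS_WEIGHTS))


def detection_loss(outputs: Dict[int, Tuple[Tensor, Tensor]],
                   gt_per_image: List[Tuple[np.ndarray, np.ndarray]],
                   reg_max: int, strides: Dict[int, int],
                   weights: Dict[str, float] = None,
                   smoothing: float = DEFAULT_LABEL_SMOOTHING,
                   topk: int = 10) -> Tuple[Tensor, LossBreakdown]:
    """Composite loss over a batch.

    ``outputs`` maps level -> (reg logits (N,4R,H,W), cls logits (N,nc,H,W));
    ``gt_per_image`` holds (boxes_xyxy_pixels, class_ids) per batch item.
    """
    weights = weights or DEFAULT_LOSS_WEIGHTS
    levels = sorted(outputs)
    shapes = {l: outputs[l][0].shape[2:] for l in levels}
    n_batch = outputs[levels[0]][0].shape[0]
    nc = outputs[levels[0]][1].shape[1]

    assignments = [assign_targets(shapes, strides, *gts, reg_max, topk=topk)
                   for gts in gt_per_image]
    n_matched = max(1, sum(a.num_matched for a in assignments))

    box_terms, dfl_terms, cls_terms = [], [], []
    offset = 0
    for l in levels:
        h, w = shapes[l]
        stride = strides[l]
        npos_lvl = h * w
        reg, cls = outputs[l]

        # per-image masks/targets on this level's grid
        mask = np.zeros((n_batch, 1, h, w), dtype=np.float32)
        tgt_ltrb = np.zeros((n_batch, 4, h, w), dtype=np.float32)
        tgt_cls = np.full((n_batch, nc, h, w), smoothing, dtype=np.float32)
        tgt_box = np.tile(np.array([0, 0, stride, stride], dtype=np.float32
                                   ).reshape(1, 4, 1, 1), (n_batch, 1, h, w))
        for n, a in enumerate(assignments):
            sel = slice(offset, offset + npos_lvl)
            gi = a.gt_index[sel].reshape(h, w)
            m = gi >= 0
            if not m.any():
                continue
            mask[n, 0][m] = 1.0
            lt = a.ltrb_targets[sel].reshape(h, w, 4)
            tgt_ltrb[n][:, m] = lt[m].T
            tgt_box[n][:, m] = a.gt_boxes[gi[m]].T
            cls_ids = a.gt_classes[gi[m]]
            hot = np.full((len(cls_ids), nc), smoothing, dtype=np.float32)
            hot[np.arange(len(cls_ids)), cls_ids] = 1.0 - smoothing
            tgt_cls[n][:, m] = hot.T

        # --- DFL: cross-entropy against the two bracketing bins --------
        bins = ad.reshape(reg, (n_batch, 4, reg_max, h, w))
        logp = ad.log(ad.clamp_min(ad.softmax(bins, axis=2), 1e-9))
        lo = np.floor(tgt_ltrb).astype(np.int64)
        hi = np.minimum(lo + 1, reg_max - 1)
        w_hi = tgt_ltrb - lo
        w_lo = 1.0 - w_hi
        ce_w = np.zeros((n_batch, 4, reg_max, h, w), dtype=np.float32)
        np.put_along_axis(ce_w, lo[:, :, None], w_lo[:, :, None], axis=2)
        hi_cur = np.take_along_axis(ce_w, hi[:, :, None], axis=2)
        np.put_along_axis(ce_w, hi[:, :, None], hi_cur + w_hi[:, :, None], axis=2)
        ce_w *= mask[:, :, None]
        dfl_terms.append(ad.scale(ad.tsum(ad.mul(logp, Tensor(ce_w))), -1.0))

        # --- CIoU on the decoded boxes ---------------------------------
        prob = ad.softmax(bins, axis=2)
        rng_t = Tensor(np.arange(reg_max, dtype=np.float32).reshape(1, 1, reg_max, 1, 1))
        dist = ad.scale(ad.tsum(ad.mul(prob, rng_t), axis=2), stride)  # (N,4,h,w) px
        cy, cx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        cx_t = Tensor(((cx + 0.5) * stride).astype(np.float32)[None, None])
        cy_t = Tensor(((cy + 0.5) * stride).astype(np.float32)[None, None])
        px1 = ad.sub(cx_t, ad.narrow(dist, 1, 0, 1))
        py1 = ad.sub(cy_t, ad.narrow(dist, 1, 1, 1))
        px2 = ad.add(cx_t, ad.narrow(dist, 1, 2, 1))
        py2 = ad.add(cy_t, ad.narrow(dist, 1, 3, 1))
        ciou_t = _ciou_tensor(px1, py1, px2, py2, tgt_box)
        one_minus = ad.sub(Tensor(mask), ad.mul(ciou_t, Tensor(mask)))
        box_terms.append(ad.tsum(one_minus))

        # --- smoothed BCE ----------------------------------------------
        p = ad.sigmoid(cls)
        y = Tensor(tgt_cls)
        term1 = ad.mul(y, ad.log(ad.clamp_min(p, 1e-9)))
        q = ad.clamp_min(ad.shift(ad.neg(p), 1.0), 1e-9)
        term2 = ad.mul(Tensor(1.0 - tgt_cls), ad.log(q))
        cls_terms.append(ad.scale(ad.tsum(ad.add(term1, term2)), -1.0))

        offset += npos_lvl

    def _accumulate(terms):
        out = terms[0]
        for t in terms[1:]:
            out = ad.add(out, t)
        return out

    box_l = ad.scale(_accumulate(box_terms), 1.0 / n_matched)
    dfl_l = ad.scale(_accumulate(dfl_terms), 1.0 / (4 * n_matched))
    cls_l = ad.scale(_accumulate(cls_terms), 1.0 / n_matched)
    total = ad.add(ad.add(ad.scale(box_l, weights["box"]),
                          ad.scale(cls_l, weights["cls"])),
                   ad.scale(dfl_l, weights["dfl"]))
    breakdown = LossBreakdown(box=box_l.item(), cls=cls_l.item(),
                              dfl=dfl_l.item(), total=total.item(),
                              weights=dict(weights))
    return total, breakdown


def _ciou_tensor(px1, py1, px2, py2, tgt_box: np.ndarray) -> Tensor:
    """Differentiable CIoU of predicted vs constant target boxes.

    The aspect-ratio coupling factor alpha is treated as a constant
    (gradient stopped), the standard practice for this loss.
    """
    eps = 1e-7
    bx1 = Tensor(tgt_box[:, 0:1])
    by1 = Tensor(tgt_box[:, 1:2])
    bx2 = Tensor(tgt_box[:, 2:3])
    by2 = Tensor(tgt_box[:, 3:4])
    pw = ad.clamp_min(ad.sub(px2, px1), eps)
    ph = ad.clamp_min(ad.sub(py2, py1), eps)
    bw = ad.clamp_min(ad.sub(bx2, bx1), eps)
    bh = ad.clamp_min(ad.sub(by2, by1), eps)
    ix = ad.clamp_min(ad.sub(ad.tminimum(px2, bx2), ad.tmaximum(px1, bx1)), 0.0)
    iy = ad.clamp_min(ad.sub(ad.tminimum(py2, by2), ad.tmaximum(py1, by1)), 0.0)
    inter = ad.mul(ix, iy)
    union = ad.shift(ad.sub(ad.add(ad.mul(pw, ph), ad.mul(bw, bh)), inter), eps)
    iou = ad.div(inter, union)
    rho2 = ad.scale(ad.add(
        ad.power(ad.sub(ad.add(px1, px2), ad.add(bx1, bx2)), 2.0),
        ad.power(ad.sub(ad.add(py1, py2), ad.add(by1, by2)), 2.0)), 0.25)
    cw = ad.sub(ad.tmaximum(px2, bx2), ad.tminimum(px1, bx1))
    ch = ad.sub(ad.tmaximum(py2, by2), ad.tminimum(py1, by1))
    c2 = ad.shift(ad.add(ad.power(cw, 2.0), ad.power(ch, 2.0)), eps)
    v = ad.scale(ad.power(ad.sub(ad.arctan(ad.div(pw, ph)),
                                 ad.arctan(ad.div(bw, bh))), 2.0),
                 4.0 / math.pi ** 2)
    alpha = v.data / (1.0 - iou.data + v.data + eps)  # stop-gradient
    return ad.sub(ad.sub(iou, ad.div(rho2, c2)), ad.mul(Tensor(alpha), v))
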