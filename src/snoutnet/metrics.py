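"""Detection metrics: per-class AP, mAP50 / mAP50-95, precision/recall,
confusion analysis, and t-distribution confidence intervals over seeds.

Average precision follows the community convention: greedy
confidence-ordered matching at a fixed IoU threshold (each detection may
claim the highest-IoU still-unmatched ground truth of its class) and
101-point interpolated integration of the precision–recall curve.
mAP50-95 averages AP over IoU thresholds 0.50:0.05:0.95.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import stats

from .model import Detection, box_iou
from .types import NUM_CLASSES, BBox

#: ground truths per image: list of (class_id, BBox)
GroundTruths = List[List[Tuple[int, BBox]]]
Detections = List[List[Detection]]

IOU_SWEEP = np.arange(0.50, 0.96, 0.05)


@dataclass
class EvalReport:
    per_class_ap50: np.ndarray
    map50: float
    map50_95: float
    precision: float
    recall: float
    confusion: np.ndarray                      # (5, 5): 4 classes + background
    size_stratified: Dict[str, float] = field(default_factory=dict)

    def summary_rows(self) -> List[Tuple[str, float]]:
        rows = [(f"AP50[{i}]", float(v)) for i, v in enumerate(self.per_class_ap50)]
        rows += [("mAP50", self.map50), ("mAP50-95", self.map50_95),
                 ("precision", self.precision), ("recall", self.recall)]
        rows += [(f"mAP50[{k}]", v) for k, v in self.size_stratified.items()]
        return rows


def _boxes_xyxy(items, size: float = 1.0) -> np.ndarray:
    return np.array([b.to_xyxy(size) for b in items], dtype=np.float64
                    ).reshape(-1, 4)


def _match_class(dets: List[Tuple[int, float, BBox]],
                 gts_by_img: Dict[int, List[BBox]],
                 iou_threshold: float) -> Tuple[np.ndarray, np.ndarray, int]:
    """Greedy matching of one class's detections across the dataset.

    Returns (tp flags, confidences, total ground truths); detections are
    processed in descending confidence and may claim the highest-IoU
    unmatched ground truth in their image.
    """
    n_gt = sum(len(v) for v in gts_by_img.values())
    dets = sorted(dets, key=lambda d: -d[1])
    used = {img: np.zeros(len(v), dtype=bool) for img, v in gts_by_img.items()}
    tp = np.zeros(len(dets), dtype=bool)
    conf = np.array([d[1] for d in dets], dtype=np.float64)
    for i, (img, _, box) in enumerate(dets):
        cand = gts_by_img.get(img, [])
        if not cand:
            continue
        ious = box_iou(_boxes_xyxy([box]), _boxes_xyxy(cand))[0]
        ious[used[img]] = -1.0
        j = int(np.argmax(ious))
        if ious[j] >= iou_threshold:
            tp[i] = True
            used[img][j] = True
    return tp, conf, n_gt


def _ap_from_matches(tp: np.ndarray, n_gt: int) -> float:
    """101-point interpolated AP from confidence-ordered TP flags."""
    if n_gt == 0:
        return 0.0
    if len(tp) == 0:
        return 0.0
    tp_cum = np.cumsum(tp)
    fp_cum = np.cumsum(~tp)
    recall = tp_cum / n_gt
    precision = tp_cum / (tp_cum + fp_cum)
    # precision envelope, sampled at 101 recall points
    ap = 0.0
    for r in np.linspace(0, 1, 101):
        mask = recall >= r
        ap += precision[mask].max() if mask.any() else 0.0
    return ap / 101.0


def average_precision(detections: Detections, ground_truths: GroundTruths,
                      iou_threshold: float = 0.5) -> np.ndarray:
    """Per-class AP at one IoU threshold over a set of images."""
    if not 0.0 < iou_threshold < 1.0:
        raise ValueError("iou_threshold must lie in (0, 1)")
    aps = np.zeros(NUM_CLASSES)
    for cid in range(NUM_CLASSES):
        dets = [(img, d.confidence, d.box)
                for img, dd in enumerate(detections)
                for d in dd if d.class_id == cid]
        gts = {img: [b for c, b in gg if c == cid]
               for img, gg in enumerate(ground_truths)}
        gts = {img: v for img, v in gts.items() if v}
        tp, _, n_gt = _match_class(dets, gts, iou_threshold)
        aps[cid] = _ap_from_matches(tp, n_gt)
    return aps


def confusion_matrix(detections: Detections, ground_truths: GroundTruths,
                     iou_threshold: float = 0.5) -> np.ndarray:
    """(NUM_CLASSES+1)^2 counts; last row/column is background.

    Detections are matched to ground truths class-agnostically (greedy,
    highest confidence first); matched pairs increment
    (gt_class, pred_class), unmatched ground truths go to
    (gt_class, background) and unmatched detections to
    (background, pred_class).
    """
    bg = NUM_CLASSES
    cm = np.zeros((NUM_CLASSES + 1, NUM_CLASSES + 1), dtype=np.int64)
    for dd, gg in zip(detections, ground_truths):
        used = np.zeros(len(gg), dtype=bool)
        for d in sorted(dd, key=lambda d: -d.confidence):
            if gg:
                ious = box_iou(_boxes_xyxy([d.box]),
                               _boxes_xyxy([b for _, b in gg]))[0]
                ious[used] = -1.0
                j = int(np.argmax(ious))
                if ious[j] >= iou_threshold:
                    used[j] = True
                    cm[gg[j][0], d.class_id] += 1
                    continue
            cm[bg, d.class_id] += 1
        for j, (c, _) in enumerate(gg):
            if not used[j]:
                cm[c, bg] += 1
    return cm


def precision_recall(detections: Detections, ground_truths: GroundTruths,
                     iou_threshold: float = 0.5) -> Tuple[float, float]:
    """Operating-point precision/recall over all classes at the threshold."""
    tp = fp = n_gt = 0
    for cid in range(NUM_CLASSES):
        dets = [(img, d.confidence, d.box)
                for img, dd in enumerate(detections)
                for d in dd if d.class_id == cid]
        gts = {img: [b for c, b in gg if c == cid]
               for img, gg in enumerate(ground_truths)}
        gts = {img: v for img, v in gts.items() if v}
        t, _, g = _match_class(dets, gts, iou_threshold)
        tp += int(t.sum())
        fp += int((~t).sum())
        n_gt += g
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / n_gt if n_gt else 0.0
    return precision, recall


def _filter_by_size(ground_truths: GroundTruths, keep_small: bool,
                    threshold: float) -> GroundTruths:
    out = []
    for gg in ground_truths:
        out.append([(c, b) for c, b in gg
                    if (b.w * b.h <= threshold) == keep_small])
    return out


def summarize(detections: Detections, ground_truths: GroundTruths,
              iou_threshold: float = 0.5) -> EvalReport:
    """Full evaluation report; errors on an empty image set."""
    if len(ground_truths) == 0:
        raise ValueError("cannot summarize an empty image set")
    if len(detections) != len(ground_truths):
        raise ValueError("detections and ground truths must align per image")
    per_class = average_precision(detections, ground_truths, 0.5)
    present = [c for c in range(NUM_CLASSES)
               if any(c in [g[0] for g in gg] for gg in ground_truths)]
    map50 = float(per_class[present].mean()) if present else 0.0
    sweep = [average_precision(detections, ground_truths, t)[present].mean()
             for t in IOU_SWEEP] if present else [0.0]
    map50_95 = float(np.mean(sweep))
    prec, rec = precision_recall(detections, ground_truths, iou_threshold)
    cm = confusion_matrix(detections, ground_truths, iou_threshold)
    areas = [b.w * b.h for gg in ground_truths for _, b in gg]
    size_strat = {}
    if areas:
        median = float(np.median(areas))
        for name, small in (("small", True), ("large", False)):
            sub = _filter_by_size(ground_truths, small, median)
            excluded = _filter_by_size(ground_truths, not small, median)
            # ignore detections that cover an out-of-stratum ground truth
            dets_kept: Detections = []
            for dd, ex in zip(detections, excluded):
                if not ex:
                    dets_kept.append(dd)
                    continue
                ex_boxes = _boxes_xyxy([b for _, b in ex])
                keep = []
                for d in dd:
                    ious = box_iou(_boxes_xyxy([d.box]), ex_boxes)[0]
                    if ious.max() < 0.5:
                        keep.append(d)
                dets_kept.append(keep)
            sub_present = [c for c in range(NUM_CLASSES)
                           if any(c in [g[0] for g in gg] for gg in sub)]
            if sub_present:
                ap = average_precision(dets_kept, sub, 0.5)
                size_strat[name] = float(ap[sub_present].mean())
    return EvalReport(per_class_ap50=per_class, map50=map50,
                      map50_95=map50_95, precision=prec, recall=rec,
                      confusion=cm, size_stratified=size_strat)


def t_confidence_interval(values: Sequence[float],
                          level: float = 0.95) -> Tuple[float, float]:
    """(mean, half-width) using the t quantile with n-1 degrees of freedom."""
    v = np.asarray(values, dtype=np.float64)
    if v.size < 2:
        raise ValueError("need at least two values for a confidence interval")
    q = stats.t.ppf((1.0 + level) / 2.0, df=v.size - 1)
    half = float(q * v.std(ddof=1) / np.sqrt(v.size))
    return float(v.mean()), half
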