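"""Compact single-stage anchor-free detector and its refined variants.

Architecture (the classic four-stage compact layout):

* **Backbone** — strided stem, four stages of stride-2 convolution plus
  CSP split/merge blocks, ending in an SPPF pooling block; emits feature
  maps at strides 4/8/16/32.
* **Neck** — PAFPN: top-down upsample-and-merge followed by a bottom-up
  downsample-and-merge path; emits the pyramid P3/P4/P5 (strides 8/16/32).
* **Head** — decoupled per-level branches: a regression branch predicting
  a discrete distribution over ``reg_max`` bins for each of the four
  box-edge distances (decoded by expectation), and a classification
  branch with one sigmoid score per health-state class.

Variants swap exactly one component: ``cspc`` replaces every CSP block's
dense bottlenecks with partial-convolution bottlenecks, ``fasff3`` /
``fasff4`` insert adaptive spatial fusion between neck and heads (the
four-head form adds a stride-4 P2 level fed by one extra top-down
stage), and ``iema`` puts an iEMA attention module ahead of each head.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .config import ModelConfig
from .cspc import CSPPC, PConvLayer
from .fasff import FASFF
from .iema import IEMA
from .nn import Conv2d, ConvBnAct, Module, ModuleList
from .types import BBox

STRIDES = {2: 4, 3: 8, 4: 16, 5: 32}


@dataclass
class FeaturePyramid:
    """Multi-scale feature maps keyed by level; stride doubles per level."""

    levels: Dict[int, Tensor]
    strides: Dict[int, int]

    def __post_init__(self):
        for l, t in self.levels.items():
            if not np.isfinite(t.data).all():
                raise ValueError(f"non-finite values at level {l}")


@dataclass
class Detection:
    box: BBox
    class_id: int
    confidence: float

    def __post_init__(self):
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence must lie in [0, 1]")


@dataclass
class ComplexityReport:
    """Exact parameter count and forward-pass cost (FLOPs = 2 x MACs)."""

    params: int
    flops: int
    input_size: int
    per_module_breakdown: List[Tuple[str, int, int]] = field(default_factory=list)
    convention: str = "1 MAC = 2 FLOPs; conv/linear ops only"

    def as_tsv(self) -> str:
        lines = [f"# {self.convention}; input {self.input_size}",
                 "module\tparams\tflops"]
        for name, p, f in self.per_module_breakdown:
            lines.append(f"{name}\t{p}\t{f}")
        lines.append(f"TOTAL\t{self.params}\t{self.flops}")
        return "\n".join(lines)


class Bottleneck(Module):
    """Dense 3x3 pair with optional residual (the C2f inner unit)."""

    def __init__(self, rng, channels, shortcut=True):
        super().__init__()
        self.cv1 = ConvBnAct(rng, channels, channels, k=3)
        self.cv2 = ConvBnAct(rng, channels, channels, k=3)
        self.shortcut = shortcut

    def forward(self, x):
        y = self.cv2(self.cv1(x))
        return ad.add(x, y) if self.shortcut else y


class C2f(Module):
    """CSP split/merge block with ``n`` stacked bottlenecks."""

    def __init__(self, rng, c_in, c_out, n=1, shortcut=True, e=0.5):
        super().__init__()
        self.h = int(c_out * e)
        self.cv1 = ConvBnAct(rng, c_in, 2 * self.h, k=1)
        self.m = ModuleList([Bottleneck(rng, self.h, shortcut) for _ in range(n)])
        self.cv2 = ConvBnAct(rng, (2 + n) * self.h, c_out, k=1)

    def forward(self, x):
        y = self.cv1(x)
        parts = [ad.narrow(y, 1, 0, self.h), ad.narrow(y, 1, self.h, self.h)]
        cur = parts[-1]
        for blk in self.m:
            cur = blk(cur)
            parts.append(cur)
        return self.cv2(ad.concat(parts, axis=1))


class SPPF(Module):
    """Spatial pyramid pooling (fast): three chained 5x5 max pools."""

    def __init__(self, rng, channels):
        super().__init__()
        h = channels // 2
        self.cv1 = ConvBnAct(rng, channels, h, k=1)
        self.cv2 = ConvBnAct(rng, 4 * h, channels, k=1)

    def forward(self, x):
        y = self.cv1(x)
        p1 = ad.maxpool2d(y, 5, stride=1, padding=2)
        p2 = ad.maxpool2d(p1, 5, stride=1, padding=2)
        p3 = ad.maxpool2d(p2, 5, stride=1, padding=2)
        return self.cv2(ad.concat([y, p1, p2, p3], axis=1))


def _block_cls(blocks: str):
    if blocks == "c2f":
        return C2f
    if blocks == "cspc":
        return CSPPC
    raise ValueError(f"unknown block type {blocks!r}")


class Backbone(Module):
    def __init__(self, rng, cfg: ModelConfig, want_p2: bool):
        super().__init__()
        c1, c2, c3, c4, c5 = cfg.channels()
        n1, n2, n3, n4 = cfg.depths()
        Block = _block_cls(cfg.resolved()[0])
        self.want_p2 = want_p2
        self.stem = ConvBnAct(rng, 3, c1, k=3, stride=2)
        self.down1 = ConvBnAct(rng, c1, c2, k=3, stride=2)
        self.stage1 = Block(rng, c2, c2, n1)
        self.down2 = ConvBnAct(rng, c2, c3, k=3, stride=2)
        self.stage2 = Block(rng, c3, c3, n2)
        self.down3 = ConvBnAct(rng, c3, c4, k=3, stride=2)
        self.stage3 = Block(rng, c4, c4, n3)
        self.down4 = ConvBnAct(rng, c4, c5, k=3, stride=2)
        self.stage4 = Block(rng, c5, c5, n4)
        self.sppf = SPPF(rng, c5)

    def forward(self, x: Tensor) -> Dict[int, Tensor]:
        p2 = self.stage1(self.down1(self.stem(x)))
        p3 = self.stage2(self.down2(p2))
        p4 = self.stage3(self.down3(p3))
        p5 = self.sppf(self.stage4(self.down4(p4)))
        out = {3: p3, 4: p4, 5: p5}
        if self.want_p2:
            out[2] = p2
        return out


class PAFPN(Module):
    """Top-down + bottom-up aggregation; optionally extends down to P2."""

    def __init__(self, rng, cfg: ModelConfig, want_p2: bool):
        super().__init__()
        _, c2, c3, c4, c5 = cfg.channels()
        n = max(1, round(3 * cfg.depth_mult))
        Block = _block_cls(cfg.resolved()[0])
        self.want_p2 = want_p2
        self.td1 = Block(rng, c5 + c4, c4, n, shortcut=False)
        self.td2 = Block(rng, c4 + c3, c3, n, shortcut=False)
        if want_p2:
            self.td3 = Block(rng, c3 + c2, c2, n, shortcut=False)
        self.down1 = ConvBnAct(rng, c3, c3, k=3, stride=2)
        self.bu1 = Block(rng, c3 + c4, c4, n, shortcut=False)
        self.down2 = ConvBnAct(rng, c4, c4, k=3, stride=2)
        self.bu2 = Block(rng, c4 + c5, c5, n, shortcut=False)

    def forward(self, feats: Dict[int, Tensor]) -> Dict[int, Tensor]:
        p3, p4, p5 = feats[3], feats[4], feats[5]
        t4 = self.td1(ad.concat([ad.upsample_nearest(p5, 2), p4], axis=1))
        n3 = self.td2(ad.concat([ad.upsample_nearest(t4, 2), p3], axis=1))
        out = {}
        if self.want_p2:
            out[2] = self.td3(ad.concat([ad.upsample_nearest(n3, 2), feats[2]], axis=1))
        n4 = self.bu1(ad.concat([self.down1(n3), t4], axis=1))
        n5 = self.bu2(ad.concat([self.down2(n4), p5], axis=1))
        out.update({3: n3, 4: n4, 5: n5})
        return out


class HeadBranch(Module):
    def __init__(self, rng, c_in, hidden, c_out, prior_bias=0.0):
        super().__init__()
        self.cv1 = ConvBnAct(rng, c_in, hidden, k=3)
        self.cv2 = ConvBnAct(rng, hidden, hidden, k=3)
        self.out = Conv2d(rng, hidden, c_out, k=1, bias=True)
        if prior_bias:
            self.out.bias.data[...] = prior_bias

    def forward(self, x):
        return self.out(self.cv2(self.cv1(x)))


class Head(Module):
    """Decoupled anchor-free head: per level, 4*reg_max regression logits
    and ``num_classes`` classification logits (so 68 output channels for
    four classes at reg_max 16)."""

    def __init__(self, rng, channels: Dict[int, int], num_classes: int,
                 reg_max: int, cls_prior: float = 0.01):
        super().__init__()
        self.levels = sorted(channels)
        self.num_classes = num_classes
        self.reg_max = reg_max
        bias = -math.log((1.0 - cls_prior) / cls_prior)
        for l, c in channels.items():
            hidden = max(16, c // 4)
            setattr(self, f"reg{l}", HeadBranch(rng, c, hidden, 4 * reg_max))
            setattr(self, f"cls{l}", HeadBranch(rng, c, hidden, num_classes,
                                                prior_bias=bias))

    def forward(self, pyr: Dict[int, Tensor]) -> Dict[int, Tuple[Tensor, Tensor]]:
        return {l: (getattr(self, f"reg{l}")(pyr[l]),
                    getattr(self, f"cls{l}")(pyr[l])) for l in self.levels}


class DetectorModel(Module):
    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.cfg = cfg
        blocks, head, attn = cfg.resolved()
        rng = np.random.default_rng(cfg.seed)
        self.head_levels = [2, 3, 4, 5] if head == "fasff4" else [3, 4, 5]
        want_p2 = head == "fasff4"
        self.backbone = Backbone(rng, cfg, want_p2)
        self.neck = PAFPN(rng, cfg, want_p2)
        chans = dict(zip((2, 3, 4, 5), cfg.channels()[1:]))
        head_ch = {l: chans[l] for l in self.head_levels}
        if head in ("fasff3", "fasff4"):
            self.fasff = FASFF(rng, head_ch)
        else:
            self.fasff = None
        if attn != "none":
            for l in self.head_levels:
                setattr(self, f"attn{l}", IEMA(
                    rng, head_ch[l],
                    use_ema=attn in ("ema", "iema"),
                    use_irmb=attn in ("irmb", "iema")))
        self.attn_kind = attn
        self.head = Head(rng, head_ch, cfg.num_classes, cfg.reg_max)

    # ------------------------------------------------------------------
    def _check_input(self, x: np.ndarray) -> Tensor:
        if isinstance(x, Tensor):
            x = x.data
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[None]
        if x.shape[2] % 32 or x.shape[3] % 32:
            raise ValueError(f"input spatial size {x.shape[2:]} not divisible by 32")
        return Tensor(x)

    def forward_pyramid(self, x) -> FeaturePyramid:
        """Backbone + neck only: the raw pyramid the heads are fed from."""
        t = self._check_input(x)
        pyr = self.neck(self.backbone(t))
        return FeaturePyramid(levels=pyr,
                              strides={l: STRIDES[l] for l in pyr})

    def forward(self, x) -> Dict[int, Tuple[Tensor, Tensor]]:
        t = self._check_input(x)
        pyr = self.neck(self.backbone(t))
        pyr = {l: pyr[l] for l in self.head_levels}
        if self.fasff is not None:
            pyr = self.fasff(pyr)
        if self.attn_kind != "none":
            pyr = {l: getattr(self, f"attn{l}")(pyr[l]) for l in pyr}
        return self.head(pyr)

    # ------------------------------------------------------------------
    def decode(self, outputs: Dict[int, Tuple[Tensor, Tensor]]
               ) -> Tuple[np.ndarray, np.ndarray]:
        """Raw head outputs -> (boxes_xyxy_pixels, class_scores), flattened
        over levels and locations for a single image."""
        all_boxes, all_scores = [], []
        for l, (reg, cls) in outputs.items():
            stride = STRIDES[l]
            r = reg.data[0]  # (4*R, H, W)
            R = self.cfg.reg_max
            _, h, w = r.shape
            bins = r.reshape(4, R, h, w)
            bins = bins - bins.max(axis=1, keepdims=True)
            e = np.exp(bins)
            prob = e / e.sum(axis=1, keepdims=True)
            dist = (prob * np.arange(R)[None, :, None, None]).sum(axis=1) * stride
            cy, cx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
            cx = (cx + 0.5) * stride
            cy = (cy + 0.5) * stride
            boxes = np.stack([cx - dist[0], cy - dist[1],
                              cx + dist[2], cy + dist[3]], axis=-1)
            scores = 1.0 / (1.0 + np.exp(-cls.data[0]))  # (nc, H, W)
            all_boxes.append(boxes.reshape(-1, 4))
            all_scores.append(scores.reshape(self.cfg.num_classes, -1).T)
        return np.concatenate(all_boxes), np.concatenate(all_scores)


def build_model(cfg: ModelConfig) -> DetectorModel:
    """Instantiate a detector; weight initialization is fixed by cfg.seed."""
    return DetectorModel(cfg)


def nms(boxes: np.ndarray, scores: np.ndarray, iou_threshold: float) -> List[int]:
    """Greedy non-maximum suppression; returns kept indices (score order)."""
    order = np.argsort(-scores, kind="stable")
    keep = []
    suppressed = np.zeros(len(boxes), dtype=bool)
    for i in order:
        if suppressed[i]:
            continue
        keep.append(int(i))
        ious = box_iou(boxes[i][None], boxes[order])[0]
        suppressed[order[ious > iou_threshold]] = True
        suppressed[i] = True
    return keep


def box_iou(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU of xyxy boxes: (n, 4) x (m, 4) -> (n, m)."""
    a, b = np.atleast_2d(a), np.atleast_2d(b)
    x1 = np.maximum(a[:, None, 0], b[None, :, 0])
    y1 = np.maximum(a[:, None, 1], b[None, :, 1])
    x2 = np.minimum(a[:, None, 2], b[None, :, 2])
    y2 = np.minimum(a[:, None, 3], b[None, :, 3])
    inter = np.clip(x2 - x1, 0, None) * np.clip(y2 - y1, 0, None)
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    union = area_a[:, None] + area_b[None, :] - inter
    return np.where(union > 0, inter / np.maximum(union, 1e-12), 0.0)


def predict(model: DetectorModel, image: np.ndarray, *,
            conf_threshold: float = 0.25, iou_threshold: float = 0.7,
            max_det: int = 300) -> List[Detection]:
    """Detections for one image after thresholding and class-wise NMS.

    ``image`` is (3, H, W) or (H, W, 3), already preprocessed to the
    model's input convention; boxes are returned normalized and clipped.
    """
    img = np.asarray(image, dtype=np.float32)
    if img.ndim == 3 and img.shape[-1] == 3 and img.shape[0] != 3:
        img = img.transpose(2, 0, 1)
    size_h, size_w = img.shape[1], img.shape[2]
    was_training = model.training
    model.eval()
    try:
        with ad.no_grad():
            outputs = model.forward(img[None])
    finally:
        model.train(was_training)
    boxes, scores = model.decode(outputs)
    detections: List[Detection] = []
    for cid in range(model.cfg.num_classes):
        s = scores[:, cid]
        mask = s >= conf_threshold
        if not mask.any():
            continue
        cb, cs = boxes[mask], s[mask]
        for i in nms(cb, cs, iou_threshold):
            x1, y1, x2, y2 = cb[i]
            x1, x2 = np.clip((x1, x2), 0, size_w)
            y1, y2 = np.clip((y1, y2), 0, size_h)
            if x2 - x1 <= 1e-3 or y2 - y1 <= 1e-3:
                continue
            box = BBox.from_xyxy(x1 / size_w, y1 / size_h,
                                 x2 / size_w, y2 / size_h)
            detections.append(Detection(box, cid, float(cs[i])))
    detections.sort(key=lambda d: -d.confidence)
    return detections[:max_det]


def audit_complexity(model: DetectorModel,
                     input_size: Optional[int] = None) -> ComplexityReport:
    """Exact parameter enumeration plus conv MAC accounting at input_size.

    A single dry forward pass records every convolution's output grid;
    FLOPs are 2 x MACs summed over conv layers (norm/activation cost is
    not modeled).  The per-module breakdown covers the model's direct
    children and sums exactly to the totals.
    """
    size = input_size or model.cfg.input_size
    was_training = model.training
    model.eval()
    try:
        with ad.no_grad():
            model.forward(np.zeros((1, 3, size, size), dtype=np.float32))
    finally:
        model.train(was_training)
    breakdown = []
    total_p = total_f = 0
    for name, child in model._modules.items():
        p = child.num_params()
        macs = sum(m.macs() for _, m in child.named_modules()
                   if isinstance(m, (Conv2d, PConvLayer)))
        breakdown.append((name, p, 2 * macs))
        total_p += p
        total_f += 2 * macs
    return ComplexityReport(params=total_p, flops=total_f, input_size=size,
                            per_module_breakdown=breakdown)
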