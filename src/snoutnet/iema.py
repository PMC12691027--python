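"""iEMA attention: efficient multi-scale attention fused with an inverted
residual mobile block, inserted ahead of each detection head.

**EMA stage.**  Channels are split into groups.  Each group is processed
by two parallel branches with different receptive fields: a 1x1 branch
driven by directional (height/width) average pooling, and a 3x3 branch.
The branches gate each other through dot-product similarity: each
branch's globally pooled descriptor is matched against the other
branch's per-position features, the two similarity maps are summed,
passed through a sigmoid, and applied multiplicatively to the input.
The exact operand pairing of the published dot-product fusion is
under-specified; this implementation is the bidirectional
pooled-descriptor reading and is shape-preserving by construction.

**iRMB stage.**  A pointwise expansion to E = round(C * expansion)
channels, a depthwise k x k convolution, and a pointwise projection back
to C, with an identity skip.  All convolutions are bias-free and carry no
norm layer, so the parameter count is exactly C*E + E*k^2 + E*C.
Zero-initializing the projection makes the block the identity at start.

The composition order is EMA -> iRMB; either stage can be disabled to
form the ablation variants (EMA-only, iRMB-only).
"""

from __future__ import annotations

from dataclasses import dataclass

from . import autodiff as ad
from .autodiff import Tensor
from .nn import Conv2d, Module


@dataclass
class EMASpec:
    channels: int
    groups: int = 8
    branch_kernels: tuple = (1, 3)

    def __post_init__(self):
        if self.channels % self.groups != 0:
            raise ValueError(
                f"channels {self.channels} not divisible by groups {self.groups}")


@dataclass
class IRMBSpec:
    channels: int
    expansion: float = 1.5
    depthwise_kernel: int = 3

    @property
    def expanded(self) -> int:
        e = int(round(self.channels * self.expansion))
        if e < self.channels:
            raise ValueError("expansion must not shrink the width")
        return e


class EMA(Module):
    """Grouped two-branch attention with bidirectional dot-product gating."""

    def __init__(self, rng, spec: EMASpec):
        super().__init__()
        self.spec = spec
        cg = spec.channels // spec.groups
        # 1x1 branch operates on the concatenated directional descriptors
        self.conv1x1 = Conv2d(rng, cg, cg, k=1, bias=True)
        # replicate padding keeps spatially constant inputs constant
        self.conv3x3 = Conv2d(rng, cg, cg, k=3, padding=0, bias=True)

    def forward(self, x: Tensor) -> Tensor:
        spec = self.spec
        if x.shape[1] != spec.channels:
            raise ValueError(f"expected {spec.channels} channels, got {x.shape[1]}")
        n, c, h, w = x.shape
        g, cg = spec.groups, c // spec.groups
        xg = ad.reshape(x, (n * g, cg, h, w))

        # 1x1 branch: directional context, broadcast back over space
        pool_h = ad.tmean(xg, axis=3, keepdims=True)        # (ng, cg, h, 1)
        pool_w = ad.tmean(xg, axis=2, keepdims=True)        # (ng, cg, 1, w)
        ctx = ad.add(pool_h, pool_w)                        # broadcast sum
        b1 = ad.silu(self.conv1x1(ad.mul(xg, ad.sigmoid(ctx))))
        # 3x3 branch: local spatial context
        b2 = ad.silu(self.conv3x3(ad.pad_replicate(xg, 1)))

        # bidirectional dot-product gating
        d1 = ad.tmean(b1, axis=(2, 3), keepdims=True)       # pooled descriptor
        d2 = ad.tmean(b2, axis=(2, 3), keepdims=True)
        s12 = ad.tsum(ad.mul(d1, b2), axis=1, keepdims=True)  # (ng,1,h,w)
        s21 = ad.tsum(ad.mul(d2, b1), axis=1, keepdims=True)
        gate = ad.sigmoid(ad.add(s12, s21))
        out = ad.mul(xg, gate)
        return ad.reshape(out, (n, c, h, w))


class IRMB(Module):
    """Inverted residual mobile block: expand -> depthwise -> project + skip."""

    def __init__(self, rng, spec: IRMBSpec, zero_init_project: bool = True):
        super().__init__()
        self.spec = spec
        e = spec.expanded
        k = spec.depthwise_kernel
        self.expand = Conv2d(rng, spec.channels, e, k=1, bias=False)
        self.dw = Conv2d(rng, e, e, k=k, groups=e, bias=False)
        self.project = Conv2d(rng, e, spec.channels, k=1, bias=False,
                              zero_init=zero_init_project)

    def forward(self, x: Tensor) -> Tensor:
        y = ad.silu(self.expand(x))
        y = ad.silu(self.dw(y))
        y = self.project(y)
        return ad.add(x, y)

    def param_count_closed_form(self) -> int:
        c, e = self.spec.channels, self.spec.expanded
        k = self.spec.depthwise_kernel
        return c * e + e * k * k + e * c


class IEMA(Module):
    """EMA attention refinement followed by iRMB transformation.

    ``use_ema`` / ``use_irmb`` expose the ablation variants; with iRMB
    disabled the module reproduces the EMA stage exactly.
    """

    def __init__(self, rng, channels: int, groups: int | None = None,
                 use_ema: bool = True, use_irmb: bool = True):
        super().__init__()
        if groups is None:
            groups = 8
            while channels % groups != 0:
                groups //= 2
        self.use_ema = use_ema
        self.use_irmb = use_irmb
        if use_ema:
            self.ema = EMA(rng, EMASpec(channels=channels, groups=groups))
        if use_irmb:
            self.irmb = IRMB(rng, IRMBSpec(channels=channels))

    def forward(self, x: Tensor) -> Tensor:
        if self.use_ema:
            x = self.ema(x)
        if self.use_irmb:
            x = self.irmb(x)
        return x


def ema_forward(x: Tensor, module: EMA) -> Tensor:
    return module(x)


def irmb_forward(x: Tensor, module: IRMB) -> Tensor:
    return module(x)


def iema_forward(x: Tensor, module: IEMA) -> Tensor:
    return module(x)
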