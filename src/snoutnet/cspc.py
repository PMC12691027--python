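"""Partial convolution (PConv) and the CSPPC lightweight block.

A standard ("dense") convolution connects every output channel to every
input channel, so its cost grows quadratically in the channel count C.
Partial convolution instead partitions the C input channels into groups
via a binary selection vector (1 = first group, 0 = second) and convolves
each group with its own sub-kernel over only its selected channels; group
outputs are merged by concatenation (scattered back to the channel
positions of their group) or element-wise addition.  For the default equal
split this halves parameters and multiply–accumulates exactly:

    dense:  C * C * k^2        PConv:  2 * (C/2) * (C/2) * k^2

The CSPPC block keeps the CSP split/merge topology of the C2f block it
replaces but swaps each dense 3x3 bottleneck for a PConv followed by a
pointwise (1x1) convolution that restores cross-group channel mixing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .nn import BatchNorm2d, ConvBnAct, Module, ModuleList, Parameter


@dataclass
class PConvSpec:
    """Configuration of one partial convolution.

    ``selection`` marks the channels of the first group with 1; by default
    the groups are the contiguous halves of the channel range.
    """

    channels: int
    groups: int = 2
    split_sizes: Optional[Tuple[int, ...]] = None
    kernel: int = 3
    merge: str = "concat"  # or "add"
    selection: Optional[np.ndarray] = None

    def __post_init__(self):
        c = self.channels
        if self.split_sizes is None:
            base = c // self.groups
            sizes = [base] * self.groups
            sizes[-1] += c - base * self.groups
            self.split_sizes = tuple(sizes)
        if sum(self.split_sizes) != c:
            raise ValueError(f"split sizes {self.split_sizes} must sum to {c}")
        if any(s <= 0 for s in self.split_sizes):
            raise ValueError("split sizes must be positive")
        if self.selection is not None:
            sel = np.asarray(self.selection)
            if sel.size != c or not np.isin(sel, (0, 1)).all():
                raise ValueError("selection must be a binary vector of length C")
            if self.groups != 2:
                raise ValueError("binary selection defines exactly two groups")
            if int(sel.sum()) != self.split_sizes[0]:
                raise ValueError("selection cardinality disagrees with split sizes")
        if self.merge not in ("concat", "add"):
            raise ValueError(f"unknown merge mode {self.merge!r}")
        if self.merge == "add" and len(set(self.split_sizes)) != 1:
            raise ValueError("merge='add' requires equal group output widths")

    def group_indices(self) -> List[np.ndarray]:
        """Channel index array per group."""
        if self.selection is not None:
            sel = np.asarray(self.selection).astype(bool)
            return [np.flatnonzero(sel), np.flatnonzero(~sel)]
        out, start = [], 0
        for s in self.split_sizes:
            out.append(np.arange(start, start + s))
            start += s
        return out


def pconv_cost(C: int, kernel: int, split_sizes: Sequence[int]) -> Tuple[int, int]:
    """Closed-form (parameter count, MACs per output position) of a PConv.

    Each group of width Cg contributes Cg * Cg * k^2 weights and the same
    number of multiply–accumulates at every spatial position.  For the
    equal split of an even C the ratio to the dense convolution's
    C * C * k^2 is exactly 1/2.
    """
    if sum(split_sizes) != C:
        raise ValueError("split sizes must sum to C")
    params = sum(int(s) * int(s) * kernel * kernel for s in split_sizes)
    return params, params


def dense_conv_cost(C: int, kernel: int) -> Tuple[int, int]:
    """(params, MACs per position) of the dense C->C convolution."""
    return C * C * kernel * kernel, C * C * kernel * kernel


def partial_conv(x: Tensor, spec: PConvSpec, weights: Sequence[Tensor]) -> Tensor:
    """Apply a partial convolution with explicit per-group weights.

    ``weights[g]`` has shape (Cg, Cg, k, k).  With ``merge='concat'`` each
    group's output is written back to that group's own channel positions,
    so the result equals a dense convolution whose cross-group kernel
    entries are zero.  With ``merge='add'`` the group outputs are summed.
    """
    if x.shape[1] != spec.channels:
        raise ValueError(f"input has {x.shape[1]} channels, spec expects {spec.channels}")
    idx_groups = spec.group_indices()
    pad = spec.kernel // 2
    outs = []
    for idx, w in zip(idx_groups, weights):
        xg = _gather_channels(x, idx)
        outs.append(ad.conv2d(xg, w, stride=1, padding=pad))
    if spec.merge == "add":
        y = outs[0]
        for o in outs[1:]:
            y = ad.add(y, o)
        return y
    order = np.concatenate(idx_groups)
    y = ad.concat(outs, axis=1)
    return _scatter_channels(y, order, spec.channels)


def _gather_channels(x: Tensor, idx: np.ndarray) -> Tensor:
    idx = np.asarray(idx)
    if idx.size and np.array_equal(idx, np.arange(idx[0], idx[0] + idx.size)):
        return ad.narrow(x, 1, int(idx[0]), int(idx.size))
    return ad.concat([ad.narrow(x, 1, int(i), 1) for i in idx], axis=1)


def _scatter_channels(y: Tensor, order: np.ndarray, channels: int) -> Tensor:
    """Reorder concatenated group outputs back to native channel positions."""
    if np.array_equal(order, np.arange(channels)):
        return y
    inv = np.empty(channels, dtype=int)
    inv[order] = np.arange(channels)
    return ad.concat([ad.narrow(y, 1, int(i), 1) for i in inv], axis=1)


def masked_dense_kernel(spec: PConvSpec, weights: Sequence[np.ndarray]) -> np.ndarray:
    """Dense C x C x k x k kernel equivalent to the PConv (concat merge).

    Cross-group entries are zero; within-group entries copy the sub-kernels.
    This is the reference object for the block-diagonal equivalence oracle.
    """
    k = spec.kernel
    dense = np.zeros((spec.channels, spec.channels, k, k), dtype=np.float32)
    for idx, w in zip(spec.group_indices(), weights):
        w = np.asarray(w)
        for a, oi in enumerate(idx):
            for b, ii in enumerate(idx):
                dense[oi, ii] = w[a, b]
    return dense


class PConvLayer(Module):
    """Learnable partial convolution (bias-free; pair with a norm layer)."""

    def __init__(self, rng: np.random.Generator, spec: PConvSpec):
        super().__init__()
        self.spec = spec
        self._weight_params = []
        k = spec.kernel
        for g, s in enumerate(spec.split_sizes):
            fan_in = s * k * k
            w = Parameter(rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                     size=(s, s, k, k)).astype(np.float32))
            setattr(self, f"w{g}", w)
            self._weight_params.append(w)
        self.last_out_hw = None

    def forward(self, x: Tensor) -> Tensor:
        y = partial_conv(x, self.spec, self._weight_params)
        self.last_out_hw = y.shape[2:]
        return y

    def macs(self) -> int:
        if self.last_out_hw is None:
            return 0
        _, macs_pos = pconv_cost(self.spec.channels, self.spec.kernel,
                                 self.spec.split_sizes)
        return int(self.last_out_hw[0] * self.last_out_hw[1] * macs_pos)


class PConvBottleneck(Module):
    """PConv -> BN -> SiLU -> pointwise conv (channel remixing) + skip."""

    def __init__(self, rng, channels: int, shortcut: bool = True):
        super().__init__()
        self.pconv = PConvLayer(rng, PConvSpec(channels=channels))
        self.bn = BatchNorm2d(channels)
        self.pw = ConvBnAct(rng, channels, channels, k=1)
        self.shortcut = shortcut

    def forward(self, x: Tensor) -> Tensor:
        y = self.pw(ad.silu(self.bn(self.pconv(x))))
        return ad.add(x, y) if self.shortcut else y


class CSPPC(Module):
    """Drop-in replacement for the C2f block using PConv bottlenecks.

    Output spatial and channel shape match the replaced block exactly; the
    dense 3x3 pair inside each bottleneck is replaced by an equal-split
    PConv plus a 1x1 remix, cutting the bottleneck's parameter count.
    """

    def __init__(self, rng, c_in: int, c_out: int, n: int = 1,
                 shortcut: bool = True, e: float = 0.5):
        super().__init__()
        self.h = int(c_out * e)
        self.n = n
        self.cv1 = ConvBnAct(rng, c_in, 2 * self.h, k=1)
        self.m = ModuleList([PConvBottleneck(rng, self.h, shortcut)
                             for _ in range(n)])
        self.cv2 = ConvBnAct(rng, (2 + n) * self.h, c_out, k=1)

    def forward(self, x: Tensor) -> Tensor:
        y = self.cv1(x)
        parts = [ad.narrow(y, 1, 0, self.h), ad.narrow(y, 1, self.h, self.h)]
        cur = parts[-1]
        for blk in self.m:
            cur = blk(cur)
            parts.append(cur)
        return self.cv2(ad.concat(parts, axis=1))
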