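"""Feature-adaptive spatial feature fusion (FASFF) ahead of the detection heads.

The PAFPN neck emits pyramid levels P3/P4/P5 at strides 8/16/32.  FASFF
re-fuses them with *learned, per-location* convex weights instead of the
neck's fixed topology:

1. **Spatial alignment** — every level is brought to a common grid:
   coarser levels are upsampled bilinearly, finer levels are downsampled
   by strided convolution, and channel counts are matched by pointwise
   projection.
2. **Co-attention weights** — the aligned maps are concatenated along
   channels and passed through a small pointwise sub-network producing one
   logit per level per location; a softmax across levels yields weights
   alpha^l_{i,j} >= 0 with sum_l alpha^l_{i,j} = 1.
3. **Weighted fusion** — the fused map is the per-location convex
   combination F_{i,j} = sum_l alpha^l_{i,j} * P~l_{i,j}.

By default fusion is computed once per output level (each level fuses the
others aligned to its own grid), which keeps head geometry exact; a
literal single-common-grid variant (fuse on the finest grid, then resize
back to each head's resolution) is available via ``common_grid=True``.
"""

from __future__ import annotations

from typing import Dict, Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .nn import ConvBnAct, Conv2d, Module, ModuleList


class AlignedTriple:
    """Feature maps from several pyramid levels on one spatial grid."""

    def __init__(self, maps: Sequence[Tensor], target_level: int, levels: Sequence[int]):
        shapes = {m.shape[1:] for m in maps}
        if len(shapes) != 1:
            raise ValueError(f"aligned maps disagree in shape: {sorted(shapes)}")
        self.maps = list(maps)
        self.target_level = target_level
        self.levels = list(levels)

    def __iter__(self):
        return iter(self.maps)

    def __len__(self):
        return len(self.maps)


def fuse_levels(aligned: AlignedTriple, weights: Tensor) -> Tensor:
    """Per-location convex combination of the aligned maps (the fusion sum).

    ``weights`` has shape (N, L, H, W); each level's map is scaled by its
    weight channel and the results are summed.
    """
    n_levels = len(aligned)
    if weights.shape[1] != n_levels:
        raise ValueError(
            f"{weights.shape[1]} weight channels for {n_levels} levels")
    if weights.shape[2:] != aligned.maps[0].shape[2:]:
        raise ValueError("weight grid does not match the aligned grid")
    out = None
    for l in range(n_levels):
        w_l = ad.narrow(weights, 1, l, 1)  # broadcast over channels
        term = ad.mul(aligned.maps[l], w_l)
        out = term if out is None else ad.add(out, term)
    return out


class CoAttention(Module):
    """Pointwise sub-network producing softmax-normalized level weights.

    Concatenated aligned features -> 1x1 conv to (levels * r) hidden
    channels -> SiLU -> 1x1 conv to one logit per level -> softmax across
    levels.  Zero-initialized logits give the uniform 1/L weighting.
    """

    def __init__(self, rng, c_in_total: int, n_levels: int, r: int = 8):
        super().__init__()
        hidden = n_levels * r
        self.n_levels = n_levels
        self.reduce = ConvBnAct(rng, c_in_total, hidden, k=1)
        self.logits = Conv2d(rng, hidden, n_levels, k=1, bias=True)

    def forward(self, aligned: AlignedTriple) -> Tensor:
        z = ad.concat(list(aligned), axis=1)
        raw = self.logits(self.reduce(z))
        return ad.softmax(raw, axis=1)


class LevelAligner(Module):
    """Resample+project every pyramid level onto one target level's grid."""

    def __init__(self, rng, channels: Dict[int, int], target_level: int):
        super().__init__()
        self.levels = sorted(channels)
        self.target_level = target_level
        c_tgt = channels[target_level]
        for l in self.levels:
            if l == target_level:
                proj = ConvBnAct(rng, channels[l], c_tgt, k=1)
            elif l > target_level:  # coarser: project then bilinear upsample
                proj = ConvBnAct(rng, channels[l], c_tgt, k=1)
            else:  # finer: strided 3x3 convs, one per octave
                steps = ModuleList()
                c = channels[l]
                for _ in range(l, target_level):
                    steps.append(ConvBnAct(rng, c, c_tgt, k=3, stride=2))
                    c = c_tgt
                proj = steps
            setattr(self, f"align{l}", proj)

    def forward(self, pyramid: Dict[int, Tensor]) -> AlignedTriple:
        missing = [l for l in self.levels if l not in pyramid]
        if missing:
            raise KeyError(f"pyramid is missing levels {missing}")
        maps = []
        for l in self.levels:
            x = pyramid[l]
            mod = getattr(self, f"align{l}")
            if l == self.target_level:
                maps.append(mod(x))
            elif l > self.target_level:
                maps.append(ad.upsample_bilinear(mod(x), 2 ** (l - self.target_level)))
            else:
                for step in mod:
                    x = step(x)
                maps.append(x)
        return AlignedTriple(maps, self.target_level, self.levels)


class FASFF(Module):
    """Full fusion stage: one aligner + co-attention per output level."""

    def __init__(self, rng, channels: Dict[int, int], common_grid: bool = False):
        super().__init__()
        self.levels = sorted(channels)
        self.channels = dict(channels)
        self.common_grid = common_grid
        self.last_weights: Dict[int, np.ndarray] = {}  # inspection hook
        targets = [min(self.levels)] if common_grid else self.levels
        for l in targets:
            setattr(self, f"aligner{l}", LevelAligner(rng, channels, l))
            setattr(self, f"attn{l}",
                    CoAttention(rng, channels[l] * len(self.levels), len(self.levels)))

    def fuse_at(self, pyramid: Dict[int, Tensor], target_level: int):
        aligned = getattr(self, f"aligner{target_level}")(pyramid)
        weights = getattr(self, f"attn{target_level}")(aligned)
        self.last_weights[target_level] = weights.data
        return fuse_levels(aligned, weights), weights

    def forward(self, pyramid: Dict[int, Tensor]) -> Dict[int, Tensor]:
        if self.common_grid:
            base = min(self.levels)
            fused, _ = self.fuse_at(pyramid, base)
            out = {}
            for l in self.levels:
                if l == base:
                    out[l] = fused
                else:
                    # redistribute: strided 2x2-mean pooling back to level l
                    f = 2 ** (l - base)
                    n, c, h, w = fused.shape
                    pooled = ad.reshape(fused, (n, c, h // f, f, w // f, f))
                    pooled = ad.tmean(pooled, axis=(3, 5))
                    out[l] = pooled
            return out
        return {l: self.fuse_at(pyramid, l)[0] for l in self.levels}


# -- functional views matching the operation-level contracts ---------------

def align_levels(aligner: LevelAligner, pyramid: Dict[int, Tensor]) -> AlignedTriple:
    return aligner(pyramid)


def co_attention(attn: CoAttention, aligned: AlignedTriple) -> Tensor:
    return attn(aligned)


def fasff_forward(fasff: FASFF, pyramid: Dict[int, Tensor]) -> Dict[int, Tensor]:
    return fasff(pyramid)
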