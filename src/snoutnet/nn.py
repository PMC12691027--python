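"""Layer/module framework on top of :mod:`snoutnet.autodiff`.

Mirrors the familiar module-tree idiom: layers register parameters and
child modules by attribute assignment, ``named_parameters`` walks the tree,
and ``state_dict``/``load_state_dict`` serialize to plain numpy arrays.

Convolutions that are followed by a normalization layer carry no bias
term; the parameter audit in :mod:`snoutnet.model` relies on that
convention.
"""

from __future__ import annotations

import math
from typing import Dict, Iterator, Tuple

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = "") -> Iterator[Tuple[str, Parameter]]:
        for name, p in self._params.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = "") -> Iterator[Tuple[str, np.ndarray]]:
        for name, b in self._buffers.items():
            yield prefix + name, b
        for name, m in self._modules.items():
            yield from m.named_buffers(prefix + name + ".")

    def named_modules(self, prefix: str = ""):
        yield prefix.rstrip("."), self
        for name, m in self._modules.items():
            yield from m.named_modules(prefix + name + ".")

    def train(self, mode: bool = True):
        object.__setattr__(self, "training", mode)
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def num_params(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_dict(self) -> Dict[str, np.ndarray]:
        out = {n: p.data.copy() for n, p in self.named_parameters()}
        out.update({"buffer:" + n: b.copy() for n, b in self.named_buffers()})
        return out

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        for key, value in state.items():
            if key.startswith("buffer:"):
                buf = buffers[key[len("buffer:"):]]
                buf[...] = value
            else:
                params[key].data[...] = np.asarray(value, dtype=np.float32)

    def param_checksum(self) -> float:
        return float(sum(float(np.abs(p.data).sum()) for p in self.parameters()))

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self._list = []
        for m in mods:
            self.append(m)

    def append(self, m: Module):
        setattr(self, str(len(self._list)), m)
        self._list.append(m)
        return self

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]


def _kaiming(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = math.sqrt(2.0) / math.sqrt(fan_in)
    return rng.normal(0.0, bound, size=shape).astype(np.float32)


class Conv2d(Module):
    """Plain convolution; bias only when not followed by a norm layer."""

    def __init__(self, rng, c_in, c_out, k=1, stride=1, padding=None,
                 groups=1, bias=True, zero_init=False):
        super().__init__()
        self.stride = stride
        self.padding = (k // 2) if padding is None else padding
        self.groups = groups
        self.c_in, self.c_out, self.k = c_in, c_out, k
        fan_in = (c_in // groups) * k * k
        w = np.zeros((c_out, c_in // groups, k, k), dtype=np.float32) if zero_init \
            else _kaiming(rng, (c_out, c_in // groups, k, k), fan_in)
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(c_out, dtype=np.float32)) if bias else None
        self.last_out_hw = None  # recorded for the FLOPs audit

    def forward(self, x: Tensor) -> Tensor:
        out = ad.conv2d(x, self.weight, self.bias, stride=self.stride,
                        padding=self.padding, groups=self.groups)
        self.last_out_hw = out.shape[2:]
        return out

    def macs(self) -> int:
        """Multiply–accumulates for the most recent forward pass."""
        if self.last_out_hw is None:
            return 0
        ho, wo = self.last_out_hw
        return int(ho * wo * self.c_out * (self.c_in // self.groups) * self.k * self.k)


class BatchNorm2d(Module):
    def __init__(self, channels, momentum=0.1, eps=1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.weight = Parameter(np.ones(channels, dtype=np.float32))
        self.bias = Parameter(np.zeros(channels, dtype=np.float32))
        self._buffers["running_mean"] = np.zeros(channels, dtype=np.float32)
        self._buffers["running_var"] = np.ones(channels, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        return ad.batchnorm2d(
            x, self.weight, self.bias,
            self._buffers["running_mean"], self._buffers["running_var"],
            training=self.training, momentum=self.momentum, eps=self.eps)


class ConvBnAct(Module):
    """Conv → BatchNorm → SiLU, the detector's basic unit (bias-free conv)."""

    def __init__(self, rng, c_in, c_out, k=1, stride=1, padding=None,
                 groups=1, act=True):
        super().__init__()
        self.conv = Conv2d(rng, c_in, c_out, k, stride, padding, groups, bias=False)
        self.bn = BatchNorm2d(c_out)
        self.act = act

    def forward(self, x: Tensor) -> Tensor:
        y = self.bn(self.conv(x))
        return ad.silu(y) if self.act else y


class AdamW:
    """Decoupled-weight-decay Adam.

    Weight decay is skipped for 1-D parameters (norm scales/shifts and
    biases), matching common detector training practice.
    """

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8,
                 weight_decay=0.05):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            if self.weight_decay and p.data.ndim > 1:
                p.data *= (1.0 - self.lr * self.weight_decay)
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def clip_grad_norm(params, max_norm: float) -> float:
    """Global-norm gradient clipping; returns the pre-clip norm."""
    total = 0.0
    grads = [p.grad for p in params if p.grad is not None]
    for g in grads:
        total += float((g * g).sum())
    norm = math.sqrt(total)
    if norm > max_norm and norm > 0:
        scale = max_norm / norm
        for g in grads:
            g *= scale
    return norm
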