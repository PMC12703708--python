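"""Module/parameter containers and the standard layers used by the detector."""

from __future__ import annotations

import pickle

import numpy as np

from . import functional as F
from .tensor import Tensor

__all__ = ["Parameter", "Module", "Conv2d", "Conv1dSeq", "Linear", "BatchNorm2d",
           "GroupNorm2d", "ReLU", "Sequential", "Identity"]

DTYPE = np.float32


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=DTYPE), requires_grad=True)


class Module:
    """Minimal module container: parameter discovery, train/eval mode, state dict."""

    def __init__(self):
        self.training = True

    def modules(self):
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def parameters(self):
        seen = set()
        for m in self.modules():
            for k, v in m.__dict__.items():
                if isinstance(v, Parameter) and id(v) not in seen:
                    seen.add(id(v))
                    yield v

    def named_parameters(self, prefix=""):
        for m_name, m in self._named_modules(prefix):
            for k, v in m.__dict__.items():
                if isinstance(v, Parameter):
                    yield (f"{m_name}.{k}" if m_name else k), v

    def _named_modules(self, prefix=""):
        yield prefix, self
        for k, v in self.__dict__.items():
            name = f"{prefix}.{k}" if prefix else k
            if isinstance(v, Module):
                yield from v._named_modules(name)
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item._named_modules(f"{name}.{i}")

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # ---------------------------------------------------------- persistence
    def state_dict(self) -> dict:
        state = {k: v.data.copy() for k, v in self.named_parameters()}
        for name, m in self._named_modules():
            if isinstance(m, BatchNorm2d):
                state[f"{name}._running_mean"] = m.running["mean"].copy()
                state[f"{name}._running_var"] = m.running["var"].copy()
        return state

    def load_state_dict(self, state: dict):
        params = dict(self.named_parameters())
        for k, v in state.items():
            if k.endswith("._running_mean") or k.endswith("._running_var"):
                continue
            params[k].data[...] = v
        for name, m in self._named_modules():
            if isinstance(m, BatchNorm2d):
                m.running["mean"][...] = state[f"{name}._running_mean"]
                m.running["var"][...] = state[f"{name}._running_var"]

    def save(self, path):
        with open(path, "wb") as fh:
            pickle.dump(self.state_dict(), fh)

    def load(self, path):
        with open(path, "rb") as fh:
            self.load_state_dict(pickle.load(fh))

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _kaiming(rng, fan_in, shape):
    std = np.sqrt(2.0 / fan_in)
    return (rng.standard_normal(shape) * std).astype(DTYPE)


class Conv2d(Module):
    def __init__(self, cin, cout, k, stride=1, pad=None, bias=True, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.stride = stride
        self.pad = (k // 2) if pad is None else pad
        self.weight = Parameter(_kaiming(rng, cin * k * k, (cout, cin, k, k)))
        self.bias = Parameter(np.zeros(cout)) if bias else None

    def forward(self, x):
        return F.conv2d(x, self.weight, self.bias, stride=self.stride, pad=self.pad)


class Conv1dSeq(Module):
    """Convolution along a point sequence (B, C, N)."""

    def __init__(self, cin, cout, k=3, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.pad = k // 2
        self.weight = Parameter(_kaiming(rng, cin * k, (cout, cin, k)))
        self.bias = Parameter(np.zeros(cout))

    def forward(self, x):
        return F.conv1d_seq(x, self.weight, self.bias, pad=self.pad)


class Linear(Module):
    def __init__(self, cin, cout, rng=None, zero_init=False):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        if zero_init:
            self.weight = Parameter(np.zeros((cout, cin)))
        else:
            self.weight = Parameter(_kaiming(rng, cin, (cout, cin)))
        self.bias = Parameter(np.zeros(cout))

    def forward(self, x):
        return F.linear(x, self.weight, self.bias)


class BatchNorm2d(Module):
    def __init__(self, c, momentum=0.1, eps=1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(c))
        self.beta = Parameter(np.zeros(c))
        self.momentum = momentum
        self.eps = eps
        self.running = {"mean": np.zeros(c, dtype=DTYPE), "var": np.ones(c, dtype=DTYPE)}

    def forward(self, x):
        return F.batchnorm(x, self.gamma, self.beta, self.running,
                           self.training, self.momentum, self.eps)


class GroupNorm2d(Module):
    """Group normalization with per-channel affine; statistics are computed
    per sample, so behavior is identical in train and eval mode."""

    def __init__(self, c, groups=None, eps=1e-5):
        super().__init__()
        self.groups = min(8, c) if groups is None else groups
        while c % self.groups:
            self.groups -= 1
        self.gamma = Parameter(np.ones(c))
        self.beta = Parameter(np.zeros(c))
        self.eps = eps

    def forward(self, x):
        return F.groupnorm(x, self.gamma, self.beta, self.groups, self.eps)


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class Identity(Module):
    def forward(self, x):
        return x


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self.mods = list(mods)

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x
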