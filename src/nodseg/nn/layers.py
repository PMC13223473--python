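"""Neural-network layers built on the autodiff core.

Layers follow the familiar Module convention: parameters are registered by
attribute assignment, ``parameters()`` walks the tree, ``state_dict()`` /
``load_state_dict()`` move weights in and out as plain arrays, and
``train()`` / ``eval()`` toggle BatchNorm and Dropout behaviour.
"""

from __future__ import annotations

import math
from collections import OrderedDict

import numpy as np

from .autograd import Tensor, conv1d, conv3d


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", OrderedDict())
        object.__setattr__(self, "_modules", OrderedDict())
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield (prefix + name, p)
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # -- serialization -----------------------------------------------------
    def _buffers(self):
        """Override in layers with non-parameter state (e.g. BN running stats)."""
        return {}

    def state_dict(self, prefix: str = "", out=None):
        if out is None:
            out = OrderedDict()
        for name, p in self._params.items():
            out[prefix + name] = p.data.copy()
        for name, b in self._buffers().items():
            out[prefix + name] = np.array(b, copy=True)
        for name, m in self._modules.items():
            m.state_dict(prefix + name + ".", out)
        return out

    def load_state_dict(self, state, prefix: str = ""):
        for name, p in self._params.items():
            p.data = np.array(state[prefix + name], dtype=np.float32, copy=True)
        for name in self._buffers():
            arr = np.array(state[prefix + name], dtype=np.float32, copy=True)
            object.__setattr__(self, name, arr)
        for name, m in self._modules.items():
            m.load_state_dict(state, prefix + name + ".")


class Identity(Module):
    def forward(self, x):
        return x


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            setattr(self, f"m{i}", layer)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


def _kaiming(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    std = math.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(np.float32)


class Conv3d(Module):
    """Stride-1 3D convolution with 'same' padding for odd kernels."""

    def __init__(self, in_channels, out_channels, kernel_size, *, dilation=1,
                 groups=1, bias=True, padding="same", rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        k = kernel_size if isinstance(kernel_size, tuple) else (kernel_size,) * 3
        d = dilation if isinstance(dilation, tuple) else (dilation,) * 3
        if padding == "same":
            if any(ki % 2 == 0 for ki in k):
                raise ValueError(f"'same' padding requires odd kernel, got {k}")
            padding = tuple(di * (ki - 1) // 2 for ki, di in zip(k, d))
        self.dilation = d
        self.padding = padding
        self.groups = groups
        fan_in = (in_channels // groups) * int(np.prod(k))
        self.weight = Parameter(_kaiming(rng, (out_channels, in_channels // groups) + k, fan_in))
        self.bias = Parameter(np.zeros(out_channels, dtype=np.float32)) if bias else None

    def forward(self, x):
        return conv3d(x, self.weight, self.bias, dilation=self.dilation,
                      padding=self.padding, groups=self.groups)


class Conv1d(Module):
    def __init__(self, in_channels, out_channels, kernel_size, *, bias=True,
                 padding="same", rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        if padding == "same":
            if kernel_size % 2 == 0:
                raise ValueError("'same' padding requires odd kernel")
            padding = (kernel_size - 1) // 2
        self.padding = padding
        fan_in = in_channels * kernel_size
        self.weight = Parameter(_kaiming(rng, (out_channels, in_channels, kernel_size), fan_in))
        self.bias = Parameter(np.zeros(out_channels, dtype=np.float32)) if bias else None

    def forward(self, x):
        return conv1d(x, self.weight, self.bias, padding=self.padding)


class Linear(Module):
    def __init__(self, in_features, out_features, *, bias=True, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.weight = Parameter(_kaiming(rng, (in_features, out_features), in_features))
        self.bias = Parameter(np.zeros(out_features, dtype=np.float32)) if bias else None

    def forward(self, x):
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class BatchNorm3d(Module):
    """Per-channel normalization over (N, D, H, W) with running statistics."""

    def __init__(self, num_features, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(num_features, dtype=np.float32))
        self.beta = Parameter(np.zeros(num_features, dtype=np.float32))
        self.running_mean = np.zeros(num_features, dtype=np.float32)
        self.running_var = np.ones(num_features, dtype=np.float32)

    def _buffers(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}

    def forward(self, x):
        if self.training:
            from .autograd import batchnorm_train
            out, mean, var = batchnorm_train(x, self.gamma, self.beta, self.eps)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean
                                 + m * mean).astype(np.float32)
            self.running_var = ((1 - m) * self.running_var
                                + m * var).astype(np.float32)
            return out
        shape = (1, -1, 1, 1, 1)
        mean = self.running_mean.reshape(shape)
        scale = self.gamma.reshape(shape) * (1.0 / np.sqrt(
            self.running_var.reshape(shape) + self.eps))
        return (x - mean) * scale + self.beta.reshape(shape)


class Dropout3d(Module):
    """Channel-wise dropout on (N, C, D, H, W); identity in eval mode."""

    def __init__(self, p: float = 0.1, rng=None):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {p}")
        self.p = p
        self.rng = rng or np.random.default_rng()

    def forward(self, x):
        if not self.training or self.p == 0.0:
            return x
        n, c = x.shape[:2]
        keep = (self.rng.random((n, c, 1, 1, 1)) >= self.p).astype(np.float32)
        return x * (keep / (1.0 - self.p))


class ReLU(Module):
    def forward(self, x):
        return x.relu()
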