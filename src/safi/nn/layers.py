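"""Neural-network modules built on the autograd engine."""
from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from . import autograd as ag
from .autograd import Parameter, Tensor

__all__ = [
    "Module", "Sequential", "Identity", "Conv2d", "BatchNorm2d", "GroupNorm",
    "SiLU", "ReLU", "ReLU6", "Upsample2x", "MaxPool2d", "Scale",
]


class Module:
    """Minimal module base: tracks sub-modules and parameters by attribute."""

    def __init__(self):
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name, value: np.ndarray):
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def modules(self) -> Iterator["Module"]:
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def named_parameters(self, prefix="") -> Iterator[tuple[str, Parameter]]:
        for n, p in self._params.items():
            yield f"{prefix}{n}", p
        for mn, m in self._modules.items():
            yield from m.named_parameters(prefix=f"{prefix}{mn}.")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def train(self, mode: bool = True):
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self, prefix="") -> dict:
        out = {}
        for n, p in self._params.items():
            out[f"{prefix}{n}"] = p.data
        for n, b in self._buffers.items():
            out[f"{prefix}{n}"] = self._buffers[n]
        for mn, m in self._modules.items():
            out.update(m.state_dict(prefix=f"{prefix}{mn}."))
        return out

    def load_state_dict(self, sd: dict, prefix=""):
        for n, p in self._params.items():
            p.data[...] = sd[f"{prefix}{n}"]
        for n in list(self._buffers):
            val = np.asarray(sd[f"{prefix}{n}"])
            self._buffers[n][...] = val
        for mn, m in self._modules.items():
            m.load_state_dict(sd, prefix=f"{prefix}{mn}.")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        self.mods = list(mods)
        for i, m in enumerate(mods):
            self._modules[str(i)] = m

    def __iter__(self):
        return iter(self.mods)

    def __getitem__(self, i):
        return self.mods[i]

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x


class Identity(Module):
    def __init__(self):
        super().__init__()

    def forward(self, x):
        return x


class Conv2d(Module):
    """2-D convolution with He-uniform init (matches common detector inits)."""

    def __init__(self, in_channels, out_channels, kernel_size, stride=1,
                 padding=None, groups=1, bias=True, rng=None):
        super().__init__()
        if in_channels % groups or out_channels % groups:
            raise ValueError("channels must be divisible by groups")
        k = kernel_size
        if padding is None:
            padding = k // 2  # 'same' for odd kernels at stride 1
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = k
        self.stride = stride
        self.padding = padding
        self.groups = groups
        rng = rng or np.random.default_rng()
        fan_in = (in_channels // groups) * k * k
        bound = 1.0 / math.sqrt(fan_in)
        self.weight = Parameter(rng.uniform(-bound, bound,
                                            (out_channels, in_channels // groups, k, k)))
        self.bias = Parameter(rng.uniform(-bound, bound, (out_channels,))) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        from .profile import record_conv
        out = ag.conv2d(x, self.weight, self.bias, self.stride, self.padding, self.groups)
        record_conv(self, out.shape)
        return out


class BatchNorm2d(Module):
    def __init__(self, num_features, eps=1e-5, momentum=0.03):
        super().__init__()
        self.num_features = num_features
        self.eps = eps
        self.momentum = momentum
        self.weight = Parameter(np.ones(num_features))
        self.bias = Parameter(np.zeros(num_features))
        self.register_buffer("running_mean", np.zeros(num_features, dtype=np.float32))
        self.register_buffer("running_var", np.ones(num_features, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        if self.training and ag.is_grad_enabled():
            out, mu, var = ag.batch_norm_train(x, self.weight, self.bias, self.eps)
            self.running_mean += self.momentum * (mu - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
            return out
        return ag.batch_norm_eval(x, self.weight, self.bias,
                                  self.running_mean, self.running_var, self.eps)


class GroupNorm(Module):
    def __init__(self, num_groups, num_channels, eps=1e-5):
        super().__init__()
        if num_channels % num_groups:
            raise ValueError("channels must be divisible by num_groups")
        self.num_groups = num_groups
        self.num_channels = num_channels
        self.eps = eps
        self.weight = Parameter(np.ones(num_channels))
        self.bias = Parameter(np.zeros(num_channels))

    def forward(self, x: Tensor) -> Tensor:
        return ag.group_norm(x, self.weight, self.bias, self.num_groups, self.eps)


class SiLU(Module):
    def __init__(self):
        super().__init__()

    def forward(self, x):
        return x.silu()


class ReLU(Module):
    def __init__(self):
        super().__init__()

    def forward(self, x):
        return x.relu()


class ReLU6(Module):
    """Bounded activation used on one multiplicative branch of star blocks."""

    def __init__(self):
        super().__init__()

    def forward(self, x):
        return x.relu6()


class Upsample2x(Module):
    def __init__(self):
        super().__init__()

    def forward(self, x):
        return ag.upsample_nearest2x(x)


class MaxPool2d(Module):
    def __init__(self, kernel_size, stride=1, padding=0):
        super().__init__()
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding

    def forward(self, x):
        return ag.max_pool2d(x, self.kernel_size, self.stride, self.padding)


class Scale(Module):
    """Single learnable scalar multiplier (per-level regression scaling)."""

    def __init__(self, init=1.0):
        super().__init__()
        self.scale = Parameter(np.array([init]))

    def forward(self, x):
        return x * self.scale.astype(x.dtype)
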