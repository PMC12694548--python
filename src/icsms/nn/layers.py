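"""Neural-network modules over the autodiff core.

Conventions follow the mobile-CNN literature: convolutions are bias-free when
followed by batch norm, batch-norm affine parameters are trainable, running
statistics are buffers (not parameters, not counted in budgets).
"""

from __future__ import annotations

import numpy as np

from . import core
from .core import Tensor


class Module:
    """Minimal module tree with parameter traversal and train/eval mode."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        elif isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield f"{prefix}{name}", p
        for mname, m in self._modules.items():
            yield from m.named_parameters(f"{prefix}{mname}.")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, m in self._named_modules():
            if isinstance(m, BatchNorm2d):
                state[f"{name}.running_mean"] = m.running_mean.copy()
                state[f"{name}.running_var"] = m.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]):
        params = dict(self.named_parameters())
        for name, p in params.items():
            if name not in state:
                raise KeyError(f"missing parameter {name}")
            if state[name].shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = np.asarray(state[name], dtype=np.float32).copy()
        for name, m in self._named_modules():
            if isinstance(m, BatchNorm2d):
                m.running_mean = np.asarray(
                    state[f"{name}.running_mean"], dtype=np.float32).copy()
                m.running_var = np.asarray(
                    state[f"{name}.running_var"], dtype=np.float32).copy()

    def _named_modules(self, prefix: str = ""):
        yield prefix.rstrip("."), self
        for mname, m in self._modules.items():
            yield from m._named_modules(f"{prefix}{mname}.")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        self.mods = list(mods)
        for i, m in enumerate(mods):
            setattr(self, f"m{i}", m)

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x

    def __iter__(self):
        return iter(self.mods)

    def __getitem__(self, i):
        return self.mods[i]


class Identity(Module):
    def forward(self, x):
        return x


def _kaiming_uniform(rng: np.random.Generator, shape, fan_in: int):
    bound = float(np.sqrt(6.0 / fan_in))
    return rng.uniform(-bound, bound, size=shape).astype(np.float32)


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 stride: int = 1, padding: int = 0, groups: int = 1,
                 bias: bool = True, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.in_channels, self.out_channels = in_channels, out_channels
        self.kernel, self.stride, self.padding = kernel, stride, padding
        self.groups = groups
        cig = in_channels // groups
        self.weight = Tensor(_kaiming_uniform(
            rng, (out_channels, cig, kernel, kernel), cig * kernel * kernel),
            requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels, dtype=np.float32),
                           requires_grad=True) if bias else None

    def forward(self, x):
        return core.conv2d(x, self.weight, self.bias, self.stride,
                           self.padding, self.groups)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.in_features, self.out_features = in_features, out_features
        self.weight = Tensor(
            (rng.standard_normal((in_features, out_features)) * 0.01
             ).astype(np.float32), requires_grad=True)
        self.bias = Tensor(np.zeros(out_features, dtype=np.float32),
                           requires_grad=True) if bias else None

    def forward(self, x):
        out = core.matmul(x, self.weight)
        if self.bias is not None:
            out = core.add(out, self.bias)
        return out


class BatchNorm2d(Module):
    def __init__(self, num_features: int, momentum: float = 0.1,
                 eps: float = 1e-5):
        super().__init__()
        self.num_features = num_features
        self.momentum, self.eps = momentum, eps
        self.weight = Tensor(np.ones(num_features, dtype=np.float32),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(num_features, dtype=np.float32),
                           requires_grad=True)
        self.running_mean = np.zeros(num_features, dtype=np.float32)
        self.running_var = np.ones(num_features, dtype=np.float32)

    def forward(self, x):
        return core.batch_norm2d(x, self.weight, self.bias, self.running_mean,
                                 self.running_var, self.training,
                                 self.momentum, self.eps)


class ReLU(Module):
    def forward(self, x):
        return core.relu(x)


class ReLU6(Module):
    def forward(self, x):
        return core.relu6(x)


class HardSwish(Module):
    def forward(self, x):
        return core.hard_swish(x)


class HardSigmoid(Module):
    def forward(self, x):
        return core.hard_sigmoid(x)


class Sigmoid(Module):
    def forward(self, x):
        return core.sigmoid(x)


class Dropout(Module):
    """Inverted dropout; a per-module RNG keeps training runs reproducible."""

    def __init__(self, p: float = 0.2, seed: int = 0):
        super().__init__()
        self.p = p
        self.rng = np.random.default_rng(seed)

    def forward(self, x):
        if not self.training or self.p <= 0.0:
            return x
        mask = (self.rng.random(x.shape) >= self.p).astype(np.float32)
        return core.mul(x, mask / (1.0 - self.p))


class MaxPool2d(Module):
    def __init__(self, kernel: int, stride: int | None = None,
                 padding: int = 0):
        super().__init__()
        self.kernel, self.stride, self.padding = kernel, stride, padding

    def forward(self, x):
        return core.max_pool2d(x, self.kernel, self.stride, self.padding)


class GlobalAvgPool(Module):
    """(N, C, H, W) -> (N, C)."""

    def forward(self, x):
        return core.mean(x, axis=(2, 3))


class AvgPool2d(Module):
    def __init__(self, kernel: int):
        super().__init__()
        self.kernel = kernel

    def forward(self, x):
        return core.avg_pool2d(x, self.kernel)


class ConvBNAct(Module):
    """conv -> batch norm -> activation, the mobile-net building idiom."""

    def __init__(self, cin: int, cout: int, kernel: int, stride: int = 1,
                 groups: int = 1, act: Module | None = None,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.conv = Conv2d(cin, cout, kernel, stride, kernel // 2,
                           groups=groups, bias=False, rng=rng)
        self.bn = BatchNorm2d(cout)
        self.act = act if act is not None else Identity()

    def forward(self, x):
        return self.act(self.bn(self.conv(x)))


def count_parameters(module: Module) -> int:
    """Number of trainable scalars (running BN statistics excluded)."""
    return int(sum(p.data.size for p in module.parameters()))
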