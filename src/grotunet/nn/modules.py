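"""Layer building blocks on top of the autodiff core.

Modules own their parameters (``Tensor`` with ``requires_grad=True``) and
non-trainable buffers (running batch-norm statistics).  Parameter traversal
is name-based so checkpoints are stable dictionaries.
"""

from __future__ import annotations

import numpy as np

from . import tensor as T
from .tensor import Tensor


class Module:
    def __init__(self):
        self.training = True

    # -- traversal -----------------------------------------------------------
    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            if isinstance(val, Tensor) and val.requires_grad:
                yield prefix + name, val
            elif isinstance(val, Module):
                yield from val.named_parameters(prefix + name + ".")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{prefix}{name}.{i}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        for name, val in vars(self).items():
            if isinstance(val, Tensor) and not val.requires_grad:
                yield prefix + name, val
            elif isinstance(val, Module):
                yield from val.named_buffers(prefix + name + ".")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_buffers(f"{prefix}{name}.{i}.")

    def modules(self):
        yield self
        for val in vars(self).values():
            if isinstance(val, Module):
                yield from val.modules()
            elif isinstance(val, (list, tuple)):
                for item in val:
                    if isinstance(item, Module):
                        yield from item.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        d = {name: p.data.copy() for name, p in self.named_parameters()}
        d.update({"buffer:" + name: b.data.copy() for name, b in self.named_buffers()})
        return d

    def load_state_dict(self, d: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        own.update({"buffer:" + n: b for n, b in self.named_buffers()})
        missing = set(own) - set(d)
        extra = set(d) - set(own)
        if missing or extra:
            raise ValueError(f"state dict mismatch: missing={sorted(missing)[:5]}, extra={sorted(extra)[:5]}")
        for name, arr in d.items():
            if own[name].data.shape != arr.shape:
                raise ValueError(f"shape mismatch for {name}: {own[name].data.shape} vs {arr.shape}")
            own[name].data = arr.astype(np.float32).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    """Cross-correlation with 'same'-style padding chosen by kernel shape."""

    def __init__(self, cin: int, cout: int, kernel, stride: int = 1,
                 bias: bool = True, rng: np.random.Generator | None = None):
        super().__init__()
        kh, kw = (kernel, kernel) if isinstance(kernel, int) else kernel
        rng = rng or np.random.default_rng(0)
        fan_in = cin * kh * kw
        std = np.sqrt(2.0 / fan_in)
        self.weight = Tensor(rng.normal(0.0, std, (cout, cin, kh, kw)).astype(np.float32), requires_grad=True)
        self.bias = Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True) if bias else None
        self.stride = (stride, stride)
        # pad only along an axis where the kernel extends (asymmetric 1x3/3x1
        # kernels pad along their long axis only)
        self.padding = (kh // 2, kw // 2)

    def forward(self, x: Tensor) -> Tensor:
        return T.conv2d(x, self.weight, self.bias, self.stride, self.padding)


class BatchNorm2d(Module):
    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.gamma = Tensor(np.ones(c, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(c, dtype=np.float32), requires_grad=True)
        self.running_mean = Tensor(np.zeros(c, dtype=np.float32))
        self.running_var = Tensor(np.ones(c, dtype=np.float32))
        self.eps = eps
        self.momentum = momentum

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            y, mu, var = T.batchnorm2d(x, self.gamma, self.beta, self.eps)
            m = self.momentum
            self.running_mean.data = ((1 - m) * self.running_mean.data + m * mu).astype(np.float32)
            self.running_var.data = ((1 - m) * self.running_var.data + m * var).astype(np.float32)
            return y
        inv = (self.running_var.data + self.eps) ** -0.5
        scale = self.gamma * Tensor(inv.astype(np.float32))
        shift = self.beta - scale * Tensor(self.running_mean.data)
        return x * scale.reshape(1, -1, 1, 1) + shift.reshape(1, -1, 1, 1)


class ConvBN(Module):
    """Conv (no bias) + batch norm; optional ReLU."""

    def __init__(self, cin, cout, kernel, stride=1, relu=False, rng=None):
        super().__init__()
        self.conv = Conv2d(cin, cout, kernel, stride=stride, bias=False, rng=rng)
        self.bn = BatchNorm2d(cout)
        self.act = relu

    def forward(self, x: Tensor) -> Tensor:
        y = self.bn(self.conv(x))
        return T.relu(y) if self.act else y


class Linear(Module):
    def __init__(self, din: int, dout: int, bias: bool = True,
                 rng: np.random.Generator | None = None, std: float | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        std = std if std is not None else np.sqrt(1.0 / din)
        self.weight = Tensor(rng.normal(0.0, std, (din, dout)).astype(np.float32), requires_grad=True)
        self.bias = Tensor(np.zeros(dout, dtype=np.float32), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-6):
        super().__init__()
        self.gamma = Tensor(np.ones(d, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(d, dtype=np.float32), requires_grad=True)
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2.0).mean(axis=-1, keepdims=True)
        xhat = (x - mu) * ((var + self.eps) ** -0.5)
        return xhat * self.gamma + self.beta


class MLP(Module):
    """Two-layer perceptron with ReLU, used inside attention layers."""

    def __init__(self, d: int, hidden: int, rng=None):
        super().__init__()
        self.fc1 = Linear(d, hidden, rng=rng)
        self.fc2 = Linear(hidden, d, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc2(T.relu(self.fc1(x)))
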