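"""Neural-network layers built on the autograd engine.

Layers follow the familiar module pattern: parameters are :class:`Tensor`
objects with ``requires_grad=True``; ``train()`` / ``eval()`` toggles batch
statistics and dropout.  Initialisation draws from a ``numpy.random
.Generator`` passed in explicitly, so a whole model is a pure function of
its seed.
"""

from __future__ import annotations

import math

import numpy as np

from .autograd import Tensor

__all__ = ["Module", "Conv2d", "BatchNorm2d", "Linear", "Dropout", "AvgPool2d"]


class Module:
    """Minimal base: parameter discovery, mode switching, state dicts."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def named_modules(self, prefix: str = "") -> list[tuple[str, "Module"]]:
        out = [(prefix or self.__class__.__name__, self)]
        for k, v in self.__dict__.items():
            sub = f"{prefix}.{k}" if prefix else k
            if isinstance(v, Module):
                out.extend(v.named_modules(sub))
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        out.extend(item.named_modules(f"{sub}[{i}]"))
        return out

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for _, m in self.named_modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    # -- checkpointing -----------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for name, m in self.named_modules():
            for k, v in m.__dict__.items():
                if isinstance(v, Tensor):
                    state[f"{name}.{k}"] = v.data.copy()
                elif isinstance(v, np.ndarray):  # running stats
                    state[f"{name}.{k}"] = v.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, m in self.named_modules():
            for k, v in m.__dict__.items():
                key = f"{name}.{k}"
                if key in state:
                    if isinstance(v, Tensor):
                        v.data = state[key].copy()
                    elif isinstance(v, np.ndarray):
                        setattr(m, k, state[key].copy())

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _glorot(rng: np.random.Generator, shape, fan_in, fan_out) -> np.ndarray:
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: tuple[int, int],
                 rng: np.random.Generator, padding: tuple[int, int] = (0, 0),
                 groups: int = 1, bias: bool = True, init_scale: float | None = None):
        super().__init__()
        if in_channels % groups or out_channels % groups:
            raise ValueError("groups must divide both channel counts")
        kh, kw = kernel_size
        self.padding = padding
        self.groups = groups
        fan_in = (in_channels // groups) * kh * kw
        fan_out = (out_channels // groups) * kh * kw
        w = _glorot(rng, (out_channels, in_channels // groups, kh, kw), fan_in, fan_out)
        if init_scale is not None:
            # near-zero start, e.g. the electrode-mixing layer
            w = (init_scale * rng.standard_normal(w.shape)).astype(np.float32)
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels, dtype=np.float32), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, padding=self.padding, groups=self.groups)


class BatchNorm2d(Module):
    """Per-feature-channel batch normalisation over (batch, height, width)."""

    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Tensor(np.ones(num_features, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(num_features, dtype=np.float32), requires_grad=True)
        self.running_mean = np.zeros(num_features, dtype=np.float32)
        self.running_var = np.ones(num_features, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        C = x.shape[1]
        if self.training:
            mean = x.mean(axis=(0, 2, 3), keepdims=True)
            centered = x - mean
            var = (centered * centered).mean(axis=(0, 2, 3), keepdims=True)
            n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
            unbiased = var.data.reshape(C) * (n / max(n - 1, 1))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean.data.reshape(C)).astype(np.float32)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * unbiased).astype(np.float32)
            inv = (var + Tensor(np.float32(self.eps))).pow(-0.5)
            xhat = centered * inv
        else:
            mean = self.running_mean.reshape(1, C, 1, 1)
            std = np.sqrt(self.running_var + self.eps).reshape(1, C, 1, 1)
            xhat = (x - Tensor(mean)) * Tensor(1.0 / std)
        g = self.gamma.reshape(1, C, 1, 1)
        b = self.beta.reshape(1, C, 1, 1)
        return xhat * g + b


def _tensor_pow(self: Tensor, p: float) -> Tensor:
    out_data = np.power(self.data, p)

    def backward(grad):
        if self.requires_grad:
            self._accum(grad * p * np.power(self.data, p - 1))

    return self._make(out_data, (self,), backward)


Tensor.pow = _tensor_pow


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        self.weight = Tensor(_glorot(rng, (in_features, out_features), in_features, out_features),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_features, dtype=np.float32), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class Dropout(Module):
    """Inverted dropout; the mask generator is supplied at call time via
    the owning model so that runs are reproducible."""

    def __init__(self, p: float):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p

    def forward(self, x: Tensor, rng: np.random.Generator | None = None) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        if rng is None:
            raise RuntimeError("training-mode dropout needs an rng")
        mask = (rng.random(x.shape) >= self.p).astype(x.data.dtype) / (1.0 - self.p)
        return x * Tensor(mask)


class AvgPool2d(Module):
    def __init__(self, kernel_size: tuple[int, int]):
        super().__init__()
        self.kernel_size = kernel_size

    def forward(self, x: Tensor) -> Tensor:
        return x.avg_pool2d(self.kernel_size)
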