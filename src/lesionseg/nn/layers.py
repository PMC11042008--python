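"""Neural-network building blocks on top of the autodiff tensor.

Modules hold :class:`Parameter` leaves plus non-trainable buffers (batch-norm
running statistics). ``state_dict``/``load_state_dict`` round-trip both, so a
checkpoint restores the exact forward behaviour in eval mode.

Weight initialisation draws from a process-wide generator seeded through
:func:`seed_all`; building the same architecture after the same seed yields
bit-identical parameters.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .tensor import Tensor, conv2d, maxpool2d

__all__ = [
    "Parameter",
    "Module",
    "ModuleList",
    "Sequential",
    "Conv2d",
    "Linear",
    "BatchNorm2d",
    "ChannelLayerNorm",
    "MaxPool2d",
    "ReLU",
    "SiLU",
    "seed_all",
    "get_rng",
]

_rng = np.random.default_rng(0)


def seed_all(seed: int) -> None:
    """Reset the global generator used for weight initialisation."""
    global _rng
    _rng = np.random.default_rng(seed)


def get_rng() -> np.random.Generator:
    return _rng


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    def __init__(self):
        self.training = True

    # -- traversal ---------------------------------------------------------

    def _children(self) -> Iterator[tuple[str, "Module"]]:
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, ModuleList):
                for i, m in enumerate(value):
                    yield f"{name}.{i}", m

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, value in vars(self).items():
            if isinstance(value, Parameter):
                yield prefix + name, value
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name in getattr(self, "_buffers", ()):  # buffers registered by subclasses
            yield prefix + name, getattr(self, name)
        for name, child in self._children():
            yield from child.named_buffers(prefix + name + ".")

    def modules(self) -> Iterator["Module"]:
        yield self
        for _, child in self._children():
            yield from child.modules()

    # -- train/eval and grads ----------------------------------------------

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    # -- serialization -----------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({name: b.copy() for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own_params = dict(self.named_parameters())
        own_buffers = dict(self.named_buffers())
        expected = set(own_params) | set(own_buffers)
        got = set(state)
        if expected != got:
            missing = sorted(expected - got)[:5]
            extra = sorted(got - expected)[:5]
            raise ValueError(f"state dict mismatch: missing={missing} unexpected={extra}")
        for name, p in own_params.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}: {p.data.shape} vs {state[name].shape}")
            p.data = state[name].astype(np.float32).copy()
        for name in own_buffers:
            # buffers live as plain attributes on their module
            *path, leaf = name.split(".")
            mod = self
            for part in path:
                mod = mod[int(part)] if part.isdigit() else getattr(mod, part)
            setattr(mod, leaf, state[name].astype(np.float32).copy())

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class ModuleList(list):
    """A list of sub-modules that participates in parameter traversal."""


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = ModuleList(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class Conv2d(Module):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        padding: int = 0,
        dilation: int = 1,
        bias: bool = True,
    ):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        self.dilation = dilation
        fan_in = in_channels * kernel_size * kernel_size
        std = np.sqrt(2.0 / fan_in)  # He init for rectifier nets
        self.weight = Parameter(
            _rng.normal(0.0, std, size=(out_channels, in_channels, kernel_size, kernel_size)).astype(np.float32)
        )
        self.bias = Parameter(np.zeros(out_channels, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.padding, self.dilation)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True):
        super().__init__()
        std = np.sqrt(2.0 / in_features)
        self.weight = Parameter(_rng.normal(0.0, std, size=(out_features, in_features)).astype(np.float32))
        self.bias = Parameter(np.zeros(out_features, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight.transpose(1, 0)
        if self.bias is not None:
            out = out + self.bias
        return out


class BatchNorm2d(Module):
    """Per-channel batch normalisation with running statistics.

    Training mode normalises by batch statistics (population variance) and
    updates the running estimates outside the autodiff graph; eval mode uses
    the stored running statistics, making inference deterministic.
    """

    _buffers = ("running_mean", "running_var")

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.channels = channels
        self.eps = eps
        self.momentum = momentum
        self.weight = Parameter(np.ones(channels, dtype=np.float32))
        self.bias = Parameter(np.zeros(channels, dtype=np.float32))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mean = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mean) ** 2.0).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mean.data.reshape(-1)
            self.running_var = (1 - m) * self.running_var + m * var.data.reshape(-1)
            xhat = (x - mean) / (var + self.eps).sqrt()
        else:
            mean = Tensor(self.running_mean.reshape(1, -1, 1, 1))
            std = Tensor(np.sqrt(self.running_var + self.eps).reshape(1, -1, 1, 1))
            xhat = (x - mean) / std
        w = self.weight.reshape(1, self.channels, 1, 1)
        b = self.bias.reshape(1, self.channels, 1, 1)
        return xhat * w + b


class ChannelLayerNorm(Module):
    """Layer norm across the channel axis, independently at every position."""

    def __init__(self, channels: int, eps: float = 1e-5):
        super().__init__()
        self.channels = channels
        self.eps = eps
        self.weight = Parameter(np.ones(channels, dtype=np.float32))
        self.bias = Parameter(np.zeros(channels, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        mean = x.mean(axis=1, keepdims=True)
        var = ((x - mean) ** 2.0).mean(axis=1, keepdims=True)
        xhat = (x - mean) / (var + self.eps).sqrt()
        w = self.weight.reshape(1, self.channels, 1, 1)
        b = self.bias.reshape(1, self.channels, 1, 1)
        return xhat * w + b


class MaxPool2d(Module):
    def __init__(self, kernel_size: int = 3, stride: int = 2, padding: int = 1):
        super().__init__()
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return maxpool2d(x, self.kernel_size, self.stride, self.padding)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class SiLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.silu()
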