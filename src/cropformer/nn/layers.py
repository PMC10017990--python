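"""Neural-network building blocks on top of the autodiff core.

All layers operate on ``n x T x C`` tensors (batch, time, channels) unless
noted.  Initialization is scaled-uniform fan-in and always draws from an
explicitly passed :class:`numpy.random.Generator`, so weight creation is
reproducible by construction.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import tensor
from .tensor import Tensor, depthwise_conv_time, layer_norm

__all__ = [
    "Parameter",
    "Module",
    "ModuleList",
    "Linear",
    "LayerNorm",
    "MaskedBatchNorm",
    "Dropout",
    "DepthwiseConv1d",
    "swish",
    "glu",
]


class Parameter(Tensor):
    """A tensor registered as a trainable weight."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def _fan_in_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int):
    bound = 1.0 / np.sqrt(max(fan_in, 1))
    return rng.uniform(-bound, bound, size=shape)


class Module:
    """Base class: parameter/buffer registration, train/eval mode, state dicts."""

    def __init__(self):
        self._training = True

    # registration is implicit via attribute scanning
    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, val in vars(self).items():
            path = f"{prefix}{name}"
            if isinstance(val, Parameter):
                yield path, val
            elif isinstance(val, Module):
                yield from val.named_parameters(f"{path}.")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name, val in vars(self).items():
            path = f"{prefix}{name}"
            if isinstance(val, Module):
                yield from val.named_buffers(f"{path}.")
            elif isinstance(val, np.ndarray) and name.startswith("running_"):
                yield path, val

    def modules(self) -> Iterator["Module"]:
        yield self
        for val in vars(self).values():
            if isinstance(val, Module):
                yield from val.modules()

    def train(self) -> "Module":
        for m in self.modules():
            m._training = True
        return self

    def eval(self) -> "Module":
        for m in self.modules():
            m._training = False
        return self

    @property
    def training(self) -> bool:
        return self._training

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({name: b.copy() for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        bufs = dict(self.named_buffers())
        missing = (set(own) | set(bufs)) - set(state)
        extra = set(state) - (set(own) | set(bufs))
        if missing or extra:
            raise ValueError(f"state mismatch: missing={sorted(missing)}, extra={sorted(extra)}")
        for name, p in own.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = state[name].astype(tensor.DTYPE, copy=True)
        for name, b in bufs.items():
            b[...] = state[name]


class ModuleList(Module):
    def __init__(self, mods: list[Module]):
        super().__init__()
        for i, m in enumerate(mods):
            setattr(self, f"m{i}", m)
        self._n = len(mods)

    def __iter__(self) -> Iterator[Module]:
        return (getattr(self, f"m{i}") for i in range(self._n))

    def __len__(self) -> int:
        return self._n


class Linear(Module):
    """Affine map applied to the last axis."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Parameter(_fan_in_uniform(rng, (d_in, d_out), d_in))
        self.bias = Parameter(_fan_in_uniform(rng, (d_out,), d_in))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class LayerNorm(Module):
    """Normalizes the last axis; position-wise, so padding cannot leak."""

    def __init__(self, d: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(d))
        self.beta = Parameter(np.zeros(d))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.gamma, self.beta, self.eps)


class MaskedBatchNorm(Module):
    """Batch normalization over channels, with statistics taken over valid
    time positions only so that padding never influences valid outputs."""

    def __init__(self, d: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(d))
        self.beta = Parameter(np.zeros(d))
        self.running_mean = np.zeros(d)
        self.running_var = np.ones(d)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor, valid_mask: np.ndarray) -> Tensor:
        m = valid_mask[:, :, None].astype(float)  # n x T x 1
        if self.training:
            count = float(valid_mask.sum())
            mean = (x * m).sum(axis=(0, 1)) * (1.0 / count)
            cent = (x - mean) * m
            var = (cent * cent).sum(axis=(0, 1)) * (1.0 / count)
            self.running_mean += self.momentum * (mean.data - self.running_mean)
            self.running_var += self.momentum * (var.data - self.running_var)
        else:
            mean = Tensor(self.running_mean)
            var = Tensor(self.running_var)
        return (x - mean) / (var + self.eps) ** 0.5 * self.gamma + self.beta


class Dropout(Module):
    """Inverted dropout; identity in eval mode. The generator is supplied by
    the owning network via :meth:`seed` before training."""

    def __init__(self, p: float):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng: np.random.Generator | None = None

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        if self.rng is None:
            raise RuntimeError("Dropout used in training mode without a seeded rng")
        keep = (self.rng.random(x.shape) >= self.p).astype(float)
        return x * (keep / (1.0 - self.p))


class DepthwiseConv1d(Module):
    """Per-channel temporal convolution (length-preserving for
    ``padding = (kernel_size - 1) / 2`` and stride 1, the only supported
    configuration)."""

    def __init__(self, channels: int, kernel_size: int, padding: int,
                 rng: np.random.Generator):
        super().__init__()
        if kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd")
        if padding != (kernel_size - 1) // 2:
            raise ValueError("only length-preserving padding is supported")
        self.kernel_size = kernel_size
        self.padding = padding
        self.weight = Parameter(
            _fan_in_uniform(rng, (kernel_size, channels), kernel_size)
        )
        self.bias = Parameter(_fan_in_uniform(rng, (channels,), kernel_size))

    def __call__(self, x: Tensor) -> Tensor:
        return depthwise_conv_time(x, self.weight, self.bias, self.padding)


def swish(x: Tensor) -> Tensor:
    """Swish / SiLU activation, x * sigmoid(x)."""
    return x * x.sigmoid()


def glu(x: Tensor) -> Tensor:
    """Gated linear unit over the last axis (must have even width)."""
    d = x.shape[-1]
    if d % 2 != 0:
        raise ValueError("GLU input width must be even")
    a = x[..., : d // 2]
    b = x[..., d // 2 :]
    return a * b.sigmoid()
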