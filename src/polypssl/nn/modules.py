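"""Layers for the nested-skip attention encoder-decoder."""

from __future__ import annotations

import numpy as np

from . import functional as F
from .tensor import Tensor


class Module:
    """Tree of parameters with torch-like (de)serialisation to flat dicts."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, "Module"] = {}

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def add_param(self, name: str, data: np.ndarray) -> Tensor:
        t = Tensor(data, requires_grad=True, name=name)
        self._params[name] = t
        return t

    def named_parameters(self, prefix: str = ""):
        for n, p in self._params.items():
            yield (prefix + n, p)
        for mn, m in self._modules.items():
            yield from m.named_parameters(prefix=f"{prefix}{mn}.")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def state_dict(self) -> dict[str, np.ndarray]:
        return {n: p.data.copy() for n, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        if set(own) != set(state):
            missing = set(own) ^ set(state)
            raise ValueError(f"state dict mismatch; differing keys: {sorted(missing)[:5]}")
        for n, p in own.items():
            if p.data.shape != state[n].shape:
                raise ValueError(f"shape mismatch for {n}")
            p.data = np.array(state[n], dtype=p.data.dtype, copy=True)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None


def _he_normal(rng: np.random.Generator, shape, fan_in: int, dtype) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        self.k = k
        self.w = self.add_param("w", _he_normal(rng, (cout, cin, k, k), cin * k * k, dtype))
        self.b = self.add_param("b", np.zeros(cout, dtype=dtype))

    def __call__(self, x: Tensor) -> Tensor:
        return F.conv2d(x, self.w, self.b)


class ConvTranspose2d(Module):
    """Kernel-2 stride-2 learnable upsampling."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        self.w = self.add_param("w", _he_normal(rng, (cin, cout, 2, 2), cin * 4, dtype))
        self.b = self.add_param("b", np.zeros(cout, dtype=dtype))

    def __call__(self, x: Tensor) -> Tensor:
        return F.conv_transpose2d(x, self.w, self.b, stride=2)


class Linear(Module):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator, bias: bool = True, dtype=np.float32):
        super().__init__()
        self.w = self.add_param("w", _he_normal(rng, (cin, cout), cin, dtype))
        self.b = self.add_param("b", np.zeros(cout, dtype=dtype)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return F.linear(x, self.w, self.b)


class ConvBlock(Module):
    """Stack of 3x3 conv + ReLU layers (a node body of the tiny backbone)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 n_convs: int = 1, dtype=np.float32):
        super().__init__()
        self.n_convs = n_convs
        for i in range(n_convs):
            setattr(self, f"c{i}", Conv2d(cin if i == 0 else cout, cout, 3, rng, dtype))

    def __call__(self, x: Tensor) -> Tensor:
        for i in range(self.n_convs):
            x = F.relu(getattr(self, f"c{i}")(x))
        return x


class ChannelSpatialAttention(Module):
    """CBAM-style gate: channel attention first, then spatial attention.

    Channel: shared 2-layer MLP on global average- and max-pooled descriptors,
    summed and squashed.  Spatial: 7x7 conv over the channel-wise mean/max
    maps.  Both gates multiply the feature map; output shape equals input.
    """

    def __init__(self, channels: int, rng: np.random.Generator, reduction: int = 2, dtype=np.float32):
        super().__init__()
        hidden = max(channels // reduction, 1)
        self.fc1 = Linear(channels, hidden, rng, bias=False, dtype=dtype)
        self.fc2 = Linear(hidden, channels, rng, bias=False, dtype=dtype)
        self.spatial = Conv2d(2, 1, 7, rng, dtype)

    def __call__(self, x: Tensor) -> Tensor:
        b, c = x.shape[:2]
        avg = F.mean(x, axis=(2, 3))          # (B, C)
        mx = F.reduce_max(x, axis=(2, 3))     # (B, C)
        gate = F.sigmoid(self.fc2(F.relu(self.fc1(avg))) + self.fc2(F.relu(self.fc1(mx))))
        x = x * F.reshape(gate, (b, c, 1, 1))
        smean = F.mean(x, axis=1, keepdims=True)
        smax = F.reduce_max(x, axis=1, keepdims=True)
        sgate = F.sigmoid(self.spatial(F.concat([smean, smax], axis=1)))
        return x * sgate
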