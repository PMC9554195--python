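"""Layer abstractions over the autodiff tensor ops.

Modules hold their parameters as :class:`Tensor` objects and discover them by
attribute scan, so composite blocks (encoder levels, dense blocks) are plain
Python objects holding sub-modules or lists of sub-modules.
"""

from __future__ import annotations

import numpy as np

from . import tensor as T
from .tensor import Tensor


class Module:
    """Base class: parameter discovery, named sub-module walk, call syntax."""

    def forward(self, *args):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args):
        return self.forward(*args)

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        for _, p in self.named_parameters():
            if id(p) not in seen:
                seen.add(id(p))
                params.append(p)
        return params

    def named_parameters(self, prefix: str = ""):
        for name, mod in self.named_modules(prefix):
            for attr, val in vars(mod).items():
                if isinstance(val, Tensor) and val.requires_grad:
                    yield (f"{name}.{attr}" if name else attr), val

    def named_modules(self, prefix: str = ""):
        yield prefix, self
        for attr, val in vars(self).items():
            sub = f"{prefix}.{attr}" if prefix else attr
            if isinstance(val, Module):
                yield from val.named_modules(sub)
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_modules(f"{sub}.{i}")

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    # -- flat state for serialization --------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise ValueError(f"state mismatch: missing {sorted(missing)}, unexpected {sorted(extra)}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=np.float32)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()


def _he_init(rng: np.random.Generator, shape: tuple, fan_in: int) -> Tensor:
    std = np.sqrt(2.0 / fan_in)
    return Tensor(rng.standard_normal(shape) * std, requires_grad=True)


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 stride: int = 1, padding: int = 0, dilation: int = 1, bias: bool = True):
        self.stride, self.padding, self.dilation = stride, padding, dilation
        self.weight = _he_init(rng, (cout, cin, k, k), cin * k * k)
        self.bias = Tensor(np.zeros(cout), requires_grad=True) if bias else None

    def forward(self, x):
        return T.conv2d(x, self.weight, self.bias, self.stride, self.padding, self.dilation)

    def n_params(self) -> int:
        n = self.weight.data.size
        return n + (self.bias.data.size if self.bias is not None else 0)


class ConvTranspose2d(Module):
    """Learnable 2x (or k-fold) upsampling; kernel size equals the stride."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, stride: int = 2):
        self.stride = stride
        self.weight = _he_init(rng, (cin, cout, stride, stride), cin * stride * stride)
        self.bias = Tensor(np.zeros(cout), requires_grad=True)

    def forward(self, x):
        return T.conv_transpose2d(x, self.weight, self.bias, self.stride)

    def n_params(self) -> int:
        return self.weight.data.size + self.bias.data.size


class Linear(Module):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.weight = _he_init(rng, (cout, cin), cin)
        self.bias = Tensor(np.zeros(cout), requires_grad=True)

    def forward(self, x):
        return T.linear(x, self.weight, self.bias)

    def n_params(self) -> int:
        return self.weight.data.size + self.bias.data.size


class SEBlock(Module):
    """Squeeze-and-excitation channel attention.

    Global average pooling squeezes each channel to a scalar; a two-layer
    bottleneck (width ``max(C // reduction, 1)``) with ReLU then sigmoid
    produces per-channel gates in (0, 1) that rescale the input channels.
    """

    def __init__(self, channels: int, reduction: int, rng: np.random.Generator):
        if channels < 1 or reduction < 1:
            raise ValueError("channels and reduction must be >= 1")
        hidden = max(channels // reduction, 1)
        self.fc1 = Linear(channels, hidden, rng)
        self.fc2 = Linear(hidden, channels, rng)

    def gates(self, x: Tensor) -> Tensor:
        z = T.global_avg_pool(x)
        return T.sigmoid(self.fc2(T.relu(self.fc1(z))))

    def forward(self, x):
        return T.channel_scale(x, self.gates(x))
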