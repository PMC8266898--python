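"""Layer containers over the autodiff engine.

Follows the familiar Module idiom: parameters are registered by
attribute assignment, ``train()``/``eval()`` toggle batch-norm behaviour,
and ``state_dict`` round-trips through plain NumPy arrays so checkpoints
serialize with ``np.savez``.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import DTYPE, Tensor


class Parameter(Tensor):
    """A tensor whose gradient is tracked and updated by optimizers."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def xavier_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> np.ndarray:
    """Glorot/Xavier uniform draw with gain 1."""
    limit = float(np.sqrt(6.0 / (fan_in + fan_out)))
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


class Module:
    def __init__(self):
        self._params: dict[str, Parameter] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self._modules: dict[str, Module] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield prefix + name, p
        for mname, m in self._modules.items():
            yield from m.named_parameters(prefix + mname + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix: str = ""):
        for name, b in self._buffers.items():
            yield prefix + name, b
        for mname, m in self._modules.items():
            yield from m.named_buffers(prefix + mname + ".")

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {name: p.data.copy() for name, p in self.named_parameters()}
        out.update({name: b.copy() for name, b in self.named_buffers()})
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, p in self.named_parameters():
            p.data = np.asarray(state[name], dtype=DTYPE).reshape(p.data.shape)
        for name, b in self.named_buffers():
            b[...] = np.asarray(state[name], dtype=DTYPE).reshape(b.shape)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    """Same-padded 2-D convolution; bias off by default (BN usually follows)."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int = 3,
                 dilation: int = 1, bias: bool = False, *, rng: np.random.Generator):
        super().__init__()
        if kernel_size % 2 == 0 or kernel_size < 1:
            raise ValueError(f"kernel_size must be odd and positive, got {kernel_size}")
        if dilation < 1:
            raise ValueError(f"dilation must be >= 1, got {dilation}")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.dilation = dilation
        fan = kernel_size * kernel_size
        self.weight = Parameter(
            xavier_uniform(rng, (out_channels, in_channels, kernel_size, kernel_size),
                           in_channels * fan, out_channels * fan)
        )
        self.bias = Parameter(np.zeros(out_channels, dtype=DTYPE)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.in_channels:
            raise ValueError(
                f"expected {self.in_channels} input channels, got {x.shape[1]}"
            )
        return ag.conv2d(x, self.weight, self.bias, dilation=self.dilation)


class ConvTranspose2d(Module):
    """2x2 stride-2 transposed convolution: doubles H and W exactly."""

    def __init__(self, in_channels: int, out_channels: int, *, rng: np.random.Generator):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.weight = Parameter(
            xavier_uniform(rng, (in_channels, out_channels, 2, 2),
                           in_channels * 4, out_channels * 4)
        )

    def forward(self, x: Tensor) -> Tensor:
        return ag.conv_transpose2d(x, self.weight)


class BatchNorm2d(Module):
    def __init__(self, num_features: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.num_features = num_features
        self.momentum = momentum
        self.eps = eps
        self.gamma = Parameter(np.ones(num_features, dtype=DTYPE))
        self.beta = Parameter(np.zeros(num_features, dtype=DTYPE))
        self.register_buffer("running_mean", np.zeros(num_features, dtype=DTYPE))
        self.register_buffer("running_var", np.ones(num_features, dtype=DTYPE))

    def forward(self, x: Tensor) -> Tensor:
        return ag.batch_norm(x, self.gamma, self.beta, self.running_mean,
                             self.running_var, self.training, self.momentum, self.eps)


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self._list: list[Module] = []
        for m in mods:
            self.append(m)

    def append(self, m: Module) -> None:
        setattr(self, str(len(self._list)), m)
        self._list.append(m)

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]
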