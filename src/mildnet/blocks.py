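"""Building blocks: dilated convolution, MLDR and MLR residual-of-residual blocks.

The MLDR (multi-level dilated residual) block replaces the plain
double-convolution of a U-Net stage. Each of its N levels (default 2)
applies one pre-activation (BN -> ReLU) followed by three parallel 3x3
convolutions at dilation rates 1, 3 and 5, fuses the branches, adds the
level's identity shortcut and applies ReLU:

    y_l = h(x_l) + F(x_l, W_l),     x_{l+1} = ReLU(y_l)

with h the identity (a 1x1 projection when the channel count changes)
and F the fused dilated branches. An outer shortcut from the block input
to the last level's output makes the block residual-of-residual.

The MLR (multi-level residual) block has the same two-level residual
structure but each level is BN -> ReLU followed by two sequential 3x3
standard convolutions (dilation 1); it preserves the channel count and
sits on the skip connections to narrow the encoder/decoder semantic gap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn.autograd import Tensor, as_tensor


class ConfigurationError(ValueError):
    """Raised when a block or network specification is inconsistent."""


def effective_receptive_field(kernel_size: int, dilation: int) -> int:
    """Pixel extent of one dilated kernel: k + (k-1)(d-1)."""
    return kernel_size + (kernel_size - 1) * (dilation - 1)


@dataclass(frozen=True)
class DilatedConvSpec:
    """Configuration of a single same-padded dilated convolution."""

    in_channels: int
    out_channels: int
    kernel_size: int = 3
    dilation: int = 1

    def __post_init__(self):
        if self.kernel_size < 1 or self.kernel_size % 2 == 0:
            raise ConfigurationError(
                f"kernel_size must be odd and positive, got {self.kernel_size}"
            )
        if self.dilation < 1:
            raise ConfigurationError(f"dilation must be positive, got {self.dilation}")
        if self.in_channels < 1 or self.out_channels < 1:
            raise ConfigurationError("channel counts must be positive")

    @property
    def receptive_field(self) -> int:
        return effective_receptive_field(self.kernel_size, self.dilation)


@dataclass(frozen=True)
class ResidualBlockSpec:
    """Configuration of an MLDR or MLR block.

    ``branch_dilations`` lists the parallel dilation rates of one MLDR
    level ([1, 3, 5] by default); for MLR blocks it is read as the two
    sequential standard convolutions of one level ([1, 1]).
    """

    kind: str  # "MLDR" | "MLR"
    in_channels: int
    out_channels: int
    levels: int = 2
    branch_dilations: tuple[int, ...] = field(default=None)  # type: ignore[assignment]
    fusion: str = "sum"  # "sum" | "concat"

    def __post_init__(self):
        if self.kind not in ("MLDR", "MLR"):
            raise ConfigurationError(f"unknown block kind {self.kind!r}")
        if self.levels < 1:
            raise ConfigurationError(f"levels must be >= 1, got {self.levels}")
        if self.branch_dilations is None:
            object.__setattr__(
                self, "branch_dilations", (1, 3, 5) if self.kind == "MLDR" else (1, 1)
            )
        object.__setattr__(self, "branch_dilations", tuple(self.branch_dilations))
        if any(d < 1 for d in self.branch_dilations):
            raise ConfigurationError("dilation rates must be positive")
        if self.fusion not in ("sum", "concat"):
            raise ConfigurationError(f"unknown fusion mode {self.fusion!r}")
        if self.kind == "MLR" and self.in_channels != self.out_channels:
            raise ConfigurationError(
                "MLR blocks preserve the channel count "
                f"(got {self.in_channels} -> {self.out_channels})"
            )


def dilated_convolve(input_map, spec: DilatedConvSpec, weights) -> np.ndarray:
    """Apply one same-padded dilated cross-correlation to a (b, c, h, w) array.

    Equivalent to a direct summation over kernel taps offset by
    ``dilation * t`` with zero padding outside the image.
    """
    x = np.asarray(input_map, dtype=float)
    w = np.asarray(weights, dtype=float)
    if x.ndim != 4:
        raise ConfigurationError(f"input must be rank-4 (b, c, h, w), got rank {x.ndim}")
    if w.shape != (spec.out_channels, spec.in_channels, spec.kernel_size, spec.kernel_size):
        raise ConfigurationError(
            f"weights shape {w.shape} does not match spec "
            f"({spec.out_channels}, {spec.in_channels}, {spec.kernel_size}, {spec.kernel_size})"
        )
    if x.shape[1] != spec.in_channels:
        raise ConfigurationError(
            f"input has {x.shape[1]} channels, spec expects {spec.in_channels}"
        )
    return nn.conv2d(as_tensor(x), as_tensor(w), dilation=spec.dilation).data


class _Level(nn.Module):
    """One pre-activation residual level shared by MLDR and MLR blocks."""

    def __init__(self, spec: ResidualBlockSpec, in_channels: int, *,
                 rng: np.random.Generator):
        super().__init__()
        out = spec.out_channels
        self.bn = nn.BatchNorm2d(in_channels)
        self.parallel = spec.kind == "MLDR"
        self.branches = nn.ModuleList(
            nn.Conv2d(in_channels if (self.parallel or i == 0) else out, out,
                      kernel_size=3, dilation=d, rng=rng)
            for i, d in enumerate(spec.branch_dilations)
        )
        self.fusion = spec.fusion
        if self.parallel and spec.fusion == "concat":
            self.fuse_proj = nn.Conv2d(out * len(spec.branch_dilations), out,
                                       kernel_size=1, rng=rng)
        if in_channels != out:
            self.shortcut = nn.Conv2d(in_channels, out, kernel_size=1, rng=rng)
        else:
            self.shortcut = None

    def forward(self, x: Tensor) -> Tensor:
        a = nn.relu(self.bn(x))
        if self.parallel:
            outs = [conv(a) for conv in self.branches]
            f = outs[0]
            if self.fusion == "sum":
                for o in outs[1:]:
                    f = nn.add(f, o)
            else:
                for o in outs[1:]:
                    f = nn.concat(f, o)
                f = self.fuse_proj(f)
        else:
            f = a
            for conv in self.branches:
                f = conv(f)
        h = x if self.shortcut is None else self.shortcut(x)
        return nn.relu(nn.add(f, h))


class ResidualBlock(nn.Module):
    """N stacked residual levels wrapped in an outer residual shortcut."""

    def __init__(self, spec: ResidualBlockSpec, *, rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        self.levels = nn.ModuleList()
        ch = spec.in_channels
        for _ in range(spec.levels):
            self.levels.append(_Level(spec, ch, rng=rng))
            ch = spec.out_channels
        if spec.in_channels != spec.out_channels:
            self.outer_shortcut = nn.Conv2d(spec.in_channels, spec.out_channels,
                                            kernel_size=1, rng=rng)
        else:
            self.outer_shortcut = None

    def forward(self, x: Tensor) -> Tensor:
        x = as_tensor(x)
        if x.shape[1] != self.spec.in_channels:
            raise ConfigurationError(
                f"{self.spec.kind} block expects {self.spec.in_channels} channels, "
                f"got {x.shape[1]}"
            )
        y = x
        for level in self.levels:
            y = level(y)
        h = x if self.outer_shortcut is None else self.outer_shortcut(x)
        return nn.relu(nn.add(y, h))


def mldr_block(in_channels: int, out_channels: int, levels: int = 2,
               dilations=(1, 3, 5), fusion: str = "sum", *,
               rng: np.random.Generator) -> ResidualBlock:
    spec = ResidualBlockSpec("MLDR", in_channels, out_channels, levels,
                             tuple(dilations), fusion)
    return ResidualBlock(spec, rng=rng)


def mlr_block(channels: int, levels: int = 2, *, rng: np.random.Generator) -> ResidualBlock:
    spec = ResidualBlockSpec("MLR", channels, channels, levels, (1, 1))
    return ResidualBlock(spec, rng=rng)


def mldr_forward(input_map, block: ResidualBlock) -> np.ndarray:
    """Functional forward through an MLDR block (evaluation-mode BN)."""
    if block.spec.kind != "MLDR":
        raise ConfigurationError("mldr_forward requires an MLDR block")
    block.eval()
    return block(as_tensor(np.asarray(input_map, dtype=float))).data


def mlr_forward(input_map, block: ResidualBlock) -> np.ndarray:
    """Functional forward through an MLR skip block (evaluation-mode BN)."""
    if block.spec.kind != "MLR":
        raise ConfigurationError("mlr_forward requires an MLR block")
    block.eval()
    return block(as_tensor(np.asarray(input_map, dtype=float))).data
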