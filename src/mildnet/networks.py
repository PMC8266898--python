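"""U-Net-style encoder/decoder assembly for MILDNet and its baselines.

Three variants share one skeleton of ``depth`` resolution stages whose
filter widths double per stage (default [32, 64, 128, 256, 512]):

* ``unet`` — classical double 3x3 convolution stages, identity skips;
* ``residual_unet`` — double-convolution stages with one residual
  shortcut each, identity skips;
* ``mildnet`` — MLDR blocks in every stage and an MLR block on each
  skip connection.

Downsampling is 2x2 stride-2 max pooling, upsampling a 2x2 stride-2
transposed convolution that halves the channel count; the processed skip
tensor is concatenated channel-wise before the decoder block. The head
is a 1x1 convolution producing logits; ``predict_mask`` applies the
sigmoid.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import nn
from .blocks import ConfigurationError, ResidualBlock, mldr_block, mlr_block
from .nn.autograd import Tensor, as_tensor

VARIANTS = ("mildnet", "unet", "residual_unet")


@dataclass(frozen=True)
class ArchitectureConfig:
    variant: str = "mildnet"
    depth: int = 5
    initial_filters: int = 32
    levels: int = 2
    dilation_rates: tuple[int, ...] = (1, 3, 5)
    in_channels: int = 1
    out_channels: int = 1
    fusion: str = "sum"

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ConfigurationError(f"unknown variant {self.variant!r}; expected one of {VARIANTS}")
        if self.depth < 2:
            raise ConfigurationError(f"depth must be >= 2, got {self.depth}")
        if self.initial_filters < 1:
            raise ConfigurationError("initial_filters must be positive")
        object.__setattr__(self, "dilation_rates", tuple(self.dilation_rates))

    @property
    def filter_schedule(self) -> list[int]:
        """Stage widths: initial_filters * 2**i for stage i."""
        return [self.initial_filters * 2 ** i for i in range(self.depth)]


class _DoubleConv(nn.Module):
    """conv3x3-BN-ReLU twice; optionally wrapped in a residual shortcut."""

    def __init__(self, in_channels: int, out_channels: int, residual: bool, *,
                 rng: np.random.Generator):
        super().__init__()
        self.conv1 = nn.Conv2d(in_channels, out_channels, rng=rng)
        self.bn1 = nn.BatchNorm2d(out_channels)
        self.conv2 = nn.Conv2d(out_channels, out_channels, rng=rng)
        self.bn2 = nn.BatchNorm2d(out_channels)
        self.residual = residual
        if residual and in_channels != out_channels:
            self.shortcut = nn.Conv2d(in_channels, out_channels, kernel_size=1, rng=rng)
        else:
            self.shortcut = None

    def forward(self, x: Tensor) -> Tensor:
        y = nn.relu(self.bn1(self.conv1(x)))
        y = self.bn2(self.conv2(y))
        if self.residual:
            h = x if self.shortcut is None else self.shortcut(x)
            y = nn.add(y, h)
        return nn.relu(y)


class _Identity(nn.Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


class NetworkModel(nn.Module):
    """Assembled encoder/decoder with skip processors and a logit head."""

    def __init__(self, config: ArchitectureConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        filters = config.filter_schedule

        def stage_block(cin, cout):
            if config.variant == "mildnet":
                return mldr_block(cin, cout, levels=config.levels,
                                  dilations=config.dilation_rates,
                                  fusion=config.fusion, rng=rng)
            return _DoubleConv(cin, cout, residual=config.variant == "residual_unet",
                               rng=rng)

        self.encoder = nn.ModuleList()
        cin = config.in_channels
        for f in filters:
            self.encoder.append(stage_block(cin, f))
            cin = f

        self.upsamplers = nn.ModuleList()
        self.skip_processors = nn.ModuleList()
        self.decoder = nn.ModuleList()
        for i in range(config.depth - 2, -1, -1):
            self.upsamplers.append(nn.ConvTranspose2d(filters[i + 1], filters[i], rng=rng))
            if config.variant == "mildnet":
                self.skip_processors.append(mlr_block(filters[i], levels=config.levels,
                                                      rng=rng))
            else:
                self.skip_processors.append(_Identity())
            self.decoder.append(stage_block(2 * filters[i], filters[i]))

        self.head = nn.Conv2d(filters[0], config.out_channels, kernel_size=1,
                              bias=True, rng=rng)

    # ------------------------------------------------------------------
    def _check_spatial(self, h: int, w: int) -> None:
        div = 2 ** (self.config.depth - 1)
        if h % div or w % div:
            raise ConfigurationError(
                f"input spatial size {h}x{w} must be divisible by 2**(depth-1)={div}"
            )

    def forward(self, x, collect_decoder: bool = False):
        x = as_tensor(x)
        if x.ndim != 4:
            raise ConfigurationError(f"expected (b, c, h, w) input, got rank {x.ndim}")
        if x.shape[1] != self.config.in_channels:
            raise ConfigurationError(
                f"expected {self.config.in_channels} input channels, got {x.shape[1]}"
            )
        self._check_spatial(x.shape[2], x.shape[3])

        skips = []
        y = x
        for i, block in enumerate(self.encoder):
            y = block(y)
            if i < self.config.depth - 1:
                skips.append(y)
                y = nn.max_pool2d(y)

        decoder_acts = []
        for up, proc, block, skip in zip(self.upsamplers, self.skip_processors,
                                         self.decoder, reversed(skips)):
            y = up(y)
            s = proc(skip)
            y = block(nn.concat(s, y))
            if collect_decoder:
                decoder_acts.append(y)

        logits = self.head(y)
        if collect_decoder:
            return logits, decoder_acts
        return logits


def build_network(config: ArchitectureConfig, seed: int = 0) -> NetworkModel:
    """Build a network variant with Xavier-initialized convolutions.

    Two builds with the same config and seed produce bit-identical
    parameter vectors.
    """
    return NetworkModel(config, seed=seed)


def predict_mask(model: NetworkModel, image_batch) -> np.ndarray:
    """Sigmoid probability maps in the open interval (0, 1); deterministic
    (evaluation-mode batch norm). Probabilities are clamped away from the
    exact endpoints by 1e-12 so saturated logits cannot produce degenerate
    0/1 values in downstream log-scores; the 0.5 decision threshold is
    unaffected."""
    was_training = model.training
    model.eval()
    try:
        with nn.no_grad():
            probs = nn.sigmoid(model(as_tensor(np.asarray(image_batch, dtype=float)))).data
    finally:
        model.train(was_training)
    return np.clip(probs, 1e-12, 1.0 - 1e-12)


def summarize(model: NetworkModel) -> dict:
    """Parameter counts and per-stage output shapes for a small probe input."""
    cfg = model.config
    probe_hw = 2 ** (cfg.depth - 1) * 2
    probe = np.zeros((1, cfg.in_channels, probe_hw, probe_hw))
    was_training = model.training
    model.eval()
    try:
        stage_shapes = []
        with nn.no_grad():
            y = as_tensor(probe)
            for i, block in enumerate(model.encoder):
                y = block(y)
                stage_shapes.append(("encoder", i, tuple(y.shape)))
                if i < cfg.depth - 1:
                    y = nn.max_pool2d(y)
            for j, (up, proc, block) in enumerate(zip(model.upsamplers,
                                                      model.skip_processors, model.decoder)):
                y = up(y)
                skip_ch = cfg.filter_schedule[cfg.depth - 2 - j]
                s = proc(as_tensor(np.zeros((1, skip_ch) + tuple(y.shape[2:]))))
                y = block(nn.concat(s, y))
                stage_shapes.append(("decoder", j, tuple(y.shape)))
    finally:
        model.train(was_training)
    return {
        "variant": cfg.variant,
        "depth": cfg.depth,
        "filter_schedule": cfg.filter_schedule,
        "total_parameters": model.num_parameters(),
        "stage_shapes": stage_shapes,
    }


# ----------------------------------------------------------------------
# checkpoints: parameters/buffers as an .npz archive with the config
# embedded as a JSON string.

def save_checkpoint(model: NetworkModel, path) -> None:
    path = Path(path)
    payload = {"__config__": np.frombuffer(
        json.dumps(asdict(model.config)).encode(), dtype=np.uint8)}
    payload.update(model.state_dict())
    with open(path, "wb") as fh:
        np.savez(fh, **payload)


def load_checkpoint(path, seed: int = 0) -> NetworkModel:
    with np.load(Path(path)) as archive:
        cfg_raw = json.loads(archive["__config__"].tobytes().decode())
        cfg_raw["dilation_rates"] = tuple(cfg_raw["dilation_rates"])
        config = ArchitectureConfig(**cfg_raw)
        model = NetworkModel(config, seed=seed)
        model.load_state_dict({k: archive[k] for k in archive.files if k != "__config__"})
    return model
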