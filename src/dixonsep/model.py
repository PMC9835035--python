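"""Network architectures for swap-free fat-water separation.

The generator is a six-level 3D U-Net-style encoder-decoder: kernel-4
stride-2 convolutions contract (no pooling), kernel-4 stride-2 transposed
convolutions expand, with skip connections between mirrored levels. It maps
one (IP) or two (IP, OP) input channels to the two output channels
(fat-hat, water-hat), bounded to [0, 1] by a sigmoid to match the jointly
normalized intensity scale.

The discriminator is a 3D PatchGAN: kernel-4 convolutions, one stride-2
layer followed by two stride-1 layers, so each unit of its score grid judges
a (16, 16, 16)-voxel neighbourhood of the fat/water pair. By default it sees
only the (F, W) pair; optional conditioning concatenates the IP/OP inputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import nn

__all__ = [
    "GeneratorConfig",
    "DiscriminatorConfig",
    "Generator",
    "Discriminator",
    "build_generator",
    "build_discriminator",
    "receptive_field",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Architecture of the encoder-decoder generator.

    ``filter_schedule`` gives per-level encoder filter counts; if None it
    defaults to the pix2pix-style doubling ``base_filters * min(2^i, 8)``
    (64, 128, 256, 512, 512, 512 at the defaults). ``in_channels`` is 1 for
    a single-input (IP only) model and 2 for dual input (IP, OP).
    """

    levels: int = 6
    base_filters: int = 64
    filter_schedule: tuple[int, ...] | None = None
    kernel: int = 4
    stride: int = 2
    in_channels: int = 2
    out_channels: int = 2
    norm_kind: str = "batch"

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if self.in_channels not in (1, 2):
            raise ValueError(f"in_channels must be 1 or 2, got {self.in_channels}")
        if self.filter_schedule is not None:
            object.__setattr__(self, "filter_schedule", tuple(self.filter_schedule))
            if len(self.filter_schedule) != self.levels:
                raise ValueError(
                    f"filter_schedule has {len(self.filter_schedule)} entries "
                    f"for {self.levels} levels"
                )
        if self.norm_kind not in ("batch", "instance"):
            raise ValueError(f"norm_kind must be 'batch' or 'instance', got {self.norm_kind!r}")

    @property
    def filters(self) -> tuple[int, ...]:
        if self.filter_schedule is not None:
            return self.filter_schedule
        return tuple(self.base_filters * min(2**i, 8) for i in range(self.levels))

    @property
    def divisor(self) -> int:
        return self.stride**self.levels


@dataclass(frozen=True)
class DiscriminatorConfig:
    """Architecture of the PatchGAN discriminator.

    ``strides`` lists the stride of every convolution including the final
    single-channel score layer; the default (2, 1, 1) with kernel 4 gives
    each score unit a 16-voxel receptive edge. ``conditioned`` adds the
    generator inputs (IP or IP+OP) as extra channels.
    """

    kernel: int = 4
    strides: tuple[int, ...] = (2, 1, 1)
    filters: tuple[int, ...] = (32, 64)
    final_channels: int = 1
    in_channels: int = 2
    conditioned: bool = False
    cond_channels: int = 2
    norm_kind: str = "batch"

    def __post_init__(self) -> None:
        object.__setattr__(self, "strides", tuple(self.strides))
        object.__setattr__(self, "filters", tuple(self.filters))
        if len(self.strides) != len(self.filters) + 1:
            raise ValueError(
                "strides must have one entry per filter layer plus the final score layer: "
                f"got {len(self.strides)} strides for {len(self.filters)} filters"
            )
        if len(self.strides) >= 2 and (self.strides[-1] != 1 or self.strides[-2] != 1):
            raise ValueError("the last two layers must have stride 1")

    @property
    def total_in_channels(self) -> int:
        return self.in_channels + (self.cond_channels if self.conditioned else 0)


def receptive_field(config: DiscriminatorConfig) -> int:
    """Input-side edge length seen by one output unit of the discriminator.

    Applies ``RF_in = RF_out * stride + (kernel - stride)`` backwards through
    the layer stack starting from RF = 1 at a single output unit.
    """
    rf = 1
    for s in reversed(config.strides):
        rf = rf * s + (config.kernel - s)
    return rf


class Generator(nn.Module):
    """Encoder-decoder with skip connections; see :class:`GeneratorConfig`."""

    def __init__(self, config: GeneratorConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        k, s = config.kernel, config.stride
        filters = config.filters
        in_ch = config.in_channels
        for i, f in enumerate(filters):
            self.add(f"enc{i}", nn.Conv3d(in_ch, f, k, s, 1, rng=rng))
            if i > 0:  # no normalization on the first encoder layer
                self.add(f"enc_norm{i}", nn.Norm3d(f, config.norm_kind))
            in_ch = f
        # decoder mirrors the encoder; inputs double where a skip concatenates
        dec_filters = list(filters[:-1][::-1])  # targets for all but final layer
        in_ch = filters[-1]
        for i, f in enumerate(dec_filters):
            self.add(f"dec{i}", nn.ConvTranspose3d(in_ch, f, k, s, 1, rng=rng))
            self.add(f"dec_norm{i}", nn.Norm3d(f, config.norm_kind))
            in_ch = 2 * f  # concatenated with the mirrored encoder output
        self.add("dec_out", nn.ConvTranspose3d(in_ch, config.out_channels, k, s, 1, rng=rng))

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        cfg = self.config
        edge = x.shape[2]
        if any(d % cfg.divisor for d in x.shape[2:]):
            raise ValueError(
                f"input spatial shape {x.shape[2:]} must be divisible by "
                f"stride^levels = {cfg.divisor}"
            )
        if x.shape[1] != cfg.in_channels:
            raise ValueError(f"expected {cfg.in_channels} input channels, got {x.shape[1]}")
        skips: list[nn.Tensor] = []
        h = x
        for i in range(cfg.levels):
            h = getattr(self, f"enc{i}")(h)
            if i > 0:
                h = getattr(self, f"enc_norm{i}")(h)
            h = h.leaky_relu(0.2)
            skips.append(h)
        for i in range(cfg.levels - 1):
            h = getattr(self, f"dec{i}")(h)
            h = getattr(self, f"dec_norm{i}")(h)
            h = h.relu()
            h = nn.Tensor.concat([h, skips[cfg.levels - 2 - i]], axis=1)
        h = self.dec_out(h)
        return h.sigmoid()


class Discriminator(nn.Module):
    """PatchGAN over the (fat, water) pair; outputs a grid of probabilities."""

    def __init__(self, config: DiscriminatorConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        k = config.kernel
        in_ch = config.total_in_channels
        for i, (f, s) in enumerate(zip(config.filters, config.strides[:-1])):
            self.add(f"conv{i}", nn.Conv3d(in_ch, f, k, s, 1, rng=rng))
            if i > 0 and config.norm_kind != "none":
                self.add(f"norm{i}", nn.Norm3d(f, config.norm_kind))
            in_ch = f
        self.add(
            "score",
            nn.Conv3d(in_ch, config.final_channels, k, config.strides[-1], 1, rng=rng),
        )

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        cfg = self.config
        rf = receptive_field(cfg)
        if min(x.shape[2:]) < rf:
            raise ValueError(
                f"input spatial shape {x.shape[2:]} is smaller than the "
                f"receptive field ({rf} voxels)"
            )
        if x.shape[1] != cfg.total_in_channels:
            raise ValueError(
                f"expected {cfg.total_in_channels} channels "
                f"(conditioned={cfg.conditioned}), got {x.shape[1]}"
            )
        h = x
        for i in range(len(cfg.filters)):
            h = getattr(self, f"conv{i}")(h)
            if i > 0 and cfg.norm_kind != "none":
                h = getattr(self, f"norm{i}")(h)
            h = h.leaky_relu(0.2)
        return self.score(h).sigmoid()


def build_generator(config: GeneratorConfig, seed: int = 0) -> Generator:
    """Instantiate a generator with seeded Gaussian(0, 0.02) weight init."""
    return Generator(config, np.random.default_rng(seed))


def build_discriminator(config: DiscriminatorConfig, seed: int = 0) -> Discriminator:
    """Instantiate a discriminator with seeded Gaussian(0, 0.02) weight init."""
    return Discriminator(config, np.random.default_rng(seed))


# ---------------------------------------------------------------------------
# checkpointing: weights plus the embedded config in a single npz file
# ---------------------------------------------------------------------------

def save_checkpoint(path: str | Path, generator: Generator, extra: dict | None = None) -> None:
    meta = {"generator_config": asdict(generator.config)}
    if extra:
        meta.update(extra)
    arrays = {f"param/{k}": v for k, v in generator.state_dict().items()}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str | Path) -> tuple[Generator, dict]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k[len("param/"):]: data[k] for k in data.files if k.startswith("param/")}
    cfg_dict = dict(meta["generator_config"])
    if cfg_dict.get("filter_schedule") is not None:
        cfg_dict["filter_schedule"] = tuple(cfg_dict["filter_schedule"])
    config = GeneratorConfig(**cfg_dict)
    gen = build_generator(config)
    gen.load_state_dict(state)
    return gen, meta
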