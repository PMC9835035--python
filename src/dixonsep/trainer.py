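"""Adversarial training loop for the fat-water separation cGAN.

Sampling follows the scheme used at full scale: every iteration picks a
random subject and a random cubic crop (default edge 128) applied
identically to all channels; inputs are the normalized IP (single-input) or
IP + OP (dual-input) channels and the labels are the curated swap-free fat
and water channels. Discriminator and generator alternate one update each
per batch under Adam (lr 0.0002, beta1 0.5), batch size 2, for a fixed
number of epochs. All randomness is seeded; a run is reproducible
bit-for-bit on a fixed platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .losses import LossConfig, adversarial_terms, dixon_loss, generator_objective, l1_loss
from .model import (
    DiscriminatorConfig,
    GeneratorConfig,
    build_discriminator,
    build_generator,
    save_checkpoint,
)
from .nn import Adam, Tensor
from .phantom import SubjectSample
from .physics import normalize_arrays

__all__ = ["TrainConfig", "TrainHistory", "sample_training_patch", "train"]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters of one training run.

    ``input_mode`` selects the single-input (IP) or dual-input (IP, OP)
    generator; ``loss.mode`` selects L1 supervision or the label-free Dixon
    loss. The single-input + Dixon combination is refused: with only IP
    constrained, IP = W_hat + F_hat admits degenerate solutions such as an
    empty water channel (``allow_degenerate=True`` overrides, for
    experimentation only). ``steps_per_epoch`` defaults to the dataset size.
    """

    patch_edge: int = 128
    batch_size: int = 2
    epochs: int = 100
    learning_rate: float = 2e-4
    beta1: float = 0.5
    beta2: float = 0.999
    input_mode: str = "dual"
    loss: LossConfig = field(default_factory=LossConfig)
    steps_per_epoch: int | None = None
    seed: int = 0
    checkpoint_every: int = 0
    checkpoint_dir: str | None = None
    allow_degenerate: bool = False

    def __post_init__(self) -> None:
        if self.input_mode not in ("single", "dual"):
            raise ValueError(f"input_mode must be 'single' or 'dual', got {self.input_mode!r}")
        if self.input_mode == "single" and self.loss.mode == "dixon" and not self.allow_degenerate:
            raise ValueError(
                "single-input model with the Dixon loss is degenerate "
                "(IP = W_hat + F_hat admits empty-channel solutions); "
                "set allow_degenerate=True to override"
            )
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")

    @property
    def in_channels(self) -> int:
        return 1 if self.input_mode == "single" else 2


@dataclass
class TrainHistory:
    """Per-step loss traces of one run."""

    d_loss: list[float] = field(default_factory=list)
    g_adversarial: list[float] = field(default_factory=list)
    reconstruction: list[float] = field(default_factory=list)

    def append(self, d: float, g: float, r: float) -> None:
        self.d_loss.append(d)
        self.g_adversarial.append(g)
        self.reconstruction.append(r)

    def __len__(self) -> int:
        return len(self.d_loss)

    def epoch_means(self, steps_per_epoch: int) -> list[dict[str, float]]:
        out = []
        for lo in range(0, len(self.d_loss), steps_per_epoch):
            hi = lo + steps_per_epoch
            out.append(
                {
                    "d_loss": float(np.mean(self.d_loss[lo:hi])),
                    "g_adversarial": float(np.mean(self.g_adversarial[lo:hi])),
                    "reconstruction": float(np.mean(self.reconstruction[lo:hi])),
                }
            )
        return out


def _normalized_stack(sample: SubjectSample) -> np.ndarray:
    """Jointly normalized (ip, op, fat, water) stack of one subject.

    The clean fat/water channels are the training labels; the subject's four
    channels share one 99th-percentile scale.
    """
    c = sample.clean
    arrays, _ = normalize_arrays([c.ip.values, c.op.values, c.fat.values, c.water.values])
    return np.stack(arrays).astype(np.float32)


def sample_training_patch(
    dataset: list[np.ndarray],
    rng: np.random.Generator,
    patch_edge: int,
    input_mode: str = "dual",
) -> tuple[np.ndarray, np.ndarray]:
    """Random subject, random cubic crop; identical crop on all channels.

    ``dataset`` holds per-subject normalized (4, X, Y, Z) stacks in
    (ip, op, fat, water) order. Returns ``(input_patch, label_patch)`` with
    1 or 2 input channels per ``input_mode`` and labels (fat, water).
    """
    idx = int(rng.integers(len(dataset)))
    stack = dataset[idx]
    shape = stack.shape[1:]
    e = patch_edge
    if any(d < e for d in shape):
        raise ValueError(f"subject {idx} volume shape {shape} smaller than patch edge {e}")
    start = [int(rng.integers(d - e + 1)) for d in shape]
    sl = (slice(None),) + tuple(slice(s, s + e) for s in start)
    crop = stack[sl]
    inputs = crop[:1] if input_mode == "single" else crop[:2]
    labels = crop[2:4]
    return inputs.copy(), labels.copy()


def train(
    dataset: list[SubjectSample],
    gen_config: GeneratorConfig,
    disc_config: DiscriminatorConfig,
    train_config: TrainConfig,
):
    """Run adversarial training; returns ``(generator, TrainHistory)``.

    One discriminator update then one generator update per batch. Non-finite
    losses abort with a diagnostic rather than training on.
    """
    if not dataset:
        raise ValueError("dataset is empty")
    if train_config.patch_edge % gen_config.divisor:
        raise ValueError(
            f"patch_edge {train_config.patch_edge} not divisible by the generator's "
            f"stride^levels = {gen_config.divisor}"
        )
    if gen_config.in_channels != train_config.in_channels:
        gen_config = replace(gen_config, in_channels=train_config.in_channels)
    if disc_config.conditioned and disc_config.cond_channels != train_config.in_channels:
        disc_config = replace(disc_config, cond_channels=train_config.in_channels)

    rng = np.random.default_rng(train_config.seed)
    generator = build_generator(gen_config, seed=int(rng.integers(2**31 - 1)))
    discriminator = build_discriminator(disc_config, seed=int(rng.integers(2**31 - 1)))
    opt_g = Adam(generator.parameters(), train_config.learning_rate,
                 train_config.beta1, train_config.beta2)
    opt_d = Adam(discriminator.parameters(), train_config.learning_rate,
                 train_config.beta1, train_config.beta2)

    stacks = [_normalized_stack(s) for s in dataset]
    steps_per_epoch = train_config.steps_per_epoch or len(dataset)
    history = TrainHistory()
    loss_cfg = train_config.loss

    total_steps = train_config.epochs * steps_per_epoch
    for step in range(total_steps):
        ins, labs = zip(*(
            sample_training_patch(stacks, rng, train_config.patch_edge, train_config.input_mode)
            for _ in range(train_config.batch_size)
        ))
        x = Tensor(np.stack(ins))
        real = Tensor(np.stack(labs))

        # --- discriminator update (generator frozen via detached fake) ---
        fake = generator(x)
        fake_detached = Tensor(fake.data.copy())
        d_real = discriminator(_disc_input(real, x, disc_config))
        d_fake = discriminator(_disc_input(fake_detached, x, disc_config))
        d_loss, _ = adversarial_terms(d_real, d_fake)
        discriminator.zero_grad()
        d_loss.backward()
        opt_d.step()

        # --- generator update (reuses the generator graph from above) ---
        d_fake2 = discriminator(_disc_input(fake, x, disc_config))
        _, g_adv = adversarial_terms(Tensor(d_real.data.copy()), d_fake2)
        if loss_cfg.mode == "l1":
            recon = _l1_from_batch(real, fake)
        else:
            recon = _dixon_from_batch(x, fake, train_config.input_mode)
        objective = generator_objective(loss_cfg, g_adv, recon)
        generator.zero_grad()
        discriminator.zero_grad()  # grads through D are discarded
        objective.backward()
        opt_g.step()

        d_val, g_val, r_val = float(d_loss.data), float(g_adv.data), float(recon.data)
        if not np.isfinite([d_val, g_val, r_val]).all():
            raise RuntimeError(
                f"non-finite loss at step {step}: d={d_val}, g_adv={g_val}, recon={r_val}"
            )
        history.append(d_val, g_val, r_val)

        if (
            train_config.checkpoint_every
            and train_config.checkpoint_dir
            and (step + 1) % train_config.checkpoint_every == 0
        ):
            path = Path(train_config.checkpoint_dir) / f"checkpoint_{step + 1:06d}.npz"
            save_checkpoint(path, generator, extra={"step": step + 1})

    return generator, history


def _disc_input(pair: Tensor, x: Tensor, disc_config: DiscriminatorConfig) -> Tensor:
    if disc_config.conditioned:
        return Tensor.concat([pair, x], axis=1)
    return pair


def _l1_from_batch(real: Tensor, fake: Tensor) -> Tensor:
    return l1_loss(
        Tensor(real.data[:, 0:1]), Tensor(real.data[:, 1:2]),
        _slice_channel(fake, 0), _slice_channel(fake, 1),
    )


def _dixon_from_batch(x: Tensor, fake: Tensor, input_mode: str) -> Tensor:
    fat_hat = _slice_channel(fake, 0)
    water_hat = _slice_channel(fake, 1)
    ip = Tensor(x.data[:, 0:1])
    if input_mode == "dual":
        op = Tensor(x.data[:, 1:2])
        return dixon_loss(ip, op, fat_hat, water_hat)
    # degenerate single-input mode (opt-in): only the IP relation is available
    r_ip = ip - (water_hat + fat_hat)
    axes = tuple(range(1, r_ip.data.ndim))
    return r_ip.square().mean(axis=axes).sqrt().mean()


def _slice_channel(t: Tensor, c: int) -> Tensor:
    data = t.data[:, c : c + 1]

    def backward(g):
        full = np.zeros_like(t.data)
        full[:, c : c + 1] = g
        t._accumulate(full)

    return Tensor._make(data, (t,), backward)
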