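"""Objective components of the adversarial fat-water separation model.

Three ingredients:

- the adversarial terms of the conditional GAN min-max game, in standard
  negative-log (binary cross-entropy) form over the PatchGAN score grid;
- an L1 reconstruction term, the mean absolute error of the predicted
  (F-hat, W-hat) pair against the scanner labels — swap-*sensitive*, since
  exchanging the channels changes the error wherever F != W;
- the physics-based Dixon loss, penalising violation of IP = W-hat + F-hat
  and OP = |W-hat - F-hat|, needing no fat/water labels — but inherently
  swap-*invariant*: globally exchanging the predicted channels leaves it
  unchanged, which is why it cannot be combined with a single-input (IP
  only) generator, whose physics term alone admits degenerate solutions
  (e.g. an empty W-hat and F-hat = IP).

The combined generator objective is ``adversarial + lambda * reconstruction``
with lambda = 100 by default.

Reduction conventions (fixed so printed example values are reproducible):
the L1 term is the mean absolute error over all voxels of both channels;
each ||.||_2 term of the Dixon loss is a per-volume root-mean-square,
averaged over the batch; adversarial terms are means over score-grid units
and batch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Tensor

__all__ = [
    "LossConfig",
    "adversarial_terms",
    "l1_loss",
    "dixon_loss",
    "generator_objective",
]


@dataclass(frozen=True)
class LossConfig:
    """Reconstruction-loss mode and its weight in the generator objective."""

    mode: str = "l1"
    lambda_weight: float = 100.0

    def __post_init__(self) -> None:
        if self.mode not in ("l1", "dixon"):
            raise ValueError(f"loss mode must be 'l1' or 'dixon', got {self.mode!r}")
        if self.lambda_weight <= 0:
            raise ValueError(f"lambda_weight must be positive, got {self.lambda_weight}")


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))


def _check_probabilities(scores: Tensor, name: str) -> None:
    if np.any(scores.data < 0.0) or np.any(scores.data > 1.0):
        raise ValueError(f"{name} must be probabilities in [0, 1]")


def adversarial_terms(d_real_scores, d_fake_scores) -> tuple[Tensor, Tensor]:
    """Discriminator and generator adversarial losses in negative-log form.

    The discriminator maximizes the log-likelihood of labelling real (F, W)
    pairs 1 and generated pairs 0; the generator minimizes
    ``-log D(G(.))``, the non-saturating form of its min-max term. Both
    reductions are means over score-grid units and batch. At maximal
    confusion (all scores 0.5) both terms equal log 2 per unit.
    """
    d_real = _as_tensor(d_real_scores)
    d_fake = _as_tensor(d_fake_scores)
    _check_probabilities(d_real, "d_real_scores")
    _check_probabilities(d_fake, "d_fake_scores")
    one_minus_fake = Tensor(np.ones_like(d_fake.data)) - d_fake
    d_loss = (d_real.log().mean() + one_minus_fake.log().mean()).scale(-0.5)
    g_loss = d_fake.log().mean().scale(-1.0)
    return d_loss, g_loss


def _shapes_match(*tensors: Tensor) -> None:
    ref = tensors[0].data.shape
    for t in tensors[1:]:
        if t.data.shape != ref:
            raise ValueError(f"shape mismatch: {ref} vs {t.data.shape}")


def l1_loss(fat, water, fat_hat, water_hat) -> Tensor:
    """Mean absolute error of the (F, W) pair over all voxels of both channels."""
    fat, water, fat_hat, water_hat = map(_as_tensor, (fat, water, fat_hat, water_hat))
    _shapes_match(fat, water, fat_hat, water_hat)
    return ((fat - fat_hat).abs().mean() + (water - water_hat).abs().mean()).scale(0.5)


def dixon_loss(ip, op, fat_hat, water_hat) -> Tensor:
    """Physics-consistency loss: RMS of the IP and OP residuals, summed.

    Zero iff the prediction satisfies both two-point Dixon relations.
    Invariant under a global exchange of the predicted channels — the
    documented weakness that makes it unusable with a single-input model.
    """
    ip, op, fat_hat, water_hat = map(_as_tensor, (ip, op, fat_hat, water_hat))
    _shapes_match(ip, op, fat_hat, water_hat)
    r_ip = ip - (water_hat + fat_hat)
    r_op = op - (water_hat - fat_hat).abs()
    # rank >= 4: leading axis is the batch; per-volume RMS, then batch mean
    if r_ip.data.ndim >= 4:
        axes = tuple(range(1, r_ip.data.ndim))
        return (r_ip.square().mean(axis=axes).sqrt() + r_op.square().mean(axis=axes).sqrt()).mean()
    return r_ip.square().mean().sqrt() + r_op.square().mean().sqrt()


def generator_objective(config: LossConfig, adversarial_g: Tensor, reconstruction: Tensor) -> Tensor:
    """Combined generator objective: adversarial + lambda * reconstruction."""
    adversarial_g = _as_tensor(adversarial_g)
    reconstruction = _as_tensor(reconstruction)
    return adversarial_g + reconstruction.scale(config.lambda_weight)
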