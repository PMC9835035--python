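"""Model / Results interface over the fat-water separation pipeline.

Mirrors the fitting idiom of statistical modelling packages: a
:class:`DixonCGAN` is constructed from data (a list of phantom or real
subjects) plus architecture and optimization configuration; ``fit()`` runs
the adversarial optimization and returns a :class:`DixonCGANResults`
carrying the trained generator, the loss history, prediction and evaluation
methods, and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .fields import ScalarField3D
from .inference import predict_volume
from .losses import LossConfig
from .metrics import MetricReport, evaluate_prediction
from .model import DiscriminatorConfig, GeneratorConfig, load_checkpoint, save_checkpoint
from .phantom import SubjectSample
from .trainer import TrainConfig, TrainHistory, train

__all__ = ["DixonCGAN", "DixonCGANResults"]


class DixonCGAN:
    """Conditional GAN for swap-free fat-water separation.

    Parameters
    ----------
    dataset : list of SubjectSample
        Training subjects; the clean fat/water channels are the labels.
    gen_config, disc_config, train_config : optional
        Architecture and optimization settings; defaults follow the
        full-scale configuration (six-level generator, 64 base filters,
        128-cubes, Adam lr 0.0002, batch 2, lambda 100).
    """

    def __init__(
        self,
        dataset: list[SubjectSample],
        gen_config: GeneratorConfig | None = None,
        disc_config: DiscriminatorConfig | None = None,
        train_config: TrainConfig | None = None,
    ):
        if not dataset:
            raise ValueError("dataset is empty")
        self.dataset = list(dataset)
        self.train_config = train_config or TrainConfig()
        gen_config = gen_config or GeneratorConfig()
        if gen_config.in_channels != self.train_config.in_channels:
            gen_config = replace(gen_config, in_channels=self.train_config.in_channels)
        self.gen_config = gen_config
        self.disc_config = disc_config or DiscriminatorConfig()

    def fit(self, epochs: int | None = None, seed: int | None = None) -> "DixonCGANResults":
        """Run adversarial training and return the results object."""
        cfg = self.train_config
        if epochs is not None:
            cfg = replace(cfg, epochs=epochs)
        if seed is not None:
            cfg = replace(cfg, seed=seed)
        generator, history = train(self.dataset, self.gen_config, self.disc_config, cfg)
        return DixonCGANResults(self, generator, history, cfg)


class DixonCGANResults:
    """Trained fat-water separation model and its training diagnostics."""

    def __init__(self, model: DixonCGAN, generator, history: TrainHistory, train_config: TrainConfig):
        self.model = model
        self.generator = generator
        self.history = history
        self.train_config = train_config

    # -- prediction ------------------------------------------------------
    def predict(
        self, ip: ScalarField3D, op: ScalarField3D | None = None, rescale: bool = False
    ) -> tuple[ScalarField3D, ScalarField3D]:
        """Whole-volume (fat_hat, water_hat) prediction, tiled at the
        training patch size (the tiling the model was optimized for)."""
        if self.train_config.input_mode == "single":
            op = None
        edge = min(self.train_config.patch_edge, min(ip.shape))
        edge -= edge % self.generator.config.divisor
        return predict_volume(self.generator, ip, op, rescale=rescale, patch_edge=edge)

    def evaluate(self, sample: SubjectSample, **kwargs) -> MetricReport:
        """Predict a subject and score it against its clean channels."""
        op = sample.clean.op if self.train_config.input_mode == "dual" else None
        fat_hat, water_hat = self.predict(sample.clean.ip, op, rescale=True)
        return evaluate_prediction(
            fat_hat, water_hat, sample.clean.fat, sample.clean.water,
            labels=sample.labels, **kwargs,
        )

    # -- persistence ------------------------------------------------------
    def save(self, path) -> None:
        save_checkpoint(
            path,
            self.generator,
            extra={
                "input_mode": self.train_config.input_mode,
                "loss_mode": self.train_config.loss.mode,
                "patch_edge": self.train_config.patch_edge,
            },
        )

    @staticmethod
    def load(path) -> "DixonCGANResults":
        generator, meta = load_checkpoint(path)
        cfg = TrainConfig(
            input_mode=meta.get("input_mode", "dual"),
            loss=LossConfig(mode=meta.get("loss_mode", "l1")),
            patch_edge=int(meta.get("patch_edge", 128)),
            allow_degenerate=True,
        )
        dummy_model = object.__new__(DixonCGAN)
        dummy_model.dataset = []
        dummy_model.gen_config = generator.config
        dummy_model.disc_config = DiscriminatorConfig()
        dummy_model.train_config = cfg
        return DixonCGANResults(dummy_model, generator, TrainHistory(), cfg)

    # -- reporting ---------------------------------------------------------
    def summary(self) -> str:
        cfg = self.train_config
        gen = self.generator
        lines = [
            "Dixon fat-water separation cGAN",
            "=" * 47,
            f"input mode:           {cfg.input_mode} ({'IP' if cfg.input_mode == 'single' else 'IP, OP'})",
            f"reconstruction loss:  {cfg.loss.mode} (lambda = {cfg.loss.lambda_weight:g})",
            f"generator levels:     {gen.config.levels} (filters {gen.config.filters})",
            f"generator parameters: {gen.n_parameters():,}",
            f"patch edge:           {cfg.patch_edge}",
            f"optimizer:            Adam(lr={cfg.learning_rate:g}, beta1={cfg.beta1}, beta2={cfg.beta2})",
            f"steps run:            {len(self.history)}",
        ]
        if len(self.history):
            k = max(1, len(self.history) // 10)
            lines += [
                f"final D loss:         {np.mean(self.history.d_loss[-k:]):.4f}",
                f"final G adversarial:  {np.mean(self.history.g_adversarial[-k:]):.4f}",
                f"final reconstruction: {np.mean(self.history.reconstruction[-k:]):.5f}",
            ]
        return "\n".join(lines)
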