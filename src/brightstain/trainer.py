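"""Training loops for the two regimes and epoch selection.

Regime 1 (U-Net): minimize the plain L1 reconstruction loss with Adam
(lr 2·10⁻⁴, weight decay 2·10⁻⁴), batch size 10, random aligned 256×256
crops, no augmentation; 50 epochs over 3000 training wells is 15,000
iterations.

Regime 2 (cWGAN-GP): continue from the L1-trained generator; batch size 4,
Adam lr 2·10⁻⁴ with (β1, β2) = (0, 0.9) for both networks, critic weight
decay 10⁻³; the critic takes 5 update steps per generator step, and the
adversarial weight follows λe = 1/epoch; 28 epochs over 3000 wells is
21,000 (critic) iterations.

Per-epoch validation metrics are recorded; the deployed checkpoint is the
epoch with the best mean validation PCC (ties go to the earlier epoch).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np

from . import nn
from .data_io import PairedField
from .image_metrics import MetricReport, evaluate_field
from .model_zoo import (CriticConfig, GeneratorConfig, PatchCritic,
                        UNetGenerator, build_critic, build_generator)
from .objectives import (LossWeights, critic_objective, generator_objective,
                         gradient_penalty, l1_loss)
from .tiling import predict_field


@dataclass
class TrainingConfig:
    patch_size: int = 256
    unet_batch: int = 10
    unet_epochs: int = 50
    gan_batch: int = 4
    gan_epochs: int = 28
    critic_steps_per_generator_step: int = 5
    gen_lr: float = 2e-4
    gen_betas_l1: tuple = (0.9, 0.999)
    gen_betas_gan: tuple = (0.0, 0.9)
    gen_weight_decay_l1: float = 2e-4
    critic_lr: float = 2e-4
    critic_betas: tuple = (0.0, 0.9)
    critic_weight_decay: float = 1e-3
    lambda_1: float = 100.0
    lambda_2: float = 10.0
    val_fraction: float = 0.1
    best_metric: str = "PCC"
    seed: int = 0

    def __post_init__(self):
        for name in ("patch_size", "unet_batch", "unet_epochs", "gan_batch",
                     "gan_epochs", "critic_steps_per_generator_step"):
            if getattr(self, name) < (0 if "epochs" in name else 1):
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")

    @property
    def weights(self) -> LossWeights:
        return LossWeights(self.lambda_1, self.lambda_2)


def iterations_per_epoch(n_train: int, batch: int) -> int:
    return math.ceil(n_train / batch)


def total_iterations(n_train: int, batch: int, epochs: int) -> int:
    """epochs × ⌈n/batch⌉ — e.g. 3000/10 × 50 = 15,000 and 3000/4 × 28 = 21,000."""
    return epochs * iterations_per_epoch(n_train, batch)


def sample_training_patch(field: PairedField, rng: np.random.Generator,
                          patch_size: int = 256):
    """One aligned random crop of brightfield and fluorescent stacks."""
    H, W = field.shape
    if H < patch_size or W < patch_size:
        raise ValueError(f"field {field.shape} smaller than patch {patch_size}")
    r = int(rng.integers(0, H - patch_size + 1))
    c = int(rng.integers(0, W - patch_size + 1))
    return (field.brightfield[:, r:r + patch_size, c:c + patch_size],
            field.fluorescent[:, r:r + patch_size, c:c + patch_size])


def split_train_val(fields: list, val_fraction: float, rng: np.random.Generator):
    n = len(fields)
    idx = rng.permutation(n)
    n_val = min(max(int(round(val_fraction * n)), 1), n - 1) if n > 1 else 0
    val_idx, train_idx = idx[:n_val], idx[n_val:]
    return [fields[i] for i in train_idx], [fields[i] for i in val_idx]


def _batch_tensors(fields, rng, patch_size):
    xs, ys = zip(*(sample_training_patch(f, rng, patch_size) for f in fields))
    return (nn.Tensor(np.stack(xs).astype(np.float32)),
            nn.Tensor(np.stack(ys).astype(np.float32)))


def _validate(generator: UNetGenerator, val_fields: list,
              patch_size: int) -> MetricReport | None:
    if not val_fields:
        return None
    reports = []
    for f in val_fields:
        H, W = f.shape
        d = generator.config.size_divisor
        if H % d == 0 and W % d == 0:
            pred = generator.predict(f.brightfield.astype(np.float32))
        else:
            pred = predict_field(generator, f, patch=patch_size, stride=patch_size // 2)
        reports.append(evaluate_field(pred, f.fluorescent))
    per_channel = sum(r.per_channel for r in reports) / len(reports)
    generator.train()
    return MetricReport(per_channel)


@dataclass
class TrainResult:
    """Checkpoint + per-epoch metric history from one training run."""

    generator: UNetGenerator
    best_state: dict
    final_state: dict
    history: list = dc_field(default_factory=list)  # one record per epoch
    critic: PatchCritic | None = None

    @property
    def best_epoch(self) -> int:
        return select_best_epoch([h["val"] for h in self.history]) if self.history else 0

    def restore_best(self) -> UNetGenerator:
        self.generator.load_state_dict(self.best_state)
        return self.generator


def select_best_epoch(history: list) -> int:
    """1-based index of the best validation epoch: argmax mean PCC, ties earliest."""
    if not history:
        raise ValueError("empty validation history")
    scores = []
    for h in history:
        if h is None:
            scores.append(float("-inf"))
        elif isinstance(h, MetricReport):
            scores.append(h.mean_pcc)
        else:
            scores.append(float(h))
    return int(np.argmax(scores)) + 1  # argmax takes the first maximum


def _check_finite(value: float, context: str):
    if not np.isfinite(value):
        raise RuntimeError(f"training diverged: non-finite {context} ({value})")


def train_unet(fields: list, config: TrainingConfig,
               generator_config: GeneratorConfig | None = None,
               generator: UNetGenerator | None = None,
               epochs: int | None = None, batch: int | None = None,
               lr: float | None = None) -> TrainResult:
    """Minimize L1 with Adam; returns checkpoint + per-epoch validation metrics.

    ``epochs``/``batch``/``lr`` override the config for scaled-down runs.
    """
    if not fields:
        raise ValueError("empty training set")
    epochs = config.unet_epochs if epochs is None else epochs
    batch = config.unet_batch if batch is None else batch
    rng = np.random.default_rng(config.seed)
    if generator is None:
        generator = build_generator(generator_config, seed=config.seed)
    patch = min(config.patch_size, min(f.shape[0] for f in fields))
    d = generator.config.size_divisor
    patch -= patch % d
    train_fields, val_fields = split_train_val(fields, config.val_fraction, rng)
    opt = nn.Adam(generator.parameters(), lr=lr if lr is not None else config.gen_lr,
                  betas=config.gen_betas_l1, weight_decay=config.gen_weight_decay_l1)
    result = TrainResult(generator, generator.state_dict(), generator.state_dict())
    best_pcc = float("-inf")
    n_iter = iterations_per_epoch(len(train_fields), batch)
    for epoch in range(1, epochs + 1):
        order = rng.permutation(len(train_fields))
        epoch_loss = 0.0
        for it in range(n_iter):
            members = [train_fields[i] for i in order[it * batch:(it + 1) * batch]]
            if not members:
                continue
            x, y = _batch_tensors(members, rng, patch)
            generator.zero_grad()
            loss = l1_loss(y, generator(x))
            _check_finite(loss.item(), f"L1 loss at epoch {epoch}")
            loss.backward()
            opt.step()
            epoch_loss += loss.item()
        val = _validate(generator, val_fields, patch)
        result.history.append({"epoch": epoch, "train_l1": epoch_loss / max(n_iter, 1),
                               "val": val})
        if val is not None and val.mean_pcc > best_pcc:
            best_pcc = val.mean_pcc
            result.best_state = generator.state_dict()
    result.final_state = generator.state_dict()
    if best_pcc == float("-inf"):
        result.best_state = result.final_state
    return result


def train_cwgan(fields: list, config: TrainingConfig,
                init_state: dict | None = None,
                generator_config: GeneratorConfig | None = None,
                critic_config: CriticConfig | None = None,
                epochs: int | None = None, batch: int | None = None) -> TrainResult:
    """Adversarial continuation: 5 critic steps per generator step, λe = 1/epoch.

    ``init_state`` is normally the L1-trained generator checkpoint; when
    None the generator starts cold.  Aborts with the last stable checkpoint
    if a loss goes non-finite.
    """
    if not fields:
        raise ValueError("empty training set")
    epochs = config.gan_epochs if epochs is None else epochs
    batch = config.gan_batch if batch is None else batch
    rng = np.random.default_rng(config.seed + 1)
    generator = build_generator(generator_config, seed=config.seed)
    if init_state is not None:
        generator.load_state_dict(init_state)
    critic = build_critic(critic_config, seed=config.seed + 7)
    weights = config.weights
    patch = min(config.patch_size, min(f.shape[0] for f in fields))
    patch -= patch % generator.config.size_divisor
    train_fields, val_fields = split_train_val(fields, config.val_fraction, rng)
    g_opt = nn.Adam(generator.parameters(), lr=config.gen_lr, betas=config.gen_betas_gan)
    c_opt = nn.Adam(critic.parameters(), lr=config.critic_lr, betas=config.critic_betas,
                    weight_decay=config.critic_weight_decay)
    result = TrainResult(generator, generator.state_dict(), generator.state_dict(),
                         critic=critic)
    best_pcc = float("-inf")
    n_iter = iterations_per_epoch(len(train_fields), batch)
    ratio = config.critic_steps_per_generator_step
    stable_state = generator.state_dict()
    counters = {"critic_steps": 0, "generator_steps": 0}
    try:
        for epoch in range(1, epochs + 1):
            lam_e = weights.lambda_e(epoch)
            order = rng.permutation(len(train_fields))
            for it in range(n_iter):
                members = [train_fields[i] for i in order[it * batch:(it + 1) * batch]]
                if not members:
                    continue
                x, y = _batch_tensors(members, rng, patch)
                # critic step
                with nn.no_grad():
                    fake = generator(x)
                critic.zero_grad()
                score_real = critic.score(x, y)
                score_fake = critic.score(x, fake)
                gp = gradient_penalty(critic, x, y, fake, rng)
                c_loss = critic_objective(score_real, score_fake, gp, weights)
                _check_finite(c_loss.item(), f"critic loss at epoch {epoch}")
                c_loss.backward()
                c_opt.step()
                counters["critic_steps"] += 1
                # generator step every `ratio` batches, on the same batch
                if counters["critic_steps"] % ratio == 0:
                    generator.zero_grad()
                    critic.zero_grad()
                    pred = generator(x)
                    l1 = l1_loss(y, pred)
                    adv_score = critic.score(x, pred)
                    g_loss = generator_objective(l1, adv_score, weights, epoch)
                    _check_finite(g_loss.item(), f"generator loss at epoch {epoch}")
                    g_loss.backward()
                    g_opt.step()
                    critic.zero_grad()
                    counters["generator_steps"] += 1
            stable_state = generator.state_dict()
            val = _validate(generator, val_fields, patch)
            result.history.append({"epoch": epoch, "lambda_e": lam_e, "val": val,
                                   **counters})
            if val is not None and val.mean_pcc > best_pcc:
                best_pcc = val.mean_pcc
                result.best_state = generator.state_dict()
    except RuntimeError:
        generator.load_state_dict(stable_state)
        result.final_state = stable_state
        raise
    result.final_state = generator.state_dict()
    if best_pcc == float("-inf"):
        result.best_state = result.final_state
    return result
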