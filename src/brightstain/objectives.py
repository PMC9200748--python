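"""Loss terms for the two training regimes.

The U-Net regime minimizes a plain L1 reconstruction loss

    L_L1 = E[ ||y - G(x)||_1 ]

realized as the mean absolute difference over batch, channels and pixels.

The conditional WGAN-GP regime adds a Wasserstein critic D(x, ·) over the
concatenated (brightfield, fluorescent) pair:

    generator:  L_G = λ1·L_L1 − λe·E[D(x, G(x))]
    critic:     minimize  −(E[D(x,y)] − E[D(x,G(x))]) + λ2·L_GP

with λ1 = 100, λ2 = 10 and the adaptive adversarial weight λe = 1/epoch
(1-based), which damps the unbounded critic score as training proceeds.
The gradient penalty is the squared WGAN-GP form,

    L_GP = E[ (||∇_x̂ D(x, x̂)||_2 − 1)^2 ],

evaluated at per-sample uniform interpolates x̂ = t·y + (1−t)·G(x); it is
the soft 1-Lipschitz constraint that replaces weight clipping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Tensor, grad
from .nn import tensor as T


@dataclass
class LossWeights:
    """λ1 (L1 weight), λ2 (gradient-penalty weight); λe is the 1/epoch schedule."""

    lambda_1: float = 100.0
    lambda_2: float = 10.0

    def __post_init__(self):
        if self.lambda_1 < 0 or self.lambda_2 < 0:
            raise ValueError("loss weights must be non-negative")

    @staticmethod
    def lambda_e(epoch: int) -> float:
        """Adaptive adversarial weight, 1/epoch with 1-based epochs."""
        if epoch < 1:
            raise ValueError(f"epoch must be >= 1 (1-based), got {epoch}")
        return 1.0 / epoch


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def l1_loss(target, prediction) -> Tensor:
    """Mean absolute difference over all entries."""
    target, prediction = _as_tensor(target), _as_tensor(prediction)
    if target.shape != prediction.shape:
        raise ValueError(f"shape mismatch: target {target.shape} vs prediction {prediction.shape}")
    return T.absolute(target - prediction).mean()


def gradient_penalty(critic, brightfield, real, fake, rng: np.random.Generator) -> Tensor:
    """Squared gradient penalty at random interpolates between real and fake.

    One uniform t ∈ [0,1] per sample; the critic score is reduced per sample
    (mean over its patch-score map) and summed over the batch before
    differentiating, so each sample's gradient is independent of batch size.
    Returns a Tensor whose graph reaches the critic weights (double backward).
    """
    brightfield, real, fake = _as_tensor(brightfield), _as_tensor(real), _as_tensor(fake)
    if real.shape != fake.shape:
        raise ValueError(f"shape mismatch: real {real.shape} vs fake {fake.shape}")
    B = real.shape[0]
    t = rng.uniform(0.0, 1.0, size=(B, 1, 1, 1)).astype(real.dtype)
    xhat = Tensor(t * real.data + (1.0 - t) * fake.data, requires_grad=True)
    score_map = critic(brightfield, xhat)            # (B, 1, h, w)
    per_sample = score_map.mean(axis=(1, 2, 3))      # (B,)
    total = per_sample.sum()
    (gx,) = grad(total, [xhat], create_graph=True)
    if gx is None:
        raise ValueError("critic score does not depend on its fluorescent input")
    sq = (gx ** 2).sum(axis=(1, 2, 3))
    norms = (sq + 1e-12) ** 0.5
    return ((norms - 1.0) ** 2).mean()


def generator_objective(l1, critic_score_on_fake, weights: LossWeights, epoch: int):
    """λ1·L_L1 − λe(epoch)·E[D(x, G(x))]; the quantity the generator minimizes."""
    lam_e = weights.lambda_e(epoch)
    return weights.lambda_1 * _as_tensor(l1) - lam_e * _as_tensor(critic_score_on_fake)


def critic_objective(score_real, score_fake, gp, weights: LossWeights):
    """−(E[D(x,y)] − E[D(x,G(x))]) + λ2·L_GP; the quantity the critic minimizes.

    Minimizing this maximizes the real−fake score gap (the Wasserstein-1
    surrogate) while penalizing gradient norms away from 1.
    """
    return -(_as_tensor(score_real) - _as_tensor(score_fake)) + weights.lambda_2 * _as_tensor(gp)
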