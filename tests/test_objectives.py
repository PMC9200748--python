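"""Loss-term correctness: L1, gradient penalty, the two objectives, λe."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from brightstain import nn
from brightstain.model_zoo import CriticConfig, build_critic
from brightstain.nn import Tensor
from brightstain.objectives import (LossWeights, critic_objective,
                                    generator_objective, gradient_penalty,
                                    l1_loss)


class TestL1:
    def test_identity_is_zero(self, rng):
        a = rng.normal(size=(2, 5, 8, 8))
        assert l1_loss(a, a).item() == 0.0

    def test_constant_offset(self, rng):
        a = rng.normal(size=(2, 5, 8, 8))
        assert l1_loss(a, a + 0.5).item() == pytest.approx(0.5, abs=1e-12)

    def test_matches_elementwise_oracle(self, rng):
        y = rng.normal(size=(3, 5, 6, 6))
        yh = rng.normal(size=(3, 5, 6, 6))
        total = 0.0
        for b in range(3):
            for c in range(5):
                total += sum(abs(y[b, c, i, j] - yh[b, c, i, j])
                             for i in range(6) for j in range(6))
        assert l1_loss(y, yh).item() == pytest.approx(total / y.size, rel=1e-12)

    def test_shape_mismatch_raises(self, rng):
        with pytest.raises(ValueError, match="shape"):
            l1_loss(rng.normal(size=(1, 5, 8, 8)), rng.normal(size=(1, 5, 4, 4)))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10 ** 6))
    def test_nonnegative_and_zero_iff_equal(self, seed):
        r = np.random.default_rng(seed)
        y, yh = r.normal(size=(4, 4)), r.normal(size=(4, 4))
        val = l1_loss(y, yh).item()
        assert val >= 0
        assert (val == 0) == np.array_equal(y, yh)


class _LinearCritic:
    """D(x, x̂) = <c, x̂> as a callable with a score map interface."""

    def __init__(self, c):
        self.c = Tensor(np.asarray(c, dtype=np.float64))

    def __call__(self, bf, fl):
        return (fl * self.c).sum(axis=(1, 2, 3), keepdims=True).reshape(
            (fl.shape[0], 1, 1, 1))


class TestGradientPenalty:
    def test_unit_gradient_linear_critic_has_zero_penalty(self, rng):
        c = rng.normal(size=(1, 5, 4, 4))
        c /= np.sqrt((c ** 2).sum())
        critic = _LinearCritic(c)
        bf = rng.normal(size=(2, 3, 4, 4))
        gp = gradient_penalty(critic, bf, rng.normal(size=(2, 5, 4, 4)),
                              rng.normal(size=(2, 5, 4, 4)), rng)
        assert gp.item() == pytest.approx(0.0, abs=1e-9)

    def test_constant_critic_has_unit_penalty(self, rng):
        critic = _LinearCritic(np.zeros((1, 5, 4, 4)))
        gp = gradient_penalty(critic, rng.normal(size=(2, 3, 4, 4)),
                              rng.normal(size=(2, 5, 4, 4)),
                              rng.normal(size=(2, 5, 4, 4)), rng)
        assert gp.item() == pytest.approx(1.0, abs=1e-5)

    def test_critic_gradient_matches_finite_differences(self):
        """∇_x̂ of the real critic agrees with central differences to 1e-3 relative."""
        rng = np.random.default_rng(5)
        critic = build_critic(CriticConfig(n_layers=2, final_filters=16), seed=11)
        for p in critic.parameters():
            p.data = p.data.astype(np.float64)
        bf = Tensor(rng.normal(size=(1, 3, 8, 8)))
        xhat = rng.normal(size=(1, 5, 8, 8))

        x = Tensor(xhat.copy(), requires_grad=True)
        (g,) = nn.grad(critic(bf, x).mean(axis=(1, 2, 3)).sum(), [x])
        fd = np.zeros_like(xhat)
        it = np.nditer(xhat, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            for sgn in (1, -1):
                xp = xhat.copy()
                xp[idx] += sgn * 1e-5
                fd[idx] += sgn * critic(bf, Tensor(xp)).mean(axis=(1, 2, 3)).sum().item()
            fd[idx] /= 2e-5
        rel = np.abs(fd - g.data).max() / (np.abs(fd).max() + 1e-12)
        assert rel < 1e-3

    def test_penalty_is_nonnegative(self, rng):
        critic = build_critic(CriticConfig(n_layers=2, final_filters=16), seed=12)
        gp = gradient_penalty(critic,
                              rng.normal(size=(3, 3, 8, 8)).astype(np.float32),
                              rng.normal(size=(3, 5, 8, 8)).astype(np.float32),
                              rng.normal(size=(3, 5, 8, 8)).astype(np.float32), rng)
        assert gp.item() >= 0


class TestObjectives:
    def test_generator_objective_arithmetic(self):
        w = LossWeights(lambda_1=100.0)
        val = generator_objective(0.5, 2.0, w, epoch=1)
        assert val.item() == pytest.approx(100 * 0.5 - 1 * 2.0) == pytest.approx(48.0)

    def test_lambda_e_schedule(self):
        assert LossWeights.lambda_e(1) == 1.0
        assert LossWeights.lambda_e(28) == pytest.approx(1 / 28)
        # halves per doubling of epoch
        for k in (1, 3, 10):
            assert LossWeights.lambda_e(2 * k) / LossWeights.lambda_e(k) == pytest.approx(0.5)
        with pytest.raises(ValueError, match="epoch"):
            LossWeights.lambda_e(0)

    def test_zero_adversarial_weight_limit_is_weighted_l1(self):
        w = LossWeights(lambda_1=100.0)
        huge_epoch = 10 ** 9  # λe → 0
        val = generator_objective(0.37, 123.0, w, epoch=huge_epoch)
        assert val.item() == pytest.approx(37.0, rel=1e-6)

    def test_generator_rewarded_for_fooling_critic(self):
        w = LossWeights()
        lo = generator_objective(0.5, 5.0, w, epoch=2).item()
        hi = generator_objective(0.5, 1.0, w, epoch=2).item()
        assert lo < hi  # higher critic score on fakes => lower generator loss

    def test_critic_objective_arithmetic(self):
        w = LossWeights(lambda_2=10.0)
        val = critic_objective(1.0, 0.2, 0.05, w)
        assert val.item() == pytest.approx(-0.8 + 0.5) == pytest.approx(-0.3)

    def test_indifferent_critic_scores_zero(self):
        assert critic_objective(0.7, 0.7, 0.0, LossWeights()).item() == 0.0

    def test_linear_critic_recovers_wasserstein_distance_on_point_masses(self):
        """Maximizing real−fake over 1-Lipschitz linear critics on two 1-D
        point masses a, b approaches W1 = |a − b|."""
        a, b = 2.0, -1.0  # real at a, fake at b; W1 = 3
        w = Tensor(np.array([0.1]), requires_grad=True)
        # a stiff penalty weight keeps the soft Lipschitz constraint tight
        weights = LossWeights(lambda_2=200.0)
        opt = nn.Adam([w], lr=0.05)
        rng = np.random.default_rng(0)
        for _ in range(400):
            w.grad = None
            score_real = (w * a).sum()
            score_fake = (w * b).sum()
            # gradient penalty for D(x) = w·x: ||∇|| = |w|
            t = rng.uniform()
            _ = t  # the interpolate's gradient is w regardless of t
            gp = ((w ** 2).sum() ** 0.5 - 1.0) ** 2
            loss = critic_objective(score_real, score_fake, gp, weights)
            loss.backward()
            opt.step()
        gap = float(w.data[0] * a - w.data[0] * b)
        assert gap == pytest.approx(abs(a - b), rel=0.05)
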