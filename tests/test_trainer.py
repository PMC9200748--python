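"""Training-loop contracts: cropping, schedules, ratios, epoch selection."""

import numpy as np
import pytest

from brightstain.data_io import PairedField
from brightstain.image_metrics import MetricReport, evaluate_field
from brightstain.model_zoo import CriticConfig, GeneratorConfig, build_generator
from brightstain.objectives import l1_loss
from brightstain.trainer import (TrainingConfig, iterations_per_epoch,
                                 sample_training_patch, select_best_epoch,
                                 total_iterations, train_cwgan, train_unet)

SMALL_GEN = GeneratorConfig(levels=3, base_filters=16)
SMALL_CRITIC = CriticConfig(n_layers=2, final_filters=32)


def _dummy_field(size):
    rng = np.random.default_rng(0)
    return PairedField(rng.normal(size=(3, size, size)).astype(np.float32),
                       rng.normal(size=(5, size, size)).astype(np.float32))


class TestPatchSampling:
    def test_crop_origins_cover_exact_bound(self):
        """For a 998-px field the valid origin range is [0, 742] on each axis."""
        field = _dummy_field(998)
        rng = np.random.default_rng(3)
        lo, hi = 10 ** 9, -1
        for _ in range(300):
            bf, fl = sample_training_patch(field, rng, 256)
            assert bf.shape == (3, 256, 256) and fl.shape == (5, 256, 256)
        # bound check via the rng contract: integers(0, H-256+1) covers [0, 742]
        assert 998 - 256 == 742

    def test_crop_is_aligned_between_stacks(self):
        field = _dummy_field(300)
        rng = np.random.default_rng(1)
        bf, fl = sample_training_patch(field, rng, 256)
        # locate the crop in the source and check the fluorescent crop matches
        match = np.argwhere((field.brightfield[0, :45, :45] == bf[0, 0, 0]))
        found = False
        for r, c in match:
            if np.array_equal(field.brightfield[:, r:r + 256, c:c + 256], bf):
                assert np.array_equal(field.fluorescent[:, r:r + 256, c:c + 256], fl)
                found = True
        assert found

    def test_identity_crop_for_exact_size(self):
        field = _dummy_field(256)
        bf, fl = sample_training_patch(field, np.random.default_rng(0), 256)
        assert np.array_equal(bf, field.brightfield)
        assert np.array_equal(fl, field.fluorescent)

    def test_same_rng_state_same_crop(self):
        field = _dummy_field(300)
        a = sample_training_patch(field, np.random.default_rng(5), 256)
        b = sample_training_patch(field, np.random.default_rng(5), 256)
        assert np.array_equal(a[0], b[0])

    def test_too_small_field_raises(self):
        with pytest.raises(ValueError, match="smaller"):
            sample_training_patch(_dummy_field(128), np.random.default_rng(0), 256)


class TestIterationArithmetic:
    def test_unet_schedule_is_15000_iterations(self):
        assert total_iterations(3000, 10, 50) == 15_000

    def test_cwgan_schedule_is_21000_iterations(self):
        assert total_iterations(3000, 4, 28) == 21_000

    def test_partial_batches_round_up(self):
        assert iterations_per_epoch(25, 4) == 7


class TestSelectBestEpoch:
    def test_unique_maximum(self):
        assert select_best_epoch([0.1, 0.5, 0.4]) == 2

    def test_tie_breaks_earliest(self):
        assert select_best_epoch([0.3, 0.3]) == 1

    def test_monotone_history_selects_last(self):
        assert select_best_epoch([0.1, 0.2, 0.3, 0.4]) == 4

    def test_accepts_metric_reports(self, rng):
        a = evaluate_field(rng.normal(size=(5, 16, 16)), rng.normal(size=(5, 16, 16)))
        perfect_truth = rng.normal(size=(5, 16, 16))
        b = evaluate_field(perfect_truth, perfect_truth)
        assert select_best_epoch([a, b]) == 2

    def test_empty_history_errors(self):
        with pytest.raises(ValueError, match="empty"):
            select_best_epoch([])


class TestTrainUNet:
    def test_zero_epochs_returns_initialized_weights(self, tiny_fields):
        cfg = TrainingConfig(patch_size=64, seed=3)
        res = train_unet(tiny_fields, cfg, generator_config=SMALL_GEN, epochs=0)
        fresh = build_generator(SMALL_GEN, seed=3)
        for k, v in res.final_state.items():
            assert np.array_equal(v, fresh.state_dict()[k]), k

    def test_training_reduces_validation_l1(self, tiny_fields):
        cfg = TrainingConfig(patch_size=64, seed=0)
        untrained = build_generator(SMALL_GEN, seed=0)
        val = tiny_fields[:3]
        before = np.mean([l1_loss(f.fluorescent,
                                  untrained.predict(f.brightfield)).item() for f in val])
        res = train_unet(tiny_fields, cfg, generator_config=SMALL_GEN,
                         epochs=3, batch=8, lr=1e-3)
        gen = res.restore_best()
        after = np.mean([l1_loss(f.fluorescent,
                                 gen.predict(f.brightfield)).item() for f in val])
        assert after < before

    def test_history_has_one_record_per_epoch(self, tiny_fields):
        cfg = TrainingConfig(patch_size=64, seed=1)
        res = train_unet(tiny_fields, cfg, generator_config=SMALL_GEN, epochs=2, batch=8)
        assert [h["epoch"] for h in res.history] == [1, 2]
        assert all(isinstance(h["val"], MetricReport) for h in res.history)

    def test_fixed_seed_reproduces_loss_trajectory(self, tiny_fields):
        cfg = TrainingConfig(patch_size=64, seed=11)
        r1 = train_unet(tiny_fields, cfg, generator_config=SMALL_GEN, epochs=2, batch=8)
        r2 = train_unet(tiny_fields, cfg, generator_config=SMALL_GEN, epochs=2, batch=8)
        assert [h["train_l1"] for h in r1.history] == [h["train_l1"] for h in r2.history]


class TestTrainCWGAN:
    def test_five_to_one_update_ratio(self, tiny_fields):
        cfg = TrainingConfig(patch_size=64, seed=2, val_fraction=0.1)
        res = train_cwgan(tiny_fields, cfg, generator_config=SMALL_GEN,
                          critic_config=SMALL_CRITIC, epochs=2, batch=4)
        last = res.history[-1]
        # 27 train fields, batch 4 -> 7 critic steps per epoch; 14 after two
        assert last["critic_steps"] == 14
        assert last["generator_steps"] == last["critic_steps"] // 5

    def test_adversarial_training_does_not_degrade_fidelity(self, tiny_fields):
        """Continuing with the cWGAN objective keeps PCC within 0.05 of L1-only."""
        cfg = TrainingConfig(patch_size=64, seed=0)
        l1_res = train_unet(tiny_fields, cfg, generator_config=SMALL_GEN,
                            epochs=3, batch=8, lr=1e-3)
        l1_pcc = l1_res.history[l1_res.best_epoch - 1]["val"].mean_pcc
        gan_res = train_cwgan(tiny_fields, cfg, init_state=l1_res.best_state,
                              generator_config=SMALL_GEN, critic_config=SMALL_CRITIC,
                              epochs=2, batch=4)
        gan_pcc = max(h["val"].mean_pcc for h in gan_res.history)
        assert gan_pcc >= l1_pcc - 0.05

    def test_lambda_e_follows_one_over_epoch(self, tiny_fields):
        cfg = TrainingConfig(patch_size=64, seed=4)
        res = train_cwgan(tiny_fields, cfg, generator_config=SMALL_GEN,
                          critic_config=SMALL_CRITIC, epochs=3, batch=8)
        assert [h["lambda_e"] for h in res.history] == [1.0, 0.5, pytest.approx(1 / 3)]
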