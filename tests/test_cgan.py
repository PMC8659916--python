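"""Loss closed forms, training-loop contracts, epoch selection and inference
for the adversarial hologram-to-phase model (desk-scale configurations)."""

import numpy as np
import pytest

from holophase.cgan import (
    DiscriminatorConfig,
    EpochMetrics,
    GeneratorConfig,
    LossWeights,
    TrainConfig,
    TrainingData,
    bce_loss,
    build_discriminator,
    build_generator,
    discriminator_loss,
    generator_loss,
    infer,
    select_best_epoch,
    train,
    train_generator_supervised,
)

TINY_G = GeneratorConfig(input_size=32, encoder_depth=5, base_filters=4, max_filters=16)
TINY_D = DiscriminatorConfig(base_filters=4, max_filters=16)


def tiny_data(n=8, seed=0, size=32):
    rng = np.random.default_rng(seed)
    x = rng.uniform(-1, 1, (n, size, size))
    y = np.clip(x * 0.5, -1, 1)
    return TrainingData(train_x=x, train_y=y, val_x=x[:4], val_y=y[:4])


class TestLosses:
    def test_half_scores_give_log_two(self):
        scores = np.full((1, 4, 4), 0.5)
        l_real, l_fake = discriminator_loss(scores, scores)
        assert l_real == pytest.approx(np.log(2))
        assert l_fake == pytest.approx(np.log(2))

    def test_perfect_discrimination_near_zero_loss(self):
        real = np.full((1, 4, 4), 1.0 - 1e-7)
        fake = np.full((1, 4, 4), 1e-7)
        l_real, l_fake = discriminator_loss(real, fake)
        assert l_real < 1e-6 and l_fake < 1e-6

    def test_label_symmetry(self):
        rng = np.random.default_rng(0)
        scores = rng.uniform(0.01, 0.99, (2, 4, 4))
        _, l_fake = discriminator_loss(scores, scores)
        l_real_flipped, _ = discriminator_loss(1.0 - scores, scores)
        assert l_fake == pytest.approx(l_real_flipped, rel=1e-12)

    def test_extreme_scores_are_clamped_finite(self):
        loss, grad = bce_loss(np.array([[0.0, 1.0]]), 0.0)
        assert np.isfinite(loss) and np.all(np.isfinite(grad))

    def test_generator_loss_decomposition(self):
        scores = np.full((1, 4, 4), 0.5)
        target = np.zeros((1, 3, 8, 8))
        generated = np.full((1, 3, 8, 8), 0.01)
        adv_only = generator_loss(scores, target, target, LossWeights(lambda_l1=100))
        assert adv_only == pytest.approx(np.log(2))  # identical images: pure adversarial
        full = generator_loss(scores, generated, target, LossWeights(lambda_l1=100))
        assert full - adv_only == pytest.approx(1.0, rel=1e-9)  # 100 x 0.01
        assert generator_loss(scores, generated, target, LossWeights(lambda_l1=0)) == pytest.approx(
            np.log(2)
        )


class TestTrainLoop:
    def test_zero_epochs_is_a_noop(self):
        ckpts, hist = train(tiny_data(), TINY_G, TINY_D, TrainConfig(epochs=0, batch_size=4))
        assert ckpts == [] and hist == []

    def test_single_epoch_is_deterministic(self):
        cfg = TrainConfig(epochs=1, batch_size=4, seed=3, std_sample_size=2)
        _, h1 = train(tiny_data(), TINY_G, TINY_D, cfg)
        _, h2 = train(tiny_data(), TINY_G, TINY_D, cfg)
        assert h1[0].gen_loss == h2[0].gen_loss
        assert h1[0].disc_loss == h2[0].disc_loss
        assert h1[0].mean_tsm_val == h2[0].mean_tsm_val

    def test_checkpoints_and_metrics_per_epoch(self, tmp_path):
        cfg = TrainConfig(epochs=2, batch_size=4, seed=1, std_sample_size=2)
        ckpts, hist = train(tiny_data(), TINY_G, TINY_D, cfg, checkpoint_dir=tmp_path)
        assert len(ckpts) == len(hist) == 2
        assert [m.epoch for m in hist] == [1, 2]
        assert sorted(p.name for p in tmp_path.glob("*.npz")) == [
            "generator_epoch001.npz",
            "generator_epoch002.npz",
        ]

    def test_supervised_baseline_reduces_l1(self):
        cfg = TrainConfig(epochs=3, batch_size=4, seed=0, std_sample_size=2)
        _, hist = train_generator_supervised(tiny_data(16), TINY_G, cfg, loss="l1")
        assert hist[-1].gen_loss < hist[0].gen_loss


class TestSelectBestEpoch:
    @staticmethod
    def curves(tsm_vals, std_vals):
        return [
            EpochMetrics(epoch=i + 1, mean_tsm_train=t, mean_tsm_val=t,
                         mean_std_train=s, mean_std_val=s)
            for i, (t, s) in enumerate(zip(tsm_vals, std_vals))
        ]

    def test_plateau_at_10_std_minimum_at_12_selects_12(self):
        # TSM falls steeply then flattens after epoch 10; STD dips at 12
        tsm_vals = [0.5, 0.4, 0.3, 0.25, 0.2, 0.16, 0.12, 0.09, 0.06, 0.05,
                    0.049, 0.048, 0.048, 0.049, 0.05]
        std_vals = [0.9, 0.8, 0.7, 0.6, 0.5, 0.45, 0.4, 0.35, 0.3, 0.28,
                    0.26, 0.20, 0.24, 0.27, 0.3]
        assert select_best_epoch(self.curves(tsm_vals, std_vals), tsm_plateau_tol=0.02) == 12

    def test_monotone_std_with_immediate_plateau_selects_last(self):
        tsm_vals = [0.1, 0.1, 0.1, 0.1]
        std_vals = [0.4, 0.3, 0.2, 0.1]
        assert select_best_epoch(self.curves(tsm_vals, std_vals)) == 4

    def test_equal_std_minima_tie_goes_to_earlier_epoch(self):
        tsm_vals = [0.1, 0.1, 0.1, 0.1]
        std_vals = [0.4, 0.2, 0.3, 0.2]
        assert select_best_epoch(self.curves(tsm_vals, std_vals)) == 2

    def test_no_plateau_warns_and_falls_back(self):
        tsm_vals = [0.9, 0.6, 0.3]
        std_vals = [0.3, 0.2, 0.4]
        with pytest.warns(UserWarning, match="plateau"):
            assert select_best_epoch(self.curves(tsm_vals, std_vals), tsm_plateau_tol=0.01) == 2


class TestInfer:
    def test_output_shape_matches_patch_and_is_deterministic(self):
        gen = build_generator(TINY_G, seed=0)
        holo = np.random.default_rng(0).uniform(-1, 1, (32, 32))
        p1 = infer(gen, holo)
        p2 = infer(gen, holo)
        assert p1.shape == (32, 32)
        assert np.array_equal(p1, p2)
        assert np.all(np.abs(p1) < np.pi)

    def test_full_frame_tiled_on_floor_grid(self):
        gen = build_generator(TINY_G, seed=0)
        frame = np.random.default_rng(1).uniform(-1, 1, (64, 96))
        out = infer(gen, frame)
        assert out.shape == (64, 96)
        tile = infer(gen, frame[:32, 32:64])
        assert np.array_equal(out[:32, 32:64], tile)

    def test_small_input_requires_resize_flag(self):
        gen = build_generator(TINY_G, seed=0)
        small = np.zeros((16, 16))
        with pytest.raises(ValueError, match="resize"):
            infer(gen, small)
        assert infer(gen, small, resize=True).shape == (32, 32)

    def test_checkpoint_round_trip(self):
        gen = build_generator(TINY_G, seed=0)
        holo = np.random.default_rng(2).uniform(-1, 1, (32, 32))
        state = gen.state_dict()
        before = infer(gen, holo)
        fresh = build_generator(TINY_G, seed=99)
        after = infer(fresh, holo, checkpoint=state)
        assert np.array_equal(before, after)


def test_discriminator_config_validation():
    with pytest.raises(ValueError):
        DiscriminatorConfig(conv_layers=5, strides=(2, 2, 2, 2, 1, 1))
    with pytest.raises(ValueError):
        GeneratorConfig(input_size=100)
    with pytest.raises(ValueError):
        LossWeights(lambda_l1=-1)
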