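"""Generalized dice loss, 1cycle schedule, augmentation, training loop."""

from dataclasses import replace

import numpy as np
import pytest

from csfseg.model import DESK_PROFILE, build_model
from csfseg.phantom import PhantomConfig, generate_phantom
from csfseg.training import (
    OneCycleSchedule,
    TrainConfig,
    augment,
    generalized_dice_loss,
    one_cycle,
    train,
)


def gdl_oracle(probs: np.ndarray, target: np.ndarray, eps: float = 1e-7) -> float:
    """Scalar-loop reference implementation of the generalized dice loss."""
    n_classes = probs.shape[0]
    num = 0.0
    den = 0.0
    for l in range(n_classes):
        r = target[l].ravel()
        p = probs[l].ravel()
        w = 1.0 / (float(r.sum()) ** 2 + eps)
        inter = 0.0
        sums = 0.0
        for i in range(r.size):
            inter += float(r[i]) * float(p[i])
            sums += float(r[i]) + float(p[i])
        num += w * inter
        den += w * sums
    return 1.0 - (2.0 * num + eps) / (den + eps)


class TestGeneralizedDiceLoss:
    def test_perfect_prediction_is_zero(self):
        target = np.zeros((2, 8, 8))
        target[1, 2:5, 2:5] = 1
        target[0] = 1 - target[1]
        loss = generalized_dice_loss(target.copy(), target)
        assert 0.0 <= loss.item() <= 1e-6

    def test_two_pixel_uniform_case(self):
        # two pixels, two classes, one pixel per class, probabilities 0.5:
        # weights are 1, intersection 0.5 per class, denominator 2 per class
        # -> 1 - 2*1/4 = 0.5
        probs = np.full((2, 2), 0.5)
        target = np.eye(2)
        assert generalized_dice_loss(probs, target).item() == pytest.approx(0.5, abs=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scalar_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        logits = rng.normal(size=(2, 8, 8))
        e = np.exp(logits)
        probs = e / e.sum(axis=0, keepdims=True)
        labels = (rng.random((8, 8)) < 0.25).astype(int)
        target = np.stack([1 - labels, labels]).astype(float)
        ours = generalized_dice_loss(probs, target).item()
        assert ours == pytest.approx(gdl_oracle(probs, target), abs=1e-6)
        assert 0.0 <= ours <= 1.0

    def test_monotone_toward_target(self):
        # moving probability mass toward the target strictly lowers the loss
        rng = np.random.default_rng(1)
        labels = (rng.random((8, 8)) < 0.2).astype(int)
        target = np.stack([1 - labels, labels]).astype(float)
        uniform = np.full_like(target, 0.5)
        losses = []
        for t in np.linspace(0.0, 1.0, 10):
            probs = (1 - t) * uniform + t * target
            losses.append(generalized_dice_loss(probs, target).item())
        assert all(a > b for a, b in zip(losses, losses[1:]))

    def test_batched_input(self):
        rng = np.random.default_rng(2)
        labels = (rng.random((3, 4, 4)) < 0.3).astype(int)
        target = np.stack([1 - labels, labels], axis=1).astype(float)
        probs = np.full_like(target, 0.5)
        # batch is pooled into the voxel sum: same as concatenating slices
        flat_target = np.concatenate([target[i] for i in range(3)], axis=-1)
        flat_probs = np.concatenate([probs[i] for i in range(3)], axis=-1)
        assert generalized_dice_loss(probs, target).item() == pytest.approx(
            generalized_dice_loss(flat_probs, flat_target).item(), abs=1e-12
        )

    def test_shape_mismatch_error(self):
        with pytest.raises(ValueError, match="shape"):
            generalized_dice_loss(np.zeros((2, 4)), np.zeros((2, 5)))

    def test_rejects_non_one_hot(self):
        with pytest.raises(ValueError, match="one-hot"):
            generalized_dice_loss(np.full((2, 4), 0.5), np.full((2, 4), 0.5))


class TestOneCycle:
    SCHED = OneCycleSchedule(total_steps=100)

    def test_start_point(self):
        lr, mom = one_cycle(0, self.SCHED, max_lr=1e-2)
        assert lr == pytest.approx(1e-2 / 25)
        assert mom == pytest.approx(0.95)

    def test_peak_at_pct_start(self):
        lr, mom = one_cycle(30, self.SCHED, max_lr=1e-2)
        assert lr == pytest.approx(1e-2)
        assert mom == pytest.approx(0.85)

    def test_end_point(self):
        lr, mom = one_cycle(100, self.SCHED, max_lr=1e-2)
        assert lr == pytest.approx(1e-2 / 1e4)
        assert mom == pytest.approx(0.95)

    def test_single_local_maximum(self):
        lrs = [one_cycle(s, self.SCHED, 1e-2)[0] for s in range(101)]
        peaks = [
            i
            for i in range(1, 100)
            if lrs[i] >= lrs[i - 1] and lrs[i] >= lrs[i + 1]
        ]
        assert peaks == [30]
        assert lrs[0] < lrs[30] and lrs[-1] < lrs[0]

    def test_out_of_range_step(self):
        with pytest.raises(ValueError):
            one_cycle(101, self.SCHED, 1e-2)
        with pytest.raises(ValueError):
            one_cycle(-1, self.SCHED, 1e-2)


class TestAugment:
    def test_disabled_is_identity(self):
        cfg = TrainConfig(augment=False)
        rng = np.random.default_rng(0)
        img = rng.normal(size=(3, 16, 16)).astype(np.float32)
        mask = (rng.random((16, 16)) < 0.5).astype(np.uint8)
        out_img, out_mask = augment(img, mask, cfg, rng)
        np.testing.assert_array_equal(out_img, img)
        np.testing.assert_array_equal(out_mask, mask)

    def test_flip_applies_to_both(self):
        cfg = TrainConfig(aug_flip_p=1.0, aug_rotate_deg=0.0, aug_zoom=(1.0, 1.0))
        rng = np.random.default_rng(0)
        img = np.arange(3 * 8 * 8, dtype=np.float32).reshape(3, 8, 8)
        mask = np.zeros((8, 8), dtype=np.uint8)
        mask[:, :4] = 1
        out_img, out_mask = augment(img, mask, cfg, rng)
        np.testing.assert_array_equal(out_img, img[..., ::-1])
        np.testing.assert_array_equal(out_mask, mask[..., ::-1])

    def test_mask_stays_binary_under_rotation(self):
        cfg = TrainConfig()
        rng = np.random.default_rng(5)
        for _ in range(100):
            mask = (rng.random((16, 16)) < 0.4).astype(np.uint8)
            img = rng.normal(size=(3, 16, 16)).astype(np.float32)
            _, out_mask = augment(img, mask, cfg, rng)
            assert set(np.unique(out_mask)) <= {0, 1}
            assert out_mask.shape == mask.shape


class TestTrainLoop:
    @staticmethod
    def _tiny_exams(n, seed0=500, shape=(6, 64, 64)):
        cfg = PhantomConfig(shape=shape, spacing=(6.0, 1.5, 1.5))
        return [
            generate_phantom(replace(cfg, seed=seed0 + i)) for i in range(n)
        ]

    def test_empty_dataset_error(self):
        model = build_model(DESK_PROFILE, seed=0)
        with pytest.raises(ValueError, match="at least one exam"):
            train(model, [], TrainConfig())

    def test_zero_epochs_rejected(self):
        with pytest.raises(ValueError, match="epochs"):
            TrainConfig(epochs=0)

    def test_seeded_training_is_bit_reproducible(self):
        exams = self._tiny_exams(2)
        cfg = TrainConfig(max_lr=1e-2, epochs=1, seed=3)
        losses = []
        for _ in range(2):
            model = build_model(DESK_PROFILE, seed=3)
            _, hist = train(model, exams, cfg)
            losses.append(hist.loss)
        assert losses[0] == losses[1]

    def test_loss_decreases_and_schedule_logged(self):
        # desk-scale run on 6 phantoms: mean loss of the last epoch must be
        # below the first epoch's
        exams = self._tiny_exams(6, shape=(8, 64, 64))
        cfg = TrainConfig(max_lr=1e-2, epochs=4, seed=0)
        model = build_model(DESK_PROFILE, seed=0)
        _, hist = train(model, exams, cfg)
        steps_per_epoch = int(np.ceil(48 / cfg.batch_size))
        assert len(hist.loss) == 4 * steps_per_epoch
        assert np.all(np.isfinite(hist.loss))
        epoch_means = hist.epoch_mean_loss(steps_per_epoch)
        assert epoch_means[-1] < epoch_means[0]
        assert max(hist.lr) == pytest.approx(1e-2, rel=1e-2)

    def test_mixed_precision_flag_runs(self):
        exams = self._tiny_exams(1)
        cfg = TrainConfig(max_lr=1e-3, epochs=1, mixed_precision=True, seed=0)
        model = build_model(DESK_PROFILE, seed=0)
        _, hist = train(model, exams, cfg)
        assert np.all(np.isfinite(hist.loss))
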