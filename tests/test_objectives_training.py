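"""Loss hand-checks, gradients, schedule, folds, and training smoke."""

import numpy as np
import pytest

from msms_seg.autodiff import Tensor
from msms_seg.objectives_training import (
    LossConfig,
    TrainConfig,
    ce_loss,
    cosine_lr,
    dice_loss,
    kfold_split,
    run_training,
    total_loss,
    total_loss_t,
)
from msms_seg.segmentation_network import (
    SegmentationOutput,
    build_network,
    small_network_spec,
)


class TestDiceLoss:
    def test_perfect_prediction(self):
        p = y = np.array([1.0, 0.0, 0.0, 0.0])
        assert dice_loss(p, y, 1e-6) == pytest.approx(0.0, abs=1e-9)

    def test_total_miss(self):
        p = np.zeros(4)
        y = np.array([1.0, 0, 0, 0])
        eps = 1e-6
        assert dice_loss(p, y, eps) == pytest.approx(1 - eps / (1 + eps), abs=1e-12)

    def test_half_overlap_hand_value(self):
        assert dice_loss([0.5, 0.5], [1.0, 0.0], 0.0) == pytest.approx(0.5, abs=1e-12)

    def test_bounds(self, rng):
        for _ in range(20):
            p = rng.random(50)
            y = (rng.random(50) < 0.2).astype(float)
            assert 0.0 <= dice_loss(p, y) <= 1.0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            dice_loss(np.zeros(3), np.zeros(4))


class TestCELoss:
    def test_perfect_prediction_near_clamp_floor(self):
        y = np.array([1.0, 0.0, 1.0])
        assert ce_loss(y, y) < 1e-6

    def test_uniform_prediction(self):
        p = np.full(10, 0.5)
        y = (np.arange(10) % 2).astype(float)
        assert ce_loss(p, y) == pytest.approx(np.log(2), rel=1e-12)

    def test_hand_value(self):
        val = ce_loss(np.array([0.9, 0.1]), np.array([1.0, 0.0]))
        assert val == pytest.approx(-np.log(0.9), rel=1e-12)
        assert val == pytest.approx(0.10536, abs=1e-5)

    def test_extreme_probabilities_finite(self):
        assert np.isfinite(ce_loss(np.array([0.0, 1.0]), np.array([1.0, 0.0])))


def _logits_for_probability(p1, shape):
    """2-class logits whose softmax foreground probability equals p1."""
    logit = np.log(p1 / (1 - p1))
    out = np.zeros((2,) + shape)
    out[1] = logit
    return out


class TestTotalLoss:
    def test_single_level_equal_weights(self, rng):
        # CE and Dice contribute half each: verify against the numpy terms
        shape = (4, 4, 2)
        y = (rng.random(shape) < 0.3).astype(np.uint8)
        p = 0.7
        logits = _logits_for_probability(p, shape)
        out = SegmentationOutput(logits, [])
        expected = 0.5 * ce_loss(np.full(y.size, p), y.reshape(-1)) + 0.5 * dice_loss(
            np.full(y.size, p), y.reshape(-1)
        )
        assert total_loss(out, y) == pytest.approx(expected, rel=1e-6)

    def test_identical_levels_normalize_to_same_value(self, rng):
        shape = (4, 4, 2)
        y = (rng.random(shape) < 0.3).astype(np.uint8)
        logits = _logits_for_probability(0.7, shape)
        single = total_loss(SegmentationOutput(logits, []), y)
        double = total_loss(SegmentationOutput(logits, [logits.copy()]), y)
        assert double == pytest.approx(single, rel=1e-9)

    def test_three_level_weighted_hand_value(self):
        # per-level losses (0.4, 0.8, 0.8) with raw weights (1, 1/2, 1/4)
        # -> (0.4 + 0.4 + 0.2) / 1.75 = 4/7
        w = np.array([1.0, 0.5, 0.25])
        w = w / w.sum()
        assert np.dot(w, [0.4, 0.8, 0.8]) == pytest.approx(4 / 7, rel=1e-12)

    def test_aux_targets_downsampled_nearest(self, rng):
        shape = (8, 8, 4)
        y = (rng.random(shape) < 0.3).astype(np.uint8)
        logits = _logits_for_probability(0.6, shape)
        aux = _logits_for_probability(0.6, (4, 4, 4))
        val = total_loss(SegmentationOutput(logits, [aux]), y)
        assert np.isfinite(val) and val > 0

    def test_numeric_vs_analytic_gradient(self):
        """Finite-difference check of the deep-supervised loss on a tiny
        two-voxel example."""
        y = np.array([[[1]], [[0]]], dtype=np.uint8).reshape(2, 1, 1)
        rng = np.random.default_rng(0)
        logits = Tensor(rng.normal(size=(2, 2, 1, 1)), requires_grad=True)
        cfg = LossConfig()
        loss = total_loss_t(logits, [], y, cfg)
        loss.backward()
        g = logits.grad.copy()
        eps = 1e-6
        for idx in np.ndindex(logits.data.shape):
            base = logits.data[idx]
            logits.data[idx] = base + eps
            up = total_loss_t(Tensor(logits.data), [], y, cfg).item()
            logits.data[idx] = base - eps
            dn = total_loss_t(Tensor(logits.data), [], y, cfg).item()
            logits.data[idx] = base
            num = (up - dn) / (2 * eps)
            assert num == pytest.approx(g[idx], rel=1e-4, abs=1e-10)

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            LossConfig(ce_weight=-0.1)
        with pytest.raises(ValueError):
            LossConfig(epsilon=0.0)


class TestSchedule:
    def test_cosine_endpoints(self):
        epochs = 50
        assert cosine_lr(0, epochs, 1e-3) == pytest.approx(1e-3)
        assert cosine_lr(epochs - 1, epochs, 1e-3) < 0.01 * 1e-3

    def test_monotone_decay(self):
        lrs = [cosine_lr(e, 20, 1e-3) for e in range(20)]
        assert all(a >= b for a, b in zip(lrs, lrs[1:]))

    def test_single_epoch(self):
        assert cosine_lr(0, 1, 1e-3) == 1e-3


class TestFolds:
    def test_each_subject_validates_once(self):
        folds = kfold_split(10, 5, seed=3)
        assert len(folds) == 5
        all_val = np.sort(np.concatenate([v for _, v in folds]))
        np.testing.assert_array_equal(all_val, np.arange(10))
        for tr, va in folds:
            assert np.intersect1d(tr, va).size == 0
            assert np.union1d(tr, va).size == 10

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            kfold_split(4, 1)
        with pytest.raises(ValueError):
            kfold_split(4, 5)


def _tiny_pairs(rng, n=4, shape=(16, 16, 4)):
    pairs = []
    for _ in range(n):
        y = np.zeros(shape, dtype=np.uint8)
        cx, cy = rng.integers(4, shape[0] - 4, 2)
        y[cx - 2 : cx + 2, cy - 2 : cy + 2, 1:3] = 1
        v = rng.normal(10.0, 1.0, shape)
        v[y == 1] *= 2.0
        pairs.append((v, y))
    return pairs


class TestRunTraining:
    def test_loss_decreases_over_two_epochs(self):
        """Two epochs on four tiny phantoms: the smoke statistic is a lower
        second-epoch loss in at least 4 of 5 seeded runs."""
        wins = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            net = build_network(small_network_spec(channels=(4, 8)), seed=seed)
            res = run_training(
                net, _tiny_pairs(rng), TrainConfig(epochs=2, seed=seed)
            )
            wins += res.history[1]["train_loss"] < res.history[0]["train_loss"]
        assert wins >= 4

    def test_seed_determinism(self):
        losses = []
        for _ in range(2):
            rng = np.random.default_rng(7)
            net = build_network(small_network_spec(channels=(4, 8)), seed=7)
            res = run_training(
                net, _tiny_pairs(rng, n=2), TrainConfig(epochs=1, seed=7)
            )
            losses.append(res.history[0]["train_loss"])
        assert losses[0] == losses[1]

    def test_checkpoint_and_history(self, tmp_path):
        rng = np.random.default_rng(0)
        net = build_network(small_network_spec(channels=(4, 8)), seed=0)
        res = run_training(
            net, _tiny_pairs(rng, n=2), TrainConfig(epochs=2, seed=0),
            val_data=_tiny_pairs(rng, n=1),
            checkpoint_path=tmp_path / "c.npz",
        )
        assert (tmp_path / "c.npz").exists()
        assert len(res.history) == 2
        assert {"epoch", "lr", "train_loss", "val_dice"} <= set(res.history[0])

    def test_pretrain_then_finetune_restarts_schedule(self, tmp_path):
        """Transfer workflow: a checkpointed model continues training with
        a fresh cosine schedule and its weights keep moving."""
        from msms_seg.segmentation_network import load_checkpoint

        rng = np.random.default_rng(3)
        pairs = _tiny_pairs(rng, n=2)
        net = build_network(small_network_spec(channels=(4, 8)), seed=3)
        run_training(net, pairs, TrainConfig(epochs=2, seed=3),
                     checkpoint_path=tmp_path / "pre.npz")
        tuned = load_checkpoint(tmp_path / "pre.npz")
        before = [p.data.copy() for p in tuned.parameters()]
        res = run_training(tuned, pairs, TrainConfig(epochs=2, seed=4))
        assert res.history[0]["lr"] == pytest.approx(1e-3)  # schedule restarted
        moved = [np.abs(a - p.data).max() for a, p in
                 zip(before, tuned.parameters())]
        assert max(moved) > 0

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            TrainConfig(epochs=0)
        with pytest.raises(ValueError):
            TrainConfig(lr=0.0)
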