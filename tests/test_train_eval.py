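"""Dice loss/metric closed forms, schedule, and training-loop bookkeeping."""

import numpy as np
import pytest

from lobeseg import nn
from lobeseg.model import UNetConfig, build_unet
from lobeseg.nn.tensor import Tensor
from lobeseg.train_eval import (
    EvaluationReport,
    TrainConfig,
    dice_loss,
    dsc,
    evaluate,
    lr_schedule,
    one_hot,
    predict_volume,
    train,
)
from lobeseg.volume import SliceSample, Volume

TINY = (2, 4, 8, 16, 16)


class TestDiceLoss:
    def test_perfect_prediction_gives_zero_loss(self, rng):
        masks = rng.integers(0, 6, (2, 8, 8))
        oh = one_hot(masks)
        assert float(dice_loss(oh, oh).data) == pytest.approx(0.0, abs=1e-5)

    def test_two_pixel_toy_matches_hand_evaluation(self):
        # class k: p = (0.5, 0.5), g = (1, 0) -> Dk = 2*0.5/(0.25+0.25+1) = 2/3
        p = np.zeros((1, 6, 1, 2), np.float64)
        g = np.zeros((1, 6, 1, 2), np.float64)
        p[0, 0] = [[0.5, 0.5]]
        g[0, 0] = [[1.0, 0.0]]
        # keep remaining probability mass in class 1 so columns sum to 1
        p[0, 1] = [[0.5, 0.5]]
        g[0, 1] = [[0.0, 1.0]]
        loss = float(dice_loss(p, g).data)
        dk0 = 2 * 0.5 / (0.25 + 0.25 + 1.0)
        dk1 = 2 * 0.5 / (0.25 + 0.25 + 1.0)
        expected = 1.0 - (dk0 + dk1 + 4 * 1.0) / 6.0  # empty classes count as 1
        assert loss == pytest.approx(expected, abs=1e-5)

    def test_disjoint_prediction_scores_zero_for_present_classes(self):
        g = one_hot(np.zeros((1, 4, 4), dtype=int))
        p = one_hot(np.ones((1, 4, 4), dtype=int))
        # classes 0 and 1 both present in exactly one of p/g -> Dk ~ 0;
        # classes 2..5 absent from both -> Dk = 1 via the epsilon
        loss = float(dice_loss(p, g).data)
        assert loss == pytest.approx(1.0 - 4.0 / 6.0, abs=1e-5)

    def test_soft_equals_hard_for_one_hot_inputs(self, rng):
        pred = rng.integers(0, 6, (3, 16, 16))
        truth = rng.integers(0, 6, (3, 16, 16))
        soft = 1.0 - float(dice_loss(one_hot(pred), one_hot(truth)).data)
        hard = np.mean([dsc(pred, truth, k) for k in range(6)])
        assert soft == pytest.approx(hard, abs=1e-4)

    def test_channel_mismatch_rejected(self):
        with pytest.raises(ValueError, match="channels"):
            dice_loss(np.zeros((1, 5, 2, 2)), np.zeros((1, 5, 2, 2)))

    def test_loss_decreases_under_gradient_descent(self, rng):
        logits = Tensor(rng.standard_normal((1, 6, 8, 8)).astype(np.float32))
        logits.requires_grad = True
        oh = one_hot(rng.integers(0, 6, (1, 8, 8)))
        losses = []
        for _ in range(10):
            loss = dice_loss(logits.softmax(axis=1), oh)
            losses.append(float(loss.data))
            logits.zero_grad()
            loss.backward()
            logits.data -= 5.0 * logits.grad
        assert losses[-1] < losses[0]
        assert all(b <= a + 1e-4 for a, b in zip(losses, losses[1:]))


class TestDsc:
    def test_exact_match_is_one(self, rng):
        m = rng.integers(0, 6, (4, 4))
        assert dsc(m, m, 2) == 1.0

    def test_counting_toy(self):
        # 2x2 maps: TP=2, FP=1, FN=1 for class 1 -> 4/6
        pred = np.array([[1, 1], [1, 0]])
        truth = np.array([[1, 1], [0, 1]])
        assert dsc(pred, truth, 1) == pytest.approx(2 / 3)

    def test_absent_class_convention(self):
        z = np.zeros((3, 3), dtype=int)
        assert dsc(z, z, 5) == 1.0

    def test_symmetry_and_range(self, rng):
        a = rng.integers(0, 3, (8, 8))
        b = rng.integers(0, 3, (8, 8))
        for k in range(3):
            assert dsc(a, b, k) == dsc(b, a, k)
            assert 0.0 <= dsc(a, b, k) <= 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dsc(np.zeros((2, 2), int), np.zeros((3, 3), int), 0)


class TestSchedule:
    @pytest.mark.parametrize(
        "epoch,expected",
        [(0, 1e-4), (1, 1e-4), (2, 9.6e-5), (3, 9.6e-5), (49, 1e-4 * 0.96**24)],
    )
    def test_closed_form(self, epoch, expected):
        assert lr_schedule(epoch) == pytest.approx(expected, rel=1e-12)


class TestEvaluate:
    def test_perfect_prediction_all_ones(self, rng):
        m = rng.integers(0, 6, (2, 8, 8))
        report = evaluate(m, m)
        assert all(v == 1.0 for v in report.per_class_dice.values())
        assert report.mean_dice == 1.0

    def test_all_background_prediction_scores_zero_on_present_lobes(self, rng):
        truth = rng.integers(0, 6, (2, 8, 8))
        report = evaluate(np.zeros_like(truth), truth)
        for k in range(1, 6):
            if (truth == k).any():
                assert report.per_class_dice[k] == 0.0

    def test_hand_counted_toy_pair(self):
        pred = np.array([[[1, 1, 2, 2], [1, 0, 2, 0], [3, 3, 4, 4], [5, 5, 0, 0]]])
        truth = np.array([[[1, 1, 2, 0], [1, 1, 2, 2], [3, 0, 4, 4], [5, 0, 0, 5]]])
        report = evaluate(pred, truth)
        # class 1: TP=3, FP=0, FN=1 -> 6/7; class 2: TP=2, FP=1, FN=1 -> 4/6
        assert report.per_class_dice[1] == pytest.approx(6 / 7)
        assert report.per_class_dice[2] == pytest.approx(2 / 3)
        # class 3: TP=1, FP=1, FN=0 -> 2/3; class 4: TP=2 FP=0 FN=0 -> 1
        assert report.per_class_dice[3] == pytest.approx(2 / 3)
        assert report.per_class_dice[4] == 1.0
        # class 5: TP=1, FP=1, FN=1 -> 2/4
        assert report.per_class_dice[5] == pytest.approx(0.5)

    def test_report_serializable(self, rng):
        m = rng.integers(0, 6, (2, 4, 4))
        d = evaluate(m, m).to_dict()
        assert set(d) == {"per_class_dice", "mean_dice", "n_instances"}


def _slices(rng, n=6):
    out = []
    for i in range(n):
        img = rng.random((1, 256, 256)).astype(np.float32)
        mask = np.zeros((256, 256), np.uint8)
        mask[64:192, 64:128] = 1
        mask[64:192, 128:192] = 2
        out.append(SliceSample(img, mask, "toy", i))
    return out


class TestTrainLoop:
    def test_bookkeeping_contract(self, rng):
        model = build_unet(UNetConfig(encoder_widths=TINY), seed=0)
        samples = _slices(rng)
        cfg = TrainConfig(epochs=2, batch_size=4, seed=1)
        result = train(model, samples[:4], samples[4:], cfg, max_steps=4)
        assert len(result.history) == 2
        assert result.best_epoch == int(
            np.argmax([h["val_dice"] for h in result.history])
        )
        assert result.best_val_dice == max(h["val_dice"] for h in result.history)
        assert set(result.best_state) == set(model.state_dict())

    def test_empty_dataset_rejected(self, rng):
        model = build_unet(UNetConfig(encoder_widths=TINY), seed=0)
        with pytest.raises(ValueError, match="non-empty"):
            train(model, [], _slices(rng, 2), TrainConfig(epochs=1))

    def test_identical_seeds_reproduce_history(self, rng):
        samples = _slices(rng)
        results = []
        for _ in range(2):
            model = build_unet(UNetConfig(encoder_widths=TINY), seed=5)
            cfg = TrainConfig(epochs=1, batch_size=4, seed=3, augmentation_class="patient")
            results.append(train(model, samples[:4], samples[4:], cfg, max_steps=1))
        a, b = results
        assert a.history[0]["train_loss"] == pytest.approx(
            b.history[0]["train_loss"], rel=1e-6
        )
        assert a.history[0]["val_dice"] == pytest.approx(b.history[0]["val_dice"], rel=1e-6)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(lr0=-1.0).validate()
        with pytest.raises(ValueError):
            TrainConfig(batch_size=0).validate()


class TestPredictVolume:
    def test_labels_in_range_and_deterministic(self, rng):
        model = build_unet(UNetConfig(encoder_widths=TINY), seed=0)
        vol = Volume(rng.random((3, 64, 64)).astype(np.float32), (2.0, 1.0, 1.0))
        a = predict_volume(model, vol)
        b = predict_volume(model, vol)
        assert set(np.unique(a.data)) <= set(range(6))
        assert np.array_equal(a.data, b.data)
        assert a.shape == (3, 256, 256)

    def test_native_inplane_resize_back(self, rng):
        model = build_unet(UNetConfig(encoder_widths=TINY), seed=0)
        vol = Volume(rng.random((2, 64, 64)).astype(np.float32), (2.0, 1.0, 1.0))
        out = predict_volume(model, vol, native_inplane=True)
        assert out.shape == (2, 64, 64)
        assert out.spacing_mm == vol.spacing_mm

    def test_unnormalized_volume_rejected(self, rng):
        model = build_unet(UNetConfig(encoder_widths=TINY), seed=0)
        vol = Volume((rng.random((2, 64, 64)) * 100).astype(np.float32), (2.0, 1.0, 1.0))
        with pytest.raises(ValueError, match="normalized"):
            predict_volume(model, vol)
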