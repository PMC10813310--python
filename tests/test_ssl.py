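"""Jigsaw pretext: shuffle geometry, loss closed forms, head widths, transfer."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lobeseg.model import UNet, UNetConfig
from lobeseg.nn.tensor import Tensor
from lobeseg.ssl import (
    JigsawHead,
    JigsawHeadConfig,
    PermutationError,
    TransferError,
    jigsaw_forward,
    jigsaw_loss,
    make_jigsaw,
    patch_accuracy,
    sample_permutation,
    transfer_encoder,
    unshuffle,
)

TINY = (2, 4, 8, 16, 16)


class TestMakeJigsaw:
    def test_identity_permutation_is_identity(self, rng):
        img = rng.random((256, 256)).astype(np.float32)
        task = make_jigsaw(img, np.arange(16))
        assert np.array_equal(task.shuffled_image[0], img)
        assert np.array_equal(task.target, np.arange(16))

    @settings(max_examples=30, deadline=None)
    @given(st.randoms(use_true_random=False))
    def test_shuffle_unshuffle_round_trip_exact(self, pyrandom):
        rng = np.random.default_rng(pyrandom.randrange(2**32))
        img = rng.random((256, 256)).astype(np.float32)
        perm = sample_permutation(rng)
        task = make_jigsaw(img, perm)
        assert np.array_equal(unshuffle(task)[0], img)

    def test_swap_of_two_patches_moves_only_those_blocks(self):
        card = np.zeros((256, 256), np.float32)
        for b in range(16):
            r, c = divmod(b, 4)
            card[r * 64 : (r + 1) * 64, c * 64 : (c + 1) * 64] = b
        perm = np.arange(16)
        perm[0], perm[5] = 5, 0
        task = make_jigsaw(card, perm)
        blocks = (
            task.shuffled_image[0]
            .reshape(4, 64, 4, 64)
            .transpose(0, 2, 1, 3)
            .reshape(16, 64, 64)
        )
        values = [int(b[0, 0]) for b in blocks]
        assert values[0] == 5 and values[5] == 0
        assert values[1:5] == [1, 2, 3, 4] and values[6:] == list(range(6, 16))
        for b in blocks:
            assert (b == b[0, 0]).all()

    def test_non_bijective_permutation_rejected(self, rng):
        img = rng.random((256, 256)).astype(np.float32)
        with pytest.raises(PermutationError):
            make_jigsaw(img, np.zeros(16, dtype=int))


class TestSamplePermutation:
    def test_seeded_repeat_identical(self):
        a = sample_permutation(np.random.default_rng(5))
        b = sample_permutation(np.random.default_rng(5))
        assert np.array_equal(a, b)

    def test_uniform_occupancy_over_many_draws(self):
        rng = np.random.default_rng(0)
        n = 10_000
        counts = np.zeros((16, 16))
        for _ in range(n):
            p = sample_permutation(rng)
            counts[np.arange(16), p] += 1
        expected = n / 16.0
        sigma = math.sqrt(n * (1 / 16) * (15 / 16))
        assert np.abs(counts - expected).max() < 3.5 * sigma


class TestJigsawLoss:
    def test_uniform_logits_give_ln_16(self):
        loss = jigsaw_loss(np.zeros((16, 16)), np.arange(16))
        assert float(loss.data) == pytest.approx(math.log(16), abs=1e-9)

    def test_concentrated_logits_drive_loss_to_zero(self):
        target = np.arange(16)
        logits = np.full((16, 16), -50.0)
        logits[np.arange(16), target] = 50.0
        assert float(jigsaw_loss(logits, target).data) < 1e-6

    def test_row_permutation_symmetry(self, rng):
        logits = rng.standard_normal((16, 16))
        target = sample_permutation(rng)
        reorder = sample_permutation(rng)
        a = float(jigsaw_loss(logits, target).data)
        b = float(jigsaw_loss(logits[reorder], target[reorder]).data)
        assert a == pytest.approx(b, rel=1e-6)

    def test_matches_brute_force_cross_entropy(self, rng):
        logits = rng.standard_normal((16, 16))
        target = sample_permutation(rng)
        brute = 0.0
        for row in range(16):
            z = logits[row]
            brute += -(z[target[row]] - math.log(np.exp(z).sum()))
        brute /= 16
        assert float(jigsaw_loss(logits, target).data) == pytest.approx(brute, rel=1e-5)

    def test_out_of_range_target_rejected(self, rng):
        with pytest.raises(ValueError, match="target"):
            jigsaw_loss(rng.standard_normal((16, 16)), np.full(16, 16))


class TestJigsawHead:
    def test_published_widths(self):
        cfg = JigsawHeadConfig()
        head = JigsawHead(cfg, np.random.default_rng(0))
        conv_out = [b.conv1.weight.shape[0] for b in head.convs]
        assert conv_out == [256, 128, 64, 32, 16]
        assert head.fc1.weight.shape == (16 * 16 * 16, 512)
        assert head.fc2.weight.shape == (512, 128)
        assert head.fc_out.weight.shape == (128, 256)
        assert cfg.dropout == 0.25

    def test_forward_logits_shape_and_determinism_in_eval(self, rng):
        unet = UNet(UNetConfig(encoder_widths=TINY), np.random.default_rng(0))
        head = JigsawHead(JigsawHeadConfig.for_unet(unet.config), np.random.default_rng(1))
        unet.eval()
        head.eval()
        task = make_jigsaw(rng.random((256, 256)).astype(np.float32), sample_permutation(rng))
        a = jigsaw_forward(unet, head, task)
        b = jigsaw_forward(unet, head, task)
        assert a.shape == (16, 16)
        assert np.isfinite(a).all()
        assert np.array_equal(a, b)

    def test_latent_shape_mismatch_rejected(self, rng):
        head = JigsawHead(JigsawHeadConfig(in_channels=8, latent_size=16,
                                           conv_widths=(4,), fc_widths=(8, 8)),
                          np.random.default_rng(0))
        with pytest.raises(ValueError, match="latent shape"):
            head(Tensor(np.zeros((1, 4, 16, 16), np.float32)))

    def test_untrained_head_is_at_chance(self, rng):
        unet = UNet(UNetConfig(encoder_widths=TINY), np.random.default_rng(0))
        head = JigsawHead(JigsawHeadConfig.for_unet(unet.config), np.random.default_rng(1))
        unet.eval(), head.eval()
        accs = []
        for _ in range(8):
            task = make_jigsaw(rng.random((256, 256)).astype(np.float32), sample_permutation(rng))
            logits = jigsaw_forward(unet, head, task)
            accs.append(patch_accuracy(logits, task.target))
        assert np.mean(accs) < 0.35  # chance is 1/16; untrained stays near it


class TestTransferEncoder:
    def test_transfer_copies_encoder_leaves_decoder(self):
        src = UNet(UNetConfig(encoder_widths=TINY), np.random.default_rng(0))
        dst = UNet(UNetConfig(encoder_widths=TINY, use_attention=True), np.random.default_rng(9))
        dec_before = {
            k: v.copy() for k, v in dst.state_dict().items() if not k.startswith("enc")
        }
        transfer_encoder(src.encoder_state(), dst)
        after = dst.state_dict()
        for k, v in src.encoder_state().items():
            assert np.array_equal(after[k], v)
        for k, v in dec_before.items():
            assert np.array_equal(after[k], v)

    def test_incompatible_width_names_first_mismatch(self):
        src = UNet(UNetConfig(encoder_widths=TINY), np.random.default_rng(0))
        dst = UNet(UNetConfig(encoder_widths=(4, 8, 16, 32, 32)), np.random.default_rng(1))
        with pytest.raises(TransferError, match="enc"):
            transfer_encoder(src.encoder_state(), dst)

    def test_transferred_encoder_remains_trainable(self, rng):
        from lobeseg import nn as lnn
        from lobeseg.train_eval import dice_loss, one_hot

        src = UNet(UNetConfig(encoder_widths=TINY), np.random.default_rng(0))
        dst = UNet(UNetConfig(encoder_widths=TINY), np.random.default_rng(1))
        transfer_encoder(src.encoder_state(), dst)
        before = {k: v.copy() for k, v in dst.encoder_state().items()}
        opt = lnn.Adam(dst.parameters(), lr=1e-2)
        x = Tensor(rng.random((1, 1, 256, 256)).astype(np.float32))
        loss = dice_loss(dst(x).softmax(axis=1), one_hot(rng.integers(0, 6, (1, 256, 256))))
        loss.backward()
        opt.step()
        changed = any(
            not np.array_equal(before[k], v)
            for k, v in dst.encoder_state().items()
            if not k.endswith(("running_mean", "running_var"))
        )
        assert changed, "encoder weights frozen after transfer"
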