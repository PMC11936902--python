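"""Pair enumeration, consistent affine augmentation, training bookkeeping."""

import dataclasses
import math

import numpy as np
import pytest

from lungreg import (
    AffineParams,
    PhantomConfig,
    TrainStepConfig,
    dsc,
    enumerate_ordered_pairs,
    generate_phantom,
    make_affine_pair,
    train_autoencoder,
    train_step1,
    train_step2,
    train_step3,
)
from lungreg.errors import ConfigurationError


class TestEnumerateOrderedPairs:
    @pytest.mark.parametrize("n,expected", [(787, 618582), (11, 110), (1, 0), (2, 2)])
    def test_published_and_edge_counts(self, n, expected):
        count, _ = enumerate_ordered_pairs(n)
        assert count == expected

    def test_counts_match_brute_force_enumeration(self):
        for n in range(1, 51):
            count, it = enumerate_ordered_pairs(n)
            brute = [(i, j) for i in range(n) for j in range(n) if i != j]
            listed = list(it)
            assert count == len(brute) == n * n - n
            assert listed == brute  # deterministic order, each pair once

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            enumerate_ordered_pairs(0)


class TestAffinePair:
    @pytest.fixture(scope="class")
    def phantom(self):
        cfg = PhantomConfig(image_size=48, seed=21)
        return generate_phantom(cfg, 0.2)

    def test_identity_params_unchanged(self, phantom):
        img, mask = phantom
        out_img, out_mask = make_affine_pair(img, mask, AffineParams.identity())
        assert np.array_equal(out_img, img)
        assert np.array_equal(out_mask, mask)

    @pytest.mark.parametrize("tx,ty", [(3, 0), (0, -2), (4, 5)])
    def test_integer_translation_moves_centroid_exactly(self, phantom, tx, ty):
        img, mask = phantom
        h, w = mask.shape
        params = AffineParams(translation_frac=(tx / w, ty / h))
        _, moved = make_affine_pair(img, mask, params)
        c0 = np.argwhere(mask).mean(axis=0)
        c1 = np.argwhere(moved).mean(axis=0)
        assert abs((c1 - c0)[0] - ty) < 0.5
        assert abs((c1 - c0)[1] - tx) < 0.5

    def test_image_and_mask_share_the_transform(self, phantom):
        """The transformed mask must coincide with the support of the
        transformed lung intensities."""
        img, mask = phantom
        params = AffineParams(rotation_deg=7.0, scale=1.04, translation_frac=(0.03, -0.02),
                              shear_deg=2.0)
        out_img, out_mask = make_affine_pair(img, mask, params)
        bright = (out_img > 0.45).astype(np.uint8)  # lungs are the bright class
        assert dsc(bright, out_mask) > 0.95

    def test_deterministic(self, phantom):
        img, mask = phantom
        params = AffineParams(rotation_deg=-4.0, scale=0.97, translation_frac=(0.02, 0.04))
        a = make_affine_pair(img, mask, params)
        b = make_affine_pair(img, mask, params)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_shape_mismatch_rejected(self, phantom):
        img, mask = phantom
        with pytest.raises(ValueError):
            make_affine_pair(img, mask[:-1], AffineParams.identity())


@pytest.fixture(scope="module")
def tiny_setup():
    """Two small phantoms and a briefly trained encoder (smoke scale)."""
    imgs, masks = [], []
    for seed in (31, 32, 33, 34):
        img, msk = generate_phantom(PhantomConfig(image_size=48, seed=seed), 0.4)
        imgs.append(img)
        masks.append(msk)
    ae, _ = train_autoencoder(masks, epochs=2, seed=0)
    return imgs, masks, ae


class TestTrainSteps:
    def test_step1_smoke_two_images(self, tiny_setup):
        imgs, masks, ae = tiny_setup
        cfg = TrainStepConfig(epochs=1, pairs_per_epoch=2, batch_size=2, seed=0)
        model, log = train_step1(imgs[:2], masks[:2], ae, cfg)
        assert len(log) == 1  # 2 pairs in one batch
        assert np.isfinite(log).all()

    def test_loss_log_bookkeeping(self, tiny_setup):
        imgs, masks, ae = tiny_setup
        cfg = TrainStepConfig(epochs=2, pairs_per_epoch=6, batch_size=4, seed=0)
        _, log = train_step1(imgs, masks, ae, cfg)
        assert len(log) == 2 * math.ceil(6 / 4)

    def test_step2_pairs_per_epoch_equals_n_images(self, tiny_setup):
        imgs, masks, ae = tiny_setup
        cfg = TrainStepConfig(epochs=3, batch_size=4, seed=0)
        model, _ = train_step1(imgs, masks, ae, TrainStepConfig(epochs=1, pairs_per_epoch=4,
                                                                batch_size=4, seed=0))
        _, log = train_step2(model, imgs, masks, None, ae, cfg)
        assert len(log) == 3 * math.ceil(len(imgs) / 4)

    def test_step2_identity_ranges_degenerate_to_self_pairs(self, tiny_setup):
        imgs, masks, ae = tiny_setup
        ranges = {"rotation": (0.0, 0.0), "scale": (1.0, 1.0),
                  "translation": (0.0, 0.0), "shear": (0.0, 0.0)}
        model, _ = train_step1(imgs, masks, ae, TrainStepConfig(epochs=1, pairs_per_epoch=4,
                                                                batch_size=4, seed=0))
        _, log = train_step2(model, imgs, masks, ranges, ae,
                             TrainStepConfig(epochs=2, batch_size=4, seed=0))
        # self-pairs: NCC term near -1 dominates, so the loss sits near best case
        assert log[-1] < -0.7

    def test_training_reproducible_bit_for_bit(self, tiny_setup):
        imgs, masks, ae = tiny_setup
        cfg = TrainStepConfig(epochs=1, pairs_per_epoch=4, batch_size=4, seed=7)
        _, log_a = train_step1(imgs, masks, ae, cfg)
        _, log_b = train_step1(imgs, masks, ae, dataclasses.replace(cfg))
        assert log_a == log_b

    def test_step3_warns_on_nonzero_background(self, tiny_setup):
        imgs, masks, ae = tiny_setup
        model, _ = train_step1(imgs, masks, ae, TrainStepConfig(epochs=1, pairs_per_epoch=2,
                                                                batch_size=2, seed=0))
        with pytest.warns(UserWarning, match="nonzero background"):
            train_step3(model, imgs, masks, None, ae,
                        TrainStepConfig(epochs=1, batch_size=4, seed=0))

    def test_fewer_than_two_images_rejected(self, tiny_setup):
        imgs, masks, ae = tiny_setup
        with pytest.raises(ValueError):
            train_step1(imgs[:1], masks[:1], ae, TrainStepConfig(seed=0))

    def test_invalid_step_config_rejected(self):
        with pytest.raises(ConfigurationError):
            TrainStepConfig(epochs=0).validate()
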