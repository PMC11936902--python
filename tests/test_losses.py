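"""Loss components: closed forms, algebraic equivalences, decomposition."""

import numpy as np
import pytest

from lungreg import (
    DisplacementField,
    LossWeights,
    bce_loss,
    composite_loss,
    l2_latent_loss,
    ncc_equivalence_check,
    ncc_loss,
    tv_loss,
)
from lungreg.errors import ConfigurationError


class TestNCC:
    def test_self_correlation_is_minus_one(self, rng):
        img = rng.random((32, 32))
        assert abs(ncc_loss(img, img) + 1.0) < 1e-3

    def test_constant_target_gives_zero(self, rng):
        img = rng.random((16, 16))
        assert ncc_loss(img, np.full((16, 16), 0.5)) == pytest.approx(0.0, abs=1e-7)
        assert ncc_loss(np.full((16, 16), 0.5), img) == pytest.approx(0.0, abs=1e-7)

    def test_affine_invariance(self, rng):
        """NCC is invariant to affine intensity rescaling of one input
        (a property of the eps-free statistic; use a negligible guard)."""
        img = rng.random((24, 24)) * 0.4 + 0.1
        scaled = 2.0 * img + 0.1
        a = ncc_loss(img, scaled, eps=1e-12)
        b = ncc_loss(img, img, eps=1e-12)
        assert a == pytest.approx(b, abs=5e-6)
        # the direct float64 evaluation agrees to the stated precision
        from lungreg.losses import _ncc_eq2

        assert _ncc_eq2(img, scaled, 1e-12) == pytest.approx(
            _ncc_eq2(img, img, 1e-12), abs=1e-6
        )

    def test_bounded_below_by_minus_one(self, rng):
        for _ in range(20):
            a, b = rng.random((12, 12)), rng.random((12, 12))
            assert ncc_loss(a, b) >= -1.0 - 1e-6

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ncc_loss(np.zeros((4, 4)), np.zeros((5, 5)))

    def test_nonpositive_eps_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            ncc_loss(rng.random((4, 4)), rng.random((4, 4)), eps=0.0)


class TestNCCEquivalence:
    def test_direct_and_expanded_forms_agree_on_random_pairs(self, rng):
        worst = max(
            ncc_equivalence_check(rng.random((16, 16)), rng.random((16, 16)))
            for _ in range(100)
        )
        assert worst < 1e-8

    def test_constant_pair_both_zero(self):
        c = np.full((8, 8), 0.3)
        assert ncc_equivalence_check(c, c) == pytest.approx(0.0, abs=1e-12)

    def test_identical_nonconstant_both_near_minus_one(self, rng):
        img = rng.random((16, 16))
        from lungreg.losses import _ncc_eq2, _ncc_eq7

        assert _ncc_eq2(img, img, 1e-5) == pytest.approx(-1.0, abs=1e-3)
        assert _ncc_eq7(img, img, 1e-5) == pytest.approx(-1.0, abs=1e-3)


class TestTV:
    def test_constant_field_is_zero(self):
        field = DisplacementField(np.full((8, 8), 2.5, np.float32), np.full((8, 8), -1.0, np.float32))
        assert tv_loss(field) == pytest.approx(0.0)

    def test_unit_row_gradient_x_plane_gives_half(self):
        rows = np.tile(np.arange(8, dtype=np.float32)[:, None], (1, 8))
        field = DisplacementField(rows, np.zeros((8, 8), np.float32))
        assert tv_loss(field) == pytest.approx(0.5)

    def test_unit_gradients_both_planes_give_one(self):
        rows = np.tile(np.arange(8, dtype=np.float32)[:, None], (1, 8))
        cols = np.tile(np.arange(8, dtype=np.float32)[None, :], (8, 1))
        field = DisplacementField(rows, cols)
        assert tv_loss(field) == pytest.approx(1.0)

    def test_translation_invariance(self, rng):
        dx = rng.normal(0, 2, (10, 10)).astype(np.float32)
        dy = rng.normal(0, 2, (10, 10)).astype(np.float32)
        a = tv_loss(DisplacementField(dx, dy))
        b = tv_loss(DisplacementField(dx + 7.0, dy + 7.0))
        assert a == pytest.approx(b, rel=1e-5, abs=1e-6)

    def test_full_mode_upper_bounds_printed_mode(self, rng):
        dx = rng.normal(0, 2, (10, 10)).astype(np.float32)
        dy = rng.normal(0, 2, (10, 10)).astype(np.float32)
        field = DisplacementField(dx, dy)
        assert tv_loss(field, mode="full") >= tv_loss(field) - 1e-6


class TestBCE:
    def test_perfect_binary_agreement_near_zero(self):
        mask = np.zeros((8, 8))
        mask[2:6, 2:6] = 1.0
        assert bce_loss(mask, mask.astype(np.uint8)) <= 1e-6

    def test_uniform_half_against_ones_is_ln2(self):
        pred = np.full((8, 8), 0.5)
        target = np.ones((8, 8), np.uint8)
        assert bce_loss(pred, target) == pytest.approx(np.log(2.0), abs=1e-6)

    def test_total_disagreement_under_clamp(self):
        # float32 arithmetic rounds the upper clamp bound, so agreement
        # with -ln(clip) is at the percent level
        target = np.zeros((8, 8), np.uint8)
        target[:4] = 1
        pred = 1.0 - target.astype(float)
        assert bce_loss(pred, target, clip=1e-7) == pytest.approx(-np.log(1e-7), rel=1e-2)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bce_loss(np.zeros((4, 4)), np.zeros((5, 5), np.uint8))


class TestLatentL2:
    def test_identical_codes_zero(self, rng):
        code = rng.normal(0, 1, (6, 6))
        assert l2_latent_loss(code, code) == pytest.approx(0.0)

    def test_single_entry_difference_mean_over_entries(self):
        a = np.zeros((3, 3))
        b = np.zeros((3, 3))
        b[1, 1] = 3.0
        assert l2_latent_loss(a, b) == pytest.approx(1.0)  # 9 / 9

    def test_uniform_difference(self):
        a = np.zeros((2, 2))
        assert l2_latent_loss(a, a + 2.0) == pytest.approx(4.0)

    def test_size_mismatch_rejected(self):
        with pytest.raises(ValueError):
            l2_latent_loss(np.zeros((3, 3)), np.zeros((4, 4)))


class _IdentityEncoder:
    """Stands in for the autoencoder's encoder in decomposition tests."""

    def encode(self, batch):
        from lungreg import nn

        return nn.as_tensor(batch)


class TestComposite:
    def test_self_pair_zero_field_is_pure_ncc(self, rng):
        img = rng.random((16, 16))
        mask = np.zeros((16, 16), np.uint8)
        mask[4:12, 4:12] = 1
        field = DisplacementField.zeros((16, 16))
        br = composite_loss(img, img, mask, mask, field, LossWeights(), _IdentityEncoder())
        v = br.values()
        assert v["ncc"] == pytest.approx(-1.0, abs=1e-3)
        assert v["tv"] == pytest.approx(0.0, abs=1e-7)
        assert v["bce"] <= 1e-5
        assert v["l2"] == pytest.approx(0.0, abs=1e-7)
        assert v["total"] == pytest.approx(v["ncc"], abs=1e-3)

    def test_weight_masking_reduces_to_ncc(self, rng):
        img, tgt = rng.random((16, 16)), rng.random((16, 16))
        mask = (rng.random((16, 16)) > 0.5).astype(np.uint8)
        field = DisplacementField.zeros((16, 16))
        w = LossWeights(lambda_tv=0.0, lambda_bce=0.0, lambda_l2=0.0)
        br = composite_loss(img, tgt, mask, mask, field, w)
        v = br.values()
        assert v["total"] == pytest.approx(v["ncc"], abs=1e-9)

    def test_decomposition_matches_independent_terms(self, rng):
        from lungreg import warp
        from lungreg.warper import warp_mask_soft

        img, tgt = rng.random((16, 16)), rng.random((16, 16))
        mask = (rng.random((16, 16)) > 0.5).astype(np.uint8)
        tmask = (rng.random((16, 16)) > 0.5).astype(np.uint8)
        field = DisplacementField(
            rng.normal(0, 1, (16, 16)).astype(np.float32),
            rng.normal(0, 1, (16, 16)).astype(np.float32),
        )
        w = LossWeights()
        br = composite_loss(img, tgt, mask, tmask, field, w, _IdentityEncoder())
        v = br.values()
        warped = warp(img, field)
        soft_mask = warp_mask_soft(mask, field)
        expected = (
            w.lambda_ncc * ncc_loss(warped, tgt, w.eps)
            + w.lambda_tv * tv_loss(field)
            + w.lambda_bce * bce_loss(soft_mask, tmask)
            + w.lambda_l2 * l2_latent_loss(soft_mask, tmask.astype(float))
        )
        assert v["total"] == pytest.approx(expected, rel=1e-4, abs=1e-5)

    def test_missing_encoder_rejected(self, rng):
        img = rng.random((8, 8))
        mask = np.ones((8, 8), np.uint8)
        with pytest.raises(ConfigurationError):
            composite_loss(img, img, mask, mask, DisplacementField.zeros((8, 8)),
                           LossWeights(), encoder=None)

    def test_default_weights_are_published_settings(self):
        w = LossWeights()
        assert (w.lambda_ncc, w.lambda_tv, w.lambda_bce, w.lambda_l2, w.eps) == (
            1.0, 5e-5, 1.0, 0.1, 1e-5)
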