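"""Evaluation metrics against brute-force oracles and closed forms."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from lungreg import assd, dsc, evaluate_pairs, hausdorff, msd, paired_significance
from lungreg.metrics import boundary_pixels


# ---------------------------------------------------------------------------
# brute-force oracles (quadratic in the number of points)


def brute_directed(a_pts, b_pts):
    return cdist(a_pts, b_pts).min(axis=1)


def brute_hd(a, b, mode="surface"):
    pa = np.argwhere(boundary_pixels(a) if mode == "surface" else a.astype(bool))
    pb = np.argwhere(boundary_pixels(b) if mode == "surface" else b.astype(bool))
    return max(brute_directed(pa, pb).max(), brute_directed(pb, pa).max())


def brute_assd(a, b):
    pa = np.argwhere(boundary_pixels(a))
    pb = np.argwhere(boundary_pixels(b))
    d_ab = brute_directed(pa, pb)
    d_ba = brute_directed(pb, pa)
    return (d_ab.sum() + d_ba.sum()) / (len(d_ab) + len(d_ba))


class TestDSC:
    def test_identical_nonempty(self, rng):
        m = (rng.random((10, 10)) > 0.5).astype(np.uint8)
        m[0, 0] = 1
        assert dsc(m, m) == 1.0

    def test_disjoint(self):
        a = np.zeros((6, 6), np.uint8)
        b = np.zeros((6, 6), np.uint8)
        a[:2, :2] = 1
        b[4:, 4:] = 1
        assert dsc(a, b) == 0.0

    def test_shifted_block_half_overlap(self):
        a = np.zeros((6, 6), np.uint8)
        b = np.zeros((6, 6), np.uint8)
        a[2:4, 1:3] = 1
        b[2:4, 2:4] = 1  # overlap 2 of 4+4
        assert dsc(a, b) == pytest.approx(0.5)

    def test_both_empty_is_one(self):
        assert dsc(np.zeros((4, 4), np.uint8), np.zeros((4, 4), np.uint8)) == 1.0


class TestHausdorff:
    def test_identical_is_zero(self, rng):
        m = np.zeros((8, 8), np.uint8)
        m[2:6, 2:6] = 1
        assert hausdorff(m, m) == 0.0

    def test_three_four_five_single_pixels(self):
        a = np.zeros((8, 8), np.uint8)
        b = np.zeros((8, 8), np.uint8)
        a[0, 0] = 1
        b[3, 4] = 1
        assert hausdorff(a, b) == pytest.approx(5.0)

    def test_asymmetric_sets(self):
        a = np.zeros((12, 12), np.uint8)
        b = np.zeros((12, 12), np.uint8)
        a[0, 0] = a[10, 0] = 1
        b[0, 0] = 1
        assert hausdorff(a, b) == pytest.approx(10.0)

    def test_empty_mask_rejected(self):
        m = np.ones((4, 4), np.uint8)
        with pytest.raises(ValueError):
            hausdorff(m, np.zeros((4, 4), np.uint8))


class TestMSD:
    def test_identical_is_zero(self, rng):
        img = rng.random((8, 8))
        assert msd(img, img) == 0.0

    def test_constant_difference_squares(self):
        a = np.full((8, 8), 0.2)
        assert msd(a, a + 0.3) == pytest.approx(0.09)

    def test_matches_double_loop(self, rng):
        a, b = rng.random((16, 16)), rng.random((16, 16))
        expected = sum(
            (a[i, j] - b[i, j]) ** 2 for i in range(16) for j in range(16)
        ) / 256.0
        assert msd(a, b) == pytest.approx(expected, abs=1e-12)

    def test_reporting_scale(self, rng):
        a, b = rng.random((8, 8)), rng.random((8, 8))
        assert msd(a, b, scale=255.0) == pytest.approx(msd(a, b) * 255.0**2, rel=1e-12)


class TestOracleEquivalence:
    def test_hd_and_assd_match_brute_force(self, random_mask_pairs):
        for a, b in random_mask_pairs:
            assert hausdorff(a, b) == pytest.approx(brute_hd(a, b), abs=1e-9)
            assert assd(a, b) == pytest.approx(brute_assd(a, b), abs=1e-9)

    def test_region_mode_matches_brute_force(self, random_mask_pairs):
        for a, b in random_mask_pairs[:20]:
            assert hausdorff(a, b, mode="region") == pytest.approx(
                brute_hd(a, b, "region"), abs=1e-9
            )


class TestInvariances:
    def test_symmetry(self, random_mask_pairs, rng):
        for a, b in random_mask_pairs[:20]:
            assert dsc(a, b) == dsc(b, a)
            assert hausdorff(a, b) == hausdorff(b, a)
            assert assd(a, b) == pytest.approx(assd(b, a))
        x, y = rng.random((8, 8)), rng.random((8, 8))
        assert msd(x, y) == msd(y, x)

    def test_translation_invariance_of_mask_metrics(self):
        a = np.zeros((20, 20), np.uint8)
        b = np.zeros((20, 20), np.uint8)
        a[4:9, 4:9] = 1
        b[5:11, 5:10] = 1
        sa = np.roll(np.roll(a, 3, axis=0), 2, axis=1)
        sb = np.roll(np.roll(b, 3, axis=0), 2, axis=1)
        assert dsc(a, b) == dsc(sa, sb)
        assert hausdorff(a, b) == pytest.approx(hausdorff(sa, sb))
        assert assd(a, b) == pytest.approx(assd(sa, sb))


class TestEvaluatePairs:
    def test_identical_pair_row(self, rng):
        m = np.zeros((8, 8), np.uint8)
        m[2:6, 2:6] = 1
        img = rng.random((8, 8))
        rep = evaluate_pairs([(m, m, img, img)])
        row = rep.rows.iloc[0]
        assert (row.dsc, row.hd, row.assd, row.msd) == (1.0, 0.0, 0.0, 0.0)

    def test_110_pairs_110_rows(self, small_sequence):
        seq = small_sequence
        pairs = []
        for i in range(len(seq)):
            for j in range(len(seq)):
                if i != j:
                    pairs.append((i, j, seq.masks[i], seq.masks[j], seq.frames[i], seq.frames[j]))
        rep = evaluate_pairs(pairs)
        assert len(rep.rows) == len(seq) ** 2 - len(seq)

    def test_aggregates_match_hand_recomputation(self, small_sequence):
        seq = small_sequence
        pairs = [(0, k, seq.masks[0], seq.masks[k], seq.frames[0], seq.frames[k])
                 for k in range(1, len(seq))]
        rep = evaluate_pairs(pairs)
        agg = rep.aggregates()
        assert agg["dsc"]["mean"] == pytest.approx(rep.rows["dsc"].mean())
        assert agg["hd"]["sd"] == pytest.approx(rep.rows["hd"].std(ddof=1))

    def test_empty_mask_flagged_and_excluded(self, rng):
        m = np.zeros((8, 8), np.uint8)
        good = m.copy()
        good[2:6, 2:6] = 1
        img = rng.random((8, 8))
        with pytest.warns(UserWarning, match="empty mask"):
            rep = evaluate_pairs([(good, good, img, img), (good, m, img, img)])
        assert np.isnan(rep.rows["hd"].iloc[1])
        assert rep.aggregates()["hd"]["n"] == 1


class TestPairedSignificance:
    def test_identical_columns_p_one(self):
        col = np.arange(10, dtype=float)
        assert paired_significance(col, col) == 1.0

    def test_large_shift_highly_significant(self, rng):
        a = rng.random(110)
        assert paired_significance(a, a + 5.0) < 1e-4

    def test_two_sided_symmetry(self, rng):
        a = rng.random(40)
        b = a + rng.normal(0.2, 0.3, 40)
        assert paired_significance(a, b) == pytest.approx(paired_significance(b, a))

    def test_ttest_option(self, rng):
        a = rng.random(50)
        b = a + 1.0
        assert paired_significance(a, b, test="ttest") < 1e-4

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            paired_significance(np.zeros(5), np.zeros(6))
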