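import numpy as np
import pytest

from petomics import discretize
from petomics.texture import (
    DiscretizedVolume,
    cooccurrence_stats,
    fusion_features,
    fusion_matrix,
    glcm_features,
    glcm_matrix,
    glszm_features,
    glszm_matrix,
    histogram_features,
    ngtdm_features,
)

import oracles
from conftest import make_mask, make_pet, random_phantom


def dvol(bins, mask, B):
    bins = np.asarray(bins, dtype=np.int64)
    mask = np.asarray(mask, dtype=bool)
    return DiscretizedVolume(np.where(mask, bins, 0), mask, B,
                             float(bins[mask].min()), float(bins[mask].max()),
                             degenerate=bool(bins[mask].min() == bins[mask].max()))


class TestDiscretize:
    def test_fixed_bin_number_rule(self):
        vals = np.arange(11, dtype=float).reshape(11, 1, 1)
        vol = make_pet(vals)
        mask = make_mask(np.ones((11, 1, 1)))
        d = discretize(vol, mask, n_bins=2)
        expected = np.where(vals < 5, 1, 2)  # B(v-min)/(max-min) flips at 5
        np.testing.assert_array_equal(d.bins, expected)
        assert d.bins[10, 0, 0] == 2  # the max clamps into bin B
        assert not d.degenerate

    def test_constant_volume_flags_degenerate(self):
        d = discretize(make_pet(np.full((3, 3, 3), 7.0)), make_mask(np.ones((3, 3, 3))), 8)
        assert d.degenerate
        assert (d.bins[d.mask] == 1).all()

    def test_affine_rescale_leaves_bins_unchanged(self):
        rng = np.random.default_rng(2)
        vals = rng.random((6, 6, 6)) * 10
        mask = make_mask(rng.random((6, 6, 6)) > 0.3)
        d1 = discretize(make_pet(vals), mask, 16)
        d2 = discretize(make_pet(3.5 * vals + 2.0), mask, 16)
        np.testing.assert_array_equal(d1.bins, d2.bins)


class TestClosedForms:
    def test_uniform_image_glcm(self):
        d = dvol(np.ones((4, 4, 4)), np.ones((4, 4, 4)), 4)
        f = glcm_features(d)
        assert f["glcm_contrast"] == 0.0
        assert f["glcm_dissimilarity"] == 0.0
        assert f["glcm_energy"] == pytest.approx(1.0)
        assert f["glcm_joint_maximum"] == pytest.approx(1.0)

    def test_strip_1d_pairs(self):
        # [1,2,1,2] along one axis: 3 symmetric (1,2) pairs
        bins = np.array([1, 2, 1, 2]).reshape(4, 1, 1)
        d = dvol(bins, np.ones((4, 1, 1)), 2)
        f = glcm_features(d)
        assert f["glcm_contrast"] == pytest.approx(1.0)
        assert f["glcm_energy"] == pytest.approx(0.5)

    def test_ngtdm_uniform_is_flat(self):
        d = dvol(np.ones((4, 4, 4)), np.ones((4, 4, 4)), 3)
        f = ngtdm_features(d)
        assert f["ngtdm_contrast"] == 0.0
        assert f["ngtdm_busyness"] == 0.0

    def test_ngtdm_checkerboard_positive_contrast(self):
        idx = np.indices((4, 4, 4)).sum(axis=0)
        bins = 1 + (idx % 2)
        d = dvol(bins, np.ones((4, 4, 4)), 2)
        assert ngtdm_features(d)["ngtdm_contrast"] > 0

    def test_ngtdm_single_voxel_convention(self):
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[1, 1, 1] = True
        d = dvol(np.ones((3, 3, 3)), mask, 2)
        assert all(v == 0.0 for v in ngtdm_features(d).values())

    def test_glszm_single_zone(self):
        d = dvol(np.ones((3, 3, 3)), np.ones((3, 3, 3)), 2)
        f = glszm_features(d)
        assert f["glszm_zone_percentage"] == pytest.approx(1.0 / 27)

    def test_glszm_all_distinct(self):
        bins = np.arange(1, 9).reshape(2, 2, 2)
        d = dvol(bins, np.ones((2, 2, 2)), 8)
        assert glszm_features(d)["glszm_zone_percentage"] == pytest.approx(1.0)

    def test_histogram_single_bin(self):
        d = dvol(np.ones((3, 3, 3)), np.ones((3, 3, 3)), 4)
        f = histogram_features(d)
        assert f["hist_uniformity"] == pytest.approx(1.0)
        assert f["hist_entropy"] == pytest.approx(0.0)
        assert f["hist_skewness"] == 0.0

    def test_histogram_two_equiprobable_bins(self):
        bins = np.array([1, 2, 1, 2]).reshape(4, 1, 1)
        d = dvol(bins, np.ones((4, 1, 1)), 2)
        f = histogram_features(d)
        assert f["hist_uniformity"] == pytest.approx(0.5)
        assert f["hist_entropy"] == pytest.approx(1.0)
        assert f["hist_skewness"] == pytest.approx(0.0)  # symmetric

    def test_fusion_identity_coupling(self):
        rng = np.random.default_rng(3)
        bins = rng.integers(1, 5, (5, 5, 5))
        mask = np.ones((5, 5, 5), dtype=bool)
        d = dvol(bins, mask, 4)
        f = fusion_features(d, d)
        assert f["fusion_contrast"] == pytest.approx(0.0)
        assert f["fusion_correlation"] == pytest.approx(1.0)

    def test_fusion_independent_bins_near_zero_correlation(self):
        rng = np.random.default_rng(7)
        shape = (20, 20, 20)
        mask = np.ones(shape, dtype=bool)
        a = dvol(rng.integers(1, 7, shape), mask, 6)
        b = dvol(rng.integers(1, 7, shape), mask, 6)
        assert abs(fusion_features(a, b)["fusion_correlation"]) < 0.05

    def test_fusion_grid_mismatch_raises(self):
        d1 = dvol(np.ones((3, 3, 3)), np.ones((3, 3, 3)), 2)
        d2 = dvol(np.ones((4, 3, 3)), np.ones((4, 3, 3)), 2)
        with pytest.raises(ValueError, match="grid"):
            fusion_matrix(d1, d2)


class TestOracleEquivalence:
    """Vectorized features must match literal brute-force enumeration."""

    @pytest.mark.parametrize("seed", range(20))
    def test_all_families_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        bins, mask, B = random_phantom(rng)
        d = dvol(np.where(mask, bins, 1), mask, B)

        got = glcm_features(d)
        want = oracles.oracle_cooccurrence_stats(oracles.oracle_glcm_matrix(bins, mask, B))
        for k, v in want.items():
            assert got[f"glcm_{k}"] == pytest.approx(v, rel=1e-10, abs=1e-12), k

        got = ngtdm_features(d)
        want = oracles.oracle_ngtdm_features(bins, mask, B)
        for k, v in want.items():
            assert got[k] == pytest.approx(v, rel=1e-10, abs=1e-12), k

        got = glszm_features(d)
        want = oracles.oracle_glszm_features(bins, mask, B)
        for k, v in want.items():
            assert got[k] == pytest.approx(v, rel=1e-10, abs=1e-12), k

        got = histogram_features(d)
        want = oracles.oracle_histogram_features(bins, mask, B)
        for k, v in want.items():
            assert got[k] == pytest.approx(v, rel=1e-10, abs=1e-12), k

        ct_bins, _, _ = random_phantom(rng, n_bins=B)
        ct_bins = np.where(mask, rng.integers(1, B + 1, size=bins.shape), 1)
        d_ct = dvol(ct_bins, mask, B)
        got = fusion_features(d, d_ct)
        want = oracles.oracle_cooccurrence_stats(
            oracles.oracle_fusion_matrix(np.where(mask, bins, 1), ct_bins, mask, B)
        )
        from petomics.texture import FUSION_FEATURES
        for k in FUSION_FEATURES:
            assert got[f"fusion_{k}"] == pytest.approx(want[k], rel=1e-10, abs=1e-12), k


class TestInvariants:
    @pytest.mark.parametrize("seed", range(5))
    def test_matrices_are_probability_distributions(self, seed):
        rng = np.random.default_rng(100 + seed)
        bins, mask, B = random_phantom(rng)
        d = dvol(np.where(mask, bins, 1), mask, B)
        P = glcm_matrix(d)
        assert P.sum() == pytest.approx(1.0)
        assert (P >= 0).all() and (P <= 1).all()
        M = fusion_matrix(d, d)
        assert M.sum() == pytest.approx(1.0)

    @pytest.mark.parametrize("axes", [(0, 1), (0, 2), (1, 2)])
    def test_rotation_invariance(self, axes):
        rng = np.random.default_rng(42)
        bins, mask, B = random_phantom(rng, max_side=6)
        d = dvol(np.where(mask, bins, 1), mask, B)
        rb = np.rot90(np.where(mask, bins, 1), axes=axes)
        rm = np.rot90(mask, axes=axes)
        dr = dvol(rb, rm, B)
        for fn in (glcm_features, ngtdm_features, glszm_features):
            a, b = fn(d), fn(dr)
            for k in a:
                assert a[k] == pytest.approx(b[k], rel=1e-9), k
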