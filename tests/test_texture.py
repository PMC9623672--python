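"""Texture matrices vs brute-force enumeration, plus their closed-form anchors."""

import numpy as np
import pytest

from teatherm import glcm, gldm, glrlm, glszm, ngtdm
from teatherm.features.texture import _DIRECTIONS, dependence_counts, ngtdm_table

from . import oracles
from .conftest import make_droi


class TestGlcm:
    def test_constant_roi_single_cell(self):
        """All mass at gray level 1 forces the formula values."""
        _, f = glcm(make_droi(np.ones((4, 4))))
        assert f["Autocorrelation"] == 1.0
        assert f["ClusterShade"] == 0.0
        assert f["SumAverage"] == 2.0
        assert f["Idm"] == 1.0
        assert f["JointEntropy"] == 0.0

    def test_two_by_two_pair_enumeration(self):
        bins = np.array([[1, 1], [1, 2]])
        tm, _ = glcm(make_droi(bins))
        for mat, direction in zip(tm.matrices, _DIRECTIONS):
            expect = oracles.glcm_matrix(bins, direction, 2)
            np.testing.assert_allclose(mat, expect)

    def test_cluster_shade_sign_flips_on_reflection(self):
        rng = np.random.default_rng(3)
        bins = rng.integers(1, 5, size=(7, 7))
        _, f = glcm(make_droi(bins))
        _, g = glcm(make_droi(bins.max() + 1 - bins))
        assert g["ClusterShade"] == pytest.approx(-f["ClusterShade"], rel=1e-9)

    def test_symmetric_matrix_equals_transpose(self):
        rng = np.random.default_rng(4)
        tm, _ = glcm(make_droi(rng.integers(1, 4, size=(6, 6))))
        for mat in tm.matrices:
            np.testing.assert_allclose(mat, mat.T)
            assert mat.sum() == pytest.approx(1.0)

    def test_single_pixel_degenerate(self):
        bins = np.zeros((3, 3), dtype=int)
        bins[1, 1] = 1
        _, f = glcm(make_droi(bins))
        assert f["MaximumProbability"] == 1.0


class TestGlrlm:
    def test_constant_row_is_one_run(self):
        tm, _ = glrlm(make_droi(np.ones((1, 7))))
        horizontal = tm.matrices[0]
        assert horizontal[0, 6] == 1
        assert horizontal.sum() == 1

    def test_checkerboard_all_runs_length_one(self):
        bins = 1 + (np.add.outer(np.arange(4), np.arange(4)) % 2)
        tm, _ = glrlm(make_droi(bins))
        for mat, (dr, dc) in zip(tm.matrices, _DIRECTIONS):
            if abs(dr) + abs(dc) == 1:  # horizontal / vertical alternate
                assert mat[:, 1:].sum() == 0
                assert mat[:, 0].sum() == 16

    def test_matches_walk_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            bins, _ = oracles.random_bin_image(rng)
            droi = make_droi(bins)
            tm, _ = glrlm(droi)
            for mat, direction in zip(tm.matrices, _DIRECTIONS):
                expect = oracles.glrlm_matrix(bins, direction, droi.ng, max(bins.shape))
                np.testing.assert_array_equal(mat, expect)


class TestGlszm:
    def test_two_level_zones_against_flood_fill(self):
        rng = np.random.default_rng(21)
        bins = rng.integers(1, 3, size=(8, 8))
        droi = make_droi(bins)
        tm, _ = glszm(droi)
        expect = oracles.glszm_matrix(bins, droi.ng, droi.n_pixels)
        np.testing.assert_array_equal(tm.matrices[0], expect)

    def test_single_zone_constant_roi(self):
        droi = make_droi(np.ones((5, 5)))
        tm, f = glszm(droi)
        assert tm.matrices[0][0, 24] == 1
        assert f["ZonePercentage"] == pytest.approx(1 / 25)


class TestGldm:
    def test_constant_roi_center_dependence(self):
        """Center of a constant 3x3 has all 8 neighbors dependent; HGLE = 1."""
        droi = make_droi(np.ones((3, 3)))
        dep = dependence_counts(droi)
        assert dep[1, 1] == 8
        _, f = gldm(droi)
        assert f["HighGrayLevelEmphasis"] == 1.0

    def test_striped_image_matches_enumeration(self):
        bins = np.tile([1, 2, 1, 2], (4, 1))
        droi = make_droi(bins)
        tm, _ = gldm(droi)
        np.testing.assert_array_equal(tm.matrices[0], oracles.gldm_matrix(bins, droi.ng))

    def test_alpha_infinity_counts_all_neighbors(self):
        rng = np.random.default_rng(13)
        bins, mask = oracles.random_bin_image(rng)
        droi = make_droi(bins)
        dep = dependence_counts(droi, alpha=10**6)
        from scipy import ndimage

        neigh = ndimage.correlate(
            (bins > 0).astype(int), np.ones((3, 3), int), mode="constant"
        ) - (bins > 0)
        np.testing.assert_array_equal(dep[bins > 0], neigh[bins > 0])


class TestNgtdm:
    def test_constant_roi_all_differences_zero(self):
        droi = make_droi(np.ones((4, 4)))
        _, f = ngtdm(droi)
        assert f["Contrast"] == 0.0
        assert f["Strength"] == 0.0

    def test_deviant_center_hand_enumeration(self):
        bins = np.ones((3, 3), dtype=int)
        bins[1, 1] = 3
        droi = make_droi(bins)
        n, s, nvp = ngtdm_table(droi)
        en, es, envp = oracles.ngtdm_table(bins, droi.ng)
        np.testing.assert_array_equal(n, en)
        np.testing.assert_allclose(s, es)
        assert nvp == envp
        # corner pixels see mean (2*1 + 3)/3, edges (4*1 + 3)/5, center sees 1
        assert s[0] == pytest.approx(4 * abs(1 - 5 / 3) + 4 * abs(1 - 7 / 5))
        assert s[2] == pytest.approx(2.0)

    def test_strength_non_negative(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            bins, _ = oracles.random_bin_image(rng)
            _, f = ngtdm(make_droi(bins))
            assert f["Strength"] >= 0.0


class TestAllMatricesPropertyBased:
    """Every texture matrix equals brute-force enumeration on random images."""

    @pytest.mark.parametrize("seed", range(100))
    def test_matrices_equal_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        bins, _ = oracles.random_bin_image(rng)
        droi = make_droi(bins)
        ng, npx = droi.ng, droi.n_pixels

        tm_glcm, _ = glcm(droi)
        pair_totals = [
            oracles.glcm_matrix(bins, d, ng) for d in _DIRECTIONS
        ]
        valid = [m for m in pair_totals if m.sum() > 0]
        if valid:
            k = 0
            for expect in pair_totals:
                if expect.sum() == 0:
                    continue  # direction skipped by the implementation too
                np.testing.assert_allclose(tm_glcm.matrices[k], expect, atol=1e-12)
                k += 1

        tm_glrlm, _ = glrlm(droi)
        for mat, d in zip(tm_glrlm.matrices, _DIRECTIONS):
            np.testing.assert_array_equal(
                mat, oracles.glrlm_matrix(bins, d, ng, max(bins.shape))
            )

        tm_glszm, _ = glszm(droi)
        np.testing.assert_array_equal(tm_glszm.matrices[0], oracles.glszm_matrix(bins, ng, npx))

        tm_gldm, _ = gldm(droi)
        np.testing.assert_array_equal(tm_gldm.matrices[0], oracles.gldm_matrix(bins, ng))

        n, s, nvp = ngtdm_table(droi)
        en, es, envp = oracles.ngtdm_table(bins, ng)
        np.testing.assert_array_equal(n, en)
        np.testing.assert_allclose(s, es, atol=1e-9)
        assert nvp == envp
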