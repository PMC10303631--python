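"""Radiomic engine: discretization, first-order, shape, and the hand-worked
texture examples (the exhaustive brute-force equivalence lives in
test_acceptance.py)."""

import numpy as np
import pytest

from oracles import first_order_oracle
from dynomics.radiomics import (
    DiscretizationScheme,
    FEATURE_NAMES,
    discretize,
    extract_all,
    first_order_features,
    gldm_features,
    glcm_features,
    glcm_matrices,
    glrlm_features,
    glszm_features,
    ngtdm_features,
    shape3d_features,
)
from dynomics.radiomics.discretize import QuantizedVoi
from dynomics.radiomics.glrlm import _features_one as glrlm_one
from dynomics.radiomics.glrlm import glrlm_matrices


def _qvoi_from(levels, ng):
    levels = np.asarray(levels)
    mask = levels > 0
    return QuantizedVoi(levels, ng, mask, (1.0, 1.0, 1.0))


class TestDiscretize:
    def test_constant_region_single_level(self):
        data = np.full((3, 3, 3), 7.0)
        q = discretize(data, np.ones_like(data, bool))
        assert q.ng == 1
        assert set(q.masked_levels) == {1}

    def test_fixed_bin_count_full_range(self):
        data = np.arange(32, dtype=float).reshape(2, 4, 4)
        q = discretize(data, np.ones_like(data, bool),
                       DiscretizationScheme("fixed_bin_count", n_bins=32))
        np.testing.assert_array_equal(np.sort(q.masked_levels),
                                      np.arange(1, 33))

    def test_fixed_bin_width(self):
        data = np.array([[[0.0, 100.0]]])
        q = discretize(data, np.ones_like(data, bool),
                       DiscretizationScheme("fixed_bin_width", bin_width=25.0))
        assert sorted(q.masked_levels) == [1, 5]
        assert q.ng == 5

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            discretize(np.ones((2, 2, 2)), np.zeros((2, 2, 2), bool))

    def test_shift_invariance_under_bin_count(self, rng):
        data = rng.random((4, 4, 4)) * 10
        mask = np.ones((4, 4, 4), bool)
        q1 = discretize(data, mask)
        q2 = discretize(data + 137.0, mask)
        np.testing.assert_array_equal(q1.levels, q2.levels)


class TestFirstOrder:
    def test_constant_region_conventions(self):
        data = np.full((3, 3, 2), 5.0)
        mask = np.ones_like(data, bool)
        q = discretize(data, mask)
        f = first_order_features(data, mask, q, 1.0)
        assert f["Mean"] == 5.0
        assert f["Variance"] == 0.0
        assert f["Entropy"] == 0.0
        assert f["Uniformity"] == 1.0
        assert f["Skewness"] == 0.0 and f["Kurtosis"] == 0.0

    def test_small_closed_forms(self):
        data = np.array([[[1.0, 2.0, 3.0, 4.0]]])
        mask = np.ones_like(data, bool)
        f = first_order_features(data, mask, discretize(data, mask), 2.0)
        assert f["Mean"] == pytest.approx(2.5)
        assert f["RootMeanSquared"] == pytest.approx(np.sqrt(30 / 4))
        assert f["Energy"] == pytest.approx(30.0)
        assert f["TotalEnergy"] == pytest.approx(60.0)

    def test_matches_independent_oracle(self, rng):
        data = rng.random((5, 5, 3)) * 20
        mask = rng.random((5, 5, 3)) < 0.8
        mask[0, 0, 0] = True
        q = discretize(data, mask)
        got = first_order_features(data, mask, q, 3.5)
        want = first_order_oracle(data[mask], q.masked_levels, q.ng, 3.5)
        for k, v in want.items():
            assert got[k] == pytest.approx(v, abs=1e-10), k


class TestShape3D:
    def test_unit_cube_block(self):
        mask = np.zeros((14, 14, 14), bool)
        mask[2:12, 2:12, 2:12] = True
        f = shape3d_features(mask, (1.0, 1.0, 1.0))
        assert f["VoxelVolume"] == pytest.approx(1000.0)
        # iso-surface triangulation chamfers the corners slightly
        assert f["MeshVolume"] == pytest.approx(1000.0, rel=0.02)
        assert f["Elongation"] == pytest.approx(1.0)
        assert f["Flatness"] == pytest.approx(1.0)

    def test_ball_approaches_sphere(self, ball_mask):
        # binary marching cubes inflates the surface area of a digitized
        # ball by a staircase factor, so sphericity sits a little below the
        # analytic limit of 1
        f = shape3d_features(ball_mask, (1.0, 1.0, 1.0))
        assert 0.90 <= f["Sphericity"] <= 1.0
        assert f["Maximum3DDiameter"] == pytest.approx(17.0, rel=0.1)

    def test_single_voxel_fallback_flagged(self):
        mask = np.zeros((3, 3, 3), bool)
        mask[1, 1, 1] = True
        with pytest.warns(UserWarning, match="voxel-based"):
            f = shape3d_features(mask, (1.0, 1.0, 1.0))
        assert f["VoxelVolume"] == pytest.approx(1.0)
        assert all(np.isfinite(v) for v in f.values())

    def test_anisotropic_voxel_volume(self):
        mask = np.ones((2, 2, 2), bool)
        f = shape3d_features(mask, (3.9, 3.9, 4.2))
        assert f["VoxelVolume"] == pytest.approx(8 * 3.9 * 3.9 * 4.2)


class TestGlcmHandExamples:
    def test_constant_region_degenerate(self):
        q = _qvoi_from(np.ones((3, 3, 3), int), 1)
        f = glcm_features(q)
        assert f["Contrast"] == 0.0
        assert f["JointEnergy"] == 1.0
        assert f["MaximumProbability"] == 1.0
        assert f["Correlation"] == 1.0

    def test_alternating_strip_single_direction(self):
        # strip 1,2,1,2 along x: pairs (1,2)x3 both ways -> P(1,2)=P(2,1)=1/2
        q = _qvoi_from(np.array([1, 2, 1, 2]).reshape(4, 1, 1), 2)
        mats = glcm_matrices(q)
        assert len(mats) == 1  # only the x direction has pairs
        np.testing.assert_allclose(mats[0], [[0.0, 0.5], [0.5, 0.0]])
        f = glcm_features(q)
        assert f["Contrast"] == pytest.approx(1.0)
        assert f["JointAverage"] == pytest.approx(1.5)
        assert f["SumAverage"] == pytest.approx(3.0)


class TestGlrlmHandExamples:
    def test_single_run_strip(self):
        q = _qvoi_from(np.ones((1, 1, 6), int), 1)
        mats = glrlm_matrices(q)
        # the z-direction matrix holds one run of length 6
        along = [m for m in mats if m.shape[1] == 6]
        assert along, "no direction captured the full run"
        f = glrlm_one(along[0], 6)
        assert f["RunLengthNonUniformity"] == pytest.approx(1.0)
        assert f["RunPercentage"] == pytest.approx(1 / 6)

    def test_alternating_strip_all_short_runs(self):
        q = _qvoi_from(np.array([1, 2] * 4).reshape(1, 1, 8), 2)
        f = glrlm_features(q)
        assert f["ShortRunEmphasis"] == pytest.approx(1.0)
        assert f["LongRunEmphasis"] == pytest.approx(1.0)


class TestGlszmHandExamples:
    def test_constant_region_single_zone(self):
        q = _qvoi_from(np.ones((3, 3, 2), int), 1)
        f = glszm_features(q)
        assert f["SizeZoneNonUniformity"] == pytest.approx(1.0)
        assert f["ZonePercentage"] == pytest.approx(1 / 18)

    def test_two_isolated_low_level_voxels(self):
        lv = np.zeros((5, 1, 1), int)
        lv[0] = 1
        lv[4] = 1
        q = QuantizedVoi(lv, 1, lv > 0, (1, 1, 1))
        f = glszm_features(q)
        assert f["LowGrayLevelZoneEmphasis"] == pytest.approx(1.0)
        assert f["SizeZoneNonUniformity"] == pytest.approx(2.0)


class TestNgtdmHandExamples:
    def test_constant_region_contrast_zero(self):
        f = ngtdm_features(_qvoi_from(np.ones((3, 3, 3), int), 1))
        assert f["Contrast"] == 0.0
        assert np.isfinite(f["Coarseness"])

    def test_checkerboard_strip_hand_computed(self):
        # levels 1,2,1,2: every voxel deviates from its neighbour mean by 1
        # -> s = (2, 2), p = (1/2, 1/2), Contrast = 1/2 * ... = 0.25
        q = _qvoi_from(np.array([1, 2, 1, 2]).reshape(1, 1, 4), 2)
        f = ngtdm_features(q)
        assert f["Contrast"] == pytest.approx(0.25)


class TestGldmHandExamples:
    def test_single_voxel_single_column(self):
        q = _qvoi_from(np.ones((1, 1, 1), int), 1)
        f = gldm_features(q)
        assert f["DependenceNonUniformityNormalized"] == pytest.approx(1.0)
        assert f["SmallDependenceEmphasis"] == pytest.approx(1.0)

    def test_isolated_voxels_have_zero_dependence(self):
        # all 4 levels distinct: with alpha=0 nobody depends on anybody
        q = _qvoi_from(np.array([1, 2, 3, 4]).reshape(1, 1, 4), 4)
        f = gldm_features(q, alpha=0.0)
        # all voxels in the j=1 (dependence size 1) column
        assert f["SmallDependenceEmphasis"] == pytest.approx(1.0)
        assert f["LargeDependenceEmphasis"] == pytest.approx(1.0)
        # with alpha large everyone depends on every neighbour
        f2 = gldm_features(q, alpha=10.0)
        assert f2["LargeDependenceEmphasis"] > f["LargeDependenceEmphasis"]


class TestExtractAll:
    def test_vector_contract(self, rng):
        data = rng.random((6, 6, 4)) * 8
        mask = rng.random((6, 6, 4)) < 0.7
        mask[2, 2, 2] = True
        vec = extract_all(data, mask, spacing=(1.0, 1.0, 1.0))
        assert len(vec) == 107
        assert list(vec.index) == list(FEATURE_NAMES)
        assert np.isfinite(vec.to_numpy()).all()

    def test_constant_region_all_finite(self):
        data = np.full((4, 4, 4), 3.3)
        mask = np.ones((4, 4, 4), bool)
        vec = extract_all(data, mask, spacing=(1.0, 1.0, 1.0))
        assert np.isfinite(vec.to_numpy()).all()
        assert vec["firstorder/Mean"] == pytest.approx(3.3)
        assert vec["glcm/Contrast"] == 0.0

    def test_intensity_shift_invariance_of_texture(self, rng):
        data = rng.random((5, 5, 4)) * 5
        mask = np.ones((5, 5, 4), bool)
        a = extract_all(data, mask, spacing=(1.0, 1.0, 1.0))
        b = extract_all(data + 42.0, mask, spacing=(1.0, 1.0, 1.0))
        texture = [n for n in FEATURE_NAMES
                   if n.split("/")[0] in ("glcm", "glrlm", "glszm", "ngtdm",
                                          "gldm")
                   or n in ("firstorder/Entropy", "firstorder/Uniformity")]
        np.testing.assert_allclose(a[texture], b[texture], rtol=1e-12)

    def test_rotation_invariance_isotropic(self, rng):
        data = rng.random((5, 5, 5)) * 6
        mask = rng.random((5, 5, 5)) < 0.8
        mask[2, 2, 2] = True
        a = extract_all(data, mask, spacing=(1.0, 1.0, 1.0))
        b = extract_all(np.rot90(data, axes=(0, 1)),
                        np.rot90(mask, axes=(0, 1)),
                        spacing=(1.0, 1.0, 1.0))
        # per-plane 2D diameters permute under rotation; everything else is
        # invariant (texture via direction averaging)
        variant = {"shape/Maximum2DDiameterSlice", "shape/Maximum2DDiameterRow",
                   "shape/Maximum2DDiameterColumn"}
        keep = [n for n in FEATURE_NAMES if n not in variant]
        np.testing.assert_allclose(a[keep], b[keep], rtol=1e-9, atol=1e-9)

    def test_grid_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="grids differ"):
            extract_all(rng.random((4, 4, 4)), np.ones((4, 4, 3), bool),
                        spacing=(1.0, 1.0, 1.0))
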