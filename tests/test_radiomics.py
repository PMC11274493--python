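"""Radiomics engine: discretization, per-family hand values, count contracts."""

import numpy as np
import pytest

from radguide.io_core import Volume
from radguide.radiomics import (
    CATEGORIES,
    N_FEATURES_PER_ROI,
    DiscretizationScheme,
    discretize_values,
    extract_all,
    firstorder_features,
    glcm_features,
    glcm_matrix,
    gldm_features,
    gldm_matrix,
    glrlm_features,
    glrlm_matrix,
    glszm_features,
    glszm_matrix,
    ngtdm_features,
    ngtdm_table,
    shape_features,
)
from radguide.radiomics._discretize import DiscretizedROI
from radguide.radiomics._texture import ANGLES
from radguide.phantom import simulate_subject


def line_roi(levels, values=None):
    """1 x 1 x n ROI with given levels."""
    levels = np.asarray(levels, dtype=np.int64)
    grid = levels.reshape(1, 1, -1)
    vals = np.asarray(values, dtype=float) if values is not None \
        else levels.astype(float)
    return DiscretizedROI(grid=grid, values=vals, ng=int(levels.max()),
                          scheme=DiscretizationScheme(), spacing=(1, 1, 1))


class TestRegistry:
    def test_107_features_decomposition(self):
        sizes = {c: len(f) for c, f in CATEGORIES.items()}
        assert sizes == {"firstorder": 18, "shape": 14, "glcm": 24,
                        "glrlm": 16, "glszm": 16, "gldm": 14, "ngtdm": 5}
        assert N_FEATURES_PER_ROI == 107


class TestDiscretize:
    def test_fixed_width_hand_example(self):
        levels, ng = discretize_values(
            np.array([1.0, 1.2, 1.4, 1.6]),
            DiscretizationScheme(mode="fixed_width", bin_width=0.2))
        assert list(levels) == [1, 2, 3, 4]
        assert ng == 4

    def test_constant_roi_single_level(self):
        levels, ng = discretize_values(np.full(5, 2.2), DiscretizationScheme())
        assert ng == 1 and set(levels) == {1}

    def test_fixed_count_2_bins(self):
        levels, ng = discretize_values(np.array([0.0, 1.0, 2.0, 3.0]),
                                       DiscretizationScheme(n_bins=2))
        assert ng == 2
        assert list(levels) == [1, 1, 2, 2]


class TestFirstOrder:
    def test_population_variance_and_rms(self):
        droi = line_roi([1, 2, 3, 4])
        f = firstorder_features(droi)
        assert f["Variance"] == pytest.approx(1.25)
        assert f["RootMeanSquared"] == pytest.approx(np.sqrt(30 / 4))
        assert f["Mean"] == pytest.approx(2.5)

    def test_constant_roi_degeneracies(self):
        droi = line_roi([1, 1, 1], values=[2.0, 2.0, 2.0])
        f = firstorder_features(droi)
        assert f["Variance"] == 0
        assert f["Range"] == 0
        assert f["Entropy"] == 0
        assert f["Uniformity"] == 1
        assert f["Skewness"] == 0 and f["Kurtosis"] == 0


class TestShape:
    def test_single_voxel(self):
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[1, 1, 1] = True
        f = shape_features(mask, (1, 1, 1))
        assert f["VoxelVolume"] == pytest.approx(1.0)
        assert f["SurfaceArea"] == pytest.approx(6.0)

    def test_cube_2x2x2(self):
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[1:3, 1:3, 1:3] = True
        f = shape_features(mask, (1, 1, 1))
        assert f["VoxelVolume"] == pytest.approx(8.0)
        assert f["SurfaceArea"] == pytest.approx(24.0)
        assert f["Sphericity"] == pytest.approx((36 * np.pi * 64) ** (1 / 3) / 24)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            shape_features(np.zeros((2, 2, 2), dtype=bool), (1, 1, 1))


class TestGLCM:
    def test_hand_counts_1114(self):
        droi = line_roi([1, 1, 2, 2])
        mats = glcm_matrix(droi)
        along = [m for m in mats if m.sum() > 0]
        assert len(along) == 1  # only (0,0,1) has in-ROI pairs
        # pairs along +z: (1,1), (1,2), (2,2), each counted in both orders:
        # unordered-pair counts {1,1}: 2, {1,2}: 2, {2,2}: 2
        m = along[0]
        np.testing.assert_array_equal(m, [[2, 1], [1, 2]])
        assert m[0, 1] + m[1, 0] == 2
        assert m.sum() == 6

    def test_sum_average_hand_value(self):
        droi = line_roi([1, 1, 2, 2])
        f = glcm_features(glcm_matrix(droi))
        assert f["SumAverage"] == pytest.approx(3.0)

    def test_constant_roi_degeneracies(self):
        droi = line_roi([1, 1, 1])
        f = glcm_features(glcm_matrix(droi))
        assert f["Correlation"] == 1.0
        assert f["Contrast"] == 0.0
        assert f["DifferenceEntropy"] == 0.0

    def test_pair_totals_are_twice_neighbor_pairs(self):
        rng = np.random.default_rng(0)
        grid = rng.integers(0, 4, size=(5, 5, 5)).astype(np.int64)
        droi = DiscretizedROI(grid=grid, values=grid[grid > 0].astype(float),
                              ng=max(int(grid.max()), 1),
                              scheme=DiscretizationScheme(), spacing=(1, 1, 1))
        for d, mat in zip(ANGLES, glcm_matrix(droi)):
            count = 0
            for x in range(5):
                for y in range(5):
                    for z in range(5):
                        q = (x + d[0], y + d[1], z + d[2])
                        if all(0 <= q[i] < 5 for i in range(3)) \
                                and grid[x, y, z] > 0 and grid[q] > 0:
                            count += 1
            assert mat.sum() == 2 * count


class TestGLRLM:
    def test_constant_line_single_run(self):
        droi = line_roi([1, 1, 1, 1])
        mats = glrlm_matrix(droi)
        # direction (0,0,1): one run of length 4 -> LRE = 16
        for d, m in zip(ANGLES, mats):
            if d == (0, 0, 1):
                lre = (m * (np.arange(1, m.shape[1] + 1) ** 2)).sum() / m.sum()
                assert lre == pytest.approx(16.0)

    def test_alternating_line(self):
        droi = line_roi([1, 2, 1, 2])
        f = glrlm_features(glrlm_matrix(droi), 4)
        assert f["LongRunEmphasis"] == pytest.approx(1.0)  # all runs length 1
        assert f["HighGrayLevelRunEmphasis"] == pytest.approx(2.5)

    def test_run_lengths_partition_voxels(self):
        rng = np.random.default_rng(1)
        grid = rng.integers(0, 4, size=(6, 6, 6)).astype(np.int64)
        droi = DiscretizedROI(grid=grid, values=grid[grid > 0].astype(float),
                              ng=int(grid.max()), scheme=DiscretizationScheme(),
                              spacing=(1, 1, 1))
        n_vox = droi.n_voxels
        for m in glrlm_matrix(droi):
            lengths = np.arange(1, m.shape[1] + 1)
            assert (m * lengths).sum() == n_vox


class TestGLSZM:
    def test_single_zone_cube(self):
        grid = np.ones((2, 2, 2), dtype=np.int64)
        droi = DiscretizedROI(grid=grid, values=np.ones(8), ng=1,
                              scheme=DiscretizationScheme(), spacing=(1, 1, 1))
        f = glszm_features(glszm_matrix(droi), 8)
        assert f["LargeAreaEmphasis"] == pytest.approx(64.0)

    def test_zone_sizes_partition_voxels(self):
        rng = np.random.default_rng(2)
        grid = rng.integers(0, 5, size=(6, 6, 6)).astype(np.int64)
        droi = DiscretizedROI(grid=grid, values=grid[grid > 0].astype(float),
                              ng=int(grid.max()), scheme=DiscretizationScheme(),
                              spacing=(1, 1, 1))
        m = glszm_matrix(droi)
        sizes = np.arange(1, m.shape[1] + 1)
        assert (m * sizes).sum() == droi.n_voxels


class TestGLDM:
    def test_single_voxel(self):
        grid = np.zeros((3, 3, 3), dtype=np.int64)
        grid[1, 1, 1] = 1
        droi = DiscretizedROI(grid=grid, values=np.array([1.0]), ng=1,
                              scheme=DiscretizationScheme(), spacing=(1, 1, 1))
        m = gldm_matrix(droi)
        assert m.sum() == 1 and m[0, 0] == 1  # dependence 0 -> first column

    def test_constant_cube_center_dependence(self):
        grid = np.ones((3, 3, 3), dtype=np.int64)
        droi = DiscretizedROI(grid=grid, values=np.ones(27), ng=1,
                              scheme=DiscretizationScheme(), spacing=(1, 1, 1))
        m = gldm_matrix(droi)
        assert m[0, 26] == 1  # only the center has all 26 neighbors
        assert m.sum() == 27


class TestNGTDM:
    def test_constant_roi(self):
        grid = np.ones((3, 3, 3), dtype=np.int64)
        droi = DiscretizedROI(grid=grid, values=np.ones(27), ng=1,
                              scheme=DiscretizationScheme(), spacing=(1, 1, 1))
        f = ngtdm_features(droi)
        assert f["Coarseness"] == 1e6
        assert f["Contrast"] == 0.0

    def test_line_hand_values(self):
        droi = line_roi([1, 2, 3])
        n_i, p_i, s_i, nvp = ngtdm_table(droi)
        assert nvp == 3
        # middle voxel: neighbors {1,3}, mean 2, |2-2| = 0
        # end voxels: single neighbor 2, |1-2| = 1 and |3-2| = 1
        np.testing.assert_allclose(s_i, [1.0, 0.0, 1.0])
        np.testing.assert_allclose(n_i, [1, 1, 1])


class TestExtractAll:
    def test_counts_2140_and_deterministic(self, toy_atlas, default_design):
        vol = simulate_subject(toy_atlas, "PSP", default_design,
                               np.random.default_rng(0))
        s1 = extract_all(vol, toy_atlas)
        assert len(s1) == 20 * 107 == 2140
        s2 = extract_all(vol, toy_atlas)
        assert (s1 == s2).all()
        assert s1.notna().all()

    def test_single_region_atlas_gives_107(self, toy_atlas, default_design):
        from radguide.io_core import Atlas
        label, name = toy_atlas.region_table[0]
        labels = np.where(toy_atlas.labels == label, 1, 0).astype(np.int64)
        one = Atlas(labels=labels, region_table=[(1, name)],
                    spacing=toy_atlas.spacing)
        vol = simulate_subject(toy_atlas, "HC", default_design,
                               np.random.default_rng(1))
        s = extract_all(vol, one)
        assert len(s) == 107

    def test_empty_region_rejected(self, toy_atlas, default_design):
        from radguide.io_core import Atlas
        labels = toy_atlas.labels.copy()
        bad = Atlas(labels=labels,
                    region_table=toy_atlas.region_table + [(99, "ghost")],
                    spacing=toy_atlas.spacing)
        vol = simulate_subject(toy_atlas, "HC", default_design,
                               np.random.default_rng(1))
        with pytest.raises(ValueError, match="99"):
            extract_all(vol, bad)
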