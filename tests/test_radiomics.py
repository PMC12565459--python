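from collections import Counter

import numpy as np
import pytest

from edemagrade.radiomics import (
    EmptyROIError,
    RadiomicsConfig,
    ROISpec,
    discretize,
    extract_all,
    extract_roi,
    firstorder_features,
    full_feature_names,
    glcm_features,
    gldm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
    shape_features,
    wavelet_subbands,
)
from edemagrade.radiomics.registry import (
    FIRSTORDER_FEATURES,
    GLCM_FEATURES,
    GLDM_FEATURES,
    GLRLM_FEATURES,
    GLSZM_FEATURES,
    NGTDM_FEATURES,
    WAVELET_BANDS,
)
from edemagrade.radiomics.roi import DiscretizedROI
from edemagrade.radiomics.texture import (
    DIRECTIONS_13,
    NGTDM_COARSENESS_SENTINEL,
    glcm_matrix,
    gldm_matrix,
    glrlm_matrices,
    glszm_matrix,
    ngtdm_table,
)
from edemagrade.types import SegMask, VolumeImage
from oracles import (
    oracle_dependence,
    oracle_firstorder,
    oracle_glcm,
    oracle_ngtdm,
    oracle_runs,
    oracle_zones,
)


def _const_roi(value=3, shape=(4, 4, 2)) -> DiscretizedROI:
    lev = np.full(shape, 1, dtype=np.int64)
    return DiscretizedROI(levels=lev, Ng=1, bin_width=25.0)


class TestRoiAndDiscretize:
    def test_roi_count_and_error(self, hgg_subject):
        roi = extract_roi(hgg_subject.modalities["FLAIR"], hgg_subject.mask, ROISpec(label=2))
        assert roi.count == (hgg_subject.mask.data == 2).sum()
        core = extract_roi(hgg_subject.modalities["FLAIR"], hgg_subject.mask, ROISpec(label=1))
        assert roi.count > core.count  # edema shell outnumbers the core

    def test_absent_label_raises(self):
        vol = VolumeImage(np.zeros((8, 8, 8)))
        mask = SegMask(np.zeros((8, 8, 8), dtype=np.int16))
        with pytest.raises(EmptyROIError):
            extract_roi(vol, mask)

    @pytest.mark.parametrize(
        "values, expected_levels, expected_ng",
        [
            (np.array([0.0, 5.0, 24.0]), [1, 1, 1], 1),
            (np.array([0.0, 25.0, 50.0]), [1, 2, 3], 3),
        ],
    )
    def test_bin_assignment(self, values, expected_levels, expected_ng):
        d = discretize(values.reshape(-1, 1, 1), 25.0)
        assert list(d.levels.ravel()) == expected_levels and d.Ng == expected_ng

    def test_uniform_range_bin_count(self):
        values = np.linspace(0, 250, 1000, endpoint=False).reshape(10, 10, 10)
        assert discretize(values, 25.0).Ng == 10

    def test_shift_invariance_of_levels(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(0, 200, (5, 5, 5))
        d1 = discretize(v, 25.0)
        d2 = discretize(v + 77.0, 25.0)
        np.testing.assert_array_equal(d1.levels, d2.levels)


class TestShape:
    def test_fourteen_features(self, hgg_subject):
        feats = shape_features(hgg_subject.mask.data == 2, (1.0, 1.0, 1.0))
        assert len(feats) == 14 and all(np.isfinite(list(feats.values())))

    def test_digital_ball_is_nearly_spherical(self):
        r = 9
        g = np.ogrid[-12:13, -12:13, -12:13]
        ball = (g[0] ** 2 + g[1] ** 2 + g[2] ** 2) <= r**2
        feats = shape_features(ball, (1.0, 1.0, 1.0))
        assert 0.9 <= feats["Sphericity"] <= 1.0
        assert feats["Maximum3DDiameter"] == pytest.approx(2 * r, rel=0.1)
        assert feats["Elongation"] == pytest.approx(1.0, abs=0.05)

    def test_rod_is_elongated_and_flat(self):
        rod = np.zeros((1, 1, 30), dtype=bool)
        rod[0, 0, :] = True
        feats = shape_features(rod, (1.0, 1.0, 1.0))
        assert feats["Elongation"] < 0.1 and feats["Flatness"] < 0.1

    def test_mesh_volume_tracks_voxel_volume(self):
        cube = np.ones((6, 6, 6), dtype=bool)
        feats = shape_features(cube, (1.0, 1.0, 1.0))
        assert feats["VoxelVolume"] == 216.0
        assert feats["MeshVolume"] == pytest.approx(216.0, rel=0.3)


class TestFirstOrder:
    def test_constant_roi_degenerates_cleanly(self):
        feats = firstorder_features(np.full(100, 9.0))
        assert feats["Variance"] == 0.0 and feats["Uniformity"] == 1.0
        assert feats["Entropy"] == 0.0 and feats["Skewness"] == 0.0

    def test_closed_form_on_1_to_100(self):
        feats = firstorder_features(np.arange(1.0, 101.0))
        assert feats["Mean"] == pytest.approx(50.5)
        assert feats["Median"] == pytest.approx(50.5)
        assert feats["Range"] == pytest.approx(99.0)

    def test_matches_naive_oracle(self):
        rng = np.random.default_rng(3)
        v = rng.uniform(0, 255, 500)
        feats = firstorder_features(v)
        oracle = oracle_firstorder(v)
        for name, expected in oracle.items():
            assert feats[name] == pytest.approx(expected, abs=1e-9), name

    def test_count_is_eighteen(self):
        assert len(firstorder_features(np.arange(10.0))) == len(FIRSTORDER_FEATURES) == 18


class TestTextureOracles:
    def test_glcm_matrices_match_bruteforce(self, tiny_levels):
        for direction in DIRECTIONS_13:
            P = glcm_matrix(tiny_levels, direction)
            np.testing.assert_allclose(
                P, oracle_glcm(tiny_levels.levels, tiny_levels.Ng, direction), atol=1e-9
            )

    def test_glrlm_matrices_match_bruteforce(self, tiny_levels):
        mats = glrlm_matrices(tiny_levels)
        for direction, R in zip(DIRECTIONS_13, mats):
            expected = oracle_runs(tiny_levels.levels, direction)
            got = Counter()
            for (g, l), c in np.ndenumerate(R):
                if c:
                    got[(g + 1, l + 1)] = int(c)
            assert got == expected, direction

    def test_glszm_matrix_matches_floodfill(self, tiny_levels):
        S = glszm_matrix(tiny_levels)
        expected = oracle_zones(tiny_levels.levels, tiny_levels.Ng)
        got = Counter()
        for (g, s), c in np.ndenumerate(S):
            if c:
                got[(g + 1, s + 1)] = int(c)
        assert got == expected

    def test_gldm_matrix_matches_bruteforce(self, tiny_levels):
        D = gldm_matrix(tiny_levels, alpha=0)
        expected = oracle_dependence(tiny_levels.levels, alpha=0)
        got = Counter()
        for (g, d), c in np.ndenumerate(D):
            if c:
                got[(g + 1, d + 1)] = int(c)
        assert got == expected

    def test_ngtdm_table_matches_bruteforce(self, tiny_levels):
        n_i, s_i = ngtdm_table(tiny_levels)
        en, es = oracle_ngtdm(tiny_levels.levels, tiny_levels.Ng)
        np.testing.assert_allclose(n_i, en, atol=1e-9)
        np.testing.assert_allclose(s_i, es, atol=1e-9)


class TestTextureFeatures:
    def test_constant_roi_glcm_degenerates(self):
        feats = glcm_features(_const_roi())
        assert feats["Contrast"] == 0.0
        assert feats["MaximumProbability"] == 1.0
        assert feats["JointEntropy"] == 0.0

    def test_checkerboard_contrast_hand_count(self):
        """4x4x1 two-level checkerboard: along (0,1,0) every adjacent
        pair alternates, so contrast = sum p(i,j)(i-j)^2 = 1."""
        lev = np.indices((4, 4, 1)).sum(axis=0) % 2 + 1
        d = DiscretizedROI(levels=lev.astype(np.int64), Ng=2, bin_width=25.0)
        P = glcm_matrix(d, (0, 1, 0))
        p = P / P.sum()
        contrast = sum(
            p[i, j] * (i - j) ** 2 for i in range(2) for j in range(2)
        )
        assert contrast == pytest.approx(1.0)

    def test_feature_family_counts(self, tiny_levels):
        assert len(glcm_features(tiny_levels)) == len(GLCM_FEATURES) == 24
        assert len(glrlm_features(tiny_levels)) == len(GLRLM_FEATURES) == 16
        assert len(glszm_features(tiny_levels)) == len(GLSZM_FEATURES) == 16
        assert len(gldm_features(tiny_levels)) == len(GLDM_FEATURES) == 14
        assert len(ngtdm_features(tiny_levels)) == len(NGTDM_FEATURES) == 5

    def test_constant_roi_family_degeneracies(self):
        d = _const_roi(shape=(4, 4, 2))
        rl = glrlm_features(d)
        sz = glszm_features(d)
        ng = ngtdm_features(d)
        assert rl["LongRunEmphasis"] > 1.0  # runs span the ROI
        assert sz["ZonePercentage"] == pytest.approx(1.0 / d.n_voxels)  # one zone
        assert ng["Coarseness"] == NGTDM_COARSENESS_SENTINEL

    def test_two_run_sequence_hand_enumerated(self):
        lev = np.array([1, 1, 1, 2, 2], dtype=np.int64).reshape(5, 1, 1)
        d = DiscretizedROI(levels=lev, Ng=2, bin_width=25.0)
        R = glrlm_matrices(d)[DIRECTIONS_13.index((1, 0, 0))]
        got = {(g + 1, l + 1): int(c) for (g, l), c in np.ndenumerate(R) if c}
        assert got == {(1, 3): 1, (2, 2): 1}
        assert R.sum() / d.n_voxels == pytest.approx(2 / 5)

    def test_rotation_invariance_of_direction_averaged_features(self):
        rng = np.random.default_rng(11)
        lev = rng.integers(1, 5, size=(7, 7, 3)).astype(np.int64)
        d1 = DiscretizedROI(levels=lev, Ng=4, bin_width=25.0)
        d2 = DiscretizedROI(levels=np.rot90(lev, axes=(0, 1)).copy(), Ng=4, bin_width=25.0)
        f1, f2 = glcm_features(d1), glcm_features(d2)
        for name in GLCM_FEATURES:
            assert f1[name] == pytest.approx(f2[name], abs=1e-9), name
        r1, r2 = glrlm_features(d1), glrlm_features(d2)
        for name in GLRLM_FEATURES:
            assert r1[name] == pytest.approx(r2[name], abs=1e-9), name


class TestWavelet:
    def test_eight_bands_input_shape(self):
        rng = np.random.default_rng(2)
        vol = rng.normal(size=(10, 12, 8))
        bands = wavelet_subbands(vol)
        assert tuple(bands) == WAVELET_BANDS
        assert all(b.shape == vol.shape for b in bands.values())

    def test_constant_volume_kills_high_bands(self):
        bands = wavelet_subbands(np.full((8, 8, 8), 5.0))
        for name, band in bands.items():
            if "H" in name:
                np.testing.assert_allclose(band, 0.0, atol=1e-9)

    def test_small_box_pads_with_warning(self):
        with pytest.warns(UserWarning, match="padding"):
            bands = wavelet_subbands(np.ones((4, 4, 4)))
        assert bands["LLL"].shape == (4, 4, 4)


class TestExtractAll:
    def test_full_bank_851(self, hgg_subject):
        feats = extract_all(hgg_subject.modalities["FLAIR"], hgg_subject.mask)
        assert len(feats) == 851
        assert list(feats) == full_feature_names()

    def test_block_sizes(self, hgg_subject):
        feats = extract_all(hgg_subject.modalities["T1"], hgg_subject.mask)
        shape = [k for k in feats if "_shape_" in k]
        original = [k for k in feats if k.startswith("original_") and "_shape_" not in k]
        wavelet = [k for k in feats if k.startswith("wavelet-")]
        assert (len(shape), len(original), len(wavelet)) == (14, 93, 744)

    def test_shape_block_mask_only(self, hgg_subject):
        f1 = extract_all(hgg_subject.modalities["T1"], hgg_subject.mask)
        f2 = extract_all(hgg_subject.modalities["FLAIR"], hgg_subject.mask)
        for k in full_feature_names()[:14]:
            assert f1[k] == f2[k]

    def test_intensity_shift_leaves_discretized_features_unchanged(self, hgg_subject):
        vol = hgg_subject.modalities["T2"]
        shifted = VolumeImage(vol.data + 50.0, vol.spacing)
        f1 = extract_all(vol, hgg_subject.mask)
        f2 = extract_all(shifted, hgg_subject.mask)
        for family in ("glcm", "gldm", "glrlm", "glszm", "ngtdm"):
            for k in full_feature_names():
                if f"original_{family}_" in k:
                    assert f1[k] == pytest.approx(f2[k], rel=1e-9), k
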