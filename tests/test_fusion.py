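import numpy as np
import pytest

from edemagrade import fusion as fu
from edemagrade.fusion import (
    FUSION_PAIRS,
    DomainMaps,
    FusionConfig,
    dgr_decompose,
    fuse_low_lem,
    fuse_nonoverlap,
    fuse_overlap,
    gdie_enhance,
    lp_decompose,
    lp_reconstruct,
    lrd_fuse_slice,
    lrd_fuse_volume,
    max_local_difference,
)
from oracles import oracle_mld, oracle_windowed_abs_sum

rng = np.random.default_rng(123)


class TestMLD:
    def test_constant_image_is_zero(self):
        assert max_local_difference(np.full((9, 9), 3.7)).max() == 0.0

    def test_single_bright_pixel_peaks_nearby(self):
        img = np.zeros((5, 5))
        img[2, 2] = 10.0
        mld = max_local_difference(img)
        np.testing.assert_allclose(mld, oracle_mld(img))
        peak = np.unravel_index(np.argmax(mld), mld.shape)
        assert max(abs(peak[0] - 2), abs(peak[1] - 2)) <= 1

    def test_shift_invariance(self):
        img = rng.uniform(0, 255, (12, 12))
        np.testing.assert_allclose(
            max_local_difference(img), max_local_difference(img + 40.0), atol=1e-9
        )

    def test_matches_bruteforce(self):
        img = rng.uniform(0, 255, (7, 8))
        np.testing.assert_allclose(max_local_difference(img), oracle_mld(img), atol=1e-9)

    def test_rejects_non_2d(self):
        with pytest.raises(ValueError, match="2D"):
            max_local_difference(np.zeros((3, 3, 3)))


class TestGDIE:
    def test_constant_image_unchanged(self):
        img = np.full((16, 16), 5.0)
        np.testing.assert_array_equal(gdie_enhance(img, FusionConfig()), img)

    def test_equal_omegas_give_uniform_gain(self):
        img = rng.uniform(0, 255, (16, 16))
        cfg = FusionConfig(omega1=0.7, omega2=0.7)
        from scipy import ndimage

        detail = img - ndimage.uniform_filter(img, size=3, mode="nearest")
        np.testing.assert_allclose(gdie_enhance(img, cfg) - img, 0.7 * detail, atol=1e-9)

    def test_edges_lifted_more_than_flats(self):
        img = np.zeros((16, 16))
        img[:, 8:] = 200.0
        cfg = FusionConfig(omega1=1.5, omega2=0.3)
        lift = np.abs(gdie_enhance(img, cfg) - img)
        edge = lift[:, 6:10].mean()
        flat = lift[:, :4].mean()
        assert edge >= flat

    def test_monotone_in_omega1(self):
        img = np.zeros((16, 16))
        img[:, 8:] = 200.0
        l1 = np.abs(gdie_enhance(img, FusionConfig(omega1=1.5)) - img)
        l2 = np.abs(gdie_enhance(img, FusionConfig(omega1=2.5)) - img)
        assert (l2 - l1).min() >= -1e-9

    def test_invalid_omegas_rejected(self):
        with pytest.raises(ValueError, match="omega"):
            FusionConfig(omega1=-1.0)


class TestLaplacianPyramid:
    def test_analysis_synthesis_inversion(self):
        x = rng.uniform(0, 255, (64, 64))
        err = np.abs(lp_reconstruct(lp_decompose(x, 3)) - x).max()
        assert err <= 1e-6 * 255

    def test_level_shapes_follow_halving(self):
        pyr = lp_decompose(np.zeros((64, 64)), 3)
        assert pyr.shapes == [(64, 64), (32, 32), (16, 16), (8, 8)]

    def test_odd_dimensions_roundtrip(self):
        x = rng.uniform(0, 255, (37, 53))
        np.testing.assert_allclose(lp_reconstruct(lp_decompose(x, 3)), x, atol=1e-9)

    def test_constant_image_has_flat_pyramid(self):
        pyr = lp_decompose(np.full((32, 32), 9.0), 3)
        for h in pyr.highs:
            np.testing.assert_allclose(h, 0.0, atol=1e-9)
        np.testing.assert_allclose(pyr.low, 9.0, atol=1e-9)

    def test_zero_pyramid_reconstructs_zero(self):
        pyr = lp_decompose(np.zeros((16, 16)), 2)
        assert lp_reconstruct(pyr).max() == 0.0

    def test_low_band_expansion_preserves_mean_roughly(self):
        pyr = lp_decompose(np.zeros((64, 64)), 3)
        pyr.low = np.full((8, 8), 10.0)
        out = lp_reconstruct(pyr)
        assert abs(out.mean() - 10.0) < 0.5

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            lp_decompose(np.zeros((4, 4)), 3)


class TestDGR:
    def test_zero_band_b_means_no_overlap(self):
        l_a = rng.normal(size=(16, 16))
        dom = dgr_decompose(l_a, np.zeros((16, 16)))
        assert dom.decision_graph.sum() == 0
        np.testing.assert_array_equal(dom.nod_a, l_a)

    def test_identical_large_amplitude_fully_overlaps(self):
        l = np.full((8, 8), 5.0)
        l[::2] = -5.0
        dom = dgr_decompose(l, l)
        assert dom.decision_graph.all()
        np.testing.assert_array_equal(dom.nod_a, 0)

    def test_disjoint_supports_stay_nonoverlapping(self):
        l_a = np.zeros((16, 16))
        l_b = np.zeros((16, 16))
        l_a[:, :8] = rng.normal(0, 10, (16, 8))
        l_b[:, 8:] = rng.normal(0, 10, (16, 8))
        dom = dgr_decompose(l_a, l_b)
        assert dom.decision_graph.sum() == 0
        np.testing.assert_array_equal(dom.nod_a, l_a)
        np.testing.assert_array_equal(dom.nod_b, l_b)

    def test_additive_split_exact(self):
        l_a = rng.normal(size=(16, 16))
        l_b = rng.normal(size=(16, 16))
        dom = dgr_decompose(l_a, l_b)
        np.testing.assert_array_equal(dom.od_a + dom.nod_a, l_a)
        np.testing.assert_array_equal(dom.od_b + dom.nod_b, l_b)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            dgr_decompose(np.zeros((4, 4)), np.zeros((5, 5)))


class TestFusionRules:
    def test_lem_identical_inputs_return_a(self):
        g = rng.normal(size=(8, 8))
        np.testing.assert_array_equal(fuse_low_lem(g, g.copy()), g)

    def test_lem_dominant_source_wins_everywhere(self):
        g_a = np.full((8, 8), 10.0)
        g_b = np.full((8, 8), 1.0)
        np.testing.assert_array_equal(fuse_low_lem(g_a, g_b), g_a)

    def test_lem_matches_windowed_argmax_oracle(self):
        g_a = rng.normal(size=(8, 8))
        g_b = rng.normal(size=(8, 8))
        fused = fuse_low_lem(g_a, g_b)
        e_a = oracle_windowed_abs_sum(g_a)
        e_b = oracle_windowed_abs_sum(g_b)
        expected = np.where(e_a >= e_b, g_a, g_b)
        np.testing.assert_allclose(fused, expected, atol=1e-9)

    def test_overlap_dominant_mld_selects_a(self):
        o = rng.normal(size=(8, 8))
        dom = DomainMaps(o, o * 0.5, o * 0, o * 0, np.ones((8, 8), dtype=np.uint8))
        fused = fuse_overlap(dom, np.full((8, 8), 100.0), np.full((8, 8), 0.1))
        np.testing.assert_array_equal(fused, dom.od_a)

    def test_overlap_equal_domains_insensitive_to_decision(self):
        o = rng.normal(size=(8, 8))
        dom = DomainMaps(o, o.copy(), o * 0, o * 0, np.ones((8, 8), dtype=np.uint8))
        fused = fuse_overlap(dom, rng.uniform(0, 1, (8, 8)), rng.uniform(0, 1, (8, 8)))
        np.testing.assert_array_equal(fused, o)

    def test_overlap_matches_per_pixel_oracle(self):
        od_a = rng.normal(size=(8, 8))
        od_b = rng.normal(size=(8, 8))
        mld_a = rng.uniform(0, 5, (8, 8))
        mld_b = rng.uniform(0, 5, (8, 8))
        dom = DomainMaps(od_a, od_b, od_a * 0, od_b * 0, np.ones((8, 8), dtype=np.uint8))
        fused = fuse_overlap(dom, mld_a, mld_b)
        ldm_a = mld_a * oracle_windowed_abs_sum(od_a)
        ldm_b = mld_b * oracle_windowed_abs_sum(od_b)
        expected = np.where(ldm_a >= ldm_b, od_a, od_b)
        np.testing.assert_allclose(fused, expected, atol=1e-9)

    def test_overlap_rejects_negative_mld(self):
        dom = DomainMaps(*(np.zeros((4, 4)),) * 4, np.zeros((4, 4), dtype=np.uint8))
        with pytest.raises(ValueError, match="nonnegative"):
            fuse_overlap(dom, np.full((4, 4), -1.0), np.zeros((4, 4)))

    def test_nonoverlap_is_elementwise_sum(self):
        n_a = rng.normal(size=(8, 8))
        n_b = rng.normal(size=(8, 8))
        dom = DomainMaps(n_a * 0, n_b * 0, n_a, n_b, np.zeros((8, 8), dtype=np.uint8))
        np.testing.assert_array_equal(fuse_nonoverlap(dom), n_a + n_b)
        dom2 = DomainMaps(n_a * 0, n_a * 0, n_a, -n_a, np.zeros((8, 8), dtype=np.uint8))
        np.testing.assert_array_equal(fuse_nonoverlap(dom2), 0 * n_a)


class TestLrdSlice:
    def test_constant_pair_returns_constant(self):
        c = np.full((32, 32), 42.0)
        np.testing.assert_allclose(lrd_fuse_slice(c, c), c, atol=1e-6)

    def test_output_shape_preserved(self):
        a = rng.uniform(0, 255, (40, 56))
        b = rng.uniform(0, 255, (40, 56))
        assert lrd_fuse_slice(a, b).shape == (40, 56)

    def test_halfplane_structure_is_inherited(self):
        """Each half of the fused slice should track the input that
        carries structure there."""
        a = 100.0 + rng.normal(0, 0.5, (64, 64))
        b = 100.0 + rng.normal(0, 0.5, (64, 64))
        pattern = 20 * np.sin(np.linspace(0, 20, 32))[None, :] * rng.uniform(0.5, 1, (64, 32))
        a[:, :32] += pattern
        b[:, 32:] += pattern[::-1]
        fused = lrd_fuse_slice(a, b)
        left = slice(None), slice(0, 32)
        right = slice(None), slice(32, None)
        corr = lambda x, y: np.corrcoef(x.ravel(), y.ravel())[0, 1]
        assert corr(fused[left], a[left]) > corr(fused[left], b[left])
        assert corr(fused[right], b[right]) > corr(fused[right], a[right])


class TestLrdVolume:
    def test_self_fusion_is_stable(self, hgg_subject):
        v = hgg_subject.modalities["T1Gd"]
        fused = lrd_fuse_volume(v, v)
        rescaled = fu._rescale_255(v.data)
        assert np.abs(fused.data - rescaled).max() <= 0.01 * 255

    def test_spacing_metadata_carried(self, hgg_subject):
        v = hgg_subject.modalities["T1"]
        w = hgg_subject.modalities["T2"]
        assert lrd_fuse_volume(v, w).spacing == v.spacing

    def test_all_six_pairs_finite(self, hgg_subject):
        for a, b in FUSION_PAIRS:
            fused = lrd_fuse_volume(hgg_subject.modalities[a], hgg_subject.modalities[b])
            assert np.isfinite(fused.data).all()

    def test_grid_mismatch_rejected(self, hgg_subject):
        from edemagrade.types import VolumeImage

        other = VolumeImage(np.zeros((16, 16, 16)))
        with pytest.raises(ValueError, match="co-registered"):
            lrd_fuse_volume(hgg_subject.modalities["T1"], other)

    def test_deterministic(self, hgg_subject):
        a = hgg_subject.modalities["T1Gd"]
        b = hgg_subject.modalities["FLAIR"]
        f1 = lrd_fuse_volume(a, b)
        f2 = lrd_fuse_volume(a, b)
        np.testing.assert_array_equal(f1.data, f2.data)
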