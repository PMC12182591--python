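"""Reference statistics, atlas search region and the threshold rule."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from nmseg.image import ImageVolume, RoiMask
from nmseg.phantom import PhantomSpec, default_affine, make_atlas, make_phantom
from nmseg.segmentation import (ReferenceStats, build_search_roi, mtc_map,
                                reference_stats, segment_snc)
from nmseg.spatial import AffineTransform, TransformChain


def _vol(data, space="gre"):
    return ImageVolume(np.asarray(data, dtype=float),
                       default_affine(grid_shape=np.shape(data)), space)


def _mask(data, space="gre"):
    return RoiMask(np.asarray(data, dtype=bool),
                   default_affine(grid_shape=np.shape(data)), space)


def brute_force_segment(image, search_roi, mu_ref, sigma_ref, k):
    """Independent triple-loop oracle for the threshold rule."""
    nx, ny, nz = image.shape
    out = np.zeros((nx, ny, nz), dtype=bool)
    thr = mu_ref + k * sigma_ref
    for i in range(nx):
        for j in range(ny):
            for kk in range(nz):
                if search_roi[i, j, kk] and image[i, j, kk] > thr:
                    out[i, j, kk] = True
    return out


class TestReferenceStats:
    def test_constant_region(self):
        img = _vol(np.full((8, 8, 4), 100.0))
        m = np.zeros((8, 8, 4), dtype=bool)
        m[2:5, 2:5, 1:3] = True
        ref = reference_stats(img, _mask(m))
        assert (ref.mu_ref, ref.sigma_ref) == (100.0, 0.0)

    def test_sd_convention_population_vs_sample(self):
        data = np.zeros((8, 8, 4))
        data[0, 0, 0], data[0, 1, 0], data[0, 2, 0] = 90.0, 100.0, 110.0
        m = np.zeros((8, 8, 4), dtype=bool)
        m[0, :3, 0] = True
        ref_pop = reference_stats(_vol(data), _mask(m))
        assert ref_pop.mu_ref == pytest.approx(100.0)
        assert ref_pop.sigma_ref == pytest.approx(8.1650, abs=1e-4)
        ref_sam = reference_stats(_vol(data), _mask(m), ddof=1)
        assert ref_sam.sigma_ref == pytest.approx(10.0)

    def test_empty_mask_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            reference_stats(_vol(np.zeros((4, 4, 2))), _mask(np.zeros((4, 4, 2))))

    def test_noise_free_phantom_reference_is_exact(self):
        measurements, _, truth = make_phantom(PhantomSpec(noise_sigma=0.0))
        ref = reference_stats(measurements[0], truth["cp_true_mask"])
        assert (ref.mu_ref, ref.sigma_ref) == (100.0, 0.0)


class TestSearchRoi:
    def test_empty_atlas_rejected(self):
        atlas = _vol(np.zeros((8, 8, 4)), space="template")
        target = _vol(np.zeros((8, 8, 4)))
        chain = TransformChain([AffineTransform.identity("template", "gre")])
        with pytest.raises(ValueError, match="empty"):
            build_search_roi(atlas, chain, target)

    def test_single_voxel_dilates_to_city_block_cross(self):
        prob = np.zeros((9, 9, 9))
        prob[4, 4, 4] = 0.10
        atlas = ImageVolume(prob, np.eye(4), "template")
        target = ImageVolume(np.zeros((9, 9, 9)), np.eye(4), "gre")
        chain = TransformChain([AffineTransform.identity("template", "gre")])
        roi = build_search_roi(atlas, chain, target, dilation_radius_voxels=1)
        assert roi.n_voxels == 7
        expected = {(4, 4, 4), (3, 4, 4), (5, 4, 4), (4, 3, 4), (4, 5, 4),
                    (4, 4, 3), (4, 4, 5)}
        assert set(map(tuple, np.argwhere(roi.data))) == expected

    def test_probability_threshold_is_strict(self):
        prob = np.zeros((8, 8, 4))
        prob[2, 2, 2], prob[5, 5, 2] = 0.04, 0.06
        atlas = ImageVolume(prob, np.eye(4), "template")
        target = ImageVolume(np.zeros((8, 8, 4)), np.eye(4), "gre")
        chain = TransformChain([AffineTransform.identity("template", "gre")])
        roi = build_search_roi(atlas, chain, target, dilation_radius_voxels=0)
        assert roi.data[5, 5, 2] and not roi.data[2, 2, 2]
        prob[2, 2, 2] = 0.05  # exactly at the threshold: excluded
        roi = build_search_roi(ImageVolume(prob, np.eye(4), "template"), chain,
                               target, dilation_radius_voxels=0)
        assert not roi.data[2, 2, 2]

    def test_out_of_range_atlas_rejected(self):
        atlas = _vol(np.full((4, 4, 2), 1.5), space="template")
        chain = TransformChain([AffineTransform.identity("template", "gre")])
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            build_search_roi(atlas, chain, _vol(np.zeros((4, 4, 2))))


class TestSegmentSnc:
    def test_all_below_threshold_gives_empty_mask(self):
        img = _vol(np.full((8, 8, 4), 50.0))
        roi = np.ones((8, 8, 4), dtype=bool)
        res = segment_snc(img, _mask(roi), ReferenceStats(100.0, 10.0, 50))
        assert res.voxel_count == 0 and res.volume_mm3 == 0.0

    def test_volume_is_count_times_voxel_volume(self):
        data = np.full((32, 32, 8), 100.0)
        flat = np.zeros(data.size, dtype=bool)
        flat[:700] = True
        roi = flat.reshape(data.shape)
        data[roi] = 200.0
        res = segment_snc(_vol(data), _mask(np.ones_like(roi)),
                          ReferenceStats(100.0, 10.0, 50))
        assert res.voxel_count == 700
        assert res.volume_mm3 == pytest.approx(350.0)  # 0.5*0.5*2 mm voxels

    def test_threshold_is_strict(self):
        data = np.full((4, 4, 2), 0.0)
        data[0, 0, 0], data[0, 1, 0] = 128.0, 128.0001
        res = segment_snc(_vol(data), _mask(np.ones((4, 4, 2))),
                          ReferenceStats(100.0, 10.0, 9), k=2.8)
        assert res.threshold == pytest.approx(128.0)
        assert not res.snc_mask.data[0, 0, 0]
        assert res.snc_mask.data[0, 1, 0]

    def test_zero_sigma_is_legal(self):
        data = np.full((4, 4, 2), 100.0)
        data[1, 1, 1] = 100.5
        res = segment_snc(_vol(data), _mask(np.ones((4, 4, 2))),
                          ReferenceStats(100.0, 0.0, 9))
        assert res.voxel_count == 1

    def test_nan_under_roi_rejected(self):
        data = np.full((4, 4, 2), 100.0)
        data[1, 1, 1] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            segment_snc(_vol(data), _mask(np.ones((4, 4, 2))),
                        ReferenceStats(100.0, 1.0, 9))

    def test_matches_brute_force_oracle(self):
        r = np.random.default_rng(0)
        for _ in range(5):
            img = r.normal(100, 20, (16, 16, 6))
            roi = r.random((16, 16, 6)) > 0.5
            mu, sd, k = 100.0, 10.0, 2.0
            res = segment_snc(_vol(img), _mask(roi), ReferenceStats(mu, sd, 10), k=k)
            oracle = brute_force_segment(img, roi, mu, sd, k)
            assert np.array_equal(res.snc_mask.data, oracle)

    def test_voxel_count_monotone_in_k(self):
        r = np.random.default_rng(1)
        img = r.normal(110, 15, (16, 16, 6))
        roi = r.random((16, 16, 6)) > 0.3
        counts = [segment_snc(_vol(img), _mask(roi),
                              ReferenceStats(100.0, 5.0, 10), k=k).voxel_count
                  for k in (1, 2, 2.8, 4, 6)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    @given(st.floats(0.1, 10.0))
    def test_scaling_equivariance(self, c):
        r = np.random.default_rng(7)
        img = r.normal(100, 10, (12, 12, 4))
        roi = r.random((12, 12, 4)) > 0.4
        cp = ~roi
        ref1 = reference_stats(_vol(img), _mask(cp))
        res1 = segment_snc(_vol(img), _mask(roi), ref1)
        ref2 = reference_stats(_vol(img * c), _mask(cp))
        res2 = segment_snc(_vol(img * c), _mask(roi), ref2)
        assert ref2.mu_ref == pytest.approx(c * ref1.mu_ref)
        assert ref2.sigma_ref == pytest.approx(c * ref1.sigma_ref)
        assert res2.threshold == pytest.approx(c * res1.threshold)
        assert np.array_equal(res1.snc_mask.data, res2.snc_mask.data)

    def test_exact_recovery_on_noise_free_phantom(self):
        spec = PhantomSpec(noise_sigma=0.0, n_measurements=1)
        measurements, _, truth = make_phantom(spec)
        snc = truth["snc_true_mask"]
        atlas = make_atlas(RoiMask(snc.data, snc.affine, "template"))
        chain = TransformChain([AffineTransform.identity("template", "gre")])
        roi = build_search_roi(atlas, chain, measurements[0])
        ref = reference_stats(measurements[0], truth["cp_true_mask"])
        res = segment_snc(measurements[0], roi, ref)
        assert np.array_equal(res.snc_mask.data, snc.data)
        assert res.volume_mm3 == snc.volume_mm3


class TestMtcMap:
    def test_definition(self):
        img = _vol(np.array([[[100.0, 130.0]]]))
        out = mtc_map(img, ReferenceStats(100.0, 1.0, 10))
        np.testing.assert_allclose(out.data, [[[0.0, 0.3]]])

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            mtc_map(_vol(np.ones((2, 2, 2))), ReferenceStats(0.0, 1.0, 10))

    def test_phantom_contrast_recovered(self):
        measurements, _, truth = make_phantom(PhantomSpec(noise_sigma=0.0))
        ref = reference_stats(measurements[0], truth["cp_true_mask"])
        out = mtc_map(measurements[0], ref)
        assert np.allclose(out.data[truth["snc_true_mask"].data], 0.3)
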