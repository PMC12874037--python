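"""Segmentation: band selection, projection, thresholding, binarization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import octvessel as ov
from octvessel.recon import OCTVolume
from octvessel.segment import NoVesselContrastError


def volume_from(arr, spacing=(1.0, 1.0, 1.0)):
    return OCTVolume(intensity=np.asarray(arr, float), voxel_spacing=spacing)


class TestSelectDepthBand:
    def test_band_slice_count_rounds_to_nearest(self):
        dz = 900 / 1024  # ~0.879 um
        vol = volume_from(np.ones((4, 4, 400)), (6.5, 6.5, dz))
        slab = ov.select_depth_band(vol, ov.DepthBand(z_extent_um=150.0, mode="fixed"))
        assert slab.intensity.shape[2] == 171  # round(150 / 0.879)

    def test_full_volume_band_is_identity(self):
        vol = volume_from(np.random.default_rng(0).random((4, 4, 20)))
        slab = ov.select_depth_band(vol, ov.DepthBand(z_extent_um=20.0, mode="fixed"))
        assert np.array_equal(slab.intensity, vol.intensity)

    def test_band_outside_volume_raises(self):
        vol = volume_from(np.ones((4, 4, 20)))
        with pytest.raises(ValueError, match="outside"):
            ov.select_depth_band(vol, ov.DepthBand(z_extent_um=10, z_start_um=15, mode="fixed"))
        with pytest.raises(ValueError, match="exceeds"):
            ov.select_depth_band(vol, ov.DepthBand(z_extent_um=50, mode="fixed"))

    def test_auto_mode_finds_dark_band(self):
        data = np.ones((6, 6, 60))
        data[:, :, 30:40] = 0.1  # the dark vascular slab
        slab = ov.select_depth_band(volume_from(data), ov.DepthBand(z_extent_um=10, mode="auto"))
        z0, z1 = slab.meta["band_indices"]
        assert (z0, z1) == (30, 40)


class TestMinIntensityProjection:
    def test_column_minimum_and_normalization(self):
        data = np.ones((5, 5, 8))
        data[2, 3, 4] = 0.1
        proj = ov.min_intensity_projection(volume_from(data))
        assert proj.values.min() == 0.0 and proj.values.max() == 1.0
        assert proj.values[2, 3] == 0.0  # the dark column
        assert proj.norm_min == pytest.approx(0.1)

    def test_constant_slab_flagged(self):
        with pytest.raises(ValueError, match="dynamic range"):
            ov.min_intensity_projection(volume_from(np.ones((4, 4, 4))))

    def test_invariant_to_z_permutation(self):
        rng = np.random.default_rng(1)
        data = rng.random((6, 6, 12))
        proj = ov.min_intensity_projection(volume_from(data))
        shuffled = data[:, :, rng.permutation(12)]
        proj2 = ov.min_intensity_projection(volume_from(shuffled))
        assert np.array_equal(proj.values, proj2.values)

    def test_cylinder_footprint_is_dark(self, cylinder_mask):
        vol = ov.render_volume(cylinder_mask, n_averages=6, seed=0)
        proj = ov.min_intensity_projection(vol)
        footprint = cylinder_mask.mask.any(axis=2)
        assert proj.values[footprint].mean() < proj.values[~footprint].mean()


class TestEstimateThreshold:
    def test_symmetric_two_point_classes(self):
        x = np.r_[np.full(500, 0.1), np.full(500, 0.9)]
        est = ov.estimate_threshold(x, domain="linear")
        assert est.threshold == pytest.approx(0.5, abs=1e-6)

    def test_imbalanced_two_point_classes(self):
        x = np.r_[np.full(900, 0.8), np.full(100, 0.2)]
        est = ov.estimate_threshold(x, domain="linear")
        assert est.threshold == pytest.approx(0.5, abs=1e-6)

    def test_overlapping_gaussians_recovered(self):
        rng = np.random.default_rng(3)
        labels = np.r_[np.zeros(5000, bool), np.ones(5000, bool)]
        x = np.r_[rng.normal(0.2, 0.1, 5000), rng.normal(0.8, 0.1, 5000)]
        est = ov.estimate_threshold(x, domain="linear")
        assert 0.4 <= est.threshold <= 0.6
        agreement = np.mean((x >= est.threshold) == labels)
        assert agreement >= 0.99

    def test_speckle_classes_in_log_domain(self):
        rng = np.random.default_rng(4)
        x = np.r_[rng.gamma(6, 0.1 / 6, 3000), rng.gamma(6, 1.0 / 6, 57000)]
        est = ov.estimate_threshold(x)  # defaults: log domain, EM split
        assert 0.2 < est.threshold < 0.45
        assert est.lumen_median == pytest.approx(0.1, rel=0.2)
        assert est.hydrogel_median == pytest.approx(0.945, rel=0.1)

    def test_em_split_agrees_with_reference_mixture_fit(self):
        # independent mixture-model route: sklearn's EM on the same
        # log-intensities should classify voxels the same way
        from sklearn.mixture import GaussianMixture

        rng = np.random.default_rng(21)
        x = np.r_[rng.gamma(6, 0.1 / 6, 2000), rng.gamma(6, 1.0 / 6, 38000)]
        est = ov.estimate_threshold(x)
        w = np.log(x)
        gm = GaussianMixture(2, covariance_type="tied", random_state=0, n_init=3)
        labels = gm.fit_predict(w[::4, None])
        dark = labels == np.argmin(gm.means_.ravel())
        ours = x[::4] < est.threshold
        assert np.mean(dark == ours) >= 0.99

    def test_contrast_free_input_rejected(self):
        rng = np.random.default_rng(5)
        with pytest.raises(NoVesselContrastError, match="contrast"):
            ov.estimate_threshold(rng.gamma(6, 1 / 6, 50000))

    def test_constant_input_rejected(self):
        with pytest.raises(NoVesselContrastError):
            ov.estimate_threshold(np.full(1000, 2.0))

    @settings(max_examples=20, deadline=None)
    @given(
        scale=st.floats(0.1, 10.0),
        shift=st.floats(-5.0, 5.0),
    )
    def test_linear_estimator_is_affine_equivariant(self, scale, shift):
        rng = np.random.default_rng(6)
        x = np.r_[rng.normal(0.2, 0.05, 2000), rng.normal(0.9, 0.05, 6000)]
        base = ov.estimate_threshold(x, domain="linear").threshold
        mapped = ov.estimate_threshold(scale * x + shift, domain="linear").threshold
        assert mapped == pytest.approx(scale * base + shift, rel=1e-6, abs=1e-8)

    @settings(max_examples=10, deadline=None)
    @given(scale=st.floats(0.05, 20.0))
    def test_log_estimator_is_scale_equivariant(self, scale):
        rng = np.random.default_rng(7)
        x = np.r_[rng.gamma(6, 0.1 / 6, 2000), rng.gamma(6, 1.0 / 6, 18000)]
        base = ov.estimate_threshold(x).threshold
        mapped = ov.estimate_threshold(scale * x).threshold
        assert mapped == pytest.approx(scale * base, rel=1e-3)


class TestBinarizeAndClean:
    def test_all_above_threshold_empty(self):
        mask = ov.binarize(np.ones((4, 4)) * 2.0, 1.0, voxel_spacing=(1, 1))
        assert not mask.mask.any()

    def test_threshold_at_minimum_strict(self):
        data = np.array([[1.0, 2.0], [3.0, 4.0]])
        mask = ov.binarize(data, 1.0, voxel_spacing=(1, 1))
        assert not mask.mask.any()  # strict inequality: ties to hydrogel

    def test_small_speck_removed_tube_kept(self):
        m = np.zeros((20, 20, 20), bool)
        m[2:4, 2:4, 2:4] = True  # 8-voxel speck
        m[10:12, 5:16, 10:15] = True  # 110-voxel slab
        mask = ov.VesselMask(m, (1, 1, 1))
        cleaned = ov.clean_mask(mask, min_component_voxels=27)
        assert not cleaned.mask[2:4, 2:4, 2:4].any()
        assert cleaned.mask[10:12, 5:16, 10:15].all()

    def test_zero_min_component_is_identity(self):
        rng = np.random.default_rng(8)
        m = rng.random((10, 10, 10)) < 0.2
        mask = ov.VesselMask(m, (1, 1, 1))
        assert np.array_equal(ov.clean_mask(mask, 0).mask, m)

    def test_cleanup_does_not_hurt_dice(self, cylinder_mask):
        vol = ov.render_volume(cylinder_mask, lumen_mean=0.1, n_averages=6, seed=11)
        est = ov.estimate_threshold(vol.intensity)
        raw = ov.binarize(vol, est.threshold)
        cleaned = ov.clean_mask(raw)
        d_raw = ov.dice_coefficient(raw, cylinder_mask)
        d_clean = ov.dice_coefficient(cleaned, cylinder_mask)
        assert d_clean >= d_raw

    def test_dice_degrades_with_contrast(self, cylinder_mask):
        dices = []
        for ratio in (0.1, 0.2, 0.25):
            vol = ov.render_volume(cylinder_mask, lumen_mean=ratio, n_averages=6, seed=12)
            est = ov.estimate_threshold(vol.intensity)
            mask = ov.clean_mask(ov.binarize(vol, est.threshold))
            dices.append(ov.dice_coefficient(mask, cylinder_mask))
        assert dices[0] >= dices[1] >= dices[2] - 0.01
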