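import numpy as np
import pytest

import noduleseg as ns
from noduleseg.config import GacParams, SegmentationConfig
from noduleseg.feature_maps import SpeedMap
from noduleseg.gac import evolve, initialize_front
from noduleseg.volume_io import BinaryMask, ImageVolume


def _grid(shape=(48, 48, 48), spacing=(1, 1, 1)):
    return ImageVolume(np.zeros(shape), spacing, (0, 0, 0))


def _speed(data, spacing=(1, 1, 1)):
    return SpeedMap(np.asarray(data, float), spacing, (0, 0, 0))


def _equiv_radius(voxel_count, voxel_volume=1.0):
    return (3.0 * voxel_count * voxel_volume / (4.0 * np.pi)) ** (1.0 / 3.0)


class TestInitializeFront:
    def test_zero_level_is_seed_sphere(self):
        st = initialize_front([ns.SeedPoint((24, 24, 24))], _grid(), 2.0)
        inside = st.phi < 0
        zz, yy, xx = np.indices(inside.shape)
        r = np.sqrt((zz - 24.0) ** 2 + (yy - 24.0) ** 2 + (xx - 24.0) ** 2)
        assert inside.sum() > 0
        assert np.all(r[inside] < 2.0)  # phi = r - 2 exactly
        # every analytic-surface-adjacent voxel is within one voxel of phi's zero level
        shell = (r >= 1.0) & (r <= 3.0)
        assert np.all(np.abs(st.phi[shell]) <= 1.0 + 1e-9)

    def test_phi_at_seed_is_minus_radius(self):
        st = initialize_front([ns.SeedPoint((24, 24, 24))], _grid(), 2.0)
        assert st.phi[24, 24, 24] == pytest.approx(-2.0, abs=np.sqrt(3.0))

    def test_two_close_seeds_form_one_component(self):
        from scipy import ndimage

        st = initialize_front(
            [ns.SeedPoint((24, 24, 23.5)), ns.SeedPoint((24, 24, 24.5))], _grid(), 2.0
        )
        _, n = ndimage.label(st.phi < 0)
        assert n == 1

    def test_seed_outside_grid_errors(self):
        with pytest.raises(ValueError):
            initialize_front([ns.SeedPoint((100, 100, 100))], _grid(), 2.0)


class TestEvolve:
    def test_zero_speed_freezes_front_with_warning(self):
        st = initialize_front([ns.SeedPoint((24, 24, 24))], _grid(), 3.0)
        init_mask = st.mask.copy()
        with pytest.warns(UserWarning):
            out = evolve(st, _speed(np.zeros((48, 48, 48))), GacParams())
        assert np.array_equal(out.data, init_mask)

    def test_constant_speed_matches_analytic_expansion(self):
        grid = _grid((64, 64, 64))
        st = initialize_front([ns.SeedPoint((32, 32, 32))], grid, 5.0)
        params = GacParams(
            curvature_weight=0.0, advection_weight=0.0,
            max_iterations=100, rms_tolerance=1e-12,
        )
        mask, info = evolve(st, _speed(np.ones((64, 64, 64))), params, return_info=True)
        expected = 5.0 + info["iterations"] * info["dt"]
        measured = _equiv_radius(mask.voxel_count)
        assert abs(measured - expected) <= 1.0

    def test_ideal_map_recovered_without_advection(self):
        zz, yy, xx = np.indices((48, 48, 48))
        r = np.sqrt((zz - 24) ** 2 + (yy - 24) ** 2 + (xx - 24) ** 2)
        truth = BinaryMask(r <= 10, (1, 1, 1), (0, 0, 0))
        st = initialize_front([ns.SeedPoint((24, 24, 24))], _grid(), 2.0)
        mask = evolve(st, _speed(np.where(truth.data, 1.0, 0.0)),
                      GacParams(advection_weight=0.0))
        assert ns.dice_pct(mask, truth) >= 95.0

    def test_ideal_map_default_params_bounded_overshoot(self):
        # with advection on, the front settles within about one voxel past
        # a hard speed cliff (the discrete width of the advection force)
        zz, yy, xx = np.indices((48, 48, 48))
        r = np.sqrt((zz - 24) ** 2 + (yy - 24) ** 2 + (xx - 24) ** 2)
        truth = BinaryMask(r <= 10, (1, 1, 1), (0, 0, 0))
        st = initialize_front([ns.SeedPoint((24, 24, 24))], _grid(), 2.0)
        mask = evolve(st, _speed(np.where(truth.data, 1.0, 0.0)), GacParams())
        assert ns.dice_pct(mask, truth) >= 85.0
        assert _equiv_radius(mask.voxel_count) <= 10.0 + 1.2

    def test_matches_itk_geodesic_active_contour(self):
        # independent cross-check against SimpleITK's GAC filter in the
        # propagation+curvature regime, where the parameterizations coincide
        import SimpleITK as sitk

        zz, yy, xx = np.indices((48, 48, 48))
        r = np.sqrt((zz - 24) ** 2 + (yy - 24) ** 2 + (xx - 24) ** 2)
        F = np.where(r <= 10, 1.0, 0.0)
        st = initialize_front([ns.SeedPoint((24, 24, 24))], _grid(), 2.0)
        ours = evolve(st, _speed(F), GacParams(advection_weight=0.0))

        seed_img = sitk.GetImageFromArray((r <= 2).astype(np.uint8))
        init_ls = sitk.SignedMaurerDistanceMap(
            seed_img, insideIsPositive=False, useImageSpacing=True
        )
        gac = sitk.GeodesicActiveContourLevelSetImageFilter()
        gac.SetPropagationScaling(1.0)
        gac.SetCurvatureScaling(0.3)
        gac.SetAdvectionScaling(0.0)
        gac.SetMaximumRMSError(1e-4)
        gac.SetNumberOfIterations(800)
        out = gac.Execute(
            sitk.Cast(init_ls, sitk.sitkFloat32),
            sitk.Cast(sitk.GetImageFromArray(F), sitk.sitkFloat32),
        )
        theirs = BinaryMask(sitk.GetArrayFromImage(out) < 0, (1, 1, 1), (0, 0, 0))
        assert ns.dice_pct(ours, theirs) >= 99.0

    def test_scaling_speed_down_never_enlarges_mask(self):
        zz, yy, xx = np.indices((40, 40, 40))
        r = np.sqrt((zz - 20) ** 2 + (yy - 20) ** 2 + (xx - 20) ** 2)
        F = np.clip(1.2 - r / 15.0, 0.0, 1.0)
        params = GacParams(
            curvature_weight=0.0, advection_weight=0.0,
            max_iterations=60, rms_tolerance=1e-12, dt=0.15,
        )
        grid = _grid((40, 40, 40))
        masks = {}
        for c in (1.0, 0.5):
            st = initialize_front([ns.SeedPoint((20, 20, 20))], grid, 2.0)
            masks[c] = evolve(st, _speed(c * F), params)
        assert masks[0.5].voxel_count <= masks[1.0].voxel_count
        assert not (masks[0.5].data & ~masks[1.0].data).any()

    def test_grid_mismatch_errors(self):
        st = initialize_front([ns.SeedPoint((24, 24, 24))], _grid(), 2.0)
        with pytest.raises(ValueError):
            evolve(st, _speed(np.ones((10, 10, 10))), GacParams())


class TestSegmentNodule:
    def test_deterministic_for_fixed_inputs(self, solid_truth, solid_segmentation):
        mask1, _ = solid_segmentation
        seed = ns.centroid_of_mask(solid_truth.nodule_mask)
        mask2 = ns.segment_nodule(solid_truth.volume, [seed], "solid")
        assert np.array_equal(mask1.data, mask2.data)

    def test_output_on_parent_grid_single_component(self, solid_truth, solid_segmentation):
        from scipy import ndimage

        mask, _ = solid_segmentation
        assert mask.grid_matches(solid_truth.volume)
        _, n = ndimage.label(mask.data)
        assert n == 1

    def test_seed_outside_volume_errors(self, solid_truth):
        with pytest.raises(ValueError):
            ns.segment_nodule(
                solid_truth.volume, [ns.SeedPoint((-50.0, 0.0, 0.0))], "solid"
            )

    def test_unknown_texture_errors(self, solid_truth):
        seed = ns.centroid_of_mask(solid_truth.nodule_mask)
        with pytest.raises(ValueError):
            ns.segment_nodule(solid_truth.volume, [seed], "weird")

    def test_nonsolid_texture_uses_shifted_sigmoid(self):
        cfg = SegmentationConfig()
        assert cfg.beta_for("solid") == -200.0
        assert cfg.beta_for("ground_glass") == -500.0
        assert cfg.beta_for("nonsolid") == -500.0
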