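"""Regional spread functions, transfer systems and the PVC solve."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from petgtm import (
    ActivityVolume,
    PVCConfig,
    RegionPVC,
    TransferSystem,
    apply_pvc,
    build_system_gtm,
    build_system_sgtm,
    compute_rsf_image_space,
    compute_rsf_sinogram_space,
    simulate_acquisition,
    solve_pvc,
)

FWHM = (7.23, 7.14, 6.65)
VOX = (2.0, 2.0, 3.15)


def _half_space_masks(shape=(32, 32, 8)):
    m1 = np.zeros(shape)
    m1[: shape[0] // 2] = 1.0
    return np.stack([m1, 1.0 - m1]), ["left", "right"]


class TestImageSpaceRSF:
    def test_all_fov_mask_gives_unit_rsf_everywhere(self):
        masks = np.ones((1, 16, 16, 8))
        rsfs = compute_rsf_image_space(masks, ["fov"], FWHM, VOX)
        np.testing.assert_allclose(rsfs.rsfs[0], 1.0, atol=1e-12)

    def test_half_space_masks_give_complementary_sigmoids(self):
        masks, names = _half_space_masks()
        rsfs = compute_rsf_image_space(masks, names, FWHM, VOX)
        total = rsfs.rsfs.sum(axis=0)
        np.testing.assert_allclose(total, 1.0, atol=1e-9)
        profile = rsfs.rsfs[0][:, 16, 4]
        assert np.all(np.diff(profile) <= 1e-12)  # monotone roll-off
        assert profile[0] > 0.99 and profile[-1] < 0.01

    def test_sphere_rsf_center_matches_dense_convolution_oracle(self):
        # direct spatial-domain convolution with an explicitly built
        # 3D Gaussian kernel, independent of scipy's separable filter
        shape = (24, 24, 16)
        masks = np.zeros((2,) + shape)
        ax = [(np.arange(n) + 0.5) * v for n, v in zip(shape, VOX)]
        X, Y, Z = np.meshgrid(*ax, indexing="ij")
        c = [n * v / 2 for n, v in zip(shape, VOX)]
        sphere = ((X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2) <= 5.0**2
        masks[0] = sphere
        masks[1] = 1.0 - masks[0]
        rsfs = compute_rsf_image_space(masks, ["sphere", "rest"], (7.0, 7.0, 7.0), VOX)

        sig = 7.0 / (2 * np.sqrt(2 * np.log(2)))
        r = 4
        kax = [np.arange(-r, r + 1) * v for v in VOX]
        KX, KY, KZ = np.meshgrid(*kax, indexing="ij")
        kern = np.exp(-(KX**2 + KY**2 + KZ**2) / (2 * sig**2))
        kern /= kern.sum()
        i, j, k = 12, 12, 8
        patch = masks[0][i - r : i + r + 1, j - r : j + r + 1, k - r : k + r + 1]
        oracle = float((patch * kern).sum())
        assert rsfs.rsfs[0][i, j, k] == pytest.approx(oracle, rel=0.01)

    def test_incomplete_partition_is_rejected(self):
        masks = np.zeros((1, 8, 8, 4))
        masks[0, :4] = 1.0
        with pytest.raises(ValueError, match="partition of unity"):
            compute_rsf_image_space(masks, ["half"], FWHM, VOX)


class TestSinogramSpaceRSF:
    def test_all_fov_mask_reconstructs_to_unity(self, calibrated_blur):
        masks = np.ones((1, 64, 64, 8))
        rsfs = compute_rsf_sinogram_space(masks, ["fov"], calibrated_blur, VOX)
        assert np.abs(rsfs.rsfs[0] - 1.0).max() < 0.005

    def test_complement_masks_sum_by_linearity(self, calibrated_blur):
        masks, names = _half_space_masks((64, 64, 4))
        rsfs = compute_rsf_sinogram_space(masks, names, calibrated_blur, VOX)
        ones = simulate_acquisition(
            ActivityVolume(np.ones((64, 64, 4)), VOX), calibrated_blur
        )
        np.testing.assert_allclose(
            rsfs.rsfs.sum(axis=0), ones.values, atol=1e-9
        )

    def test_small_sphere_rsf_retains_negative_values(self, sphere_sino_rsfs, sphere_study):
        idx = sphere_study.region_names.index("sphere13_inner")
        assert sphere_sino_rsfs.rsfs[idx].min() < 0.0

    def test_partition_of_unity_within_half_percent(self, sphere_sino_rsfs):
        assert sphere_sino_rsfs.unity_deviation() < 0.005


class TestTransferSystems:
    def test_single_region_constant_image_recovers_the_constant(self):
        masks = np.ones((1, 16, 16, 8))
        rsfs = compute_rsf_image_space(masks, ["fov"], FWHM, VOX)
        img = ActivityVolume(np.full((16, 16, 8), 3.7), VOX)
        system = solve_pvc(build_system_gtm(rsfs, masks, img))
        assert system.T[0] == pytest.approx(3.7, abs=1e-12)

    def test_matched_image_recovers_uptakes_exactly(self):
        masks, names = _half_space_masks()
        rsfs = compute_rsf_image_space(masks, names, FWHM, VOX)
        truth = np.array([2.0, 0.5])
        img = ActivityVolume(np.tensordot(truth, rsfs.rsfs, axes=1), VOX)
        for build in (
            lambda: build_system_gtm(rsfs, masks, img),
            lambda: build_system_sgtm(rsfs, img),
        ):
            system = solve_pvc(build())
            np.testing.assert_allclose(system.T, truth, atol=1e-10)

    def test_sphere_to_background_ratio_recovered(self, sphere_study, pvc_config):
        # noiseless matched simulation of the 13 mm hollow sphere system
        from petgtm.evaluation import _build_models, _global_rsfs, _noiseless_images

        images = _noiseless_images(sphere_study, pvc_config, ("GTM",))
        rsfs = _global_rsfs(sphere_study, pvc_config, ("GTM",))
        res = _build_models(sphere_study, pvc_config, ("GTM",), images, rsfs)[
            ("GTM", "sphere13")
        ].fit()
        ratio = res.uptakes[0] / res.uptakes[2]  # inner / background
        assert ratio == pytest.approx(3.0, abs=3e-3)

    def test_sgtm_matrix_is_symmetric_and_psd(self, rng):
        masks, names = _half_space_masks()
        rsfs = compute_rsf_image_space(masks, names, FWHM, VOX)
        img = ActivityVolume(rng.random((32, 32, 8)), VOX)
        system = build_system_sgtm(rsfs, img)
        np.testing.assert_allclose(system.omega, system.omega.T, rtol=1e-10)
        assert np.linalg.eigvalsh(system.omega).min() >= -1e-9

    def test_gtm_omega_row_sums_equal_mask_volumes(self, sphere_study, pvc_config):
        from petgtm.evaluation import _global_rsfs

        rsfs = _global_rsfs(sphere_study, pvc_config, ("GTM",))["image-space"]
        img = sphere_study.ideal_pet
        system = build_system_gtm(rsfs, sphere_study.masks, img)
        vols = sphere_study.masks.reshape(len(sphere_study.masks), -1).sum(axis=1)
        vols = vols * img.voxel_volume
        np.testing.assert_allclose(system.omega.sum(axis=1), vols, rtol=1e-3)

    def test_grid_mismatch_is_rejected(self):
        masks, names = _half_space_masks()
        rsfs = compute_rsf_image_space(masks, names, FWHM, VOX)
        img = ActivityVolume(np.ones((8, 8, 8)), VOX)
        with pytest.raises(ValueError, match="PET grid"):
            build_system_gtm(rsfs, masks, img)
        with pytest.raises(ValueError, match="PET grid"):
            build_system_sgtm(rsfs, img)


class TestSolve:
    def test_identity_system_returns_input(self):
        system = TransferSystem(np.eye(3), np.array([1.0, 2.0, 3.0]), "GTM", list("abc"))
        solved = solve_pvc(system)
        np.testing.assert_allclose(solved.T, [1.0, 2.0, 3.0])

    def test_hand_solvable_two_by_two(self):
        system = TransferSystem(
            np.array([[2.0, 1.0], [1.0, 2.0]]), np.array([4.0, 5.0]), "GTM", ["a", "b"]
        )
        np.testing.assert_allclose(solve_pvc(system).T, [1.0, 2.0], atol=1e-14)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_solution_reproduces_sampled_vector(self, seed):
        # residual check on random diagonally dominant 6x6 systems
        rng = np.random.default_rng(seed)
        omega = rng.random((6, 6)) + 6.0 * np.eye(6)
        t = rng.random(6)
        solved = solve_pvc(TransferSystem(omega, t, "GTM", [f"r{i}" for i in range(6)]))
        assert np.abs(omega @ solved.T - t).max() <= 1e-10 * np.abs(t).max()

    def test_singular_matrix_advises_region_merge(self):
        omega = np.array([[1.0, 1.0], [1.0, 1.0]])
        with pytest.raises(ValueError, match="merge"):
            solve_pvc(TransferSystem(omega, np.array([1.0, 1.0]), "GTM", ["a", "b"]))

    def test_condition_warning_above_threshold(self, caplog):
        import logging

        omega = np.diag([1.0, 1e-8])
        system = TransferSystem(omega, np.array([1.0, 1.0]), "GTM", ["a", "b"])
        with caplog.at_level(logging.WARNING, logger="petgtm.model"):
            solve_pvc(system)
        assert any("condition" in r.message for r in caplog.records)


class TestRegionPVCModel:
    def test_scale_equivariance_of_the_correction(self, rng):
        masks, names = _half_space_masks()
        cfg = PVCConfig(psf_fwhm=FWHM)
        img = ActivityVolume(rng.random((32, 32, 8)) + 0.5, VOX)
        model = RegionPVC(img, masks=masks, region_names=names, method="sGTM", config=cfg)
        base = model.fit()
        scaled = model.refit(img.with_values(img.values * 3.5))
        np.testing.assert_allclose(scaled.uptakes, 3.5 * base.uptakes, rtol=1e-12)

    def test_image_space_methods_share_one_rsf_set(self, rng):
        masks, names = _half_space_masks()
        cfg = PVCConfig(psf_fwhm=FWHM)
        img = ActivityVolume(rng.random((32, 32, 8)), VOX)
        res_gtm = RegionPVC(img, masks=masks, region_names=names, method="GTM", config=cfg).fit()
        res_sgtm = RegionPVC(img, masks=masks, region_names=names, method="sGTM", config=cfg).fit()
        assert res_gtm.rsfs is res_sgtm.rsfs  # computed once, shared via config

    def test_apply_pvc_runs_end_to_end_from_fine_labels(self):
        from petgtm import default_sphere_spec, make_sphere_phantom

        spec = default_sphere_spec(
            pet_shape=(32, 32, 16), pet_voxel=(2.0, 2.0, 2.0), fine_voxel=(1.0, 1.0, 1.0)
        )
        from petgtm.phantoms import SphereDef

        spec.region_defs = [SphereDef("s", (32.0, 32.0, 16.0), 14.0, 1.0)]
        spec.uptake_map = {"background": 1.0, "s_inner": 3.0, "s_wall": 0.0}
        labels, activity = make_sphere_phantom(spec)

        from petgtm import downsample_to_pet
        from scipy.ndimage import gaussian_filter

        ideal = downsample_to_pet(activity, (2.0, 2.0, 2.0), (32, 32, 16))
        sig = np.asarray(FWHM) / (2 * np.sqrt(2 * np.log(2))) / 2.0
        pet = ideal.with_values(gaussian_filter(ideal.values, sig, mode="nearest"))
        res = apply_pvc(pet, labels, "sGTM", PVCConfig(psf_fwhm=FWHM))
        np.testing.assert_allclose(res.uptakes, [1.0, 3.0, 0.0], atol=0.02)
        assert res.condition_number > 1.0
        assert "sGTM" in res.summary()

    def test_unknown_method_is_rejected(self):
        img = ActivityVolume(np.ones((8, 8, 4)), VOX)
        with pytest.raises(ValueError, match="unknown method"):
            RegionPVC(img, masks=np.ones((1, 8, 8, 4)), method="MLEM")
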