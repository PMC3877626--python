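"""Projector, sinogram blur, FBP and PSF calibration."""

import numpy as np
import pytest

from petgtm import (
    ActivityVolume,
    BlurModel,
    ParallelGeometry,
    backproject,
    blur_sinogram,
    calibrate_blur,
    fbp_reconstruct,
    fit_psf_fwhm,
    forward_project,
    fwhm_to_sigma,
    simulate_acquisition,
)
from petgtm.projector import FILTERS


def _aa_disk_slice(n, radius_mm, ds, ss=8):
    """Supersampled (antialiased) disk on an n x n grid of pixel size ds."""
    c = (n - 1) / 2.0
    fine = ((np.arange(n * ss) + 0.5) / ss - 0.5 - c) * ds
    X, Y = np.meshgrid(fine, fine, indexing="ij")
    d = (X**2 + Y**2 <= radius_mm**2).astype(float)
    return d.reshape(n, ss, n, ss).mean(axis=(1, 3))


class TestForwardProject:
    def test_zero_image_projects_to_zero(self):
        vol = ActivityVolume(np.zeros((32, 32, 4)), (2, 2, 3.15))
        sino = forward_project(vol)
        assert np.all(sino.data == 0)

    def test_centered_point_source_stays_in_central_bin(self):
        # odd grid: the central voxel coincides with the rotation axis,
        # so the trace sits in the central radial bin at every angle
        n = 65
        vals = np.zeros((n, n, 1))
        vals[n // 2, n // 2, 0] = 1.0
        sino = forward_project(ActivityVolume(vals, (2, 2, 2)))
        peak_bins = sino.data[:, :, 0].argmax(axis=1)
        assert np.all(peak_bins == sino.n_radial // 2)

    def test_uniform_disk_profile_matches_analytic_chord(self):
        n, ds, R = 64, 2.0, 40.0
        disk = _aa_disk_slice(n, R, ds)
        sino = forward_project(ActivityVolume(disk[:, :, None], (ds, ds, ds)))
        s = sino.radial_offsets
        analytic = 2.0 * np.sqrt(np.clip(R**2 - s**2, 0.0, None))
        probe = np.abs(s) < 0.8 * R
        # >= 10 radial positions, every angle, within 1%
        assert probe.sum() >= 10
        rel = np.abs(sino.data[:, probe, 0] - analytic[probe]) / analytic[probe]
        assert rel.max() < 0.01

    def test_per_angle_counts_are_conserved(self):
        rng = np.random.default_rng(0)
        vals = rng.random((48, 48, 3))
        vol = ActivityVolume(vals, (2, 2, 3.15))
        sino = forward_project(vol)
        pixel_area = 4.0
        expected = vals.sum(axis=(0, 1)) * pixel_area
        got = sino.data.sum(axis=1) * sino.radial_spacing
        assert np.abs(got - expected[None, :]).max() / expected.max() < 0.005

    def test_rotational_symmetry_of_centered_sphere(self):
        # a band-limited sphere: a hard pixelized edge is itself not
        # rotationally symmetric on a Cartesian grid, so the object is
        # smoothed to the scale the grid can represent isotropically
        from scipy.ndimage import gaussian_filter

        n, ds = 64, 2.0
        disk = gaussian_filter(_aa_disk_slice(n, 20.0, ds), 1.0)
        sino = forward_project(ActivityVolume(disk[:, :, None], (ds, ds, ds)))
        spread = np.abs(sino.data[:, :, 0] - sino.data[0:1, :, 0]).max()
        assert spread / sino.data.max() < 0.01

    def test_image_wider_than_radial_fov_is_rejected(self):
        vol = ActivityVolume(np.ones((64, 64, 1)), (2, 2, 2))
        with pytest.raises(ValueError, match="radial field of view"):
            forward_project(vol, n_radial=40)

    def test_adjoint_consistency_of_projector_pair(self, rng):
        geom = ParallelGeometry(n_angles=48)
        x = ActivityVolume(rng.random((32, 32, 2)), (2, 2, 2))
        ax = forward_project(x, geom)
        y = ax.copy()
        y.data = rng.random(ax.data.shape)
        lhs = float((ax.data * y.data).sum())
        rhs = float((x.values * backproject(y, x.shape, geom).values).sum())
        assert abs(lhs - rhs) / abs(lhs) < 0.005


class TestBlurSinogram:
    def _sino(self):
        # compact content well away from the axial boundaries, where
        # boundary handling cannot interfere with convolution identities
        vals = np.zeros((32, 32, 33))
        vals[16, 16, 16] = 1.0
        return forward_project(ActivityVolume(vals, (2, 2, 3.15)))

    def test_zero_sigma_is_identity(self):
        sino = self._sino()
        out = blur_sinogram(sino, BlurModel(0.0, 0.0))
        np.testing.assert_array_equal(out.data, sino.data)

    def test_delta_trace_blurs_to_gaussian_of_requested_sigma(self):
        sino = self._sino()
        sigma = 3.0  # mm
        out = blur_sinogram(sino, BlurModel(sigma, 0.0))
        prof = out.data[0, :, 16]
        s = sino.radial_offsets
        mu = (s * prof).sum() / prof.sum()
        std = np.sqrt((prof * (s - mu) ** 2).sum() / prof.sum())
        assert abs(std - sigma) < sino.radial_spacing

    def test_gaussian_semigroup_property(self):
        # sigma comfortably above the sampling scale: sub-voxel sigmas are
        # Nyquist-truncated and only approximately compose
        sino = self._sino()
        s = 5.0
        twice = blur_sinogram(blur_sinogram(sino, BlurModel(s, s)), BlurModel(s, s))
        once = blur_sinogram(sino, BlurModel(s * np.sqrt(2), s * np.sqrt(2)))
        scale = np.abs(once.data).max()
        assert np.abs(twice.data - once.data).max() / scale < 1e-6

    def test_counts_preserved_per_angle(self):
        sino = self._sino()
        out = blur_sinogram(sino, BlurModel(4.0, 3.0))
        before = sino.data.sum(axis=(1, 2))
        after = out.data.sum(axis=(1, 2))
        assert np.abs(after - before).max() / before.max() < 0.001


class TestFBP:
    def test_zero_sinogram_reconstructs_to_zero(self):
        vol = ActivityVolume(np.zeros((32, 32, 2)), (2, 2, 2))
        sino = forward_project(vol)
        rec = fbp_reconstruct(sino, vol.shape)
        assert np.all(rec.values == 0)

    def test_unknown_filter_lists_available_ones(self):
        vol = ActivityVolume(np.ones((32, 32, 1)), (2, 2, 2))
        sino = forward_project(vol)
        with pytest.raises(ValueError, match="ramp.*shepp-logan.*hann"):
            fbp_reconstruct(sino, vol.shape, "butterworth")

    def test_reconstruction_is_linear(self, rng):
        geom = ParallelGeometry(n_angles=64)
        v1 = ActivityVolume(rng.random((32, 32, 2)), (2, 2, 2))
        v2 = ActivityVolume(rng.random((32, 32, 2)), (2, 2, 2))
        s1 = forward_project(v1, geom)
        s2 = forward_project(v2, geom)
        combo = s1.copy()
        combo.data = 2.0 * s1.data - 0.5 * s2.data
        lhs = fbp_reconstruct(combo, v1.shape, geometry=geom).values
        rhs = (
            2.0 * fbp_reconstruct(s1, v1.shape, geometry=geom).values
            - 0.5 * fbp_reconstruct(s2, v1.shape, geometry=geom).values
        )
        assert np.abs(lhs - rhs).max() <= 1e-6 * np.abs(lhs).max()

    def test_smooth_blob_round_trip_interior_rms_under_two_percent(self):
        n, ds = 64, 2.0
        c = (n - 1) / 2.0
        x = (np.arange(n) - c) * ds
        X, Y = np.meshgrid(x, x, indexing="ij")
        blob = np.exp(-(X**2 + Y**2) / (2 * 12.0**2))
        vol = ActivityVolume(blob[:, :, None], (ds, ds, ds))
        sino = forward_project(vol)  # default geometry: 192 angles
        rec = fbp_reconstruct(sino, vol.shape)
        sel = blob > 0.05
        rms = np.sqrt(((rec.values[:, :, 0] - blob)[sel] ** 2).mean())
        assert rms / blob[sel].max() < 0.02

    def test_uniform_disk_mean_is_recovered(self):
        n, ds, R = 64, 2.0, 40.0
        disk = _aa_disk_slice(n, R, ds)
        vol = ActivityVolume(disk[:, :, None], (ds, ds, ds))
        rec = fbp_reconstruct(forward_project(vol), vol.shape)
        c = (n - 1) / 2.0
        x = (np.arange(n) - c) * ds
        X, Y = np.meshgrid(x, x, indexing="ij")
        interior = X**2 + Y**2 < (0.75 * R) ** 2
        assert rec.values[:, :, 0][interior].mean() == pytest.approx(1.0, abs=0.02)

    def test_matches_reference_fbp_implementation(self):
        # independent cross-check of projector + FBP conventions against
        # scikit-image's radon/iradon on the same disk phantom
        skimage = pytest.importorskip("skimage.transform")
        n, ds = 64, 1.0
        disk = _aa_disk_slice(n, 20.0, ds)
        vol = ActivityVolume(disk[:, :, None], (ds, ds, ds))
        rec = fbp_reconstruct(forward_project(vol), vol.shape, "hann")
        theta = np.arange(192) * 180.0 / 192
        ref = skimage.iradon(
            skimage.radon(disk, theta=theta, circle=False).astype(float),
            theta=theta,
            filter_name="hann",
            circle=False,
        )
        sel = disk > 0.9
        assert np.abs(rec.values[:, :, 0] - ref)[sel].max() < 0.05


class TestSimulateAcquisition:
    def test_cylinder_interior_mean_preserved(self, calibrated_blur):
        n, ds = 64, 2.0
        disk = _aa_disk_slice(n, 44.0, ds)
        vol = ActivityVolume(np.repeat(disk[:, :, None], 8, axis=2), (ds, ds, 3.15))
        out = simulate_acquisition(vol, calibrated_blur)
        c = (n - 1) / 2.0
        x = (np.arange(n) - c) * ds
        X, Y = np.meshgrid(x, x, indexing="ij")
        interior = X**2 + Y**2 < 30.0**2
        assert out.values[interior, 4].mean() == pytest.approx(1.0, abs=0.02)
        # global activity conservation
        assert out.total_activity() == pytest.approx(vol.total_activity(), rel=0.01)

    def test_point_source_psf_matches_calibrated_fwhm(self, calibrated_blur):
        vals = np.zeros((64, 64, 48))
        vals[32, 32, 24] = 1.0
        out = simulate_acquisition(ActivityVolume(vals, (2, 2, 3.15)), calibrated_blur)
        fwhm = fit_psf_fwhm(out)
        for got, ref in zip(fwhm, calibrated_blur.fitted_fwhm):
            assert got == pytest.approx(ref, rel=0.02)

    def test_equivalent_to_image_space_gaussian_for_smooth_images(self, calibrated_blur):
        # the bridge property that makes GTM-vs-GTMo comparisons meaningful
        from scipy.ndimage import gaussian_filter

        n = 64
        c = (n - 1) / 2.0
        x = (np.arange(n) - c) * 2.0
        z = (np.arange(48) - 23.5) * 3.15
        X, Y, Z = np.meshgrid(x, x, z, indexing="ij")
        blob = np.exp(-(X**2 + Y**2) / (2 * 15.0**2) - Z**2 / (2 * 18.0**2))
        vol = ActivityVolume(blob, (2, 2, 3.15))
        sino_route = simulate_acquisition(vol, calibrated_blur)
        sigma_vox = fwhm_to_sigma(calibrated_blur.fitted_fwhm) / np.array([2, 2, 3.15])
        conv_route = gaussian_filter(blob, sigma_vox, mode="nearest")
        sel = blob > 0.05
        rms = np.sqrt(((sino_route.values - conv_route)[sel] ** 2).mean())
        assert rms / conv_route[sel].max() < 0.03


class TestCalibration:
    def test_default_targets_are_matched_within_two_percent(self, calibrated_blur):
        targets = (7.23, 7.14, 6.65)
        for got, want in zip(calibrated_blur.fitted_fwhm, targets):
            assert abs(got - want) / want < 0.02

    def test_target_below_intrinsic_floor_reports_the_floor(self):
        with pytest.raises(ValueError, match="intrinsic resolution floor"):
            calibrate_blur(
                (1.0, 1.0, 6.65), grid_shape=(32, 32, 8), voxel_size=(2, 2, 3.15)
            )

    def test_doubling_the_target_increases_sigma_monotonically(self, calibrated_blur):
        wider = calibrate_blur(
            (14.46, 14.28, 13.3), grid_shape=(64, 64, 48), voxel_size=(2, 2, 3.15)
        )
        assert wider.sigma_radial > calibrated_blur.sigma_radial
        assert wider.sigma_axial > calibrated_blur.sigma_axial


def test_filter_registry_is_consistent():
    assert set(FILTERS) == {"ramp", "shepp-logan", "hann"}
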