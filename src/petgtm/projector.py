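"""Idealized PET acquisition model: project, blur, reconstruct.

The scanner is modelled as a slice-parallel parallel-beam system: each
transaxial slice is forward projected with a 2D Radon transform, the
sinograms are blurred with a Gaussian in the radial (Fourier) and axial
directions, and images are recovered by 2D filtered back-projection per
slice.  This keeps the structure that matters for sinogram-space
partial-volume correction -- regional spread functions computed by
project/blur/reconstruct, including the negative values and streaks the
reconstruction introduces -- in an exactly implementable, desk-scale
form.

Numerical design
----------------
The forward projector uses Joseph-style bilinear sampling along rays,
with two refinements over the textbook scheme, both needed to keep the
reconstruction of a constant image flat to a few parts per thousand
(the partition-of-unity requirement of region-based PVC):

* each detector bin is supersampled with ``detector_supersample``
  sub-rays whose contributions are averaged (models finite bin width
  and suppresses center-of-rotation aliasing);
* the ray sampling step is ``ray_step_fraction`` of the radial spacing.

Per view angle the projector is assembled once as a sparse matrix and
cached, so the backprojector used by FBP is the *exact transpose* of
the forward projector: the adjoint identity <Ax, y> = <x, A'y> holds to
machine precision.  The ramp filter is built from the band-limited
spatial-domain kernel (direct |f| sampling leaves a percent-level DC
bias), apodized with a Hann or Shepp-Logan window.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import sparse
from scipy.fft import fft, irfft, next_fast_len, rfft
from scipy.optimize import brentq, curve_fit

from .volumes import ActivityVolume

__all__ = [
    "ParallelGeometry",
    "SinogramStack",
    "BlurModel",
    "forward_project",
    "backproject",
    "blur_sinogram",
    "fbp_reconstruct",
    "simulate_acquisition",
    "calibrate_blur",
    "fwhm_to_sigma",
    "sigma_to_fwhm",
    "fit_psf_fwhm",
    "read_sinogram",
    "write_sinogram",
    "FILTERS",
]

#: FWHM = 2 sqrt(2 ln 2) sigma; stated once, used everywhere.
_FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))

FILTERS = ("ramp", "shepp-logan", "hann")


def fwhm_to_sigma(fwhm):
    return np.asarray(fwhm, dtype=float) / _FWHM_FACTOR


def sigma_to_fwhm(sigma):
    return np.asarray(sigma, dtype=float) * _FWHM_FACTOR


@dataclass(frozen=True)
class ParallelGeometry:
    """Parallel-beam acquisition geometry (angles in [0, pi)).

    ``radial_spacing`` defaults to the in-plane PET voxel size when the
    sinogram is created from an image.  ``pad_xy`` is the replicate-edge
    padding (in voxels) applied by :func:`simulate_acquisition` so that
    the field of view behaves as the interior of a larger object --
    the sinogram-space analog of replicate-edge convolution.
    """

    n_angles: int = 192
    extent_factor: float = 1.1
    detector_supersample: int = 3
    ray_step_fraction: float = 1.0 / 3.0
    pad_xy: int = 16

    def __post_init__(self) -> None:
        if self.n_angles < 2:
            raise ValueError("n_angles must be >= 2")
        if self.extent_factor < 1.0:
            raise ValueError("radial extent must cover the image diagonal")

    @property
    def angles(self) -> np.ndarray:
        return np.arange(self.n_angles) * np.pi / self.n_angles

    def n_radial(self, n_xy: int) -> int:
        n = int(np.ceil(n_xy * np.sqrt(2.0) * self.extent_factor))
        return n + 1 if n % 2 == 0 else n


@dataclass
class SinogramStack:
    """Parallel-beam projection data, indexed (angle, radial bin, slice)."""

    data: np.ndarray
    angles: np.ndarray
    radial_spacing: float
    slice_spacing: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.angles = np.asarray(self.angles, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("sinogram data must be (n_angles, n_radial, n_slices)")
        if len(self.angles) != self.data.shape[0]:
            raise ValueError("angles do not match data")
        if len(self.angles) < 2 or np.any(np.diff(self.angles) <= 0):
            raise ValueError("need >= 2 strictly increasing angles")

    @property
    def n_radial(self) -> int:
        return self.data.shape[1]

    @property
    def radial_offsets(self) -> np.ndarray:
        """Signed radial coordinates (mm) of the bin centers."""
        n = self.n_radial
        return (np.arange(n) - (n - 1) / 2.0) * self.radial_spacing

    def copy(self) -> "SinogramStack":
        return replace(self, data=self.data.copy(), angles=self.angles.copy())


@dataclass
class BlurModel:
    """Sinogram-domain Gaussian blur calibrated to a target scanner PSF.

    ``sigma_radial`` acts on the radial coordinate of every projection
    (equivalent, by the central-slice theorem, to an isotropic in-plane
    image blur), ``sigma_axial`` along the slice direction.
    ``fitted_fwhm`` records the reconstructed point-source FWHM (x, y, z)
    this blur produces; it is filled in by :func:`calibrate_blur`.
    """

    sigma_radial: float
    sigma_axial: float
    fitted_fwhm: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.sigma_radial < 0 or self.sigma_axial < 0:
            raise ValueError("blur sigmas must be >= 0")


# ---------------------------------------------------------------------------
# sparse projection operators (cached per geometry/grid)

_OPS_CACHE: dict[tuple, list] = {}
_OPS_CACHE_MAX = 4


def _projection_ops(n_xy: int, geometry: ParallelGeometry) -> list[sparse.csr_matrix]:
    """Per-angle sparse forward operators, in radial-spacing pixel units.

    Operator ``M[a]`` maps a flattened (n_xy, n_xy) slice to the
    ``n_radial`` projection values at angle ``a``; values are line
    integrals in units of pixels (multiply by radial_spacing for mm).
    """
    key = (
        n_xy,
        geometry.n_angles,
        geometry.extent_factor,
        geometry.detector_supersample,
        round(geometry.ray_step_fraction, 9),
    )
    if key in _OPS_CACHE:
        return _OPS_CACHE[key]

    n_rad = geometry.n_radial(n_xy)
    ss = geometry.detector_supersample
    step = geometry.ray_step_fraction
    c = (n_xy - 1) / 2.0
    s = np.arange(n_rad) - (n_rad - 1) / 2.0
    sub = (np.arange(ss) - (ss - 1) / 2.0) / ss
    tmax = (n_rad - 1) / 2.0
    nt = int(np.ceil(2 * tmax / step)) + 1
    t = np.linspace(-tmax, tmax, nt)
    dt = t[1] - t[0]

    S = (s[:, None] + sub[None, :]).ravel()  # supersampled detector positions
    rows_all = np.repeat(np.arange(n_rad), ss * nt)
    SS, TT = np.meshgrid(S, t, indexing="ij")
    SS = SS.ravel()
    TT = TT.ravel()

    mats = []
    for a in geometry.angles:
        ca, sa = np.cos(a), np.sin(a)
        X = SS * ca - TT * sa + c
        Y = SS * sa + TT * ca + c
        valid = (X > -1) & (X < n_xy) & (Y > -1) & (Y < n_xy)
        Xv, Yv, rows = X[valid], Y[valid], rows_all[valid]
        x0 = np.floor(Xv).astype(np.int64)
        y0 = np.floor(Yv).astype(np.int64)
        fx, fy = Xv - x0, Yv - y0
        R, C, D = [], [], []
        for ddx, wx in ((0, 1.0 - fx), (1, fx)):
            for ddy, wy in ((0, 1.0 - fy), (1, fy)):
                xx, yy = x0 + ddx, y0 + ddy
                ok = (xx >= 0) & (xx < n_xy) & (yy >= 0) & (yy < n_xy)
                w = (wx * wy)[ok]
                nz = w > 0
                R.append(rows[ok][nz])
                C.append((xx * n_xy + yy)[ok][nz])
                D.append(w[nz] * (dt / ss))
        M = sparse.csr_matrix(
            (np.concatenate(D), (np.concatenate(R), np.concatenate(C))),
            shape=(n_rad, n_xy * n_xy),
        )
        mats.append(M)

    if len(_OPS_CACHE) >= _OPS_CACHE_MAX:
        _OPS_CACHE.pop(next(iter(_OPS_CACHE)))
    _OPS_CACHE[key] = mats
    return mats


def _check_inplane(image: ActivityVolume) -> float:
    if image.shape[0] != image.shape[1]:
        raise ValueError("in-plane image dimensions must be square (nx == ny)")
    if not np.isclose(image.voxel_size[0], image.voxel_size[1]):
        raise ValueError("in-plane voxel size must be isotropic")
    return image.voxel_size[0]


def forward_project(
    image: ActivityVolume,
    geometry: ParallelGeometry = ParallelGeometry(),
    n_radial: int | None = None,
) -> SinogramStack:
    """Line-integrate every transaxial slice along rays at each angle.

    Returns a :class:`SinogramStack` whose values are length-weighted
    line integrals in mm * activity; per-slice, per-angle total counts
    (sum over radial bins times radial spacing) match the image slice
    integral to a fraction of a percent.
    """
    ds = _check_inplane(image)
    n_xy = image.shape[0]
    if n_radial is not None and n_radial < geometry.n_radial(n_xy):
        raise ValueError(
            f"image diagonal exceeds the radial field of view "
            f"({n_radial} bins of {ds} mm)"
        )
    mats = _projection_ops(n_xy, geometry)
    flat = image.values.reshape(n_xy * n_xy, -1)
    data = np.stack([M @ flat for M in mats]) * ds  # pixel -> mm line integrals
    return SinogramStack(data, geometry.angles, ds, image.voxel_size[2])


def backproject(
    sino: SinogramStack,
    grid_shape: tuple[int, int, int],
    geometry: ParallelGeometry = ParallelGeometry(),
) -> ActivityVolume:
    """Exact adjoint of :func:`forward_project` (unfiltered backprojection)."""
    n_xy = grid_shape[0]
    mats = _projection_ops(n_xy, geometry)
    if mats[0].shape[0] != sino.n_radial:
        raise ValueError("sinogram radial size does not match geometry/grid")
    out = None
    for ia, M in enumerate(mats):
        term = M.T @ sino.data[ia]
        out = term if out is None else out + term
    out = out.reshape(n_xy, n_xy, -1) * sino.radial_spacing
    return ActivityVolume(
        out, (sino.radial_spacing, sino.radial_spacing, sino.slice_spacing)
    )


# ---------------------------------------------------------------------------
# sinogram blurring


def blur_sinogram(sino: SinogramStack, blur: BlurModel) -> SinogramStack:
    """Gaussian-blur projection data radially (Fourier domain) and axially.

    The radial blur multiplies the Fourier transform of each projection
    with a Gaussian (unit DC gain, so per-angle counts are preserved);
    the axial blur convolves each (angle, radial) trace along slices
    with a normalized Gaussian using replicate boundaries.
    """
    data = sino.data
    if blur.sigma_radial > 0:
        data = _fourier_gaussian_1d(data, blur.sigma_radial, sino.radial_spacing, axis=1)
    if blur.sigma_axial > 0:
        # replicate-pad the slice direction so constants are preserved at
        # the axial boundaries (the radial direction has its own margin)
        nz = data.shape[2]
        pad = min(nz, int(np.ceil(6.0 * blur.sigma_axial / sino.slice_spacing)) + 1)
        padded = np.pad(data, ((0, 0), (0, 0), (pad, pad)), mode="edge")
        padded = _fourier_gaussian_1d(padded, blur.sigma_axial, sino.slice_spacing, axis=2)
        data = padded[:, :, pad : pad + nz]
    return replace(sino, data=data, angles=sino.angles.copy())


def _fourier_gaussian_1d(data: np.ndarray, sigma: float, spacing: float, axis: int) -> np.ndarray:
    """Convolve one axis with an exact Gaussian via its frequency response.

    The transfer function exp(-2 pi^2 sigma^2 f^2) has unit DC gain and
    composes exactly (blurring twice with sigma equals once with
    sigma*sqrt(2)), unlike sampled spatial kernels at sub-voxel sigmas.
    """
    n = data.shape[axis]
    nfft = next_fast_len(2 * n)
    f = np.fft.rfftfreq(nfft, d=spacing)
    gauss = np.exp(-2.0 * (np.pi * f * sigma) ** 2)
    shape = [1, 1, 1]
    shape[axis] = len(f)
    spec = rfft(data, nfft, axis=axis)
    out = irfft(spec * gauss.reshape(shape), nfft, axis=axis)
    return np.take(out, np.arange(n), axis=axis)


# ---------------------------------------------------------------------------
# filtered back-projection


def _ramp_kernel_spectrum(n_rad: int, ds: float, filter_name: str) -> tuple[np.ndarray, int]:
    """Band-limited ramp filter spectrum (built in the spatial domain)."""
    if filter_name not in FILTERS:
        raise ValueError(f"unknown filter {filter_name!r}; available: {', '.join(FILTERS)}")
    nfft = next_fast_len(4 * n_rad)
    h = np.zeros(nfft)
    k = np.arange(1, n_rad, 2)
    h[0] = 1.0 / (4.0 * ds * ds)
    h[k] = -1.0 / (np.pi * k * ds) ** 2
    h[-k] = -1.0 / (np.pi * k * ds) ** 2
    H = np.real(fft(h))[: nfft // 2 + 1]
    f = np.fft.rfftfreq(nfft)  # cycles per sample; Nyquist = 0.5
    if filter_name == "hann":
        H = H * 0.5 * (1.0 + np.cos(2.0 * np.pi * f))
    elif filter_name == "shepp-logan":
        H = H * np.sinc(f)
    return H, nfft


def fbp_reconstruct(
    sino: SinogramStack,
    grid_shape: tuple[int, int, int],
    filter_name: str = "hann",
    geometry: ParallelGeometry = ParallelGeometry(),
) -> ActivityVolume:
    """Slice-by-slice 2D filtered back-projection.

    Each radial profile is ramp-filtered (with the selected apodization
    window), backprojected over angles with the transpose operator, and
    scaled by pi / n_angles.
    """
    H, nfft = _ramp_kernel_spectrum(sino.n_radial, sino.radial_spacing, filter_name)
    spec = rfft(sino.data, nfft, axis=1)
    filtered = irfft(spec * H[None, :, None], nfft, axis=1)[:, : sino.n_radial, :]
    filtered_stack = replace(sino, data=filtered, angles=sino.angles.copy())
    img = backproject(filtered_stack, grid_shape, geometry)
    # transpose backprojection carries the radial_spacing factor and the
    # ramp kernel carries 1/radial_spacing^2; the angular quadrature
    # weight pi/n_angles completes the scale (validated against the
    # analytic uniform disk: reconstructed mean = true intensity).
    scale = np.pi / len(sino.angles)
    return img.with_values(img.values * scale)


def _pad_replicate_xy(values: np.ndarray, pad: int) -> np.ndarray:
    return np.pad(values, ((pad, pad), (pad, pad), (0, 0)), mode="edge")


def simulate_acquisition(
    image: ActivityVolume,
    blur: BlurModel,
    geometry: ParallelGeometry = ParallelGeometry(),
    filter_name: str = "hann",
) -> ActivityVolume:
    """Forward-project, blur and reconstruct an ideal PET-grid image.

    The image is replicate-padded in-plane by ``geometry.pad_xy`` voxels
    before projection and cropped afterwards, so grid-edge voxels behave
    as the interior of a larger object (matching the replicate-edge
    convention of image-space RSF convolution).  Global activity of
    compactly supported images is conserved to better than 1%.
    """
    ds = _check_inplane(image)
    pad = geometry.pad_xy
    padded = ActivityVolume(
        _pad_replicate_xy(image.values, pad), image.voxel_size, image.origin
    )
    sino = forward_project(padded, geometry)
    sino = blur_sinogram(sino, blur)
    rec = fbp_reconstruct(sino, padded.shape, filter_name, geometry)
    values = rec.values[pad:-pad, pad:-pad, :] if pad else rec.values
    return ActivityVolume(values, image.voxel_size, image.origin)


# ---------------------------------------------------------------------------
# PSF calibration


def _gaussian(x, amp, mu, sigma):
    return amp * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))


def _fit_profile_fwhm(coords: np.ndarray, profile: np.ndarray) -> float:
    """FWHM (same units as coords) of a Gaussian fitted to one profile."""
    i = int(np.argmax(profile))
    amp0 = profile[i]
    if amp0 <= 0:
        raise ValueError("profile has no positive peak to fit")
    width0 = max((coords[1] - coords[0]) if len(coords) > 1 else 1.0, 1e-3)
    popt, _ = curve_fit(
        _gaussian,
        coords,
        profile,
        p0=[amp0, coords[i], width0],
        maxfev=10000,
    )
    return float(sigma_to_fwhm(abs(popt[2])))


def fit_psf_fwhm(image: ActivityVolume) -> tuple[float, float, float]:
    """Gaussian-fitted FWHM (mm) of three orthogonal profiles through the peak.

    Axes with fewer than four samples cannot support a fit and yield NaN.
    """
    ix, iy, iz = np.unravel_index(np.argmax(image.values), image.shape)
    out = []
    for axis, idx in ((0, (slice(None), iy, iz)), (1, (ix, slice(None), iz)), (2, (ix, iy, slice(None)))):
        profile = image.values[idx]
        if len(profile) < 4:
            out.append(float("nan"))
            continue
        coords = image.voxel_centers(axis)
        out.append(_fit_profile_fwhm(coords, profile))
    return tuple(out)


def _point_source(grid_shape, voxel_size) -> ActivityVolume:
    values = np.zeros(grid_shape)
    values[grid_shape[0] // 2, grid_shape[1] // 2, grid_shape[2] // 2] = 1.0
    return ActivityVolume(values, voxel_size)


def calibrate_blur(
    target_fwhm,
    geometry: ParallelGeometry = ParallelGeometry(),
    grid_shape: tuple[int, int, int] = (64, 64, 48),
    voxel_size=(2.0, 2.0, 3.15),
    filter_name: str = "hann",
    rtol: float = 1e-3,
) -> BlurModel:
    """Find sinogram blur sigmas that reproduce a target scanner PSF.

    A simulated point source is passed through project/blur/reconstruct
    and the blur sigmas are root-found (1D per component) so that the
    Gaussian-fitted FWHMs of three orthogonal profiles match the target.
    The radial blur is in-plane isotropic, so one sigma is calibrated
    against the mean of the x/y targets; with the 7.23/7.14 mm targets
    the individual fits still land well within 2% of each.

    Raises when the target is below the intrinsic resolution of the
    discrete projector (reported in the error message).
    """
    target = np.broadcast_to(np.asarray(target_fwhm, float), (3,))
    target_xy = float(target[:2].mean())
    target_z = float(target[2])

    point = _point_source(grid_shape, voxel_size)
    pad = geometry.pad_xy
    padded = ActivityVolume(
        _pad_replicate_xy(point.values, pad), point.voxel_size, point.origin
    )
    sino0 = forward_project(padded, geometry)
    z_idx = grid_shape[2] // 2

    def inplane_fwhm(sigma_r: float) -> float:
        s = replace(sino0, data=sino0.data[:, :, z_idx : z_idx + 1], angles=sino0.angles.copy())
        s = blur_sinogram(s, BlurModel(sigma_r, 0.0))
        rec = fbp_reconstruct(s, (padded.shape[0], padded.shape[1], 1), filter_name, geometry)
        fx, fy, _ = fit_psf_fwhm(
            ActivityVolume(rec.values, point.voxel_size, point.origin)
        )
        return 0.5 * (fx + fy)

    floor = inplane_fwhm(0.0)
    if target_xy < floor * (1.0 - rtol):
        raise ValueError(
            f"target in-plane FWHM {target_xy:.2f} mm is below the intrinsic "
            f"resolution floor of the discrete projector ({floor:.2f} mm)"
        )
    if target_xy <= floor:
        sigma_r = 0.0
    else:
        hi = float(fwhm_to_sigma(2.0 * target_xy))
        sigma_r = brentq(
            lambda s: inplane_fwhm(s) - target_xy, 0.0, hi, xtol=1e-3, rtol=1e-4
        )

    # Axial: slices are reconstructed independently, so the axial profile
    # of the point image is the (sampled) axial blur kernel itself.
    dz = float(voxel_size[2])
    zc = (np.arange(grid_shape[2]) + 0.5) * dz
    z0 = zc[z_idx]

    def axial_fwhm(sigma_z: float) -> float:
        prof = np.exp(-((zc - z0) ** 2) / (2.0 * max(sigma_z, 1e-6) ** 2))
        return _fit_profile_fwhm(zc, prof)

    axial_floor = axial_fwhm(0.35 * dz)
    if target_z < axial_floor:
        raise ValueError(
            f"target axial FWHM {target_z:.2f} mm is below the axial sampling "
            f"floor ({axial_floor:.2f} mm at {dz} mm slices)"
        )
    sigma_z = brentq(
        lambda s: axial_fwhm(s) - target_z,
        0.35 * dz,
        float(fwhm_to_sigma(2.0 * target_z)),
        xtol=1e-3,
        rtol=1e-4,
    )

    blur = BlurModel(float(sigma_r), float(sigma_z))
    psf_img = simulate_acquisition(point, blur, geometry, filter_name)
    blur.fitted_fwhm = fit_psf_fwhm(psf_img)
    return blur


# ---------------------------------------------------------------------------
# HDF5 I/O


def write_sinogram(path, sino: SinogramStack) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=sino.data, compression="gzip")
        f.create_dataset("angles", data=sino.angles)
        f.attrs["radial_spacing"] = sino.radial_spacing
        f.attrs["slice_spacing"] = sino.slice_spacing


def read_sinogram(path) -> SinogramStack:
    import h5py

    with h5py.File(path, "r") as f:
        return SinogramStack(
            f["data"][()],
            f["angles"][()],
            float(f.attrs["radial_spacing"]),
            float(f.attrs["slice_spacing"]),
        )
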