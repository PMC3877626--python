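"""Regional spread functions (RSFs).

An RSF is the PET image a VOI of unit uptake would produce through the
scanner's resolution model.  Image-space RSFs convolve the PET-grid
tissue-fraction masks with the global Gaussian PSF; sinogram-space RSFs
push each mask through the full project/blur/reconstruct chain and may
therefore contain negative values and streak artifacts (retained, not
clipped -- they do not harm the transfer-matrix algebra).

Because the masks tile the field of view and every step is linear with
unit DC gain, the RSFs of a complete region set sum to one at every
voxel: exactly for image-space RSFs, and to within a configurable
tolerance (default 0.5%) for sinogram-space RSFs, where the residual is
pure reconstruction discretization error.  This partition-of-unity
property is asserted at construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .projector import BlurModel, ParallelGeometry, fwhm_to_sigma, simulate_acquisition
from .volumes import ActivityVolume

__all__ = ["RSFSet", "compute_rsf_image_space", "compute_rsf_sinogram_space"]


@dataclass
class RSFSet:
    """N regional spread functions on the PET grid."""

    rsfs: np.ndarray  # (N, nx, ny, nz)
    region_names: list[str]
    method_tag: str  # "image-space" | "sinogram-space"
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.rsfs = np.asarray(self.rsfs, dtype=float)
        if self.rsfs.ndim != 4 or self.rsfs.shape[0] != len(self.region_names):
            raise ValueError("rsfs must be (n_regions, nx, ny, nz) matching region_names")

    @property
    def n_regions(self) -> int:
        return self.rsfs.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.rsfs.shape[1:]

    def unity_deviation(self) -> float:
        """Max voxelwise deviation of the RSF sum from 1."""
        return float(np.abs(self.rsfs.sum(axis=0) - 1.0).max())

    def check_partition(self, tol: float) -> None:
        dev = self.unity_deviation()
        if dev > tol:
            raise ValueError(
                f"RSF sum deviates from unity by {dev:.3%} (max over voxels), "
                f"beyond the {tol:.3%} tolerance"
            )

    def subset(self, indices) -> "RSFSet":
        """An RSFSet restricted to selected regions (no partition check)."""
        return RSFSet(
            self.rsfs[list(indices)],
            [self.region_names[i] for i in indices],
            self.method_tag,
            self.voxel_size,
        )


def _check_masks(masks: np.ndarray, tol: float = 1e-3) -> np.ndarray:
    masks = np.asarray(masks, dtype=float)
    if masks.ndim != 4:
        raise ValueError("masks must be a (n_regions, nx, ny, nz) array")
    dev = np.abs(masks.sum(axis=0) - 1.0).max()
    if dev > tol:
        raise ValueError(
            f"tissue-fraction masks are not a partition of unity "
            f"(max deviation {dev:.2e}); pass the complete region set "
            "including background"
        )
    return masks


def compute_rsf_image_space(
    masks: np.ndarray,
    region_names: list[str],
    psf_fwhm,
    voxel_size,
) -> RSFSet:
    """Convolve each PET-grid mask with the global 3D Gaussian PSF.

    Replicate-edge padding keeps the partition of unity exact at the
    grid borders (an all-FOV region set convolves to exactly one
    everywhere).
    """
    masks = _check_masks(masks)
    voxel_size = np.broadcast_to(np.asarray(voxel_size, float), (3,))
    sigma_vox = fwhm_to_sigma(psf_fwhm) / voxel_size
    rsfs = np.stack(
        [gaussian_filter(m, sigma_vox, mode="nearest", truncate=6.0) for m in masks]
    )
    out = RSFSet(rsfs, list(region_names), "image-space", tuple(voxel_size))
    out.check_partition(1e-6)
    return out


def compute_rsf_sinogram_space(
    masks: np.ndarray,
    region_names: list[str],
    blur: BlurModel,
    voxel_size,
    geometry: ParallelGeometry = ParallelGeometry(),
    filter_name: str = "hann",
    unity_tol: float = 0.005,
) -> RSFSet:
    """Push each PET-grid mask through project/blur/reconstruct.

    Uses the same geometry, calibrated blur and reconstruction filter as
    the PET simulation or acquisition (both sides of the transfer system
    must see the same system model).  Negative voxel values from the
    reconstruction are retained.  Raises if the voxelwise RSF sum
    deviates from unity by more than ``unity_tol`` (default 0.5%).
    """
    masks = _check_masks(masks)
    voxel_size = tuple(np.broadcast_to(np.asarray(voxel_size, float), (3,)))
    rsfs = np.stack(
        [
            simulate_acquisition(
                ActivityVolume(m, voxel_size), blur, geometry, filter_name
            ).values
            for m in masks
        ]
    )
    out = RSFSet(rsfs, list(region_names), "sinogram-space", voxel_size)
    out.check_partition(unity_tol)
    return out
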