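"""Region-based partial volume correction via the geometric transfer matrix.

The measured PET image is modelled as a superposition of regional
spread functions with unknown homogeneous regional uptakes T_j:

    I(r) = sum_j T_j RSF_j(r)

Sampling both sides with a set of weighting functions w_j gives the
linear system

    omega_ij T_j = t_i,    omega_ij = int RSF_i w_j dr,
                           t_j     = int I w_j dr,

solved by a direct dense solve.  The four classical variants differ in
how the RSFs are computed and how the image is sampled:

=======  ==================  ==========================
method   RSF computation     sampling weight w_j
=======  ==================  ==========================
GTM      PSF convolution     VOI tissue fraction (sharp)
sGTM     PSF convolution     RSF (blurry, symmetric omega)
GTMo     project/blur/FBP    VOI tissue fraction
sGTMo    project/blur/FBP    RSF
=======  ==================  ==========================

The symmetric variants sample the image with the blurred RSFs rather
than the sharp masks, which makes omega a Gram matrix (symmetric
positive semidefinite for image-space RSFs) and improves noise
propagation and robustness to mask/PET misregistration.

`RegionPVC` is the model object (PET image + region masks + method);
its :meth:`~RegionPVC.fit` returns a :class:`PVCResults` carrying the
corrected uptakes, the transfer matrix, its condition number and, when
a voxel-noise level is given, analytic standard errors.  RSFs and the
weighting matrix depend only on the masks, so Monte-Carlo loops should
build the model once and call :meth:`~RegionPVC.refit` per noisy image.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .phantoms import downsample_masks
from .projector import BlurModel, ParallelGeometry
from .rsf import RSFSet, compute_rsf_image_space, compute_rsf_sinogram_space
from .volumes import ActivityVolume, LabelVolume

__all__ = [
    "METHODS",
    "PVCConfig",
    "TransferSystem",
    "RegionPVC",
    "PVCResults",
    "build_system_gtm",
    "build_system_sgtm",
    "solve_pvc",
    "apply_pvc",
]

logger = logging.getLogger(__name__)

METHODS = ("GTM", "sGTM", "GTMo", "sGTMo")
_IMAGE_SPACE = {"GTM": True, "sGTM": True, "GTMo": False, "sGTMo": False}
_SYMMETRIC = {"GTM": False, "sGTM": True, "GTMo": False, "sGTMo": True}


@dataclass
class TransferSystem:
    """The N x N weighting matrix, sampled vector and solution of one PVC."""

    omega: np.ndarray
    t: np.ndarray
    method: str
    region_names: list[str]
    T: np.ndarray | None = None
    condition_number: float | None = None

    def __post_init__(self) -> None:
        self.omega = np.asarray(self.omega, dtype=float)
        self.t = np.asarray(self.t, dtype=float)
        n = len(self.t)
        if self.omega.shape != (n, n):
            raise ValueError("omega must be square and match t")
        if not np.all(np.isfinite(self.omega)):
            raise ValueError("omega entries must be finite")


def _flat_weights(weights: np.ndarray) -> np.ndarray:
    return weights.reshape(weights.shape[0], -1)


def build_system_gtm(
    rsfs: RSFSet,
    masks: np.ndarray,
    pet_image: ActivityVolume,
    fov_weight: np.ndarray | None = None,
    method: str = "GTM",
) -> TransferSystem:
    """Eq.-(2)-style system: sample with the sharp VOI tissue fractions.

    omega_ij = sum_r RSF_i VOI_j [fov] * voxel_volume, t_j likewise with
    the PET image.  ``fov_weight`` optionally restricts the integrals to
    a local field of view (e.g. the per-sphere background cylinder).
    """
    masks = np.asarray(masks, dtype=float)
    if masks.shape != rsfs.rsfs.shape or pet_image.shape != rsfs.grid_shape:
        raise ValueError("masks, RSFs and PET image must share the PET grid")
    w = masks if fov_weight is None else masks * fov_weight
    vv = pet_image.voxel_volume
    wf = _flat_weights(w)
    # omega_ij = int RSF_i * w_j: rows index the RSF, columns the sampling VOI
    omega = _flat_weights(rsfs.rsfs) @ wf.T * vv
    t = wf @ pet_image.values.ravel() * vv
    return TransferSystem(omega, t, method, list(rsfs.region_names))


def build_system_sgtm(
    rsfs: RSFSet,
    pet_image: ActivityVolume,
    fov_weight: np.ndarray | None = None,
    method: str = "sGTM",
) -> TransferSystem:
    """Eq.-(3)-style symmetric system: sample with the RSFs themselves."""
    if pet_image.shape != rsfs.grid_shape:
        raise ValueError("RSFs and PET image must share the PET grid")
    w = rsfs.rsfs if fov_weight is None else rsfs.rsfs * fov_weight
    vv = pet_image.voxel_volume
    wf = _flat_weights(w)
    # omega_ij = int fov * RSF_i * RSF_j: symmetric regardless of fov weight
    omega = (_flat_weights(rsfs.rsfs) @ wf.T) * vv
    omega = 0.5 * (omega + omega.T)  # remove fp summation-order asymmetry
    t = wf @ pet_image.values.ravel() * vv
    return TransferSystem(omega, t, method, list(rsfs.region_names))


def solve_pvc(
    system: TransferSystem,
    cond_warn_threshold: float = 1e6,
    ridge: float = 0.0,
) -> TransferSystem:
    """Solve omega T = t by a direct dense solve (no explicit inverse).

    Records the condition number and logs a warning above the threshold.
    An optional ridge term (off by default) stabilizes near-singular
    systems; the classical methods use the plain solve.
    """
    omega = system.omega
    if ridge > 0:
        omega = omega + ridge * np.eye(len(system.t))
    cond = float(np.linalg.cond(omega))
    if not np.isfinite(cond):
        raise ValueError(
            "weighting matrix is singular; merge indistinguishable regions"
        )
    if cond > cond_warn_threshold:
        logger.warning(
            "transfer matrix condition number %.3g exceeds %.1g; corrected "
            "uptakes may be noise-sensitive (consider merging regions)",
            cond,
            cond_warn_threshold,
        )
    try:
        T = np.linalg.solve(omega, system.t)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "weighting matrix is singular; merge indistinguishable regions"
        ) from exc
    system.T = T
    system.condition_number = cond
    return system


# ---------------------------------------------------------------------------
# model / results objects


@dataclass
class PVCConfig:
    """Shared configuration for building PVC models.

    ``psf_fwhm`` (mm, x/y/z) drives the image-space methods; ``blur``
    (a calibrated :class:`BlurModel`) plus ``geometry``/``filter_name``
    drive the sinogram-space methods.  ``rsf_cache`` lets several
    methods on the same masks share RSF computations.
    """

    psf_fwhm: tuple[float, float, float] | None = None
    blur: BlurModel | None = None
    geometry: ParallelGeometry = field(default_factory=ParallelGeometry)
    filter_name: str = "hann"
    binarize_masks: bool = False
    unity_tol: float = 0.005
    rsf_cache: dict = field(default_factory=dict)


class RegionPVC:
    """Region-based PVC model: a PET image observed through known regions.

    Parameters
    ----------
    pet_image : ActivityVolume
        The measured (or simulated) PET image.
    masks : ndarray (n_regions, nx, ny, nz), optional
        Tissue-fraction masks on the PET grid, a partition of unity.
        Either ``masks`` (+ ``region_names``) or ``labels`` must be given.
    labels : LabelVolume, optional
        Fine-grid segmentation; downsampled to the PET grid internally.
    method : {"GTM", "sGTM", "GTMo", "sGTMo"}
    config : PVCConfig
        PSF / blur / geometry settings (see :class:`PVCConfig`).
    fov_weight : ndarray, optional
        Voxelwise weight restricting the sampling integrals to a local
        field of view.
    rsfs : RSFSet, optional
        Precomputed spread functions (skips the expensive step).

    Examples
    --------
    >>> model = RegionPVC(pet, labels=ct_labels, method="sGTMo",
    ...                   config=PVCConfig(blur=calibrated_blur))
    >>> res = model.fit()
    >>> res.uptakes
    """

    def __init__(
        self,
        pet_image: ActivityVolume,
        masks: np.ndarray | None = None,
        region_names: list[str] | None = None,
        labels: LabelVolume | None = None,
        method: str = "GTM",
        config: PVCConfig | None = None,
        fov_weight: np.ndarray | None = None,
        rsfs: RSFSet | None = None,
    ) -> None:
        if method not in METHODS:
            raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
        self.method = method
        self.config = config or PVCConfig()
        self.pet_image = pet_image
        if masks is None:
            if labels is None:
                raise ValueError("provide either masks or a fine-grid label volume")
            masks, region_names = downsample_masks(
                labels, pet_image.voxel_size, pet_image.shape
            )
        masks = np.asarray(masks, dtype=float)
        if self.config.binarize_masks:
            masks = (masks >= 0.5).astype(float)
        self.masks = masks
        self.region_names = list(
            region_names
            if region_names is not None
            else (f"region{i}" for i in range(masks.shape[0]))
        )
        self.fov_weight = fov_weight
        self._rsfs = rsfs
        self._omega_system: TransferSystem | None = None

    # -- lazy heavy pieces -------------------------------------------------

    @property
    def rsfs(self) -> RSFSet:
        if self._rsfs is None:
            cfg = self.config
            space = "image-space" if _IMAGE_SPACE[self.method] else "sinogram-space"
            cached = cfg.rsf_cache.get(space)
            if cached is not None and cached.rsfs.shape == self.masks.shape:
                self._rsfs = cached
            elif space == "image-space":
                if cfg.psf_fwhm is None:
                    raise ValueError(f"{self.method} requires config.psf_fwhm")
                self._rsfs = compute_rsf_image_space(
                    self.masks, self.region_names, cfg.psf_fwhm, self.pet_image.voxel_size
                )
            else:
                if cfg.blur is None:
                    raise ValueError(f"{self.method} requires a calibrated config.blur")
                self._rsfs = compute_rsf_sinogram_space(
                    self.masks,
                    self.region_names,
                    cfg.blur,
                    self.pet_image.voxel_size,
                    cfg.geometry,
                    cfg.filter_name,
                    cfg.unity_tol,
                )
            cfg.rsf_cache.setdefault(space, self._rsfs)
        return self._rsfs

    def _build(self, pet_image: ActivityVolume) -> TransferSystem:
        if _SYMMETRIC[self.method]:
            return build_system_sgtm(self.rsfs, pet_image, self.fov_weight, self.method)
        return build_system_gtm(
            self.rsfs, self.masks, pet_image, self.fov_weight, self.method
        )

    # -- fitting -----------------------------------------------------------

    def fit(self, sigma_noise: float | None = None) -> "PVCResults":
        """Build the transfer system, solve it and wrap the results.

        ``sigma_noise`` (activity units per voxel) enables analytic
        standard errors under iid stationary voxel noise.
        """
        system = solve_pvc(self._build(self.pet_image))
        self._omega_system = system
        return PVCResults(self, system, sigma_noise)

    def refit(self, pet_image: ActivityVolume, sigma_noise: float | None = None) -> "PVCResults":
        """Re-solve for a new PET image reusing masks, RSFs and omega.

        The weighting matrix depends only on the region model, so for
        Monte-Carlo noise studies only the sampled vector t is updated.
        """
        if pet_image.shape != self.pet_image.shape:
            raise ValueError("new image must share the PET grid")
        base = self._omega_system
        if base is None:
            base = solve_pvc(self._build(self.pet_image))
            self._omega_system = base
        w = self.rsfs.rsfs if _SYMMETRIC[self.method] else self.masks
        if self.fov_weight is not None:
            w = w * self.fov_weight
        t = _flat_weights(w) @ pet_image.values.ravel() * pet_image.voxel_volume
        system = TransferSystem(
            base.omega.copy(), t, self.method, list(self.region_names)
        )
        system.condition_number = base.condition_number
        system.T = np.linalg.solve(base.omega, t)
        return PVCResults(self, system, sigma_noise)


class PVCResults:
    """Corrected regional uptakes and diagnostics of one PVC solve."""

    def __init__(
        self, model: RegionPVC, system: TransferSystem, sigma_noise: float | None = None
    ) -> None:
        self.model = model
        self.system = system
        self.sigma_noise = sigma_noise
        self._cov: np.ndarray | None = None
        if sigma_noise is not None:
            self._cov = self._analytic_cov(sigma_noise)

    # convenient views ------------------------------------------------------

    @property
    def uptakes(self) -> np.ndarray:
        """Corrected regional uptakes T (activity units of the input)."""
        return self.system.T

    @property
    def sampled(self) -> np.ndarray:
        """Raw sampled regional values t (before correction)."""
        return self.system.t

    @property
    def omega(self) -> np.ndarray:
        return self.system.omega

    @property
    def condition_number(self) -> float:
        return self.system.condition_number

    @property
    def region_names(self) -> list[str]:
        return self.system.region_names

    @property
    def rsfs(self) -> RSFSet:
        return self.model.rsfs

    def _analytic_cov(self, sigma: float) -> np.ndarray:
        """cov(T) for iid voxel noise of std sigma: omega^-1 S omega^-T."""
        w = (
            self.model.rsfs.rsfs
            if _SYMMETRIC[self.model.method]
            else self.model.masks
        )
        if self.model.fov_weight is not None:
            w = w * self.model.fov_weight
        wf = _flat_weights(w)
        vv = self.model.pet_image.voxel_volume
        cov_t = (wf @ wf.T) * (sigma * vv) ** 2
        inv = np.linalg.inv(self.system.omega)
        return inv @ cov_t @ inv.T

    @property
    def bse(self) -> np.ndarray | None:
        """Analytic standard errors of T (requires sigma_noise at fit)."""
        if self._cov is None:
            return None
        return np.sqrt(np.diag(self._cov))

    def summary(self) -> str:
        """Plain-text summary table of the correction."""
        lines = [
            f"Region-based PVC ({self.system.method}, "
            f"{self.model.rsfs.method_tag} RSFs)",
            f"regions: {len(self.region_names)}   "
            f"condition number: {self.condition_number:.3g}",
            "",
            f"{'region':<20}{'sampled t':>14}{'corrected T':>14}"
            + ("" if self.bse is None else f"{'se(T)':>12}"),
        ]
        for i, name in enumerate(self.region_names):
            row = f"{name:<20}{self.system.t[i]:>14.5g}{self.system.T[i]:>14.5g}"
            if self.bse is not None:
                row += f"{self.bse[i]:>12.3g}"
            lines.append(row)
        return "\n".join(lines)

    def to_dict(self) -> dict:
        out = {
            "method": self.system.method,
            "regions": self.region_names,
            "omega": self.system.omega.tolist(),
            "t": self.system.t.tolist(),
            "T": self.system.T.tolist(),
            "condition_number": self.condition_number,
        }
        if self.bse is not None:
            out["se_T"] = self.bse.tolist()
        return out


def apply_pvc(
    pet_image: ActivityVolume,
    labels_fine: LabelVolume,
    method: str,
    config: PVCConfig | None = None,
    fov_weight: np.ndarray | None = None,
) -> PVCResults:
    """One-call orchestration: downsample masks, compute RSFs, build, solve."""
    model = RegionPVC(
        pet_image, labels=labels_fine, method=method, config=config, fov_weight=fov_weight
    )
    return model.fit()
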