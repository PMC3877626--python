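"""Monte-Carlo evaluation harness for the four PVC methods.

Reproduces the simulation experiments the methods are characterized
with: accuracy and precision of recovery coefficients (RC) over noisy
realizations, noise magnification factors (NMF), and robustness of the
correction to mask/PET misregistration.

A :class:`PhantomStudy` bundles a phantom's fine-grid truth, its
PET-grid tissue-fraction masks and the transfer systems to solve.  For
the sphere tank each sphere gets its own 3x3 system (hot interior, cold
wall, shared tank background) with the sampling integrals restricted to
a local cylinder extending 20 mm beyond the sphere wall; the brain
phantom is a single 6x6 system over the whole field of view.

Definitions
-----------
recovery coefficient
    RC = measured activity within the VOI / true activity within the
    VOI; corrected RC uses the solved uptake T_i against the true
    uptake, uncorrected RC the mean image value in the
    (tissue-fraction-weighted) VOI.  Regions of zero true uptake
    (sphere walls, brain background) have no RC; their absolute
    corrected uptake is reported instead.
noise magnification factor
    NMF = CV(T_i) / CV(t_i) across realizations, each method judged
    against its own raw sample t_i (mask-weighted for GTM/GTMo,
    RSF-weighted for sGTM/sGTMo).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .model import METHODS, PVCConfig, RegionPVC, _IMAGE_SPACE
from .phantoms import (
    PhantomSpec,
    default_brain_spec,
    default_sphere_spec,
    downsample_masks,
    downsample_to_pet,
    make_brain_phantom,
    make_sphere_phantom,
    shift_labels,
    sphere_local_fov,
)
from .projector import BlurModel, calibrate_blur, fwhm_to_sigma, simulate_acquisition
from .rsf import compute_rsf_image_space, compute_rsf_sinogram_space
from .volumes import ActivityVolume, LabelVolume

__all__ = [
    "DEFAULT_PSF_FWHM",
    "SystemDef",
    "PhantomStudy",
    "ExperimentResult",
    "build_sphere_study",
    "build_brain_study",
    "default_config",
    "recovery_coefficient",
    "noise_magnification",
    "run_accuracy_experiment",
    "run_misregistration_experiment",
]

#: Measured scanner PSF FWHMs (mm, x/y/z) the simulations emulate.
DEFAULT_PSF_FWHM = (7.23, 7.14, 6.65)


def recovery_coefficient(measured: float, truth: float) -> float:
    """RC = measured activity within the VOI over true activity (ideal: 1)."""
    if truth == 0:
        raise ValueError(
            "RC is undefined for a zero-uptake region; report the absolute "
            "corrected uptake instead"
        )
    return float(measured) / float(truth)


def noise_magnification(T_samples, t_samples) -> float:
    """NMF = CV(T)/CV(t) across realizations (coefficient-of-variation ratio)."""
    T = np.asarray(T_samples, dtype=float)
    t = np.asarray(t_samples, dtype=float)
    if T.shape != t.shape or T.ndim != 1:
        raise ValueError("need matching 1D per-realization samples of T and t")
    if len(T) < 2:
        raise ValueError("need at least 2 realizations to estimate a CV")
    mT, mt = np.abs(T.mean()), np.abs(t.mean())
    if mT == 0 or mt == 0:
        raise ValueError("CV undefined: zero mean sample")
    return float((T.std(ddof=1) / mT) / (t.std(ddof=1) / mt))


# ---------------------------------------------------------------------------
# studies


@dataclass
class SystemDef:
    """One transfer system: which regions, over which local FOV weight."""

    name: str
    region_indices: list[int]
    fov_weight: np.ndarray | None = None


@dataclass
class PhantomStudy:
    """A phantom prepared for Monte-Carlo PVC evaluation."""

    name: str
    spec: PhantomSpec
    labels_fine: LabelVolume
    activity_fine: ActivityVolume
    masks: np.ndarray
    region_names: list[str]
    truth: np.ndarray
    systems: list[SystemDef]
    ideal_pet: ActivityVolume
    noise_reference: float

    @property
    def pet_shape(self):
        return self.ideal_pet.shape

    @property
    def pet_voxel(self):
        return self.ideal_pet.voxel_size


def _study_from_phantom(
    name: str,
    spec: PhantomSpec,
    labels: LabelVolume,
    activity: ActivityVolume,
    systems_for,
) -> PhantomStudy:
    pet_voxel = spec.voxel_size_pet
    extent = np.asarray(spec.grid_shape) * np.asarray(spec.voxel_size_fine)
    pet_shape = tuple(int(np.floor(e / v + 1e-9)) for e, v in zip(extent, pet_voxel))
    masks, names = downsample_masks(labels, pet_voxel, pet_shape)
    truth = np.array([spec.uptake_map[n] for n in names])
    ideal_pet = downsample_to_pet(activity, pet_voxel, pet_shape)
    # noise reference: tank background mean where it exists, else the mean
    # uptake over nonzero-uptake tissue of the ideal PET-grid image
    if truth[0] > 0:  # background is the warm tank
        ref_mask = masks[0]
    else:
        ref_mask = (truth[:, None, None, None] > 0) * masks
        ref_mask = ref_mask.sum(axis=0)
    ref = float((ideal_pet.values * ref_mask).sum() / ref_mask.sum())
    return PhantomStudy(
        name=name,
        spec=spec,
        labels_fine=labels,
        activity_fine=activity,
        masks=masks,
        region_names=names,
        truth=truth,
        systems=systems_for(names, masks),
        ideal_pet=ideal_pet,
        noise_reference=ref,
    )


def build_sphere_study(
    spec: PhantomSpec | None = None, background_margin_mm: float = 20.0
) -> PhantomStudy:
    """Sphere-tank study: one local 3x3 system per sphere.

    Each system holds {inner sphere, wall, tank background} and weights
    its integrals with a cylinder extending ``background_margin_mm``
    beyond the outer wall, as in the physical-phantom analysis.
    """
    spec = spec or default_sphere_spec()
    labels, activity = make_sphere_phantom(spec)
    pet_voxel = spec.voxel_size_pet
    extent = np.asarray(spec.grid_shape) * np.asarray(spec.voxel_size_fine)
    pet_shape = tuple(int(np.floor(e / v + 1e-9)) for e, v in zip(extent, pet_voxel))

    def systems_for(names, masks):
        systems = []
        for k, sphere in enumerate(spec.region_defs):
            inner_id, wall_id = 2 * k + 1, 2 * k + 2
            fov_fine = sphere_local_fov(
                sphere, spec.grid_shape, spec.voxel_size_fine, background_margin_mm
            )
            fov = downsample_to_pet(fov_fine, pet_voxel, pet_shape).values
            systems.append(SystemDef(sphere.name, [inner_id, wall_id, 0], fov))
        return systems

    return _study_from_phantom("spheres", spec, labels, activity, systems_for)


def build_brain_study(
    spec: PhantomSpec | None = None, atlas: LabelVolume | None = None
) -> PhantomStudy:
    """Brain study: a single 6x6 system over the full field of view."""
    spec = spec or default_brain_spec()
    labels, activity = make_brain_phantom(spec, atlas)
    return _study_from_phantom(
        "brain",
        spec,
        labels,
        activity,
        lambda names, masks: [SystemDef("brain", list(range(len(names))), None)],
    )


def default_config(
    study: PhantomStudy,
    psf_fwhm=DEFAULT_PSF_FWHM,
    need_sinogram: bool = True,
    filter_name: str = "hann",
) -> PVCConfig:
    """A PVCConfig with the blur calibrated against the target PSF."""
    blur = (
        calibrate_blur(
            psf_fwhm,
            grid_shape=study.pet_shape,
            voxel_size=study.pet_voxel,
            filter_name=filter_name,
        )
        if need_sinogram
        else None
    )
    return PVCConfig(psf_fwhm=psf_fwhm, blur=blur, filter_name=filter_name)


# ---------------------------------------------------------------------------
# experiments


@dataclass
class ExperimentResult:
    """Tables of RC / NMF / misregistration curves plus the run snapshot."""

    rc: pd.DataFrame
    nmf: pd.DataFrame | None
    shift_curves: pd.DataFrame | None
    config: dict = field(default_factory=dict)
    seed: int = 0
    n_realizations: int = 1
    extras: dict = field(default_factory=dict)


def _noiseless_images(study: PhantomStudy, config: PVCConfig, methods) -> dict:
    """The noise-free simulated PET image of each RSF branch."""
    images = {}
    if any(_IMAGE_SPACE[m] for m in methods):
        sigma_vox = fwhm_to_sigma(config.psf_fwhm) / np.asarray(study.pet_voxel)
        images["image-space"] = study.ideal_pet.with_values(
            gaussian_filter(study.ideal_pet.values, sigma_vox, mode="nearest", truncate=6.0)
        )
    if any(not _IMAGE_SPACE[m] for m in methods):
        images["sinogram-space"] = simulate_acquisition(
            study.ideal_pet, config.blur, config.geometry, config.filter_name
        )
    return images


def _global_rsfs(study: PhantomStudy, config: PVCConfig, methods) -> dict:
    """RSF sets of the full region partition, cached on the config."""
    rsfs = {}
    for space, wanted in (
        ("image-space", any(_IMAGE_SPACE[m] for m in methods)),
        ("sinogram-space", any(not _IMAGE_SPACE[m] for m in methods)),
    ):
        if not wanted:
            continue
        key = (space, tuple(study.region_names))
        cached = config.rsf_cache.get(key)
        if cached is not None and cached.grid_shape == tuple(study.pet_shape):
            rsfs[space] = cached
            continue
        if space == "image-space":
            rsfs[space] = compute_rsf_image_space(
                study.masks, study.region_names, config.psf_fwhm, study.pet_voxel
            )
        else:
            rsfs[space] = compute_rsf_sinogram_space(
                study.masks,
                study.region_names,
                config.blur,
                study.pet_voxel,
                config.geometry,
                config.filter_name,
                config.unity_tol,
            )
        config.rsf_cache[key] = rsfs[space]
    return rsfs


def _build_models(study, config, methods, images, rsfs) -> dict:
    models = {}
    for m in methods:
        space = "image-space" if _IMAGE_SPACE[m] else "sinogram-space"
        for sysdef in study.systems:
            idx = sysdef.region_indices
            models[(m, sysdef.name)] = RegionPVC(
                images[space],
                masks=study.masks[idx],
                region_names=[study.region_names[i] for i in idx],
                method=m,
                config=config,
                fov_weight=sysdef.fov_weight,
                rsfs=rsfs[space].subset(idx),
            )
    return models


def _noise_streams(seed: int, n_realizations: int):
    root = np.random.SeedSequence(seed)
    return [child.spawn(2) for child in root.spawn(n_realizations)]


def _noisy(images: dict, study, config_noise: float, streams_r) -> dict:
    out = {}
    for branch_i, space in enumerate(("image-space", "sinogram-space")):
        if space in images:
            rng = np.random.default_rng(streams_r[branch_i])
            noise = rng.normal(
                0.0, config_noise * study.noise_reference, size=images[space].shape
            )
            out[space] = images[space].with_values(images[space].values + noise)
    return out


def run_accuracy_experiment(
    study: PhantomStudy,
    methods=METHODS,
    n_realizations: int = 100,
    seed: int = 0,
    config: PVCConfig | None = None,
    include_uncorrected: bool = True,
) -> ExperimentResult:
    """RC accuracy/precision and NMF over noisy realizations.

    Simulates ``n_realizations`` noisy PET images per RSF branch
    (stationary Gaussian noise at the study's noise fraction), applies
    every method to every system of the study, and tabulates the RC
    mean +- std and the NMF per (method, system, region).
    """
    if n_realizations < 1:
        raise ValueError("n_realizations must be >= 1")
    if config is None:
        config = default_config(study, need_sinogram=any(not _IMAGE_SPACE[m] for m in methods))
    images = _noiseless_images(study, config, methods)
    rsfs = _global_rsfs(study, config, methods)
    models = _build_models(study, config, methods, images, rsfs)
    for model in models.values():
        model.fit()

    streams = _noise_streams(seed, n_realizations)
    frac = study.spec.noise_fraction
    samples: dict[tuple, dict[str, list]] = {
        key: {"T": [], "t": []} for key in models
    }
    unc: dict[tuple, list] = {}
    for r in range(n_realizations):
        noisy = _noisy(images, study, frac, streams[r])
        for (m, sysname), model in models.items():
            space = "image-space" if _IMAGE_SPACE[m] else "sinogram-space"
            res = model.refit(noisy[space])
            samples[(m, sysname)]["T"].append(res.uptakes)
            samples[(m, sysname)]["t"].append(res.sampled)
        if include_uncorrected:
            for sysdef in study.systems:
                key = ("none", sysdef.name)
                idx = sysdef.region_indices
                w = study.masks[idx]
                if sysdef.fov_weight is not None:
                    w = w * sysdef.fov_weight
                wf = w.reshape(len(idx), -1)
                vols = wf.sum(axis=1)
                means = []
                for space in ("image-space", "sinogram-space"):
                    if space in noisy:
                        means.append(wf @ noisy[space].values.ravel() / vols)
                unc.setdefault(key, []).append(np.mean(means, axis=0))

    rc_rows, nmf_rows = [], []
    for (m, sysname), s in samples.items():
        T = np.asarray(s["T"])
        t = np.asarray(s["t"])
        sysdef = next(sd for sd in study.systems if sd.name == sysname)
        for j, gi in enumerate(sysdef.region_indices):
            name = study.region_names[gi]
            truth = study.truth[gi]
            row = dict(method=m, system=sysname, region=name, truth=truth, n=n_realizations)
            if truth > 0:
                rc = T[:, j] / truth
                row.update(rc_mean=rc.mean(), rc_std=rc.std(ddof=1) if len(rc) > 1 else 0.0)
            else:
                row.update(rc_mean=np.nan, rc_std=np.nan)
            row.update(T_mean=T[:, j].mean(), T_std=T[:, j].std(ddof=1) if len(T) > 1 else 0.0)
            rc_rows.append(row)
            if n_realizations >= 2 and truth > 0:
                nmf_rows.append(
                    dict(
                        method=m,
                        system=sysname,
                        region=name,
                        nmf=noise_magnification(T[:, j], t[:, j]),
                        n=n_realizations,
                    )
                )
    for key, vals in unc.items():
        _, sysname = key
        sysdef = next(sd for sd in study.systems if sd.name == sysname)
        V = np.asarray(vals)
        for j, gi in enumerate(sysdef.region_indices):
            truth = study.truth[gi]
            if truth <= 0:
                continue
            rc = V[:, j] / truth
            rc_rows.append(
                dict(
                    method="none",
                    system=sysname,
                    region=study.region_names[gi],
                    truth=truth,
                    n=n_realizations,
                    rc_mean=rc.mean(),
                    rc_std=rc.std(ddof=1) if len(rc) > 1 else 0.0,
                    T_mean=V[:, j].mean(),
                    T_std=V[:, j].std(ddof=1) if len(V) > 1 else 0.0,
                )
            )

    return ExperimentResult(
        rc=pd.DataFrame(rc_rows),
        nmf=pd.DataFrame(nmf_rows) if nmf_rows else None,
        shift_curves=None,
        config=_config_snapshot(study, config, methods),
        seed=seed,
        n_realizations=n_realizations,
    )


def _shift_values_edge(values: np.ndarray, steps: tuple[int, int, int]) -> np.ndarray:
    """Integer-voxel shift with replicate fill at the trailing boundary."""
    out = values
    for axis, k in enumerate(steps):
        if k == 0:
            continue
        pad = [(0, 0)] * 3
        pad[axis] = (k, 0) if k > 0 else (0, -k)
        padded = np.pad(out, pad, mode="edge")
        sl = [slice(None)] * 3
        sl[axis] = slice(0, values.shape[axis]) if k > 0 else slice(-k, None)
        out = padded[tuple(sl)]
    return out


def run_misregistration_experiment(
    study: PhantomStudy,
    methods=METHODS,
    shifts_mm=(0.0, 2.0, 4.0, 6.0, 8.0, 10.0),
    axis: int | str = 0,
    n_realizations: int = 25,
    seed: int = 0,
    config: PVCConfig | None = None,
    mode: str = "image",
) -> ExperimentResult:
    """Normalized RC versus mask/PET misregistration along one axis.

    ``mode="image"`` (default) realizes the relative misregistration by
    shifting the PET image against the fixed mask frame: the RSFs and
    the weighting matrix are untouched (registration errors affect only
    the sampled t values, which this mode makes exact by construction)
    and shifts are rounded to whole PET voxels.  ``mode="labels"``
    shifts the fine-grid labels, re-downsamples and recomputes the RSFs
    per shift -- the literal acquisition-side procedure, at
    fine-voxel granularity but with a full RSF recomputation per shift.

    RC curves are normalized to the zero-shift RC of the same
    method/region.  The per-shift weighting matrices are stored in
    ``extras["omega"]`` keyed by ``(method, system, shift)``.
    """
    axis = {"x": 0, "y": 1, "z": 2}.get(axis, axis)
    if mode not in ("image", "labels"):
        raise ValueError("mode must be 'image' or 'labels'")
    if config is None:
        config = default_config(study, need_sinogram=any(not _IMAGE_SPACE[m] for m in methods))
    images = _noiseless_images(study, config, methods)
    rsfs = _global_rsfs(study, config, methods)
    models = _build_models(study, config, methods, images, rsfs)
    for model in models.values():
        model.fit()

    streams = _noise_streams(seed, n_realizations)
    frac = study.spec.noise_fraction
    noisy_list = [_noisy(images, study, frac, streams[r]) for r in range(n_realizations)]

    rows = []
    omegas = {}
    for shift in shifts_mm:
        if mode == "image":
            vox = study.pet_voxel[axis]
            steps = [0, 0, 0]
            steps[axis] = -int(round(shift / vox))  # mask +s == image -s
            shift_models = models
            shifted_noisy = [
                {
                    space: img.with_values(_shift_values_edge(img.values, steps))
                    for space, img in noisy.items()
                }
                for noisy in noisy_list
            ]
        else:
            dvec = [0.0, 0.0, 0.0]
            dvec[axis] = shift
            shifted_labels = shift_labels(study.labels_fine, dvec)
            masks, names = downsample_masks(
                shifted_labels, study.pet_voxel, study.pet_shape
            )
            shifted_study = PhantomStudy(
                study.name,
                study.spec,
                shifted_labels,
                study.activity_fine,
                masks,
                names,
                study.truth,
                study.systems,
                study.ideal_pet,
                study.noise_reference,
            )
            cfg = PVCConfig(
                psf_fwhm=config.psf_fwhm,
                blur=config.blur,
                geometry=config.geometry,
                filter_name=config.filter_name,
                unity_tol=config.unity_tol,
            )
            shift_rsfs = _global_rsfs(shifted_study, cfg, methods)
            shift_models = _build_models(shifted_study, cfg, methods, images, shift_rsfs)
            for model in shift_models.values():
                model.fit()
            shifted_noisy = noisy_list

        for (m, sysname), model in shift_models.items():
            space = "image-space" if _IMAGE_SPACE[m] else "sinogram-space"
            T = np.asarray(
                [model.refit(noisy[space]).uptakes for noisy in shifted_noisy]
            )
            omegas[(m, sysname, float(shift))] = model._omega_system.omega.copy()
            sysdef = next(sd for sd in study.systems if sd.name == sysname)
            for j, gi in enumerate(sysdef.region_indices):
                truth = study.truth[gi]
                if truth <= 0:
                    continue
                rc = T[:, j] / truth
                rows.append(
                    dict(
                        method=m,
                        system=sysname,
                        region=study.region_names[gi],
                        axis="xyz"[axis],
                        shift_mm=float(shift),
                        rc_mean=rc.mean(),
                        rc_std=rc.std(ddof=1) if len(rc) > 1 else 0.0,
                        n=n_realizations,
                    )
                )

    curves = pd.DataFrame(rows)
    base = curves[curves.shift_mm == 0].set_index(["method", "system", "region"]).rc_mean
    curves["rc_norm"] = [
        row.rc_mean / base.loc[(row.method, row.system, row.region)]
        for row in curves.itertuples()
    ]
    return ExperimentResult(
        rc=curves[curves.shift_mm == 0].copy(),
        nmf=None,
        shift_curves=curves,
        config=_config_snapshot(study, config, methods)
        | {"mode": mode, "axis": "xyz"[axis], "shifts_mm": list(map(float, shifts_mm))},
        seed=seed,
        n_realizations=n_realizations,
        extras={"omega": omegas},
    )


def _config_snapshot(study: PhantomStudy, config: PVCConfig, methods) -> dict:
    blur = config.blur
    return {
        "phantom": study.name,
        "pet_shape": list(study.pet_shape),
        "pet_voxel_mm": list(study.pet_voxel),
        "noise_fraction": study.spec.noise_fraction,
        "noise_reference": study.noise_reference,
        "methods": list(methods),
        "psf_fwhm_mm": list(config.psf_fwhm) if config.psf_fwhm is not None else None,
        "blur_sigma_mm": [blur.sigma_radial, blur.sigma_axial] if blur else None,
        "blur_fitted_fwhm_mm": list(blur.fitted_fwhm) if blur and blur.fitted_fwhm else None,
        "filter": config.filter_name,
        "n_angles": config.geometry.n_angles,
    }
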