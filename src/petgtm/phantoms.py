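"""Digital phantoms for PET partial-volume studies.

Two families of phantom are provided:

* a **sphere tank**: hollow spheres (hot interior, cold wall) of 5-30 mm
  inner diameter suspended in a uniform warm background, built on a fine
  0.6 mm isotropic grid from analytic geometry evaluated at voxel centers;
* a **brain**: a six-region labelled head (putamen, caudate, skin/muscle,
  grey matter, white matter, background) with striatal-tracer relative
  uptakes, either from a user-supplied labelled atlas or from the built-in
  procedural surrogate made of nested ellipsoids.

The fine-grid label volumes are converted to PET-resolution
tissue-fraction masks by :func:`downsample_to_pet` (trilinear
interpolation at PET voxel centers; optional box-average antialiasing),
which models the tissue fraction effect.  Stationary
Gaussian noise is added post-reconstruction by :func:`add_noise`, and
:func:`shift_labels` applies rigid mask translations for misregistration
experiments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates, uniform_filter1d

from .volumes import ActivityVolume, LabelVolume

__all__ = [
    "SphereDef",
    "PhantomSpec",
    "default_sphere_spec",
    "default_brain_spec",
    "make_sphere_phantom",
    "make_brain_phantom",
    "surrogate_brain_atlas",
    "downsample_to_pet",
    "downsample_masks",
    "add_noise",
    "shift_labels",
    "sphere_local_fov",
]

#: PET grid used throughout the simulation studies (64 x 64 x 48 voxels
#: of 2 x 2 x 3.15 mm), a scaled-down analog of a clinical whole-body FOV.
DEFAULT_PET_SHAPE = (64, 64, 48)
DEFAULT_PET_VOXEL = (2.0, 2.0, 3.15)

#: Sphere-to-background uptake ratio of the tank phantom.
SPHERE_UPTAKE = 3.0
BACKGROUND_UPTAKE = 1.0

#: Relative uptakes of the brain regions (striatal tracer).
BRAIN_UPTAKES = {
    "putamen": 4.5,
    "caudate": 4.0,
    "skin_muscle": 1.0,
    "grey_matter": 2.5,
    "white_matter": 2.0,
    "background": 0.0,
}


@dataclass(frozen=True)
class SphereDef:
    """A hollow sphere: hot interior of ``inner_diameter``, cold wall."""

    name: str
    center: tuple[float, float, float]  # mm
    inner_diameter: float  # mm
    wall_thickness: float = 0.6  # mm

    @property
    def inner_radius(self) -> float:
        return self.inner_diameter / 2.0

    @property
    def outer_radius(self) -> float:
        return self.inner_radius + self.wall_thickness


@dataclass
class PhantomSpec:
    """Full description of a simulated phantom study.

    ``grid_shape``/``voxel_size_fine`` define the anatomical (CT/MR-like)
    grid, ``voxel_size_pet`` the PET grid the masks are decimated to.
    ``region_defs`` holds the geometric primitives (:class:`SphereDef`
    list for the tank phantom; ignored when an atlas is supplied).
    ``noise_fraction`` is the std of the added stationary Gaussian noise
    relative to the reference-region mean.
    """

    grid_shape: tuple[int, int, int]
    voxel_size_fine: tuple[float, float, float]
    voxel_size_pet: tuple[float, float, float]
    region_defs: list = field(default_factory=list)
    uptake_map: dict[str, float] = field(default_factory=dict)
    noise_fraction: float = 0.25
    n_realizations: int = 100
    rng_seed: int = 0

    def __post_init__(self) -> None:
        fine = np.asarray(self.voxel_size_fine, float)
        pet = np.asarray(self.voxel_size_pet, float)
        if np.any(fine <= 0) or np.any(pet <= 0):
            raise ValueError("voxel sizes must be positive")
        if np.any(pet < fine):
            raise ValueError(
                f"PET voxel size {tuple(pet)} must be >= fine voxel size "
                f"{tuple(fine)} on every axis"
            )
        if any(u < 0 for u in self.uptake_map.values()):
            raise ValueError("uptake values must be non-negative")
        names = [getattr(r, "name", None) for r in self.region_defs]
        if len(names) != len(set(names)):
            raise ValueError("region names must be unique")
        if self.noise_fraction < 0:
            raise ValueError("noise_fraction must be >= 0")
        if self.n_realizations < 1:
            raise ValueError("n_realizations must be >= 1")

    @property
    def fine_extent(self) -> np.ndarray:
        return np.asarray(self.grid_shape) * np.asarray(self.voxel_size_fine)


def _pet_extent(pet_shape, pet_voxel) -> np.ndarray:
    return np.asarray(pet_shape) * np.asarray(pet_voxel)


def default_sphere_spec(
    pet_shape=DEFAULT_PET_SHAPE,
    pet_voxel=DEFAULT_PET_VOXEL,
    fine_voxel=(0.6, 0.6, 0.6),
    diameters=(5.0, 8.0, 13.0, 17.0, 22.0, 30.0),
    noise_fraction=0.25,
    n_realizations=100,
    rng_seed=0,
) -> PhantomSpec:
    """The six-sphere tank phantom on the default scaled PET grid.

    The spheres sit on two axial planes (three per plane, on a 26 mm
    ring around the tank axis) so that each sphere's 20 mm-margin
    background cylinder fits inside the grid and the spheres are
    pairwise well separated.
    """
    extent = _pet_extent(pet_shape, pet_voxel)
    cx, cy, cz = extent / 2.0
    ring = 26.0
    dz = 37.0
    placements = [  # (diameter, angle deg, z offset)
        (diameters[5], 0.0, -dz),
        (diameters[3], 120.0, -dz),
        (diameters[1], 240.0, -dz),
        (diameters[4], 60.0, +dz),
        (diameters[2], 180.0, +dz),
        (diameters[0], 300.0, +dz),
    ]
    spheres = []
    for d, ang, zoff in placements:
        a = np.deg2rad(ang)
        spheres.append(
            SphereDef(
                name=f"sphere{d:g}",
                center=(cx + ring * np.cos(a), cy + ring * np.sin(a), cz + zoff),
                inner_diameter=d,
            )
        )
    spheres.sort(key=lambda s: s.inner_diameter)
    uptakes = {"background": BACKGROUND_UPTAKE}
    for s in spheres:
        uptakes[f"{s.name}_inner"] = SPHERE_UPTAKE
        uptakes[f"{s.name}_wall"] = 0.0
    fine_shape = tuple(int(np.ceil(e / v)) for e, v in zip(extent, fine_voxel))
    return PhantomSpec(
        grid_shape=fine_shape,
        voxel_size_fine=fine_voxel,
        voxel_size_pet=pet_voxel,
        region_defs=spheres,
        uptake_map=uptakes,
        noise_fraction=noise_fraction,
        n_realizations=n_realizations,
        rng_seed=rng_seed,
    )


def default_brain_spec(
    pet_shape=DEFAULT_PET_SHAPE,
    pet_voxel=DEFAULT_PET_VOXEL,
    fine_voxel=(1.1, 1.1, 1.4),
    noise_fraction=0.25,
    n_realizations=100,
    rng_seed=0,
) -> PhantomSpec:
    """The six-region brain phantom on the default scaled PET grid."""
    extent = _pet_extent(pet_shape, pet_voxel)
    fine_shape = tuple(int(np.ceil(e / v)) for e, v in zip(extent, fine_voxel))
    return PhantomSpec(
        grid_shape=fine_shape,
        voxel_size_fine=fine_voxel,
        voxel_size_pet=pet_voxel,
        uptake_map=dict(BRAIN_UPTAKES),
        noise_fraction=noise_fraction,
        n_realizations=n_realizations,
        rng_seed=rng_seed,
    )


def _center_grids(shape, voxel_size):
    axes = [(np.arange(n) + 0.5) * v for n, v in zip(shape, voxel_size)]
    return np.meshgrid(*axes, indexing="ij", sparse=True)


def make_sphere_phantom(spec: PhantomSpec) -> tuple[LabelVolume, ActivityVolume]:
    """Build the fine-grid label and ideal activity volumes of the tank.

    A voxel is labelled by the distance of its center to each sphere
    center: interior if ``d <= r_inner``, wall if ``r_inner < d <=
    r_outer``, background otherwise.  Spheres with non-positive inner
    diameter are treated as absent.  Raises if spheres overlap (walls
    included) or stick out of the grid.
    """
    spheres = [s for s in spec.region_defs if s.inner_diameter > 0]
    extent = spec.fine_extent
    for s in spheres:
        c = np.asarray(s.center)
        if np.any(c - s.outer_radius < 0) or np.any(c + s.outer_radius > extent):
            raise ValueError(f"sphere {s.name!r} exceeds the grid extent {tuple(extent)}")
    for i, a in enumerate(spheres):
        for b in spheres[i + 1 :]:
            d = np.linalg.norm(np.subtract(a.center, b.center))
            if d <= a.outer_radius + b.outer_radius:
                raise ValueError(f"spheres {a.name!r} and {b.name!r} overlap")

    labels = np.zeros(spec.grid_shape, dtype=np.int16)
    names = {0: "background"}
    X, Y, Z = _center_grids(spec.grid_shape, spec.voxel_size_fine)
    for k, s in enumerate(spheres):
        d2 = (X - s.center[0]) ** 2 + (Y - s.center[1]) ** 2 + (Z - s.center[2]) ** 2
        inner_id, wall_id = 2 * k + 1, 2 * k + 2
        labels[d2 <= s.inner_radius**2] = inner_id
        labels[(d2 > s.inner_radius**2) & (d2 <= s.outer_radius**2)] = wall_id
        names[inner_id] = f"{s.name}_inner"
        names[wall_id] = f"{s.name}_wall"

    label_vol = LabelVolume(labels, spec.voxel_size_fine, names)
    activity = _assign_uptakes(label_vol, spec.uptake_map)
    return label_vol, activity


def _assign_uptakes(label_vol: LabelVolume, uptake_map: dict[str, float]) -> ActivityVolume:
    lut = np.zeros(label_vol.n_labels)
    for lid, name in label_vol.label_names.items():
        if name not in uptake_map:
            raise ValueError(f"uptake_map is missing region {name!r}")
        lut[lid] = uptake_map[name]
    return ActivityVolume(lut[label_vol.labels], label_vol.voxel_size, label_vol.origin)


# ---------------------------------------------------------------------------
# brain phantom

#: Surrogate head geometry: nested ellipsoids (semi-axes and centers in mm,
#: relative to the grid center).  Later entries overwrite earlier ones, so
#: skin/muscle, grey and white matter come out as shells automatically.
_BRAIN_ELLIPSOIDS = [
    ("skin_muscle", (0.0, 0.0, 0.0), (54.0, 62.0, 66.0)),
    ("grey_matter", (0.0, 0.0, 0.0), (48.0, 56.0, 60.0)),
    ("white_matter", (0.0, 0.0, 0.0), (40.0, 48.0, 52.0)),
    ("caudate", (-14.0, 15.0, 5.0), (6.0, 15.0, 6.0)),
    ("caudate", (14.0, 15.0, 5.0), (6.0, 15.0, 6.0)),
    ("putamen", (-22.0, 0.0, 0.0), (8.0, 16.0, 7.0)),
    ("putamen", (22.0, 0.0, 0.0), (8.0, 16.0, 7.0)),
]

_BRAIN_LABEL_IDS = {
    "background": 0,
    "putamen": 1,
    "caudate": 2,
    "skin_muscle": 3,
    "grey_matter": 4,
    "white_matter": 5,
}


def surrogate_brain_atlas(
    grid_shape: tuple[int, int, int],
    voxel_size: tuple[float, float, float],
) -> LabelVolume:
    """Procedural stand-in for a segmented head atlas.

    Synthetic geometry: an ellipsoidal head with a skin/skeletal-muscle
    outer shell, a grey-matter shell, a white-matter core, and paired
    caudate/putamen ellipsoids (left and right merged into one VOI per
    structure).  Region volumes are of the same order as human anatomy;
    the anatomy itself is deliberately schematic.
    """
    X, Y, Z = _center_grids(grid_shape, voxel_size)
    extent = np.asarray(grid_shape) * np.asarray(voxel_size)
    cx, cy, cz = extent / 2.0
    labels = np.zeros(grid_shape, dtype=np.int16)
    for name, (ox, oy, oz), (a, b, c) in _BRAIN_ELLIPSOIDS:
        inside = (
            ((X - cx - ox) / a) ** 2 + ((Y - cy - oy) / b) ** 2 + ((Z - cz - oz) / c) ** 2
        ) <= 1.0
        labels[inside] = _BRAIN_LABEL_IDS[name]
    names = {v: k for k, v in _BRAIN_LABEL_IDS.items()}
    return LabelVolume(labels, voxel_size, names)


def make_brain_phantom(
    spec: PhantomSpec, atlas: LabelVolume | None = None
) -> tuple[LabelVolume, ActivityVolume]:
    """Assign relative uptakes to a labelled head volume.

    Uses the built-in surrogate atlas when none is supplied.  Every
    label present in the atlas must appear in ``spec.uptake_map``.
    """
    if atlas is None:
        atlas = surrogate_brain_atlas(spec.grid_shape, spec.voxel_size_fine)
    missing = [
        name
        for lid, name in atlas.label_names.items()
        if name not in spec.uptake_map and np.any(atlas.labels == lid)
    ]
    if missing:
        raise ValueError(f"uptake_map is missing atlas regions: {missing}")
    return atlas, _assign_uptakes(atlas, spec.uptake_map)


# ---------------------------------------------------------------------------
# resampling, noise, misregistration


def downsample_to_pet(
    volume: ActivityVolume,
    pet_voxel_size,
    pet_shape: tuple[int, int, int] | None = None,
    antialias: bool = False,
) -> ActivityVolume:
    """Resample a fine-grid volume onto the PET grid (tissue fractions).

    Plain trilinear interpolation at PET voxel centers (the convention
    of the region-based PVC literature; the default here).  Binary
    masks come out as fractions in [0, 1]; constants are preserved
    exactly; the volume integral of compact masks is preserved to ~1-2%.
    Upsampling requests raise.

    With ``antialias=True`` a box-average prefilter is applied on axes
    whose decimation factor exceeds 2, which makes the output approach
    the true within-voxel volume fraction.  This is *not* the default:
    the extra smoothing makes the spread functions of adjacent thin
    structures (for example a sphere interior and its sub-voxel wall)
    substantially more collinear, which inflates the noise
    amplification of the correction several-fold for the smallest
    structures and misrepresents how the method behaves in practice.
    """
    pet_voxel_size = np.broadcast_to(np.asarray(pet_voxel_size, float), (3,))
    fine_voxel = np.asarray(volume.voxel_size)
    if np.any(pet_voxel_size < fine_voxel):
        raise ValueError(
            f"upsampling not supported: PET voxel {tuple(pet_voxel_size)} < "
            f"fine voxel {tuple(fine_voxel)}"
        )
    if pet_shape is None:
        extent = np.asarray(volume.shape) * fine_voxel
        pet_shape = tuple(int(np.floor(e / v + 1e-9)) for e, v in zip(extent, pet_voxel_size))

    values = volume.values
    if antialias:
        for axis, r in enumerate(pet_voxel_size / fine_voxel):
            if r > 2.0:
                values = uniform_filter1d(
                    values, size=int(round(r)), axis=axis, mode="nearest"
                )

    coords = [
        ((np.arange(n) + 0.5) * v) / fv - 0.5
        for n, v, fv in zip(pet_shape, pet_voxel_size, fine_voxel)
    ]
    grid = np.meshgrid(*coords, indexing="ij")
    out = map_coordinates(values, grid, order=1, mode="nearest")
    return ActivityVolume(out, tuple(pet_voxel_size), volume.origin)


def downsample_masks(
    labels: LabelVolume,
    pet_voxel_size,
    pet_shape: tuple[int, int, int] | None = None,
    antialias: bool = False,
) -> tuple[np.ndarray, list[str]]:
    """Tissue-fraction masks of every label on the PET grid.

    Returns ``(masks, names)`` with ``masks`` of shape ``(n_labels, *pet_shape)``.
    Because the fine-grid binary masks tile the volume and the resampling
    is linear and constant-preserving, the output masks are a partition
    of unity on the PET grid.
    """
    masks = []
    names = []
    for lid in range(labels.n_labels):
        m = downsample_to_pet(labels.mask_volume(lid), pet_voxel_size, pet_shape, antialias)
        masks.append(m.values)
        names.append(labels.label_names.get(lid, f"region{lid}"))
    return np.stack(masks), names


def add_noise(
    image: ActivityVolume,
    noise_fraction: float,
    reference_mean: float,
    rng_seed,
) -> ActivityVolume:
    """Add stationary, uncorrelated Gaussian noise to an image.

    The noise std is ``noise_fraction * reference_mean`` at every voxel
    (spatially uniform, as appropriate for post-reconstruction noise of
    FBP images).  ``rng_seed`` may be an int, a ``SeedSequence`` or a
    ``Generator``; output is deterministic given the seed.
    """
    if noise_fraction < 0:
        raise ValueError("noise_fraction must be >= 0")
    if reference_mean <= 0:
        raise ValueError("reference_mean must be > 0")
    if noise_fraction == 0:
        return image.copy()
    rng = np.random.default_rng(rng_seed)
    noise = rng.normal(0.0, noise_fraction * reference_mean, size=image.shape)
    return image.with_values(image.values + noise)


def shift_labels(labels: LabelVolume, shift_mm) -> LabelVolume:
    """Rigidly translate a label volume by the nearest whole fine voxels.

    Masks are categorical, so sub-voxel shifts are not interpolated: the
    shift is rounded to fine-grid voxels (<= half a fine voxel of error,
    small against the 1-10 mm misregistrations of interest).  Voxels
    shifted in from outside the grid take the background label 0.
    """
    shift_mm = np.broadcast_to(np.asarray(shift_mm, float), (3,))
    if np.any(np.abs(shift_mm) > 10.0):
        warnings.warn(
            f"shift {tuple(shift_mm)} mm exceeds the 10 mm range the method "
            "was characterized for",
            stacklevel=2,
        )
    steps = [int(round(s / v)) for s, v in zip(shift_mm, labels.voxel_size)]
    out = np.zeros_like(labels.labels)
    src = []
    dst = []
    for n, k in zip(labels.shape, steps):
        if abs(k) >= n:
            return LabelVolume(out, labels.voxel_size, dict(labels.label_names), labels.origin)
        if k >= 0:
            dst.append(slice(k, n))
            src.append(slice(0, n - k))
        else:
            dst.append(slice(0, n + k))
            src.append(slice(-k, n))
    out[tuple(dst)] = labels.labels[tuple(src)]
    return LabelVolume(out, labels.voxel_size, dict(labels.label_names), labels.origin)


def sphere_local_fov(
    sphere: SphereDef,
    grid_shape: tuple[int, int, int],
    voxel_size,
    margin_mm: float = 20.0,
) -> ActivityVolume:
    """Binary cylinder mask around one sphere: the local analysis FOV.

    The cylinder is coaxial with z through the sphere center, with
    radius and axial half-height ``outer_radius + margin_mm`` (clipped
    to the grid).  Used to localize the Eq.-style integrals of the
    per-sphere 3x3 transfer systems.
    """
    voxel_size = np.broadcast_to(np.asarray(voxel_size, float), (3,))
    X, Y, Z = _center_grids(grid_shape, voxel_size)
    r = sphere.outer_radius + margin_mm
    inside = ((X - sphere.center[0]) ** 2 + (Y - sphere.center[1]) ** 2 <= r**2) & (
        np.abs(Z - sphere.center[2]) <= r
    )
    return ActivityVolume(
        np.broadcast_to(inside, grid_shape).astype(float), tuple(voxel_size)
    )
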