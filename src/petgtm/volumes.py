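"""In-memory containers for 3D volumes on regular grids.

Two kinds of volume travel through the package: integer-labelled
segmentations on a fine anatomical (CT/MR-like) grid and real-valued
activity images on either grid.  Both store voxel spacing in mm and a
physical origin.  The coordinate convention is fixed package-wide:
voxel indices are 0-based and the physical position of the *center* of
voxel ``(i, j, k)`` is ``origin + (index + 0.5) * voxel_size``; the
origin is therefore the corner of the grid.  Array axes are (x, y, z)
and the z axis is the scanner (axial) direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["ActivityVolume", "LabelVolume"]


def _as_triple(v) -> tuple[float, float, float]:
    a = np.broadcast_to(np.asarray(v, dtype=float), (3,))
    return (float(a[0]), float(a[1]), float(a[2]))


@dataclass
class ActivityVolume:
    """A real-valued 3D image (ideal, blurred, reconstructed or measured PET).

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Voxel values, finite everywhere.
    voxel_size : triple of float
        Voxel edge lengths in mm.
    origin : triple of float
        Physical position (mm) of the grid corner; the center of voxel
        ``(i, j, k)`` sits at ``origin + (index + 0.5) * voxel_size``.
    """

    values: np.ndarray
    voxel_size: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D array, got shape {self.values.shape}")
        self.voxel_size = _as_triple(self.voxel_size)
        self.origin = _as_triple(self.origin)
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel sizes must be positive, got {self.voxel_size}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("activity values must be finite everywhere")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.voxel_size))

    def voxel_centers(self, axis: int) -> np.ndarray:
        """Physical center coordinates (mm) of voxels along one axis."""
        n = self.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.voxel_size[axis]

    def total_activity(self) -> float:
        """Integral of the image: sum of values times voxel volume."""
        return float(self.values.sum() * self.voxel_volume)

    def with_values(self, values: np.ndarray) -> "ActivityVolume":
        """A copy of this volume carrying different voxel values."""
        return replace(self, values=np.asarray(values, dtype=float))

    def copy(self) -> "ActivityVolume":
        return replace(self, values=self.values.copy())


@dataclass
class LabelVolume:
    """An integer-labelled segmentation: N non-overlapping VOIs plus background.

    Every voxel carries exactly one label; label IDs are contiguous
    ``0..N-1`` with 0 reserved for background.  ``label_names`` maps IDs
    to human-readable region names.
    """

    labels: np.ndarray
    voxel_size: tuple[float, float, float]
    label_names: dict[int, str] = field(default_factory=dict)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("label array must have an integer dtype")
        if self.labels.ndim != 3:
            raise ValueError(f"expected a 3D array, got shape {self.labels.shape}")
        self.voxel_size = _as_triple(self.voxel_size)
        self.origin = _as_triple(self.origin)
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel sizes must be positive, got {self.voxel_size}")
        present = np.unique(self.labels)
        if present.min() < 0:
            raise ValueError("labels must be non-negative")
        if not self.label_names:
            self.label_names = {int(v): f"region{int(v)}" for v in present}

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def n_labels(self) -> int:
        """Number of labels including background (max ID + 1)."""
        return int(self.labels.max()) + 1

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.voxel_size))

    def mask(self, label: int) -> np.ndarray:
        """Binary (float) mask of one label on the fine grid."""
        return (self.labels == label).astype(float)

    def mask_volume(self, label: int) -> ActivityVolume:
        return ActivityVolume(self.mask(label), self.voxel_size, self.origin)

    def region_volumes(self) -> dict[str, float]:
        """Physical volume (mm^3) of every label, keyed by region name."""
        counts = np.bincount(self.labels.ravel(), minlength=self.n_labels)
        return {
            self.label_names.get(i, f"region{i}"): float(c) * self.voxel_volume
            for i, c in enumerate(counts)
        }

    def copy(self) -> "LabelVolume":
        return replace(self, labels=self.labels.copy(), label_names=dict(self.label_names))
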