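"""Core domain types shared across the habitat-mapping pipeline.

Geometry convention
-------------------
Patient space is DICOM LPS (+x left, +y posterior, +z superior), millimetres.
Voxel arrays are indexed ``voxels[z, y, x]`` (slice, row, column).  An
:class:`ImageVolume` maps the 0-based index ``(ix, iy, iz)`` to patient space
as::

    p = origin + orientation @ (spacing * [ix, iy, iz])

where ``spacing = (dx, dy, dz)`` is the physical step along the column, row
and slice axes and the columns of ``orientation`` are the unit direction
vectors of the three index axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class HabitatError(Exception):
    """Base class for pipeline errors."""


class GeometryError(HabitatError):
    """Invalid or inconsistent image geometry."""


class EmptyMaskError(HabitatError):
    """A mask that must contain foreground is empty."""


def _as_float_array(x, name: str, shape=None) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if shape is not None and arr.shape != shape:
        raise GeometryError(f"{name} must have shape {shape}, got {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise GeometryError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class ImageVolume:
    """A 3D scalar volume in Hounsfield units with patient-space geometry.

    Attributes
    ----------
    voxels : (nz, ny, nx) float array
        HU values, indexed [slice, row, column].
    spacing : (3,) array
        (dx, dy, dz) in mm along the column, row and slice index axes.
    origin : (3,) array
        LPS position (mm) of voxel index (0, 0, 0).
    orientation : (3, 3) array
        Columns are the patient-space unit directions of the column, row
        and slice index axes; orthonormal with determinant +1.
    """

    voxels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    orientation: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        vox = np.asarray(self.voxels, dtype=float)
        if vox.ndim != 3 or vox.size == 0:
            raise GeometryError("voxels must be a non-empty 3D array")
        spacing = _as_float_array(self.spacing, "spacing", (3,))
        if np.any(spacing <= 0):
            raise GeometryError("spacing components must be strictly positive")
        origin = _as_float_array(self.origin, "origin", (3,))
        R = _as_float_array(self.orientation, "orientation", (3, 3))
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-6):
            raise GeometryError("orientation must be orthonormal")
        if np.linalg.det(R) < 0:
            raise GeometryError("orientation must have determinant +1")
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "orientation", R)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def index_to_patient(self, indices: np.ndarray) -> np.ndarray:
        """Map (..., 3) arrays of (ix, iy, iz) indices to LPS mm positions."""
        idx = np.asarray(indices, dtype=float)
        return self.origin + (idx * self.spacing) @ self.orientation.T

    def patient_to_index(self, points: np.ndarray) -> np.ndarray:
        """Map (..., 3) LPS mm positions to continuous (ix, iy, iz) indices."""
        p = np.asarray(points, dtype=float)
        return ((p - self.origin) @ self.orientation) / self.spacing

    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass(frozen=True)
class VOIMask:
    """Binary volume-of-interest mask congruent with a reference volume."""

    voxels: np.ndarray
    reference_shape: tuple[int, int, int]

    def __post_init__(self):
        vox = np.asarray(self.voxels) != 0
        if vox.shape != tuple(self.reference_shape):
            raise GeometryError(
                "mask/volume geometry mismatch: "
                f"{vox.shape} vs {tuple(self.reference_shape)}"
            )
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "reference_shape", tuple(self.reference_shape))

    @property
    def count(self) -> int:
        return int(self.voxels.sum())

    def require_nonempty(self):
        if self.count == 0:
            raise EmptyMaskError("empty VOI")
        return self


@dataclass(frozen=True)
class HabitatMap:
    """Integer habitat label grid: 0 outside the VOI, 1..k inside.

    ``volumes_cm3[i]`` is the physical volume of label ``i + 1``.
    """

    labels: np.ndarray
    k: int
    volumes_cm3: np.ndarray

    def __post_init__(self):
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise GeometryError("labels must be 3D")
        if not np.issubdtype(labels.dtype, np.integer):
            labels = labels.astype(np.int32)
        present = np.unique(labels[labels > 0])
        if self.k < 1:
            raise HabitatError("empty habitat map")
        if len(present) and (present.min() < 1 or present.max() > self.k):
            raise HabitatError("labels outside 1..k")
        if len(present) != self.k or not np.array_equal(
            present, np.arange(1, self.k + 1)
        ):
            raise HabitatError("non-contiguous labels")
        vols = _as_float_array(self.volumes_cm3, "volumes_cm3", (self.k,))
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "volumes_cm3", vols)

    @property
    def voi_mask(self) -> np.ndarray:
        return self.labels > 0


@dataclass(frozen=True)
class RigidTransform:
    """Rigid-body map ``p_us = rotation @ p_ct + translation`` (mm, LPS)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = _as_float_array(self.rotation, "rotation", (3, 3))
        t = _as_float_array(self.translation, "translation", (3,))
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
            raise GeometryError("rotation must be orthonormal")
        if np.linalg.det(R) < 0:
            raise GeometryError("rotation must be proper (det +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        Rinv = self.rotation.T
        return RigidTransform(Rinv, -Rinv @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying `other` then `self`."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )
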