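"""Landmark-based rigid CT/US registration and fusion-accuracy metrics.

The CT volume is registered to ultrasound space from 1-3 paired anatomical
landmarks (pubic symphysis, umbilicus, anterior superior iliac spine): one
pair gives a pure translation, two pairs add a rotation about the
craniocaudal axis (the axial orientation having been aligned first), and
three non-collinear pairs give the full least-squares rigid fit (Kabsch /
orthogonal Procrustes).  Fusion accuracy is quantified with the Dice
similarity coefficient between the resliced CT tumour silhouette and the US
tumour segmentation on the plane covering the largest tumour area.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import GeometryError, HabitatError, ImageVolume, RigidTransform, VOIMask

KNOWN_LANDMARKS = ("pubic_symphysis", "umbilicus", "asis", "custom")


@dataclass(frozen=True)
class LandmarkSet:
    """Paired CT/US fiducial points in LPS millimetres (1-3 pairs)."""

    names: tuple
    ct: np.ndarray
    us: np.ndarray

    def __post_init__(self):
        ct = np.atleast_2d(np.asarray(self.ct, float))
        us = np.atleast_2d(np.asarray(self.us, float))
        n = len(self.names)
        if not 1 <= n <= 3:
            raise HabitatError("between one and three landmark pairs required")
        if len(set(self.names)) != n:
            raise HabitatError("duplicate landmark names")
        if ct.shape != (n, 3) or us.shape != (n, 3):
            raise GeometryError("landmark arrays must be (n, 3)")
        if not (np.all(np.isfinite(ct)) and np.all(np.isfinite(us))):
            raise GeometryError("landmark coordinates must be finite")
        object.__setattr__(self, "names", tuple(self.names))
        object.__setattr__(self, "ct", ct)
        object.__setattr__(self, "us", us)

    def __len__(self) -> int:
        return len(self.names)


@dataclass(frozen=True)
class USFrame:
    """A 2D ultrasound frame with its pose in patient space.

    ``pixels[iy, ix]`` maps to ``origin + ix*spacing[0]*dir_col +
    iy*spacing[1]*dir_row`` (mm, LPS); the direction vectors are orthonormal.
    """

    pixels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    dir_col: np.ndarray
    dir_row: np.ndarray

    def __post_init__(self):
        px = np.asarray(self.pixels, float)
        if px.ndim != 2:
            raise GeometryError("US frame must be 2D")
        sp = np.asarray(self.spacing, float)
        dc = np.asarray(self.dir_col, float)
        dr = np.asarray(self.dir_row, float)
        if abs(dc @ dc - 1) > 1e-6 or abs(dr @ dr - 1) > 1e-6 or abs(dc @ dr) > 1e-6:
            raise GeometryError("frame direction vectors must be orthonormal")
        object.__setattr__(self, "pixels", px)
        object.__setattr__(self, "spacing", sp)
        object.__setattr__(self, "origin", np.asarray(self.origin, float))
        object.__setattr__(self, "dir_col", dc)
        object.__setattr__(self, "dir_row", dr)

    def pixel_positions(self) -> np.ndarray:
        """(ny, nx, 3) patient-space positions of all pixel centres."""
        ny, nx = self.pixels.shape
        ix, iy = np.meshgrid(np.arange(nx), np.arange(ny))
        return (
            self.origin
            + ix[..., None] * self.spacing[0] * self.dir_col
            + iy[..., None] * self.spacing[1] * self.dir_row
        )


def _z_rotation_fit(ct: np.ndarray, us: np.ndarray) -> RigidTransform:
    """Best rigid fit restricted to rotation about the craniocaudal axis."""
    cct, cus = ct.mean(axis=0), us.mean(axis=0)
    a, b = ct - cct, us - cus
    num = float(np.sum(a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]))
    den = float(np.sum(a[:, 0] * b[:, 0] + a[:, 1] * b[:, 1]))
    theta = 0.0 if (num == 0.0 and den == 0.0) else np.arctan2(num, den)
    c, s = np.cos(theta), np.sin(theta)
    R = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    return RigidTransform(R, cus - R @ cct)


def fit_rigid(landmarks: LandmarkSet) -> RigidTransform:
    """Least-squares rigid CT->US transform from 1-3 landmark pairs.

    One pair: pure translation.  Two pairs: centroid translation plus the
    residual-minimising rotation about z (axial pre-alignment fixes the
    other axes).  Three pairs: full Kabsch fit with determinant correction;
    a collinear triplet falls back to the two-pair solution with a warning.
    """
    ct, us = landmarks.ct, landmarks.us
    n = len(landmarks)
    if n == 1:
        return RigidTransform(np.eye(3), us[0] - ct[0])
    if n == 2:
        return _z_rotation_fit(ct, us)
    v1, v2 = ct[1] - ct[0], ct[2] - ct[0]
    if np.linalg.norm(np.cross(v1, v2)) < 1e-9 * max(
        np.linalg.norm(v1) * np.linalg.norm(v2), 1.0
    ):
        warnings.warn(
            "collinear landmarks: falling back to in-plane rotation fit",
            stacklevel=2,
        )
        return _z_rotation_fit(ct, us)
    cct, cus = ct.mean(axis=0), us.mean(axis=0)
    H = (ct - cct).T @ (us - cus)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return RigidTransform(R, cus - R @ cct)


def fre(landmarks: LandmarkSet, transform: RigidTransform) -> float:
    """Fiducial registration error: RMS residual distance in mm."""
    residuals = transform.apply(landmarks.ct) - landmarks.us
    return float(np.sqrt(np.mean(np.sum(residuals**2, axis=1))))


def reslice_mask(
    mask: VOIMask,
    ct: ImageVolume,
    frame: USFrame,
    transform: RigidTransform,
) -> np.ndarray:
    """CT tumour silhouette in the US plane (nearest-neighbour sampling).

    Each US pixel's patient position is pulled back through the inverse
    transform into CT space and the VOI mask is sampled at the nearest
    voxel; positions outside the CT grid sample background.
    """
    pos_us = frame.pixel_positions()
    pos_ct = transform.inverse().apply(pos_us.reshape(-1, 3))
    idx = np.round(ct.patient_to_index(pos_ct)).astype(np.int64)  # (n, 3) x,y,z
    nz, ny, nx = ct.shape
    inside = (
        (idx[:, 0] >= 0) & (idx[:, 0] < nx)
        & (idx[:, 1] >= 0) & (idx[:, 1] < ny)
        & (idx[:, 2] >= 0) & (idx[:, 2] < nz)
    )
    if not inside.any():
        raise GeometryError("no overlap between frame and CT")
    out = np.zeros(pos_us.shape[:2], dtype=bool).ravel()
    sel = idx[inside]
    out[inside] = mask.voxels[sel[:, 2], sel[:, 1], sel[:, 0]]
    return out.reshape(pos_us.shape[:2])


def dice(a: np.ndarray, b: np.ndarray) -> float | None:
    """Dice similarity coefficient 2|A^B|/(|A|+|B|); None when undefined."""
    a = np.asarray(a) != 0
    b = np.asarray(b) != 0
    if a.shape != b.shape:
        raise GeometryError(f"mask shape mismatch: {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return None
    return 2.0 * int((a & b).sum()) / denom


def select_largest_slice(mask: VOIMask | np.ndarray) -> int:
    """Axial slice index with the largest tumour area (ties: inferior-most)."""
    vox = mask.voxels if isinstance(mask, VOIMask) else np.asarray(mask) != 0
    areas = vox.reshape(vox.shape[0], -1).sum(axis=1)
    if areas.sum() == 0:
        raise HabitatError("empty VOI")
    return int(np.argmax(areas))


def summarize(values) -> tuple[float, float, float]:
    """(median, min, max) over the defined entries of ``values``.

    ``None``/NaN entries (undefined DSC) are excluded; the median of an
    even count is the mean of the middle two.
    """
    vals = [float(v) for v in values if v is not None and np.isfinite(v)]
    if not vals:
        raise HabitatError("no defined values to summarise")
    return float(np.median(vals)), float(min(vals)), float(max(vals))


@dataclass(frozen=True)
class DSCReport:
    """Per-lesion fusion-accuracy report with summary statistics."""

    per_lesion: tuple  # of (lesion_id, site, dsc-or-None)

    def __post_init__(self):
        for _, site, d in self.per_lesion:
            if d is not None and not 0.0 <= d <= 1.0:
                raise HabitatError("DSC outside [0, 1]")
            if site not in ("pelvis", "omentum"):
                raise HabitatError(f"unknown site {site!r}")
        object.__setattr__(self, "per_lesion", tuple(self.per_lesion))

    def summary(self) -> tuple[float, float, float]:
        return summarize([d for _, _, d in self.per_lesion])

    def to_dict(self) -> dict:
        median, lo, hi = self.summary()
        return {
            "per_lesion": [
                {"lesion": lid, "site": site, "dsc": d}
                for lid, site, d in self.per_lesion
            ],
            "median_dsc": median,
            "min_dsc": lo,
            "max_dsc": hi,
        }
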