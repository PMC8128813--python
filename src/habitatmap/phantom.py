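"""Seeded synthetic CT lesions with ground-truth habitats and US frames.

The phantom emulates the two lesion types the pipeline targets: pelvic
masses (solid soft tissue) and omental deposits (soft tissue with
interspersed fat at around -100 HU).  An ellipsoidal lesion is partitioned
into 1-3 azimuthal wedge sub-regions; each wedge gets its own mean HU and a
Gaussian noise field with its own amplitude and (optionally) correlation
length, so habitats differ in *texture*, not only in mean attenuation, and
clustering must use the texture maps to recover them.  A simulated axial US
frame is derived from the largest-area lesion slice through a known
ground-truth rigid transform, giving a closed loop for registration and
Dice testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import GeometryError, HabitatError, HabitatMap, ImageVolume, RigidTransform, VOIMask
from .fusion import LandmarkSet, USFrame, select_largest_slice


@dataclass(frozen=True)
class HabitatTexture:
    """Texture recipe of one phantom sub-region."""

    mean_hu: float
    noise_sigma_hu: float = 20.0
    smooth_mm: float = 0.0  # Gaussian correlation length of the noise


#: Default per-habitat textures: >=40 HU mean separation with noise
#: amplitudes graded >=2x between habitats, so habitats differ both in mean
#: attenuation and in local texture (entropy/contrast scale with the number
#: of grey levels a 5x5 window spans).  Pure white noise keeps the windowed
#: texture statistics stationary within a habitat, which keeps the habitat
#: recovery task well-posed for a Gaussian mixture.
DEFAULT_TEXTURES = (
    HabitatTexture(mean_hu=0.0, noise_sigma_hu=10.0, smooth_mm=0.0),
    HabitatTexture(mean_hu=55.0, noise_sigma_hu=22.0, smooth_mm=0.0),
    HabitatTexture(mean_hu=110.0, noise_sigma_hu=50.0, smooth_mm=0.0),
)


def _default_transform() -> RigidTransform:
    theta = np.deg2rad(12.0)
    c, s = np.cos(theta), np.sin(theta)
    R = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    return RigidTransform(R, np.array([8.0, -6.0, 3.0]))


@dataclass(frozen=True)
class PhantomSpec:
    """Generative description of a synthetic lesion (fully seeded).

    Grid and spacing follow typical portal-venous CT reconstructions
    (sub-millimetre in plane, thicker slices).  ``fat_fraction`` scatters
    fat (-100 HU) inside the VOI for omental lesions only.
    """

    shape: tuple = (4, 128, 128)  # (nz, ny, nx)
    spacing: tuple = (1.0, 1.0, 3.75)  # (dx, dy, dz) mm
    semi_axes_mm: tuple = (56.0, 56.0, 5.6)  # flat ~66 cm^3 lesion
    site: str = "pelvis"
    true_k: int = 3
    textures: tuple = DEFAULT_TEXTURES
    fat_fraction: float = 0.0
    background_hu: float = 40.0
    background_sigma_hu: float = 5.0
    us_transform: RigidTransform = field(default_factory=_default_transform)
    landmark_jitter_mm: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.site not in ("pelvis", "omentum"):
            raise HabitatError("site must be 'pelvis' or 'omentum'")
        if not 1 <= self.true_k <= 3:
            raise HabitatError("true_k must be in 1..3")
        if self.site == "pelvis" and self.fat_fraction != 0.0:
            raise HabitatError("pelvic lesions do not contain interspersed fat")
        if not 0.0 <= self.fat_fraction < 1.0:
            raise HabitatError("fat_fraction must be in [0, 1)")
        if len(self.textures) < self.true_k:
            raise HabitatError("need one texture recipe per habitat")
        if self.landmark_jitter_mm < 0:
            raise HabitatError("landmark_jitter_mm must be >= 0")


@dataclass(frozen=True)
class Phantom:
    """A generated phantom: CT volume, VOI mask and ground-truth labels."""

    volume: ImageVolume
    mask: VOIMask
    truth: HabitatMap
    fat_mask: np.ndarray
    spec: PhantomSpec


def _correlated_noise(rng, shape, sigma, smooth_mm, spacing):
    """Zero-mean Gaussian field with the requested pointwise sigma after
    smoothing (the smoothed field is rescaled back to sigma)."""
    noise = rng.standard_normal(shape)
    if smooth_mm > 0:
        sig_vox = [smooth_mm / spacing[2], smooth_mm / spacing[1], smooth_mm / spacing[0]]
        noise = ndimage.gaussian_filter(noise, sigma=sig_vox)
        sd = noise.std()
        if sd > 0:
            noise = noise / sd
    return noise * sigma


def make_phantom(spec: PhantomSpec) -> Phantom:
    """Generate a seeded CT-like lesion with known habitat labels."""
    nz, ny, nx = spec.shape
    dx, dy, dz = spec.spacing
    rng = np.random.default_rng([spec.seed, 0xC7])

    zz, yy, xx = np.meshgrid(
        np.arange(nz) * dz, np.arange(ny) * dy, np.arange(nx) * dx, indexing="ij"
    )
    centre = np.array([(nx - 1) * dx, (ny - 1) * dy, (nz - 1) * dz]) / 2.0
    ax, ay, az = spec.semi_axes_mm
    if ax > centre[0] or ay > centre[1] or az > centre[2]:
        raise GeometryError("lesion semi-axes do not fit inside the grid")
    u = (xx - centre[0]) / ax
    v = (yy - centre[1]) / ay
    w = (zz - centre[2]) / az
    lesion = u * u + v * v + w * w <= 1.0
    if not lesion.any():
        raise GeometryError("degenerate lesion geometry")

    # azimuthal wedges -> ground-truth habitats 1..k
    angle = np.arctan2(yy - centre[1], xx - centre[0])  # [-pi, pi)
    wedge = np.floor((angle + np.pi) / (2 * np.pi) * spec.true_k).astype(np.int64)
    wedge = np.clip(wedge, 0, spec.true_k - 1)
    truth_labels = np.where(lesion, wedge + 1, 0).astype(np.int32)

    voxels = np.full(spec.shape, spec.background_hu, dtype=float)
    voxels += _correlated_noise(rng, spec.shape, spec.background_sigma_hu, 0.0, spec.spacing)
    for lbl in range(1, spec.true_k + 1):
        tx = spec.textures[lbl - 1]
        fld = tx.mean_hu + _correlated_noise(
            rng, spec.shape, tx.noise_sigma_hu, tx.smooth_mm, spec.spacing
        )
        sel = truth_labels == lbl
        voxels[sel] = fld[sel]

    fat_mask = np.zeros(spec.shape, dtype=bool)
    if spec.site == "omentum" and spec.fat_fraction > 0:
        blob = _correlated_noise(rng, spec.shape, 1.0, 3.0, spec.spacing)
        thresh = np.quantile(blob[lesion], spec.fat_fraction)
        fat_mask = lesion & (blob < thresh)
        voxels[fat_mask] = -100.0 + 5.0 * rng.standard_normal(int(fat_mask.sum()))

    volume = ImageVolume(voxels=voxels, spacing=np.array(spec.spacing))
    mask = VOIMask(voxels=lesion, reference_shape=spec.shape)
    voxel_cm3 = volume.voxel_volume_mm3() / 1000.0
    counts = np.bincount(truth_labels.ravel(), minlength=spec.true_k + 1)[1:]
    truth = HabitatMap(
        labels=truth_labels, k=spec.true_k, volumes_cm3=counts * voxel_cm3
    )
    return Phantom(volume=volume, mask=mask, truth=truth, fat_mask=fat_mask, spec=spec)


#: CT-side anatomical landmark analogues, mm offsets from the volume centre.
_LANDMARK_OFFSETS = {
    "pubic_symphysis": np.array([0.0, 60.0, -40.0]),
    "umbilicus": np.array([0.0, -80.0, 20.0]),
    "asis": np.array([55.0, 45.0, 5.0]),
}


def make_us_frame(
    phantom: Phantom, spec: PhantomSpec | None = None
) -> tuple[USFrame, np.ndarray, LandmarkSet]:
    """Simulate the axial US frame through the largest lesion cross-section.

    The frame pose is the CT slice pose pushed through the ground-truth
    rigid transform; the returned 2D mask is the true lesion silhouette in
    that frame; landmarks are the three anatomical analogues with Gaussian
    jitter of ``landmark_jitter_mm`` applied to the US side.
    """
    spec = spec or phantom.spec
    rng = np.random.default_rng([spec.seed, 0x05])
    vol = phantom.volume
    iz = select_largest_slice(phantom.mask)
    T = spec.us_transform

    origin_ct = vol.index_to_patient(np.array([0.0, 0.0, float(iz)]))
    origin_us = T.apply(origin_ct)
    dir_col = T.rotation @ vol.orientation[:, 0]
    dir_row = T.rotation @ vol.orientation[:, 1]

    silhouette = phantom.mask.voxels[iz].copy()
    speckle = rng.rayleigh(scale=1.0, size=silhouette.shape)
    image = (0.25 + 0.75 * silhouette) * speckle

    frame = USFrame(
        pixels=image,
        spacing=np.array([vol.spacing[0], vol.spacing[1]]),
        origin=origin_us,
        dir_col=dir_col,
        dir_row=dir_row,
    )

    nz, ny, nx = vol.shape
    grid_centre = vol.index_to_patient(
        np.array([(nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0])
    )
    names = tuple(_LANDMARK_OFFSETS)
    ct_pts = np.array([grid_centre + off for off in _LANDMARK_OFFSETS.values()])
    us_pts = T.apply(ct_pts)
    if spec.landmark_jitter_mm > 0:
        us_pts = us_pts + spec.landmark_jitter_mm * rng.standard_normal(us_pts.shape)
    landmarks = LandmarkSet(names=names, ct=ct_pts, us=us_pts)
    return frame, silhouette, landmarks
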