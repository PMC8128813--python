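"""Reading and writing CT volumes, VOI masks and habitat label maps.

Supports DICOM series (CT Image Storage) and NIfTI-1 for volumes and masks,
and a DICOM Segmentation object (binary segments, one per habitat) for
habitat maps, with a NIfTI label-map mirror for convenience.  All geometry
is kept in the LPS patient frame (see :mod:`habitatmap.core`).
"""

from __future__ import annotations

import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.pixels import pack_bits, unpack_bits
from pydicom.uid import ExplicitVRLittleEndian, generate_uid
from scipy import ndimage

from .core import (
    EmptyMaskError,
    GeometryError,
    HabitatError,
    HabitatMap,
    ImageVolume,
    VOIMask,
)

CT_STORAGE = "1.2.840.10008.5.1.4.1.1.2"
SEG_STORAGE = "1.2.840.10008.5.1.4.1.1.66.4"

_RAS_TO_LPS = np.diag([-1.0, -1.0, 1.0])


# ---------------------------------------------------------------------------
# NIfTI
# ---------------------------------------------------------------------------

def _volume_from_nifti(img: nib.Nifti1Image) -> ImageVolume:
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise GeometryError("invalid geometry: NIfTI volume must be 3D")
    affine = np.asarray(img.affine, float).copy()  # nibabel affines are RAS
    affine[:3] = _RAS_TO_LPS @ affine[:3]
    M = affine[:3, :3]
    spacing = np.linalg.norm(M, axis=0)
    if np.any(spacing <= 0) or not np.all(np.isfinite(affine)):
        raise GeometryError("invalid geometry")
    R = M / spacing
    if np.linalg.det(R) < 0:  # flip slice axis to keep a right-handed frame
        data = data[:, :, ::-1]
        affine = affine @ np.array(
            [[1, 0, 0, 0], [0, 1, 0, 0], [0, 0, -1, data.shape[2] - 1],
             [0, 0, 0, 1]], dtype=float)
        M = affine[:3, :3]
        R = M / spacing
    # NIfTI data is indexed [i, j, k] = (col, row, slice); ours is [z, y, x].
    return ImageVolume(
        voxels=np.ascontiguousarray(data.T),
        spacing=spacing,
        origin=affine[:3, 3],
        orientation=R,
    )


def _nifti_from_array(array_zyx: np.ndarray, reference: ImageVolume) -> nib.Nifti1Image:
    affine_lps = np.eye(4)
    affine_lps[:3, :3] = reference.orientation * reference.spacing
    affine_lps[:3, 3] = reference.origin
    affine_ras = affine_lps.copy()
    affine_ras[:3] = _RAS_TO_LPS @ affine_lps[:3]
    return nib.Nifti1Image(np.ascontiguousarray(array_zyx.T), affine_ras)


def write_nifti(volume: ImageVolume, path) -> Path:
    """Write a volume as NIfTI-1 (geometry converted to the RAS affine)."""
    path = Path(path)
    nib.save(_nifti_from_array(volume.voxels, volume), str(path))
    return path


def write_nifti_labels(labels_zyx: np.ndarray, reference: ImageVolume, path) -> Path:
    path = Path(path)
    img = _nifti_from_array(np.asarray(labels_zyx, dtype=np.int16), reference)
    nib.save(img, str(path))
    return path


# ---------------------------------------------------------------------------
# CT volumes
# ---------------------------------------------------------------------------

def read_ct_series(path) -> ImageVolume:
    """Read a CT volume from a DICOM series directory or a NIfTI file.

    DICOM slices are sorted by their position along the slice normal
    regardless of on-disk order.  A directory containing more than one
    SeriesInstanceUID is rejected.
    """
    path = Path(path)
    if path.is_file():
        if path.name.endswith((".nii", ".nii.gz")):
            return _volume_from_nifti(nib.load(str(path)))
        return _volume_from_dicom_files([path])
    files = sorted(p for p in path.iterdir() if p.is_file() and p.suffix != ".json")
    datasets = []
    for f in files:
        try:
            datasets.append(pydicom.dcmread(str(f)))
        except Exception:
            continue
    if not datasets:
        raise GeometryError(f"no readable DICOM files in {path}")
    return _volume_from_datasets(datasets)


def _volume_from_dicom_files(files) -> ImageVolume:
    return _volume_from_datasets([pydicom.dcmread(str(f)) for f in files])


def _volume_from_datasets(datasets) -> ImageVolume:
    uids = {getattr(ds, "SeriesInstanceUID", None) for ds in datasets}
    if len(uids) != 1:
        raise GeometryError("ambiguous series: multiple SeriesInstanceUIDs")
    for ds in datasets:
        if "ImagePositionPatient" not in ds or "ImageOrientationPatient" not in ds \
                or "PixelSpacing" not in ds:
            raise GeometryError("invalid geometry: missing position/orientation tags")
    iop = np.asarray(datasets[0].ImageOrientationPatient, dtype=float)
    row_dir, col_dir = iop[:3], iop[3:]
    normal = np.cross(row_dir, col_dir)
    order = np.argsort(
        [float(np.dot(np.asarray(ds.ImagePositionPatient, float), normal))
         for ds in datasets]
    )
    datasets = [datasets[i] for i in order]
    slices = []
    for ds in datasets:
        arr = ds.pixel_array.astype(float)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(arr * slope + intercept)
    voxels = np.stack(slices, axis=0)  # [z, y, x]
    ps = np.asarray(datasets[0].PixelSpacing, dtype=float)  # (row, col)
    if len(datasets) > 1:
        p0 = np.asarray(datasets[0].ImagePositionPatient, float)
        p1 = np.asarray(datasets[1].ImagePositionPatient, float)
        dz = float(np.linalg.norm(p1 - p0))
    else:
        dz = float(getattr(datasets[0], "SliceThickness", 1.0))
    if dz <= 0:
        raise GeometryError("invalid geometry: non-positive slice spacing")
    orientation = np.column_stack([row_dir, col_dir, normal])
    return ImageVolume(
        voxels=voxels,
        spacing=np.array([ps[1], ps[0], dz]),
        origin=np.asarray(datasets[0].ImagePositionPatient, float),
        orientation=orientation,
    )


def _content_uid(*parts) -> str:
    """Deterministic UID derived from content, so seeded reruns re-hash."""
    return generate_uid(entropy_srcs=[str(p) for p in parts])


def write_ct_series(volume: ImageVolume, directory) -> list[Path]:
    """Write a volume as a DICOM CT series, one file per axial slice."""
    import hashlib

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    digest = hashlib.sha256(
        np.round(volume.voxels).astype(np.int16).tobytes()
        + volume.spacing.tobytes() + volume.origin.tobytes()
    ).hexdigest()
    series_uid = _content_uid(digest, "series")
    study_uid = _content_uid(digest, "study")
    frame_uid = _content_uid(digest, "frame")
    nz, ny, nx = volume.shape
    iop = list(volume.orientation[:, 0]) + list(volume.orientation[:, 1])
    paths = []
    for iz in range(nz):
        ds = Dataset()
        ds.file_meta = FileMetaDataset()
        ds.file_meta.MediaStorageSOPClassUID = CT_STORAGE
        ds.file_meta.MediaStorageSOPInstanceUID = _content_uid(digest, "sop", iz)
        ds.file_meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.SOPClassUID = CT_STORAGE
        ds.SOPInstanceUID = ds.file_meta.MediaStorageSOPInstanceUID
        ds.Modality = "CT"
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.FrameOfReferenceUID = frame_uid
        ds.PatientName = "PHANTOM"
        ds.PatientID = "PHANTOM"
        ds.InstanceNumber = iz + 1
        ds.Rows, ds.Columns = ny, nx
        ds.PixelSpacing = [float(volume.spacing[1]), float(volume.spacing[0])]
        ds.SliceThickness = float(volume.spacing[2])
        ds.ImageOrientationPatient = [float(v) for v in iop]
        pos = volume.index_to_patient(np.array([0.0, 0.0, float(iz)]))
        ds.ImagePositionPatient = [float(v) for v in pos]
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1  # signed, HU stored directly
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = 0.0
        ds.PixelData = np.round(volume.voxels[iz]).astype(np.int16).tobytes()
        out = directory / f"ct_{iz:04d}.dcm"
        ds.save_as(str(out), enforce_file_format=True)
        paths.append(out)
    return paths


# ---------------------------------------------------------------------------
# VOI masks
# ---------------------------------------------------------------------------

def read_mask(path, reference: ImageVolume) -> VOIMask:
    """Read a binary VOI mask (NIfTI or DICOM-SEG); any nonzero is foreground."""
    path = Path(path)
    if path.name.endswith((".nii", ".nii.gz")):
        vol = _volume_from_nifti(nib.load(str(path)))
        arr = vol.voxels
    else:
        arr = read_habitat_dicom(path, reference).labels
    if arr.shape != reference.shape:
        raise GeometryError(
            f"mask/volume geometry mismatch: {arr.shape} vs {reference.shape}"
        )
    mask = VOIMask(voxels=arr != 0, reference_shape=reference.shape)
    return mask.require_nonempty()


def mask_volume_cm3(mask: VOIMask | np.ndarray, spacing) -> float:
    """Foreground volume in cm^3 (voxel count x voxel volume)."""
    spacing = np.asarray(spacing, dtype=float)
    if np.any(spacing <= 0):
        raise GeometryError("spacing must be positive")
    count = mask.count if isinstance(mask, VOIMask) else int(np.count_nonzero(mask))
    return count * float(np.prod(spacing)) / 1000.0


def sub_segment_solid(
    volume: ImageVolume,
    mask: VOIMask,
    fat_hu_max: float = -30.0,
    min_component_cm3: float = 0.1,
) -> VOIMask:
    """Restrict an omental VOI to solid (non-fat) tissue.

    Keeps voxels with HU strictly above ``fat_hu_max``, applies an in-plane
    3x3 morphological opening, and removes connected components smaller than
    ``min_component_cm3``.  The result is always a subset of the input mask.
    """
    mask.require_nonempty()
    keep = mask.voxels & (volume.voxels > fat_hu_max)
    structure = np.ones((1, 3, 3), dtype=bool)  # in-plane opening
    keep = ndimage.binary_opening(keep, structure=structure)
    if keep.any():
        labels, n = ndimage.label(keep)
        min_voxels = min_component_cm3 * 1000.0 / volume.voxel_volume_mm3()
        counts = np.bincount(labels.ravel())
        small = np.flatnonzero(counts < min_voxels)
        keep &= ~np.isin(labels, small[small > 0])
    if not keep.any():
        raise EmptyMaskError("no solid tissue in VOI")
    return VOIMask(voxels=keep, reference_shape=mask.reference_shape)


# ---------------------------------------------------------------------------
# DICOM Segmentation habitat export
# ---------------------------------------------------------------------------

def write_habitat_dicom(habitat_map: HabitatMap, reference: ImageVolume, path) -> Path:
    """Write a habitat map as a DICOM Segmentation object.

    One binary segment per habitat label, frames bit-packed, sharing the
    reference volume's frame of reference.  ``read_habitat_dicom`` restores
    the label array exactly.
    """
    if habitat_map.labels.shape != reference.shape:
        raise GeometryError("habitat map/volume geometry mismatch")
    path = Path(path)
    nz, ny, nx = reference.shape
    k = habitat_map.k
    import hashlib

    digest = hashlib.sha256(
        habitat_map.labels.astype(np.int32).tobytes()
        + reference.spacing.tobytes() + reference.origin.tobytes()
    ).hexdigest()

    ds = Dataset()
    ds.file_meta = FileMetaDataset()
    ds.file_meta.MediaStorageSOPClassUID = SEG_STORAGE
    ds.file_meta.MediaStorageSOPInstanceUID = _content_uid(digest, "sop")
    ds.file_meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds.SOPClassUID = SEG_STORAGE
    ds.SOPInstanceUID = ds.file_meta.MediaStorageSOPInstanceUID
    ds.Modality = "SEG"
    ds.SeriesInstanceUID = _content_uid(digest, "series")
    ds.StudyInstanceUID = _content_uid(digest, "study")
    ds.FrameOfReferenceUID = _content_uid(digest, "frame")
    ds.PatientName = "PHANTOM"
    ds.PatientID = "PHANTOM"
    ds.SegmentationType = "BINARY"
    ds.ContentLabel = "HABITATS"
    ds.Rows, ds.Columns = ny, nx
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 1
    ds.BitsStored = 1
    ds.HighBit = 0
    ds.PixelRepresentation = 0

    seg_seq = []
    for label in range(1, k + 1):
        seg = Dataset()
        seg.SegmentNumber = label
        seg.SegmentLabel = f"habitat {label}"
        seg.SegmentAlgorithmType = "AUTOMATIC"
        seg.SegmentAlgorithmName = "habitatmap"
        seg_seq.append(seg)
    ds.SegmentSequence = seg_seq

    shared = Dataset()
    pm = Dataset()
    pm.PixelSpacing = [float(reference.spacing[1]), float(reference.spacing[0])]
    pm.SpacingBetweenSlices = float(reference.spacing[2])
    pm.SliceThickness = float(reference.spacing[2])
    po = Dataset()
    iop = list(reference.orientation[:, 0]) + list(reference.orientation[:, 1])
    po.ImageOrientationPatient = [float(v) for v in iop]
    shared.PixelMeasuresSequence = [pm]
    shared.PlaneOrientationSequence = [po]
    ds.SharedFunctionalGroupsSequence = [shared]

    frames = []
    per_frame = []
    for label in range(1, k + 1):
        for iz in range(nz):
            frames.append((habitat_map.labels[iz] == label).astype(np.uint8))
            fg = Dataset()
            sid = Dataset()
            sid.ReferencedSegmentNumber = label
            fg.SegmentIdentificationSequence = [sid]
            pp = Dataset()
            pos = reference.index_to_patient(np.array([0.0, 0.0, float(iz)]))
            pp.ImagePositionPatient = [float(v) for v in pos]
            fg.PlanePositionSequence = [pp]
            per_frame.append(fg)
    ds.PerFrameFunctionalGroupsSequence = per_frame
    ds.NumberOfFrames = len(frames)
    ds.PixelData = pack_bits(np.stack(frames, axis=0))
    ds.save_as(str(path), enforce_file_format=True)
    return path


def read_habitat_dicom(path, reference: ImageVolume | None = None) -> HabitatMap:
    """Read a habitat map written by :func:`write_habitat_dicom`."""
    ds = pydicom.dcmread(str(path))
    if ds.SOPClassUID != SEG_STORAGE:
        raise HabitatError(f"not a DICOM Segmentation object: {path}")
    ny, nx = int(ds.Rows), int(ds.Columns)
    n_frames = int(ds.NumberOfFrames)
    bits = unpack_bits(ds.PixelData)
    frames = bits[: n_frames * ny * nx].reshape(n_frames, ny, nx)

    per_frame = ds.PerFrameFunctionalGroupsSequence
    seg_numbers = [int(f.SegmentIdentificationSequence[0].ReferencedSegmentNumber)
                   for f in per_frame]
    positions = np.array(
        [np.asarray(f.PlanePositionSequence[0].ImagePositionPatient, float)
         for f in per_frame]
    )
    shared = ds.SharedFunctionalGroupsSequence[0]
    iop = np.asarray(
        shared.PlaneOrientationSequence[0].ImageOrientationPatient, float
    )
    normal = np.cross(iop[:3], iop[3:])
    k = len(ds.SegmentSequence)
    # Recover slice indices from positions along the slice normal.
    proj = positions @ normal
    unique_proj = np.unique(np.round(proj, 6))
    nz = len(unique_proj)
    slice_of = {p: i for i, p in enumerate(unique_proj)}
    labels = np.zeros((nz, ny, nx), dtype=np.int32)
    for frame, seg_no, p in zip(frames, seg_numbers, proj):
        iz = slice_of[round(float(p), 6)]
        sel = frame != 0
        labels[iz][sel] = seg_no
    pm = shared.PixelMeasuresSequence[0]
    spacing = np.array(
        [float(pm.PixelSpacing[1]), float(pm.PixelSpacing[0]),
         float(pm.SpacingBetweenSlices)]
    )
    if reference is not None and labels.shape != reference.shape:
        raise GeometryError("mask/volume geometry mismatch")
    counts = np.bincount(labels.ravel(), minlength=k + 1)[1:]
    vols = counts * float(np.prod(spacing)) / 1000.0
    present = np.unique(labels[labels > 0])
    if len(present) != k:
        warnings.warn("segmentation contains empty segments", stacklevel=2)
    return HabitatMap(labels=labels, k=k, volumes_cm3=vols)
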