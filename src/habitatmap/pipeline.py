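"""End-to-end orchestration: phantom/CT -> habitats -> fusion report.

`compute_habitats` is the library entry point chaining sub-segmentation,
texture maps, PCA, mixture clustering, labelling and the volume floor.
`run_pipeline` drives the same stages from a JSON config file and records a
manifest with content hashes so seeded runs can be verified to reproduce.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clustering import (
    HabitatModel,
    PCAModel,
    PipelineConfig,
    enforce_min_volume,
    fit_habitats,
    fit_pca,
    label_habitats,
    project,
)
from .core import HabitatError, HabitatMap, ImageVolume, VOIMask
from .fusion import (
    LandmarkSet,
    USFrame,
    dice,
    fit_rigid,
    fre,
    reslice_mask,
)
from .io import (
    mask_volume_cm3,
    read_ct_series,
    read_mask,
    sub_segment_solid,
    write_habitat_dicom,
    write_nifti_labels,
)
from .textures import TextureConfig, TextureMapStack, texture_map_stack


@dataclass
class HabitatResult:
    """Everything produced by one habitat-mapping run."""

    stack: TextureMapStack
    pca: PCAModel
    model: HabitatModel
    habitat_map: HabitatMap
    posteriors: np.ndarray
    solid_mask: VOIMask


def compute_habitats(
    volume: ImageVolume,
    mask: VOIMask,
    config: PipelineConfig = PipelineConfig(),
    site: str = "pelvis",
    pca: PCAModel | None = None,
) -> HabitatResult:
    """Run the full habitat pipeline on one lesion.

    Omental lesions are first sub-segmented to solid tissue.  When no
    pre-fitted PCA model is supplied the PCA is fitted on this lesion's own
    texture maps.
    """
    work_mask = mask
    if site == "omentum":
        work_mask = sub_segment_solid(volume, mask, config.fat_hu_max)
    tex_cfg = TextureConfig(
        window=config.window,
        n_levels=config.n_levels,
        window_masking=config.window_masking,
    )
    stack = texture_map_stack(volume, work_mask, tex_cfg)
    if pca is None:
        pca = fit_pca([stack], config.m_cap, config.variance_target)
    pcs = project(stack, pca)
    hu = stack.hu_vector()
    model = fit_habitats(pcs, hu, config)
    habitat_map, posteriors = label_habitats(
        model, pcs, hu, work_mask, valid=stack.valid,
        spacing=tuple(volume.spacing), config=config,
    )
    habitat_map = enforce_min_volume(
        habitat_map, posteriors, config.min_habitat_cm3, tuple(volume.spacing)
    )
    return HabitatResult(
        stack=stack, pca=pca, model=model, habitat_map=habitat_map,
        posteriors=posteriors, solid_mask=work_mask,
    )


def fuse_and_score(
    ct: ImageVolume,
    mask: VOIMask,
    landmarks: LandmarkSet,
    frame: USFrame,
    us_segmentation: np.ndarray,
) -> dict:
    """Register CT to US from landmarks and score the fusion with DSC."""
    transform = fit_rigid(landmarks)
    ct_silhouette = reslice_mask(mask, ct, frame, transform)
    return {
        "dsc": dice(ct_silhouette, us_segmentation),
        "fre_mm": fre(landmarks, transform),
        "rotation": transform.rotation.tolist(),
        "translation": transform.translation.tolist(),
    }


# ---------------------------------------------------------------------------
# file-level orchestration
# ---------------------------------------------------------------------------

def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def read_landmarks_csv(path) -> LandmarkSet:
    df = pd.read_csv(path)
    required = ["name", "ct_x", "ct_y", "ct_z", "us_x", "us_y", "us_z"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise HabitatError(f"landmark CSV missing columns: {missing}")
    return LandmarkSet(
        names=tuple(df["name"]),
        ct=df[["ct_x", "ct_y", "ct_z"]].to_numpy(float),
        us=df[["us_x", "us_y", "us_z"]].to_numpy(float),
    )


def write_landmarks_csv(landmarks: LandmarkSet, path) -> Path:
    df = pd.DataFrame(
        {
            "name": landmarks.names,
            "ct_x": landmarks.ct[:, 0], "ct_y": landmarks.ct[:, 1],
            "ct_z": landmarks.ct[:, 2],
            "us_x": landmarks.us[:, 0], "us_y": landmarks.us[:, 1],
            "us_z": landmarks.us[:, 2],
        }
    )
    df.to_csv(path, index=False)
    return Path(path)


def write_us_frame(frame: USFrame, path_json, path_image) -> None:
    import nibabel as nib

    img = nib.Nifti1Image(np.asarray(frame.pixels, dtype=np.float32).T, np.eye(4))
    nib.save(img, str(path_image))
    with open(path_json, "w") as fh:
        json.dump(
            {
                "image": str(Path(path_image).name),
                "spacing_mm": frame.spacing.tolist(),
                "origin_lps_mm": frame.origin.tolist(),
                "dir_col": frame.dir_col.tolist(),
                "dir_row": frame.dir_row.tolist(),
            },
            fh, indent=1,
        )


def read_us_frame(path_json) -> USFrame:
    import nibabel as nib

    path_json = Path(path_json)
    with open(path_json) as fh:
        meta = json.load(fh)
    img = nib.load(str(path_json.parent / meta["image"]))
    pixels = np.asanyarray(img.dataobj).T
    return USFrame(
        pixels=pixels,
        spacing=np.asarray(meta["spacing_mm"], float),
        origin=np.asarray(meta["origin_lps_mm"], float),
        dir_col=np.asarray(meta["dir_col"], float),
        dir_row=np.asarray(meta["dir_row"], float),
    )


def run_pipeline(config_path) -> dict:
    """One-shot run from a JSON config file; returns the manifest dict.

    The config names the CT and mask inputs (plus optional landmarks, US
    frame and US segmentation for fusion scoring) and may override any
    PipelineConfig field.  Outputs and the manifest are written to
    ``out_dir``; every file is recorded with a SHA-256 content hash.
    """
    config_path = Path(config_path)
    with open(config_path) as fh:
        cfg = json.load(fh)
    out_dir = Path(cfg.get("out_dir", config_path.parent / "habitat_out"))
    out_dir.mkdir(parents=True, exist_ok=True)

    pc_fields = {f.name for f in dataclasses.fields(PipelineConfig)}
    config = PipelineConfig(**{k: v for k, v in cfg.items() if k in pc_fields})
    site = cfg.get("site", "pelvis")

    manifest: dict = {
        "tool": "habitatmap",
        "version": __version__,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "config": {**dataclasses.asdict(config), "site": site},
        "inputs": {},
        "stages": [],
        "outputs": {},
        "seed": config.seed,
    }

    def record_input(name, path):
        manifest["inputs"][name] = {"path": str(path), "sha256": sha256_of(path)}

    def record_output(name, path):
        manifest["outputs"][name] = {"path": str(path), "sha256": sha256_of(path)}

    def stage(name):
        manifest["stages"].append(name)

    try:
        ct_path, mask_path = cfg["ct"], cfg["mask"]
        record_input("ct", ct_path) if Path(ct_path).is_file() else None
        volume = read_ct_series(ct_path)
        mask = read_mask(mask_path, volume)
        record_input("mask", mask_path)
        stage("load")

        if site == "omentum":
            stage("sub_segmentation")
        result = compute_habitats(volume, mask, config, site=site)
        stage("textures")
        stage("pca")
        stage("clustering")

        seg_path = out_dir / "habitats.dcm"
        write_habitat_dicom(result.habitat_map, volume, seg_path)
        record_output("habitats_dicom", seg_path)
        nifti_path = out_dir / "habitats.nii.gz"
        write_nifti_labels(result.habitat_map.labels, volume, nifti_path)
        record_output("habitats_nifti", nifti_path)
        pca_path = out_dir / "pca_model.json"
        result.pca.to_json(pca_path)
        record_output("pca_model", pca_path)
        stage("export")

        report = {
            "site": site,
            "k": result.habitat_map.k,
            "habitat_volumes_cm3": result.habitat_map.volumes_cm3.tolist(),
            "voi_volume_cm3": mask_volume_cm3(result.solid_mask, volume.spacing),
            "aic_by_k": {str(k): v for k, v in result.model.aic_by_k.items()},
            "pca_m": result.pca.m,
            "pca_cumulative_explained": result.pca.cumulative_explained,
        }
        if "landmarks" in cfg and "us_frame" in cfg and "us_seg" in cfg:
            import nibabel as nib

            landmarks = read_landmarks_csv(cfg["landmarks"])
            record_input("landmarks", cfg["landmarks"])
            frame = read_us_frame(cfg["us_frame"])
            record_input("us_frame", cfg["us_frame"])
            us_seg = np.asanyarray(nib.load(str(cfg["us_seg"])).dataobj).T != 0
            record_input("us_seg", cfg["us_seg"])
            report["fusion"] = fuse_and_score(volume, mask, landmarks, frame, us_seg)
            stage("fusion")

        report_path = out_dir / "report.json"
        with open(report_path, "w") as fh:
            json.dump(report, fh, indent=1)
        record_output("report", report_path)
    except HabitatError as exc:
        failed = manifest["stages"][-1] if manifest["stages"] else "load"
        raise HabitatError(f"pipeline failed after stage '{failed}': {exc}") from exc

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest_path = out_dir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


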