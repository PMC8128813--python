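# habitatmap

CT radiomic tumour-habitat mapping with landmark-based CT/US fusion scoring,
built for image-guided precision biopsy workflows in high-grade serous
ovarian cancer (HGSOC) and other settings where different sub-regions of a
tumour should be sampled separately.

## What it does

A contrast-enhanced CT volume and a tumour VOI mask go in; a habitat label
map (DICOM Segmentation object) and a fusion-accuracy report come out:

1. **Texture maps.** For every VOI voxel a 5×5 axial window is extracted,
   HU values are quantised to Ng = 32 grey levels over the lesion range,
   and a symmetric grey-level co-occurrence matrix (GLCM) is accumulated
   over the four in-plane unit offsets. Nine Haralick statistics are
   evaluated per voxel: energy, entropy, sum average, correlation, inverse
   difference moment normalised, contrast, cluster shade, cluster
   prominence and Haralick correlation.
2. **Dimensionality reduction.** Features are z-scored and projected onto
   the smallest number of principal components m that retains ≥ 90% of the
   variance (m ≤ 6).
3. **Habitat clustering.** The per-voxel vector (m PCs, standardised HU) is
   modelled by a full-covariance Gaussian mixture fitted by EM for
   k = 1..3; k is selected by minimum AIC,
   `AIC = 2q − 2 ln L̂` with `q = k−1 + kd + k d(d+1)/2`, d = m+1.
   Habitats smaller than 3 cm³ — too small to biopsy — are dissolved into
   the remaining components by posterior reassignment.
4. **CT/US fusion scoring.** A rigid CT→US transform is fitted from 1–3
   anatomical landmark pairs (translation / z-rotation / full Kabsch), the
   CT tumour silhouette is resliced into the US plane on the slice with the
   largest tumour area, and the overlap with the US segmentation is scored
   with the Dice similarity coefficient, `DSC = 2|A∩B| / (|A|+|B|)`.
   An undefined DSC (tumour edge not visible on US) is a first-class state,
   excluded from the median rather than counted as zero.

Omental lesions are first sub-segmented to solid tissue (fat excluded at
−30 HU with morphological cleanup); pelvic lesions are used as segmented.

A seeded phantom generator (`habitatmap.phantom`) builds CT-like ellipsoid
lesions with 1–3 ground-truth texture habitats, fat interspersion for
omental sites, and a simulated US frame under a known rigid transform, so
every stage is testable end to end without patient data.

## Worked example

```bash
python examples/habitat_mapping.py
```

prints, for a seeded three-habitat phantom:

```
lesion: 65.6 cm^3, 17496 voxels, 3 ground-truth habitats
PCA: 4 components retain 96.6% of the texture variance
AIC by habitat count: {1: 265850, 2: 160557, 3: 117960} -> selected k = 3 (lower AIC is better)
habitat volumes (cm^3): [20.1 20.3 25.2] - all above the 3 cm^3 biopsy-feasibility floor
agreement with ground truth: ARI = 0.85 (1 = perfect, 0 = chance; boundary voxels blur the wedge edges)
DICOM-SEG round trip exact: True
```

The AIC falls monotonically to k = 3 because the phantom really contains
three texture-distinct sub-regions; the adjusted Rand index of 0.85 against
the generative labels reflects near-perfect interior recovery with mixing
confined to wedge boundaries, where a 5×5 window necessarily straddles two
textures. `examples/fusion_accuracy.py` closes the registration loop (exact
landmarks → DSC 1.0, mean DSC falling to ≈ 0.75 at 5 mm landmark jitter)
and `examples/clinical_summary.py` reduces per-lesion values to
median/range summaries.

## Command line

The same stages are exposed as a thin CLI:

```bash
habitat phantom --site omentum --k 3 --seed 7 --out lesion/
habitat prep     --ct lesion/ct.nii.gz --mask lesion/mask.nii.gz --out solid.nii.gz
habitat textures --ct lesion/ct.nii.gz --mask solid.nii.gz --out maps.nii.gz
habitat pca      maps.nii.gz --out pca.json
habitat cluster  --maps maps.nii.gz --pca pca.json --seed 7 --out habitats.dcm
habitat fuse     --ct lesion/ct.nii.gz --mask lesion/mask.nii.gz \
                 --landmarks lesion/landmarks.csv --usframe lesion/us_frame.json \
                 --us-seg lesion/us_truth.nii.gz --out fusion.json
habitat run      config.json   # one-shot pipeline with a hashed manifest
```

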