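# Methods

## Texture maps

Per-voxel texture is computed in the axial plane with a sliding window of
5×5 voxels (odd, ≥ 3; configurable). HU values inside the (sub-segmented)
VOI are quantised by equal-width min–max binning into Ng = 32 grey levels;
the maximum maps to level Ng and a constant lesion maps to level 1. Min–max
binning makes every texture map invariant to positive affine rescalings of
HU. Two window policies exist: `voi` (default) uses only VOI voxels inside
the window, `volume` lets surrounding tissue contribute context (the
window is then clipped only at the volume edge). The default is `voi`
because windows that mix peritumoural tissue into the co-occurrence counts
blur the feature distributions at the lesion rim and measurably degrade
habitat recovery on phantoms.

For each window a grey-level co-occurrence matrix is accumulated over the
four unit-distance in-plane offsets (0°, 45°, 90°, 135°), counting each
pair in both directions (symmetric GLCM) and pooling all offsets into a
single matrix normalised to sum to 1; level-0 cells (outside the
quantisation domain) never pair. Nine statistics are evaluated with
1-based level values i, j and marginals μ, σ² (equal for the two margins by
symmetry):

| feature | definition |
|---|---|
| energy | Σ p² |
| entropy | −Σ p log₂ p (0·log 0 := 0) |
| sum average | Σ (i+j) p |
| correlation | (Σ ij p − μ²)/σ², 0 when σ² = 0 |
| IDMN | Σ p / (1 + ((i−j)/Ng)²) |
| contrast | Σ (i−j)² p |
| cluster shade | Σ (i+j−2μ)³ p |
| cluster prominence | Σ (i+j−2μ)⁴ p |
| Haralick correlation | (Σ ij p − μ²)/σ², 0 when σ² = 0 |

On a symmetric GLCM the two correlation variants are algebraically
identical; both slots are kept so the feature vector layout matches the
standard nine-name panel, and the PCA step absorbs the redundancy (the
duplicated column simply yields one exactly-zero eigenvalue). Entropy uses
base 2; the choice only scales one feature and is undone by the z-scoring
that precedes PCA.

The map engine computes per-window pair counts with zero-padded window
gathering and bincount accumulation, then evaluates all windows' features
in one vectorised pass. Feature sums use per-row pairwise summation so the
engine is bit-identical to composing `glcm` and `haralick_features` one
voxel at a time; that equivalence against a naive per-voxel loop is the
engine's primary test oracle.

## Sub-segmentation of omental lesions

Omental VOIs contain interspersed fat that is not tumour. The solid-tissue
mask keeps voxels with HU > −30 (fat ≈ −190..−30 HU), applies an in-plane
3×3 morphological opening, and removes connected components smaller than
0.1 cm³. The result is always a subset of the input mask and the operation
is idempotent. Pelvic lesions skip this step.

## PCA

Pooled per-voxel feature vectors are z-scored with the training mean and
standard deviation (a zero-variance feature is left unscaled with a
warning) and decomposed by full SVD. The retained count m is the smallest
number of components whose cumulative explained variance reaches 90%,
capped at 6; if even 6 fall short the model is flagged `capped`. The model
(mean, scale, loadings, explained fractions) serialises to JSON so a
pre-fitted reference model can be applied to new lesions; by default the
PCA is fitted on the lesion (or lesion set) being analysed.

## Habitat clustering

Each valid voxel contributes (m PCs, HU). HU is z-scored over the lesion
before joining the PCs — otherwise its numeric range (hundreds of HU
against unit-variance components) would dominate the Euclidean geometry EM
relies on; raw HU remains available via `standardize_hu=False`. For
k = 1..3 a full-covariance Gaussian mixture is fitted by EM with k-means++
initialisation, 5 restarts, convergence tolerance 1e-4 on the
log-likelihood, covariance regularisation 1e-6 and a fixed seed; k is
chosen by minimum AIC with q = k−1 + kd + kd(d+1)/2 free parameters
(d = m+1), ties breaking toward smaller k. Mixture component labels are
arbitrary, so habitats are renumbered 1..k by increasing component mean HU
(a deterministic rule needed for testing and export); empty components are
dropped. VOI voxels without valid texture features (possible only for
degenerate windows) inherit the label of the nearest valid voxel.

Habitats below the 3 cm³ floor are dissolved smallest-first: each voxel of
the dissolved habitat moves to the remaining habitat with the highest
posterior, labels are renumbered, and the step repeats until every habitat
reaches the floor or one habitat remains. Total volume is conserved
exactly because voxels are reassigned, never discarded.

With identical inputs and seed the whole pipeline is bit-reproducible.

## Registration and fusion scoring

The CT→US transform is rigid. One landmark pair gives a pure translation;
two pairs give the centroid translation plus the least-squares rotation
about the craniocaudal axis (the axial orientation having been aligned
first, matching a protocol that acquires a strictly axial US frame before
placing fusion points); three non-collinear pairs give the full Kabsch
solution with determinant correction; a collinear triplet falls back to
the two-pair solution with a warning. Registration quality is reported as
the fiducial registration error (RMS landmark residual, mm).

The fusion score reslices the CT VOI mask into the US plane by mapping
each US pixel through the inverse transform and sampling the mask at the
nearest voxel (nearest-neighbour keeps the mask binary), on the axial
slice with the largest tumour area (ties break toward the inferior-most
slice). The Dice coefficient compares that silhouette with the US
segmentation; when both masks are empty the DSC is undefined and is
reported as such, not as zero. Medians use the mean-of-middle-two
convention for even counts.

Patient space is DICOM LPS everywhere; voxel arrays are indexed
[slice, row, column] with 0-based indices.

## File formats

CT volumes read from DICOM series (slices sorted along the slice normal;
mixed SeriesInstanceUIDs rejected) or NIfTI-1 (RAS affines converted to
LPS). Habitat maps export as a DICOM Segmentation object — one bit-packed
binary segment per habitat, per-frame plane positions, shared geometry —
written directly with pydicom, plus a NIfTI label-map mirror; the
round trip restores labels bit-exactly. Output UIDs are derived from
content hashes so seeded reruns produce byte-identical files, which the
run manifest verifies with SHA-256 hashes. Landmarks travel as CSV
(name, ct_x..us_z, mm) and US frames as an image plus a JSON pose sidecar.

## The phantom generator

The generator emulates the measurement situation, not CT physics: an
ellipsoidal lesion of soft-tissue attenuation inside a ≈ 40 HU background,
partitioned into 1–3 azimuthal wedges with known labels. Each wedge gets
mean HU plus a Gaussian noise field with a per-habitat amplitude and
optional Gaussian-smoothing correlation length (the smoothed field is
rescaled to keep its pointwise standard deviation, so amplitude and
correlation length are independent dials). Omental phantoms additionally
scatter fat blobs (−100 HU) over a stated fraction of the VOI using a
thresholded correlated field. The US frame is a geometric silhouette of
the largest-area lesion slice pushed through a known rigid transform, with
multiplicative speckle on the image channel and three anatomical landmark
analogues jittered on the US side; acoustic wave propagation is out of
scope because only geometry matters for Dice-based accuracy.

Default conditions: 1.0×1.0 mm pixels with 3.75 mm slices, a flat
56×56×5.6 mm semi-axis lesion (≈ 66 cm³, within the 16–592 cm³ range of
lesions this workflow targets), habitat means 0/55/110 HU and noise
amplitudes 10/22/50 HU. Two deliberate choices deserve explanation:

- **Amplitude-graded white noise rather than correlation-length-graded
  noise.** Fields whose correlation length approaches the 5×5 window are
  non-stationary at window scale: the same habitat then produces windows
  that are locally flat and windows that sit on a patch gradient, so its
  feature distribution becomes bimodal and heavy-tailed, and the mixture
  model carves it along texture drift rather than habitat identity.
  Amplitude-graded white noise keeps each habitat's windowed statistics
  stationary and compact while still separating habitats in entropy,
  contrast and energy (entropy gaps ≈ 0.5–1 bit between adjacent
  habitats). Correlation length remains a supported parameter and the
  smoothing→entropy relationship (a ≥ 3× length ratio shifts mean entropy
  by well over 0.2 bits) is asserted in the tests.
- **A wide, flat lesion.** Any window-based texture map mixes textures
  within (window−1) voxels of a habitat boundary; those voxels are
  systematically mis-assignable and their fraction scales as
  window/radius. A ≥ 56-voxel in-plane radius keeps the boundary band
  below ≈ 7% of the lesion so that label recovery (ARI ≥ 0.8) is
  achievable when the habitat count is recovered; restricting the lesion
  to two thick axial slices avoids the small extreme-z cross-sections of a
  round ellipsoid, which are almost entirely boundary band.

What passing phantom tests do **not** show: real lesions have scanner
noise spectra, partial-volume effects at 2–5 mm slice thickness,
reconstruction-kernel texture and habitats of irregular shape; the phantom
establishes the computational contract, not clinical performance.

## Known limitations

- **AIC selects the habitat cap on textured data.** Per-voxel GLCM
  statistics from 5×5 windows are sampling statistics over ~160 level
  pairs; their distributions are intrinsically skewed (energy, cluster
  prominence) and the per-habitat feature cloud is a curved manifold. A
  mixture with more Gaussian components always fits such a cloud better by
  far more than the AIC penalty, so on textured input the selected k
  reaches the cap k = 3 regardless of the generative habitat count — for
  every noise family we tested and at every sample size from 5×10² to
  2×10⁴ voxels. The cap, not the AIC minimum, is therefore the effective
  regulariser of the habitat count; the same behaviour is visible in
  clinical use of this pipeline class, where the selected cluster count
  sits at the cap across patients. Consequently phantoms with one or two
  generative habitats are over-segmented (the acceptance suite records
  this as a failing recovery-rate check), while three-habitat phantoms are
  recovered with ARI 0.83–0.86.
- The 2D window means habitats thinner than one slice cannot be separated
  along z.
- Rigid registration cannot model the soft-tissue deformation that lowers
  fusion accuracy for mobile omental deposits; landmark jitter in the
  phantom emulates localisation error, not deformation.
- The DICOM-SEG writer targets round-trip fidelity and standard geometry
  modules; it does not claim full IOD conformance against clinical
  validators.
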