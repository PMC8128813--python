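"""Map tumour habitats on a synthetic CT lesion and export them as DICOM.

Builds a seeded phantom lesion with three texture-distinct sub-regions,
runs the full pipeline (sliding-window texture maps -> PCA -> Gaussian
mixture with AIC selection -> 3 cm^3 volume floor) and prints what each
stage decided.
"""

import tempfile
from pathlib import Path

import numpy as np
from sklearn.metrics import adjusted_rand_score

import habitatmap as hm

spec = hm.PhantomSpec(true_k=3, seed=17)
phantom = hm.make_phantom(spec)
print(f"lesion: {hm.mask_volume_cm3(phantom.mask, spec.spacing):.1f} cm^3, "
      f"{phantom.mask.count} voxels, {spec.true_k} ground-truth habitats")

result = hm.compute_habitats(phantom.volume, phantom.mask,
                             hm.PipelineConfig(seed=17))

print(f"PCA: {result.pca.m} components retain "
      f"{100 * result.pca.cumulative_explained:.1f}% of the texture variance")
print("AIC by habitat count:",
      {k: round(v) for k, v in result.model.aic_by_k.items()},
      f"-> selected k = {result.habitat_map.k} (lower AIC is better)")
print("habitat volumes (cm^3):",
      np.round(result.habitat_map.volumes_cm3, 1),
      "- all above the 3 cm^3 biopsy-feasibility floor")

voi = phantom.mask.voxels
ari = adjusted_rand_score(phantom.truth.labels[voi],
                          result.habitat_map.labels[voi])
print(f"agreement with ground truth: ARI = {ari:.2f} "
      "(1 = perfect, 0 = chance; boundary voxels blur the wedge edges)")

with tempfile.TemporaryDirectory() as td:
    path = hm.write_habitat_dicom(result.habitat_map, phantom.volume,
                                  Path(td) / "habitats.dcm")
    back = hm.read_habitat_dicom(path)
    print("DICOM-SEG round trip exact:",
          bool(np.array_equal(back.labels, result.habitat_map.labels)))
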