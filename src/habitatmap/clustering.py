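"""Habitat clustering: PCA reduction and Gaussian-mixture habitat models.

Per-voxel texture vectors are standardised and reduced to the smallest
number of principal components retaining at least 90% of the variance
(capped at 6).  The retained components together with the (standardised)
HU value feed a full-covariance Gaussian mixture; the habitat count k is
selected as the argmin of the Akaike information criterion over k = 1..3,
and habitats smaller than a physical volume floor (default 3 cm^3) are
dissolved into the remaining components by posterior reassignment.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA
from sklearn.mixture import GaussianMixture

from .core import HabitatError, HabitatMap, VOIMask
from .textures import FEATURE_NAMES, TextureMapStack


@dataclass(frozen=True)
class PipelineConfig:
    """Fixed constants of the habitat pipeline."""

    window: int = 5
    n_levels: int = 32
    m_cap: int = 6
    variance_target: float = 0.90
    k_max: int = 3
    min_habitat_cm3: float = 3.0
    fat_hu_max: float = -30.0
    standardize_hu: bool = True
    window_masking: str = "voi"
    seed: int = 0

    def __post_init__(self):
        if self.k_max < 1:
            raise HabitatError("k_max must be >= 1")
        for name in ("m_cap", "variance_target", "min_habitat_cm3"):
            if getattr(self, name) <= 0:
                raise HabitatError(f"{name} must be positive")


@dataclass(frozen=True)
class PCAModel:
    """Standardisation + principal-component loadings fitted on training maps.

    ``loadings`` is (n_features, m) with orthonormal columns; ``explained``
    holds the per-component explained-variance fractions (non-increasing).
    ``capped`` is True when even ``m`` = cap components fall short of the
    variance target.
    """

    mean: np.ndarray
    scale: np.ndarray
    loadings: np.ndarray
    explained: np.ndarray
    m: int
    variance_target: float = 0.90
    capped: bool = False

    @property
    def cumulative_explained(self) -> float:
        return float(np.sum(self.explained))

    def transform(self, features: np.ndarray) -> np.ndarray:
        """Project (n, 9) raw feature vectors onto the retained components."""
        z = (np.asarray(features, float) - self.mean) / self.scale
        return z @ self.loadings

    def to_json(self, path) -> None:
        payload = {
            "mean": self.mean.tolist(),
            "scale": self.scale.tolist(),
            "loadings": self.loadings.tolist(),
            "explained": self.explained.tolist(),
            "m": self.m,
            "variance_target": self.variance_target,
            "capped": self.capped,
            "feature_names": list(FEATURE_NAMES),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "PCAModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            mean=np.asarray(d["mean"], float),
            scale=np.asarray(d["scale"], float),
            loadings=np.asarray(d["loadings"], float),
            explained=np.asarray(d["explained"], float),
            m=int(d["m"]),
            variance_target=float(d.get("variance_target", 0.90)),
            capped=bool(d.get("capped", False)),
        )


def select_component_count(explained_ratios, variance_target: float = 0.90,
                           m_cap: int = 6) -> int:
    """Smallest component count whose cumulative explained variance reaches
    the target, capped at ``m_cap``."""
    ratios = np.asarray(explained_ratios, float)
    cum = np.cumsum(ratios)
    reach = np.flatnonzero(cum >= variance_target - 1e-12)
    m_needed = int(reach[0]) + 1 if len(reach) else len(ratios)
    return min(m_needed, m_cap, len(ratios))


def fit_pca(
    training_stacks: list[TextureMapStack],
    m_cap: int = 6,
    variance_target: float = 0.90,
) -> PCAModel:
    """Fit the texture-map PCA on pooled valid voxels of training stacks.

    Features are z-scored with the pooled mean and standard deviation
    (zero-variance features are left unscaled with a warning); the retained
    component count m is the smallest whose cumulative explained variance
    reaches ``variance_target``, capped at ``m_cap``.
    """
    if not training_stacks:
        raise HabitatError("insufficient training data")
    X = np.vstack([s.feature_matrix() for s in training_stacks])
    n, d = X.shape
    if n < 10 * d:
        raise HabitatError(
            f"insufficient training data: {n} voxels < {10 * d} required"
        )
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    zero = scale <= 1e-12
    if zero.any():
        names = [FEATURE_NAMES[i] for i in np.flatnonzero(zero)]
        warnings.warn(
            f"zero-variance features excluded from standardisation: {names}",
            stacklevel=2,
        )
        scale = np.where(zero, 1.0, scale)
    Z = (X - mean) / scale
    pca = PCA(svd_solver="full")
    pca.fit(Z)
    ratios = pca.explained_variance_ratio_
    m = select_component_count(ratios, variance_target, m_cap)
    capped = float(np.sum(ratios[:m])) < variance_target - 1e-12
    return PCAModel(
        mean=mean,
        scale=scale,
        loadings=pca.components_[:m].T.copy(),
        explained=ratios[:m].copy(),
        m=m,
        variance_target=variance_target,
        capped=capped,
    )


def project(stack: TextureMapStack, pca: PCAModel) -> np.ndarray:
    """Per-voxel PC values, shape (n_valid, m), aligned with stack.valid."""
    return pca.transform(stack.feature_matrix())


@dataclass(frozen=True)
class HabitatModel:
    """Selected Gaussian-mixture habitat model over (PCs, standardised HU)."""

    k: int
    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray
    aic_by_k: dict
    seed: int
    hu_mean: float
    hu_std: float
    mixtures: dict = field(repr=False, default_factory=dict)

    @property
    def mixture(self) -> GaussianMixture:
        return self.mixtures[self.k]

    def component_mean_hu(self) -> np.ndarray:
        """Mean HU of each mixture component, back on the raw HU scale."""
        return self.means[:, -1] * self.hu_std + self.hu_mean


def _clustering_matrix(pc_values, hu_values, standardize_hu, hu_mean, hu_std):
    pcs = np.asarray(pc_values, float)
    hu = np.asarray(hu_values, float)
    hu_col = (hu - hu_mean) / hu_std if standardize_hu else hu
    return np.column_stack([pcs, hu_col])


def fit_habitats(
    pc_values: np.ndarray,
    hu_values: np.ndarray,
    config: PipelineConfig = PipelineConfig(),
) -> HabitatModel:
    """Fit Gaussian mixtures for k = 1..k_max and select k by minimum AIC.

    EM uses k-means++ initialisation with 5 restarts, tolerance 1e-4 and
    covariance regularisation 1e-6, all seeded for bit-reproducibility.
    AIC = 2q - 2 ln L with q = k-1 + k d + k d(d+1)/2 free parameters
    (full covariances, d = m+1 dimensions); ties break toward smaller k.
    """
    pcs = np.atleast_2d(np.asarray(pc_values, float))
    hu = np.asarray(hu_values, float)
    if pcs.shape[0] < 50:
        raise HabitatError("too few voxels for clustering (need >= 50)")
    hu_mean = float(hu.mean())
    hu_std = float(hu.std())
    if hu_std <= 1e-12:
        hu_std = 1.0
    X = _clustering_matrix(pcs, hu, config.standardize_hu, hu_mean, hu_std)
    aic_by_k: dict[int, float] = {}
    mixtures: dict[int, GaussianMixture] = {}
    for k in range(1, config.k_max + 1):
        gm = GaussianMixture(
            n_components=k,
            covariance_type="full",
            n_init=5,
            init_params="k-means++",
            tol=1e-4,
            reg_covar=1e-6,
            max_iter=300,
            random_state=config.seed,
        )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                gm.fit(X)
            if not gm.converged_ and gm.lower_bound_ == -np.inf:
                raise ValueError("EM did not converge")
        except Exception as exc:  # pragma: no cover - rare numerical failure
            warnings.warn(f"EM failed for k={k}: {exc}", stacklevel=2)
            continue
        aic_by_k[k] = float(gm.aic(X))
        mixtures[k] = gm
    if not aic_by_k:
        raise HabitatError("clustering failed")
    k_sel = min(aic_by_k, key=lambda k: (aic_by_k[k], k))
    gm = mixtures[k_sel]
    return HabitatModel(
        k=k_sel,
        weights=gm.weights_.copy(),
        means=gm.means_.copy(),
        covariances=gm.covariances_.copy(),
        aic_by_k=aic_by_k,
        seed=config.seed,
        hu_mean=hu_mean,
        hu_std=hu_std,
        mixtures=mixtures,
    )


def label_habitats(
    model: HabitatModel,
    pc_values: np.ndarray,
    hu_values: np.ndarray,
    mask: VOIMask,
    valid: np.ndarray | None = None,
    spacing=(1.0, 1.0, 1.0),
    config: PipelineConfig = PipelineConfig(),
) -> tuple[HabitatMap, np.ndarray]:
    """Assign each VOI voxel its maximum-posterior habitat.

    Labels are renumbered 1..k in increasing order of component mean HU so
    that label identity is deterministic.  VOI voxels without valid texture
    features (degenerate windows) inherit the label of the nearest valid
    voxel.  Returns the map together with the per-voxel posterior array
    (n_voi_voxels, k) aligned with the VOI voxels in C order, which
    :func:`enforce_min_volume` uses for reassignment.
    """
    from scipy import ndimage

    X = _clustering_matrix(
        pc_values, hu_values, config.standardize_hu, model.hu_mean, model.hu_std
    )
    post_valid = model.mixture.predict_proba(X)
    comp = post_valid.argmax(axis=1)

    valid_grid = np.asarray(valid) if valid is not None else mask.voxels
    comp_grid = np.full(mask.voxels.shape, -1, dtype=np.int64)
    comp_grid[valid_grid] = comp
    post_grid = np.zeros(mask.voxels.shape + (post_valid.shape[1],))
    post_grid[valid_grid] = post_valid
    missing = mask.voxels & ~valid_grid
    if missing.any():
        _, nearest = ndimage.distance_transform_edt(
            ~valid_grid, return_indices=True, sampling=spacing[::-1]
        )
        src = tuple(ind[missing] for ind in nearest)
        comp_grid[missing] = comp_grid[src]
        post_grid[missing] = post_grid[src]

    # renumber components -> labels by increasing mean HU, dropping empties
    assigned = comp_grid[mask.voxels]
    present = np.unique(assigned)
    order = present[np.argsort(model.component_mean_hu()[present], kind="stable")]
    label_of = np.zeros(model.k, dtype=np.int64)
    for lbl, c in enumerate(order, start=1):
        label_of[c] = lbl
    labels = np.zeros(mask.voxels.shape, dtype=np.int32)
    labels[mask.voxels] = label_of[assigned]
    k = len(present)
    voxel_cm3 = float(np.prod(spacing)) / 1000.0
    counts = np.bincount(labels.ravel(), minlength=k + 1)[1 : k + 1]
    habitat_map = HabitatMap(labels=labels, k=k, volumes_cm3=counts * voxel_cm3)
    posteriors = post_grid[mask.voxels][:, order]  # columns in label order
    return habitat_map, posteriors


def enforce_min_volume(
    habitat_map: HabitatMap,
    posteriors: np.ndarray,
    min_habitat_cm3: float = 3.0,
    spacing=(1.0, 1.0, 1.0),
) -> HabitatMap:
    """Dissolve habitats smaller than the volume floor.

    The smallest sub-threshold habitat's voxels are reassigned to the
    remaining habitat with the highest posterior; labels are renumbered and
    the step repeats until every habitat reaches the floor or one habitat
    remains.  Total volume is conserved exactly.
    """
    labels = habitat_map.labels.copy()
    voi = labels > 0
    flat = labels[voi]  # C-order VOI voxels, aligned with posteriors rows
    post = np.asarray(posteriors, float)
    if post.shape[0] != flat.shape[0]:
        raise HabitatError("posterior array does not match the habitat map")
    voxel_cm3 = float(np.prod(spacing)) / 1000.0
    active = list(range(1, habitat_map.k + 1))
    while len(active) > 1:
        counts = {lbl: int((flat == lbl).sum()) for lbl in active}
        vols = {lbl: counts[lbl] * voxel_cm3 for lbl in active}
        small = [lbl for lbl in active if vols[lbl] < min_habitat_cm3]
        if not small:
            break
        victim = min(small, key=lambda lbl: (vols[lbl], lbl))
        active.remove(victim)
        cols = [lbl - 1 for lbl in active]
        sel = flat == victim
        repl = post[np.ix_(sel, cols)].argmax(axis=1)
        flat[sel] = np.asarray(active)[repl]
    # renumber surviving labels contiguously, preserving order
    remap = {old: new for new, old in enumerate(sorted(active), start=1)}
    flat = np.vectorize(remap.get)(flat) if len(remap) else flat
    labels[voi] = flat
    k = len(active)
    counts = np.bincount(labels.ravel(), minlength=k + 1)[1 : k + 1]
    return HabitatMap(labels=labels, k=k, volumes_cm3=counts * voxel_cm3)
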