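"""Sliding-window grey-level co-occurrence texture maps.

For every voxel of the VOI a 2D window (default 5x5, axial plane) is
extracted, HU values are quantised to ``n_levels`` grey levels over the
lesion's min-max range, a symmetric GLCM is accumulated over the four
unit-distance in-plane offsets, and nine Haralick statistics are evaluated:
energy, entropy, sum average, correlation, inverse difference moment
normalised (IDMN), contrast, cluster shade, cluster prominence and Haralick
correlation.

The map engine computes per-window co-occurrence counts with integer
summed-area tables, so a slow per-voxel loop over :func:`glcm` +
:func:`haralick_features` reproduces it bit-for-bit; that equivalence is the
engine's main correctness oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import EmptyMaskError, HabitatError, ImageVolume, VOIMask

#: Feature order used throughout the package.
FEATURE_NAMES = (
    "energy",
    "entropy",
    "sum_average",
    "correlation",
    "idmn",
    "contrast",
    "cluster_shade",
    "cluster_prominence",
    "haralick_correlation",
)

#: (dy, dx) unit offsets at 0, 45, 90 and 135 degrees.
DEFAULT_OFFSETS = ((0, 1), (-1, 1), (-1, 0), (-1, -1))


@dataclass(frozen=True)
class TextureConfig:
    """Parameters of the sliding-window texture extraction.

    window:
        odd in-plane window size in voxels.
    n_levels:
        number of grey levels for quantisation.
    offsets:
        2D (dy, dx) displacement vectors; each is accumulated together with
        its negation (symmetric GLCM).
    window_masking:
        "volume" clips windows at the volume edge only, so tissue just
        outside the VOI contributes context; "voi" restricts window content
        to VOI voxels.
    """

    window: int = 5
    n_levels: int = 32
    offsets: tuple = DEFAULT_OFFSETS
    window_masking: str = "voi"

    def __post_init__(self):
        if self.window < 3 or self.window % 2 == 0:
            raise HabitatError("window must be odd and >= 3")
        if self.n_levels < 2:
            raise HabitatError("n_levels must be >= 2")
        if not self.offsets:
            raise HabitatError("offsets must be non-empty")
        for off in self.offsets:
            if len(off) != 2:
                raise HabitatError("offsets must be in-plane (dy, dx) pairs")
        if self.window_masking not in ("volume", "voi"):
            raise HabitatError("window_masking must be 'volume' or 'voi'")


@dataclass(frozen=True)
class TextureMapStack:
    """Per-voxel texture feature maps over a VOI.

    features : (9, nz, ny, nx) array in FEATURE_NAMES order.
    hu : (nz, ny, nx) HU values copied from the source volume.
    valid : boolean grid; True where all nine features were computed.
    """

    features: np.ndarray
    hu: np.ndarray
    valid: np.ndarray

    def __post_init__(self):
        if self.features.shape[0] != len(FEATURE_NAMES):
            raise HabitatError("feature stack must have 9 channels")

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def feature_matrix(self) -> np.ndarray:
        """(n_valid, 9) matrix of feature vectors at valid voxels."""
        return self.features[:, self.valid].T

    def hu_vector(self) -> np.ndarray:
        return self.hu[self.valid]


def quantize(
    volume: ImageVolume | np.ndarray,
    mask: VOIMask | np.ndarray,
    n_levels: int,
    extent: str = "mask",
) -> np.ndarray:
    """Quantise HU to integer grey levels 1..n_levels by min-max binning.

    Bin edges are equal-width over the HU range *inside the mask*; the
    maximum maps to ``n_levels``; a constant region maps to level 1.  With
    ``extent="mask"`` voxels outside the mask get level 0; with
    ``extent="volume"`` the mask-derived binning is applied (clipped) to the
    whole grid so windows can draw context from surrounding tissue.
    """
    hu = volume.voxels if isinstance(volume, ImageVolume) else np.asarray(volume, float)
    m = mask.voxels if isinstance(mask, VOIMask) else np.asarray(mask) != 0
    if not m.any():
        raise EmptyMaskError("empty VOI")
    lo = float(hu[m].min())
    hi = float(hu[m].max())
    levels = np.zeros(hu.shape, dtype=np.int32)
    target = None if extent == "volume" else m
    if hi == lo:
        if target is None:
            levels[:] = 1
        else:
            levels[target] = 1
        return levels
    scaled = np.floor((hu - lo) / (hi - lo) * n_levels).astype(np.int64) + 1
    scaled = np.clip(scaled, 1, n_levels)
    if target is None:
        levels[:] = scaled
    else:
        levels[target] = scaled[target]
    return levels


def glcm(levels: np.ndarray, offsets=DEFAULT_OFFSETS, n_levels: int = 32) -> np.ndarray:
    """Symmetric normalised grey-level co-occurrence matrix of one 2D window.

    Counts level pairs for each (dy, dx) offset and its negation, pooling
    all offsets into a single n_levels x n_levels matrix normalised to sum
    to 1.  Cells with level 0 are ignored.
    """
    lv = np.asarray(levels)
    if lv.ndim != 2:
        raise HabitatError("glcm expects a 2D window of levels")
    counts = np.zeros(n_levels * n_levels, dtype=np.int64)
    ny, nx = lv.shape
    for dy, dx in offsets:
        a = lv[max(0, -dy): ny - max(0, dy), max(0, -dx): nx - max(0, dx)]
        b = lv[max(0, dy): ny - max(0, -dy), max(0, dx): nx - max(0, -dx)]
        ok = (a > 0) & (b > 0)
        if not ok.any():
            continue
        ai = a[ok].astype(np.int64) - 1
        bi = b[ok].astype(np.int64) - 1
        np.add.at(counts, ai * n_levels + bi, 1)
        np.add.at(counts, bi * n_levels + ai, 1)
    total = counts.sum()
    if total == 0:
        raise HabitatError("degenerate window")
    return (counts / total).reshape(n_levels, n_levels)


def _feature_rows(p_rows: np.ndarray, n_levels: int) -> np.ndarray:
    """Evaluate the nine Haralick statistics for rows of flattened GLCMs.

    ``p_rows`` is (n, n_levels**2), each row a normalised symmetric GLCM
    flattened in row-major (i, j) order with 1-based level values.  Returns
    (n, 9) in FEATURE_NAMES order.  Shared by :func:`haralick_features` and
    the sliding-window engine so both paths are numerically identical.
    """
    ng = n_levels
    i_val = (1.0 + np.arange(ng * ng) // ng)
    j_val = (1.0 + np.arange(ng * ng) % ng)
    s_val = i_val + j_val
    d_val = i_val - j_val

    def rowsum(weights):
        # row-wise weighted sums via pairwise summation: bit-identical
        # whether called on one GLCM or a whole batch
        return (p_rows * weights).sum(axis=1)

    energy = (p_rows * p_rows).sum(axis=1)
    logs = np.zeros_like(p_rows)
    np.log2(p_rows, where=p_rows > 0, out=logs)
    entropy = -(p_rows * logs).sum(axis=1)
    sum_avg = rowsum(s_val)
    mu = rowsum(i_val)  # symmetric: mu_x == mu_y
    var = rowsum(i_val * i_val) - mu * mu
    e_ij = rowsum(i_val * j_val)
    cov = e_ij - mu * mu
    corr = np.where(var > 1e-12, cov / np.where(var > 1e-12, var, 1.0), 0.0)
    idmn = rowsum(1.0 / (1.0 + (d_val / ng) ** 2))
    contrast = rowsum(d_val * d_val)
    # central moments of s = i + j about 2*mu
    e_s1 = sum_avg
    e_s2 = rowsum(s_val**2)
    e_s3 = rowsum(s_val**3)
    e_s4 = rowsum(s_val**4)
    c = 2.0 * mu
    shade = e_s3 - 3 * c * e_s2 + 3 * c * c * e_s1 - c**3
    prom = e_s4 - 4 * c * e_s3 + 6 * c * c * e_s2 - 4 * c**3 * e_s1 + c**4
    har_corr = corr  # identical to correlation for a symmetric GLCM
    return np.column_stack(
        [energy, entropy, sum_avg, corr, idmn, contrast, shade, prom, har_corr]
    )


def haralick_features(p: np.ndarray) -> np.ndarray:
    """Nine Haralick statistics of one normalised symmetric GLCM.

    Order: energy, entropy, sum average, correlation, IDMN, contrast,
    cluster shade, cluster prominence, Haralick correlation.  Correlation
    and Haralick correlation are algebraically identical on a symmetric
    matrix and are reported in both slots.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 2 or p.shape[0] != p.shape[1]:
        raise HabitatError("invalid GLCM: must be square")
    if abs(p.sum() - 1.0) > 1e-6 or np.any(p < 0):
        raise HabitatError("invalid GLCM: not a normalised distribution")
    if not np.allclose(p, p.T, atol=1e-9):
        raise HabitatError("invalid GLCM: not symmetric")
    return _feature_rows(p.reshape(1, -1), p.shape[0])[0]


def _window_pair_counts(levels2d: np.ndarray, offsets, n_levels: int,
                        centers_y: np.ndarray, centers_x: np.ndarray,
                        half: int) -> np.ndarray:
    """Per-window symmetric co-occurrence counts for one slice.

    For each requested window centre, counts every ordered level pair whose
    two cells both lie inside the (edge-clipped) window, for each offset
    and its negation; edge clipping is realised by zero-padding (level 0 is
    never a valid pair member).  Returns (n_centers, n_levels**2) int64.
    """
    ny, nx = levels2d.shape
    ncodes = n_levels * n_levels
    w = 2 * half + 1
    pad = np.zeros((ny + 2 * half, nx + 2 * half), dtype=np.int64)
    pad[half: half + ny, half: half + nx] = levels2d
    n = len(centers_y)
    wy = centers_y[:, None, None] + np.arange(w)[None, :, None]
    wx = centers_x[:, None, None] + np.arange(w)[None, None, :]
    win = pad[wy, wx]  # (n, w, w); pad offset cancels the -half shift
    counts = np.zeros((n, ncodes), dtype=np.int64)
    rows = np.broadcast_to(np.arange(n, dtype=np.int64)[:, None, None], win.shape)
    for dy, dx in offsets:
        a = win[:, max(0, -dy): w - max(0, dy), max(0, -dx): w - max(0, dx)]
        b = win[:, max(0, dy): w - max(0, -dy), max(0, dx): w - max(0, -dx)]
        ok = (a > 0) & (b > 0)
        if not ok.any():
            continue
        r = rows[:, : a.shape[1], : a.shape[2]][ok]
        ai, bi = a[ok] - 1, b[ok] - 1
        for code in (ai * n_levels + bi, bi * n_levels + ai):
            counts += np.bincount(
                r * ncodes + code, minlength=n * ncodes
            ).reshape(n, ncodes)
    return counts


def texture_map_stack(
    volume: ImageVolume,
    mask: VOIMask,
    config: TextureConfig = TextureConfig(),
) -> TextureMapStack:
    """Compute the nine sliding-window texture maps over every VOI voxel.

    Windows are 2D in the axial plane, centred on each VOI voxel and clipped
    at the volume edge.  Voxels whose window yields no valid co-occurrence
    pair are marked invalid.
    """
    mask.require_nonempty()
    extent = "volume" if config.window_masking == "volume" else "mask"
    levels = quantize(volume, mask, config.n_levels, extent=extent)
    nz, ny, nx = volume.shape
    half = config.window // 2
    features = np.zeros((len(FEATURE_NAMES),) + volume.shape, dtype=float)
    valid = np.zeros(volume.shape, dtype=bool)
    chunk = 4096  # bounds the (chunk, n_levels**2) working arrays
    for iz in range(nz):
        my, mx = np.nonzero(mask.voxels[iz])
        if len(my) == 0:
            continue
        for lo in range(0, len(my), chunk):
            cy, cx = my[lo: lo + chunk], mx[lo: lo + chunk]
            counts = _window_pair_counts(
                levels[iz], config.offsets, config.n_levels, cy, cx, half
            )
            totals = counts.sum(axis=1)
            ok = totals > 0
            if not ok.any():
                continue
            p_rows = counts[ok] / totals[ok, None]
            feats = _feature_rows(p_rows, config.n_levels)
            features[:, iz, cy[ok], cx[ok]] = feats.T
            valid[iz, cy[ok], cx[ok]] = True
    if not valid.any():
        raise HabitatError("lesion too small for texture analysis")
    return TextureMapStack(features=features, hu=volume.voxels.copy(), valid=valid)
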