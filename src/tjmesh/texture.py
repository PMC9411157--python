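"""Gray-level co-occurrence texture features of meshwork ROIs.

The classification pipeline characterises STED intensity texture with three
Haralick statistics — sum average, sum variance and "sum of squares:
variance" — computed from gray-level co-occurrence matrices (GLCMs) at pixel
offsets 1, 3, 5 and 10 px, each averaged over the four standard directions
(0, 45, 90, 135 degrees). Images are prefiltered with a 3 px Gaussian kernel
of sigma 1 before GLCM accumulation.

Gray levels: 8-bit data are used as-is (256 levels); other inputs are
linearly rebinned to 256 levels. Inside the Haralick formulas gray levels
are indexed 1-based (so the pair-sum index k runs over [2, 2*Ng]),
matching the canonical definitions; only relative values matter downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import PixelImage

__all__ = [
    "DISTANCES_PX",
    "ANGLES",
    "GlcmMatrix",
    "TextureFeatures",
    "prefilter_gaussian",
    "quantize_image",
    "compute_glcm",
    "haralick_selected",
]

DISTANCES_PX = (1, 3, 5, 10)
ANGLES = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)
N_LEVELS = 256

# Short names used in feature tables: f_SA = sum average, f_SV = sum
# variance, f_VAR = sum of squares: variance.
FEATURE_NAMES = ("sum_average", "sum_variance", "variance_sos")


@dataclass
class GlcmMatrix:
    """Normalized (sum == 1) gray-level co-occurrence matrix at one offset."""

    matrix: np.ndarray
    distance_px: int
    angle: float
    n_levels: int
    symmetric: bool = True


@dataclass
class TextureFeatures:
    """The 3 selected Haralick features at each of the 4 distances (12 values).

    ``values[d]`` maps each name in :data:`FEATURE_NAMES` to the
    angle-averaged feature at distance ``d``.
    """

    values: dict[int, dict[str, float]]

    def as_row(self) -> dict[str, float]:
        return {
            f"{name}_d{d}": self.values[d][name]
            for d in sorted(self.values)
            for name in FEATURE_NAMES
        }


def _gaussian_kernel_3px(sigma: float = 1.0) -> np.ndarray:
    ax = np.arange(-1, 2, dtype=float)
    g1 = np.exp(-(ax**2) / (2 * sigma**2))
    k = np.outer(g1, g1)
    return k / k.sum()


def prefilter_gaussian(image: PixelImage, sigma: float = 1.0) -> PixelImage:
    """Convolve with a renormalized 3x3 Gaussian kernel (sigma 1 px), reflect borders."""
    if min(image.shape) < 3:
        raise ValueError("image smaller than the 3x3 filter kernel")
    out = ndimage.convolve(image.pixels, _gaussian_kernel_3px(sigma), mode="reflect")
    # convolution of non-negative data with a non-negative kernel; clip tiny
    # negative round-off so the PixelImage invariant holds
    np.clip(out, 0.0, None, out=out)
    return PixelImage(out, image.pixel_size_nm, image.channel_name)


def quantize_image(image: PixelImage, n_levels: int = N_LEVELS) -> np.ndarray:
    """Map intensities to integer gray levels 0..n_levels-1.

    Integer-valued data already within range are used unchanged; everything
    else is linearly rebinned from [min, max] onto the level range.
    """
    px = image.pixels
    if np.all(px == np.round(px)) and px.max() <= n_levels - 1:
        return px.astype(np.uint16)
    lo, hi = float(px.min()), float(px.max())
    if hi == lo:
        return np.zeros(px.shape, dtype=np.uint16)
    scaled = (px - lo) / (hi - lo) * (n_levels - 1)
    return np.clip(np.round(scaled), 0, n_levels - 1).astype(np.uint16)


# unit pixel steps per direction, (row, col) with rows increasing downwards;
# diagonal directions step a full pixel on both axes (Chebyshev offset d*step)
_ANGLE_STEPS = {
    0.0: (0, 1),
    round(np.pi / 4, 12): (1, 1),
    round(np.pi / 2, 12): (1, 0),
    round(3 * np.pi / 4, 12): (1, -1),
}


def compute_glcm(
    image: PixelImage,
    distance_px: int,
    angle: float,
    n_levels: int = N_LEVELS,
    symmetric: bool = True,
) -> GlcmMatrix:
    """Normalized GLCM at one (distance, angle) offset.

    The pixel offset is ``distance_px`` times the unit step of the
    direction, so diagonal directions pair pixels at (d, d) — the offset
    convention of the classic texture toolkits. Pairs are accumulated
    symmetrically (each ordered pair counted in both directions) and the
    matrix is normalized to sum 1. Raises if the offset leaves no valid
    pixel pairs.
    """
    try:
        step = _ANGLE_STEPS[round(float(angle), 12)]
    except KeyError:
        raise ValueError(f"angle must be one of {ANGLES}") from None
    if distance_px < 1:
        raise ValueError("distance_px must be >= 1")
    levels = quantize_image(image, n_levels)
    dr, dc = step[0] * distance_px, step[1] * distance_px
    h, w = levels.shape
    if abs(dr) >= h or abs(dc) >= w:
        raise ValueError(
            f"offset (d={distance_px}, angle={angle:.3f}) leaves no valid pixel pairs"
        )
    src = levels[max(0, -dr) : h - max(0, dr), max(0, -dc) : w - max(0, dc)]
    dst = levels[max(0, dr) : h + min(0, dr), max(0, dc) : w + min(0, dc)]
    idx = src.astype(np.int64).ravel() * n_levels + dst.astype(np.int64).ravel()
    counts = np.bincount(idx, minlength=n_levels * n_levels).astype(np.float64)
    counts = counts.reshape(n_levels, n_levels)
    if symmetric:
        counts = counts + counts.T
    return GlcmMatrix(counts / counts.sum(), distance_px, angle, n_levels,
                      symmetric)


def glcm_features(glcm: GlcmMatrix) -> dict[str, float]:
    """Sum average, sum variance and sum-of-squares variance of one GLCM.

    With P the normalized GLCM over 1-based gray levels i, j in [1, Ng]:

    * p_{x+y}(k) = sum_{i+j=k} P(i, j),  k in [2, 2 Ng]
    * f_SA  = sum_k k * p_{x+y}(k)
    * f_SV  = sum_k (k - f_SA)^2 * p_{x+y}(k)
    * f_VAR = sum_{i,j} (i - mu)^2 * P(i, j), mu the GLCM gray-level mean
    """
    p = glcm.matrix
    ng = glcm.n_levels
    # p_{x+y} via anti-diagonal sums; index k0 = (i-1)+(j-1) -> k = k0 + 2
    p_sum = np.zeros(2 * ng - 1)
    idx = np.add.outer(np.arange(ng), np.arange(ng))
    np.add.at(p_sum, idx.ravel(), p.ravel())
    k = np.arange(2, 2 * ng + 1, dtype=np.float64)
    f_sa = float(np.dot(k, p_sum))
    f_sv = float(np.dot((k - f_sa) ** 2, p_sum))
    # marginal over rows (symmetric GLCM: row and column marginals coincide)
    p_x = p.sum(axis=1)
    i = np.arange(1, ng + 1, dtype=np.float64)
    mu = float(np.dot(i, p_x))
    f_var = float(np.dot((i - mu) ** 2, p_x))
    return {"sum_average": f_sa, "sum_variance": f_sv, "variance_sos": f_var}


def haralick_selected(
    image: PixelImage,
    distances=DISTANCES_PX,
    n_levels: int = N_LEVELS,
) -> TextureFeatures:
    """Angle-averaged selected Haralick features at each distance.

    The caller is responsible for having applied :func:`prefilter_gaussian`
    (and any ROI crop) first, matching the pipeline's order of operations.
    """
    values: dict[int, dict[str, float]] = {}
    for d in distances:
        per_angle = [
            glcm_features(compute_glcm(image, d, a, n_levels)) for a in ANGLES
        ]
        values[d] = {
            name: float(np.mean([f[name] for f in per_angle]))
            for name in FEATURE_NAMES
        }
    return TextureFeatures(values)
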