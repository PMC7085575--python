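"""Hand-engineered zone-level radiomic sequence (96 features).

Per 32x32 zone patch the sequence concatenates:

* 4 first-order statistics of in-mask intensities: mean, population
  standard deviation, skewness, excess kurtosis;
* 18 Haralick statistics of the normalized symmetric gray-level
  co-occurrence matrix (GLCM) at unit distance, in each of 4 directions
  (0, 45, 90, 135 degrees) = 72 features;
* 8 Kirsch compass edge features (mean absolute response per direction);
* 12 Gabor features (4 orientations x 3 wavelengths, mean response
  magnitude).

All features depend on in-mask pixels only: GLCM pixel pairs touching an
out-of-mask pixel are excluded, and for the convolutional features the
out-of-mask region is replaced by the in-mask mean before filtering, so the
sequence is invariant to the modality fill value (3949 / 0). A config flag
restores full-patch computation (fill included) for sensitivity analysis.

Entropies use the natural logarithm. Degenerate (constant) patches follow
the conventions: skewness = kurtosis = 0, GLCM energy = 1, contrast =
entropy = 0, correlation = 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.ndimage import correlate
from scipy.signal import fftconvolve
from scipy.stats import kurtosis as _kurtosis, skew as _skew
from skimage.filters import gabor_kernel

from .zoning import ZonePatch

__all__ = [
    "RadiomicsConfig",
    "RadiomicSequence",
    "first_order_features",
    "haralick_features",
    "kirsch_features",
    "gabor_features",
    "extract_sequence",
    "feature_names",
    "GLCM_DIRECTIONS",
    "HARALICK_NAMES",
]

# unit-distance pixel offsets (row, col) for 0, 45, 90, 135 degrees
GLCM_DIRECTIONS = ((0, 1), (-1, 1), (-1, 0), (-1, -1))

HARALICK_NAMES = (
    "energy", "contrast", "correlation", "sum_of_squares_variance",
    "homogeneity", "sum_average", "sum_variance", "sum_entropy", "entropy",
    "difference_variance", "difference_entropy", "imc1", "imc2",
    "autocorrelation", "cluster_shade", "cluster_prominence",
    "dissimilarity", "maximum_probability",
)

GABOR_ORIENTATIONS_DEG = (0.0, 45.0, 90.0, 135.0)


@dataclass(frozen=True)
class RadiomicsConfig:
    n_gray_levels: int = 32
    gabor_wavelengths: tuple[float, ...] = (2.0, 4.0, 8.0)
    gabor_bandwidth: float = 1.0
    include_fill: bool = False   # compute over the full filled patch instead

    def __post_init__(self) -> None:
        if self.n_gray_levels < 2:
            raise ValueError("need at least 2 gray levels")


DEFAULT_CONFIG = RadiomicsConfig()


@dataclass
class RadiomicSequence:
    """Ordered 96-vector with its block-structured feature names."""

    values: np.ndarray
    block_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.values) != 96 or len(self.block_names) != 96:
            raise ValueError("radiomic sequence must have exactly 96 entries")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("radiomic sequence contains non-finite values")


def feature_names(config: RadiomicsConfig = DEFAULT_CONFIG) -> tuple[str, ...]:
    names = ["fo_mean", "fo_std", "fo_skewness", "fo_kurtosis"]
    for ang in (0, 45, 90, 135):
        names += [f"haralick_{nm}_d{ang}" for nm in HARALICK_NAMES]
    names += [f"kirsch_dir{k}" for k in range(8)]
    for ang in GABOR_ORIENTATIONS_DEG:
        for lam in config.gabor_wavelengths:
            names.append(f"gabor_o{int(ang)}_w{lam:g}")
    return tuple(names)


def _mask_of(patch: ZonePatch, config: RadiomicsConfig) -> np.ndarray:
    if config.include_fill:
        return np.ones_like(patch.mask, dtype=bool)
    return patch.mask.astype(bool)


def first_order_features(patch: ZonePatch,
                         config: RadiomicsConfig = DEFAULT_CONFIG) -> np.ndarray:
    """Mean, population SD, skewness, excess kurtosis of in-mask pixels."""
    mask = _mask_of(patch, config)
    if not mask.any():
        raise ValueError("empty mask")
    x = patch.pixels[mask].astype(float)
    sd = float(x.std())
    # degenerate-by-convention: constant (or numerically constant) patches
    if np.ptp(x) <= 1e-12 * max(1.0, abs(float(x.mean()))):
        return np.array([float(x.mean()), 0.0, 0.0, 0.0])
    return np.array([float(x.mean()), sd,
                     float(_skew(x, bias=True)),
                     float(_kurtosis(x, fisher=True, bias=True))])


def _quantize(pixels: np.ndarray, mask: np.ndarray, levels: int) -> np.ndarray:
    """Min–max quantization of in-mask pixels to {0..levels-1}; -1 outside."""
    q = np.full(pixels.shape, -1, dtype=np.int64)
    x = pixels[mask]
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        q[mask] = 0
    else:
        q[mask] = np.minimum(
            ((pixels[mask] - lo) / (hi - lo) * levels).astype(np.int64),
            levels - 1)
    return q


def glcm(patch: ZonePatch, direction: tuple[int, int],
         config: RadiomicsConfig = DEFAULT_CONFIG) -> np.ndarray:
    """Normalized symmetric co-occurrence matrix at unit distance.

    Pixel pairs where either end lies out of mask are excluded. Returns an
    (L, L) matrix summing to 1, or all-zeros when no valid pair exists.
    """
    mask = _mask_of(patch, config)
    L = config.n_gray_levels
    q = _quantize(patch.pixels, mask, L)
    dr, dc = direction
    h, w = q.shape
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    a = q[r0:r1, c0:c1]
    b = q[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
    valid = (a >= 0) & (b >= 0)
    av, bv = a[valid], b[valid]
    P = np.zeros((L, L), dtype=float)
    if av.size == 0:
        return P
    np.add.at(P, (av, bv), 1.0)
    np.add.at(P, (bv, av), 1.0)   # symmetric accumulation
    return P / P.sum()


def _haralick_from_glcm(P: np.ndarray) -> np.ndarray:
    L = P.shape[0]
    i = np.arange(L, dtype=float)
    I, J = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)                      # symmetric: px == py
    mu = float(np.dot(i, px))
    var = float(np.dot((i - mu) ** 2, px))
    sigma = np.sqrt(var)

    def ent(p):
        p = p[p > 0]
        return float(-(p * np.log(p)).sum())

    # cross-diagonal distributions
    k_sum = np.arange(2 * L - 1, dtype=float)
    p_sum = np.zeros(2 * L - 1)
    np.add.at(p_sum, (I + J).astype(int).ravel(), P.ravel())
    k_diff = np.arange(L, dtype=float)
    p_diff = np.zeros(L)
    np.add.at(p_diff, np.abs(I - J).astype(int).ravel(), P.ravel())

    energy = float((P ** 2).sum())
    contrast = float(((I - J) ** 2 * P).sum())
    correlation = (float(((I - mu) * (J - mu) * P).sum()) / var) if var > 0 else 0.0
    homogeneity = float((P / (1.0 + (I - J) ** 2)).sum())
    sum_average = float(np.dot(k_sum, p_sum))
    sum_variance = float(np.dot((k_sum - sum_average) ** 2, p_sum))
    sum_entropy = ent(p_sum)
    entropy = ent(P.ravel())
    diff_mean = float(np.dot(k_diff, p_diff))
    diff_variance = float(np.dot((k_diff - diff_mean) ** 2, p_diff))
    diff_entropy = ent(p_diff)

    hxy = entropy
    pxpy = np.outer(px, px)
    nz = pxpy > 0
    hxy1 = float(-(P[nz] * np.log(pxpy[nz])).sum())
    hxy2 = float(-(pxpy[nz] * np.log(pxpy[nz])).sum())
    hx = ent(px)
    imc1 = (hxy - hxy1) / hx if hx > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    autocorrelation = float((I * J * P).sum())
    cluster_shade = float(((I + J - 2 * mu) ** 3 * P).sum())
    cluster_prominence = float(((I + J - 2 * mu) ** 4 * P).sum())
    dissimilarity = float((np.abs(I - J) * P).sum())
    maximum_probability = float(P.max())

    return np.array([
        energy, contrast, correlation, var, homogeneity, sum_average,
        sum_variance, sum_entropy, entropy, diff_variance, diff_entropy,
        imc1, imc2, autocorrelation, cluster_shade, cluster_prominence,
        dissimilarity, maximum_probability,
    ])


def haralick_features(patch: ZonePatch, direction: tuple[int, int],
                      config: RadiomicsConfig = DEFAULT_CONFIG) -> np.ndarray:
    """The 18 GLCM statistics for one direction offset."""
    if direction not in GLCM_DIRECTIONS:
        raise ValueError(f"direction must be one of {GLCM_DIRECTIONS}")
    P = glcm(patch, direction, config)
    if P.sum() == 0:
        warnings.warn("no valid in-mask pixel pair; Haralick features zeroed",
                      stacklevel=2)
        return np.zeros(18)
    return _haralick_from_glcm(P)


# 8 Kirsch compass kernels: 5s rotate around the 3x3 neighbour ring in
# 45-degree steps, so a 90-degree patch rotation shifts features by 2 slots.
_RING = ((0, 0), (0, 1), (0, 2), (1, 2), (2, 2), (2, 1), (2, 0), (1, 0))


def _kirsch_kernels() -> np.ndarray:
    kernels = np.full((8, 3, 3), -3.0)
    for k in range(8):
        kernels[k, 1, 1] = 0.0
        for j in range(3):
            r, c = _RING[(k + j) % 8]
            kernels[k, r, c] = 5.0
    return kernels


KIRSCH_KERNELS = _kirsch_kernels()


def _fill_neutral(patch: ZonePatch, config: RadiomicsConfig) -> tuple[np.ndarray, np.ndarray]:
    """Patch with out-of-mask pixels replaced by the in-mask mean."""
    mask = _mask_of(patch, config)
    if not mask.any():
        raise ValueError("empty mask")
    img = patch.pixels.astype(float).copy()
    img[~mask] = img[mask].mean()
    return img, mask


def kirsch_features(patch: ZonePatch,
                    config: RadiomicsConfig = DEFAULT_CONFIG) -> np.ndarray:
    """Mean absolute compass-edge response per direction (8 values)."""
    img, mask = _fill_neutral(patch, config)
    out = np.empty(8)
    for k in range(8):
        resp = correlate(img, KIRSCH_KERNELS[k], mode="nearest")
        out[k] = float(np.abs(resp[mask]).mean())
    return out


@lru_cache(maxsize=8)
def _gabor_bank(wavelengths: tuple[float, ...], bandwidth: float):
    """Zero-DC complex Gabor kernels, orientation-major order."""
    bank = []
    for ang in GABOR_ORIENTATIONS_DEG:
        for lam in wavelengths:
            k = gabor_kernel(frequency=1.0 / lam, theta=np.deg2rad(ang),
                             bandwidth=bandwidth)
            k = k - k.real.mean()          # remove DC of the even part
            bank.append(k)
    return bank


def _fft_correlate_edge(img: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Correlation with edge-replicated boundary, via FFT (complex kernels)."""
    kh, kw = kernel.shape
    padded = np.pad(img, ((kh // 2, kh // 2), (kw // 2, kw // 2)), mode="edge")
    return fftconvolve(padded, np.conj(kernel[::-1, ::-1]), mode="valid")


def gabor_features(patch: ZonePatch,
                   config: RadiomicsConfig = DEFAULT_CONFIG) -> np.ndarray:
    """Mean complex-response magnitude per (orientation, wavelength) pair."""
    img, mask = _fill_neutral(patch, config)
    bank = _gabor_bank(config.gabor_wavelengths, config.gabor_bandwidth)
    out = np.empty(len(bank))
    for idx, k in enumerate(bank):
        resp = _fft_correlate_edge(img, k)
        out[idx] = float(np.abs(resp)[mask].mean())
    return out


def extract_sequence(patch: ZonePatch,
                     config: RadiomicsConfig = DEFAULT_CONFIG) -> RadiomicSequence:
    """Full 96-feature sequence: first-order | Haralick x4 | Kirsch | Gabor."""
    blocks = [first_order_features(patch, config)]
    blocks += [haralick_features(patch, d, config) for d in GLCM_DIRECTIONS]
    blocks.append(kirsch_features(patch, config))
    blocks.append(gabor_features(patch, config))
    return RadiomicSequence(values=np.concatenate(blocks),
                            block_names=feature_names(config))
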