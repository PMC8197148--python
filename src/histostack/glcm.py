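"""Gray-level co-occurrence matrices and the 14 Haralick texture statistics.

A GLCM is the normalized joint distribution of the gray levels of pixel pairs
at a fixed spatial offset.  Intensities in [0, 255] are first linearly binned
into ``levels`` gray levels (64 by default: fewer levels densify the matrix on
50x50 patches and stabilize the eigen-computation behind the maximal
correlation coefficient).  The per-patch protocol is the canonical one:
symmetric, normalized GLCMs at distance 1 for the four directions 0/45/90/135
degrees, the 14 statistics computed per direction and averaged element-wise,
which makes the vector invariant to 90-degree rotations and flips.

The statistic vector is ordered:

    correlation, variance, inverse difference moment, sum average,
    sum variance, sum entropy, entropy, information measure of correlation 2,
    maximal correlation coefficient, difference variance, difference entropy,
    information measure of correlation 1, angular second moment, contrast

All entropy-type statistics use log base 2 (bits).  Degenerate inputs
(constant patches, which do occur as blank tiles in real slide data) yield
correlation = 0 and MCC = 0 by convention rather than NaN.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage.feature import graycomatrix

from .patch_io import GrayImage

log = logging.getLogger(__name__)

ANGLES_DEG = (0, 45, 90, 135)

HARALICK_FEATURE_NAMES = (
    "correlation",
    "variance",
    "inverse_difference_moment",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "entropy",
    "imc2",
    "max_correlation_coefficient",
    "difference_variance",
    "difference_entropy",
    "imc1",
    "angular_second_moment",
    "contrast",
)


@dataclass
class GLCM:
    """A normalized L x L co-occurrence matrix plus its offset metadata."""

    P: np.ndarray
    levels: int
    distance: int
    angle: int
    symmetric: bool
    normalized: bool

    def __post_init__(self) -> None:
        P = np.asarray(self.P, dtype=np.float64)
        if P.ndim != 2 or P.shape[0] != P.shape[1]:
            raise ValueError(f"GLCM must be square, got {P.shape}")
        if np.any(P < 0):
            raise ValueError("GLCM entries must be nonnegative")
        if self.normalized and abs(P.sum() - 1.0) > 1e-9:
            raise ValueError(f"normalized GLCM must sum to 1, got {P.sum()!r}")
        if self.symmetric and not np.allclose(P, P.T, atol=1e-12):
            raise ValueError("symmetric GLCM must equal its transpose")
        self.P = P


def quantize(gray: GrayImage, levels: int) -> np.ndarray:
    """Linear binning of [0, 255] intensities into ``levels`` gray levels."""
    if not 1 <= levels <= 256:
        raise ValueError(f"levels must be in [1, 256], got {levels}")
    return (np.asarray(gray, dtype=np.int64) * levels) // 256


def compute_glcm(
    gray: GrayImage,
    distance: int = 1,
    angle: int = 0,
    levels: int = 64,
    symmetric: bool = True,
    assume_binned: bool = False,
) -> GLCM:
    """Co-occurrence counts of quantized gray levels at one offset, normalized to sum 1.

    With ``assume_binned=True`` the input already holds gray-level indices in
    ``[0, levels)`` and no [0, 255] quantization is applied.
    """
    if angle not in ANGLES_DEG:
        raise ValueError(f"angle must be one of {ANGLES_DEG}, got {angle}")
    gray = np.asarray(gray)
    if levels == 1:
        if np.unique(gray).size > 1:
            raise ValueError("levels=1 is only valid for constant images")
        return GLCM(np.ones((1, 1)), 1, distance, angle, symmetric, True)
    if assume_binned:
        if gray.min() < 0 or gray.max() >= levels:
            raise ValueError("assume_binned input must hold levels in [0, levels)")
        binned = gray.astype(np.uint8)
    else:
        binned = quantize(gray, levels).astype(np.uint8)
    counts = graycomatrix(
        binned,
        distances=[distance],
        angles=[np.deg2rad(angle)],
        levels=levels,
        symmetric=symmetric,
        normed=False,
    )[:, :, 0, 0].astype(np.float64)
    total = counts.sum()
    if total == 0:
        raise ValueError(f"image of shape {gray.shape} has no pixel pair at distance {distance}, angle {angle}")
    return GLCM(counts / total, levels, distance, angle, symmetric, True)


def _entropy(p: np.ndarray, base: float) -> float:
    """-sum p log p with the 0 log 0 = 0 convention."""
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)) / np.log(base))


def _max_correlation_coefficient(P: np.ndarray, px: np.ndarray, py: np.ndarray) -> float:
    nz_x = px > 0
    nz_y = py > 0
    if nz_x.sum() < 2 or nz_y.sum() < 2:
        return 0.0
    # Q(i, j) = sum_k P(i,k) P(j,k) / (px(i) py(k)), on the support of px/py
    A = P[np.ix_(nz_x, nz_y)]
    Q = (A / py[nz_y][None, :]) @ A.T / px[nz_x][:, None]
    eig = np.sort(np.real(np.linalg.eigvals(Q)))
    second = max(eig[-2], 0.0)
    return float(np.sqrt(second))


def haralick_features(glcm: GLCM, base: float = 2.0) -> np.ndarray:
    """The 14 Haralick statistics of a normalized GLCM, in the fixed order above."""
    if not glcm.normalized:
        raise ValueError("haralick_features requires a normalized GLCM")
    P = glcm.P
    L = P.shape[0]
    i = np.arange(L, dtype=np.float64)
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = float(i @ px)
    mu_y = float(i @ py)
    sigma_x = float(np.sqrt(((i - mu_x) ** 2) @ px))
    sigma_y = float(np.sqrt(((i - mu_y) ** 2) @ py))

    ii, jj = np.meshgrid(i, i, indexing="ij")
    asm = float(np.sum(P**2))
    contrast = float(np.sum((ii - jj) ** 2 * P))
    if sigma_x > 0 and sigma_y > 0:
        correlation = float((np.sum(ii * jj * P) - mu_x * mu_y) / (sigma_x * sigma_y))
    else:
        log.debug("constant-intensity GLCM: correlation set to 0 by convention")
        correlation = 0.0
    variance = float(np.sum((ii - mu_x) ** 2 * P))
    idm = float(np.sum(P / (1.0 + (ii - jj) ** 2)))

    # distributions of i + j (0 .. 2L-2) and |i - j| (0 .. L-1)
    p_sum = np.zeros(2 * L - 1)
    p_diff = np.zeros(L)
    for offset in range(-(L - 1), L):
        diag = np.diagonal(P, offset=offset)  # cells with j - i == offset
        p_diff[abs(offset)] += diag.sum()
    for s in range(2 * L - 1):
        anti = P[:, ::-1].diagonal(offset=(L - 1) - s)  # cells with i + j == s
        p_sum[s] = anti.sum()
    k_sum = np.arange(2 * L - 1, dtype=np.float64)
    k_diff = np.arange(L, dtype=np.float64)

    sum_average = float(k_sum @ p_sum)
    sum_variance = float(((k_sum - sum_average) ** 2) @ p_sum)
    sum_entropy = _entropy(p_sum, base)
    entropy = _entropy(P.ravel(), base)
    diff_mean = float(k_diff @ p_diff)
    difference_variance = float(((k_diff - diff_mean) ** 2) @ p_diff)
    difference_entropy = _entropy(p_diff, base)

    hx = _entropy(px, base)
    hy = _entropy(py, base)
    outer = np.outer(px, py)
    mask = (P > 0) & (outer > 0)
    hxy1 = float(-np.sum(P[mask] * np.log(outer[mask])) / np.log(base))
    mask2 = outer > 0
    hxy2 = float(-np.sum(outer[mask2] * np.log(outer[mask2])) / np.log(base))
    denom = max(hx, hy)
    imc1 = float((entropy - hxy1) / denom) if denom > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * np.log(base) * (hxy2 - entropy)))))
    mcc = _max_correlation_coefficient(P, px, py)

    return np.array(
        [
            correlation,
            variance,
            idm,
            sum_average,
            sum_variance,
            sum_entropy,
            entropy,
            imc2,
            mcc,
            difference_variance,
            difference_entropy,
            imc1,
            asm,
            contrast,
        ]
    )


def haralick_patch(
    gray: GrayImage,
    distance: int = 1,
    levels: int = 64,
    base: float = 2.0,
) -> np.ndarray:
    """Direction-averaged 14-statistic vector: symmetric GLCMs at the four angles."""
    per_angle = [
        haralick_features(compute_glcm(gray, distance, angle, levels, symmetric=True), base=base)
        for angle in ANGLES_DEG
    ]
    return np.mean(per_angle, axis=0)
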