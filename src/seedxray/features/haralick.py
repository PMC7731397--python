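"""Haralick co-occurrence statistics of the masked seed region.

The masked intensities are quantized to a fixed number of gray levels over
their own range, a symmetric normalized gray-level co-occurrence matrix
(GLCM) is built at distance 1 for the four standard offsets (0, 45, 90,
135 degrees) — pairs that touch background pixels are excluded — and the
14 classic Haralick statistics are computed per offset, then summarized by
their mean and range over offsets (28 features).
"""

from __future__ import annotations

import numpy as np
from skimage.feature import graycomatrix

GLCM_ANGLES = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)

HARALICK_STAT_NAMES = (
    "ASM",
    "Contrast",
    "Correlation",
    "Variance",
    "IDM",
    "SumAverage",
    "SumVariance",
    "SumEntropy",
    "Entropy",
    "DiffVariance",
    "DiffEntropy",
    "IMC1",
    "IMC2",
    "MCC",
)


def quantize_masked(image: np.ndarray, mask: np.ndarray, levels: int) -> np.ndarray:
    """Integer level image: 0 = background, 1..levels inside the mask,
    equal-width bins over the masked intensity range."""
    mask = np.asarray(mask, dtype=bool)
    img = np.asarray(image, dtype=float)
    q = np.zeros(img.shape, dtype=np.uint16)
    px = img[mask]
    lo, hi = px.min(), px.max()
    if hi > lo:
        scaled = np.floor((img - lo) / (hi - lo) * levels)
        q[mask] = np.clip(scaled[mask], 0, levels - 1).astype(np.uint16) + 1
    else:
        q[mask] = 1
    return q


def masked_glcm(
    image: np.ndarray, mask: np.ndarray, levels: int = 32, distance: int = 1
) -> np.ndarray:
    """Symmetric, normalized GLCMs, shape (levels, levels, n_angles)."""
    q = quantize_masked(image, mask, levels)
    raw = graycomatrix(
        q, distances=[distance], angles=list(GLCM_ANGLES), levels=levels + 1, symmetric=True
    )
    glcm = raw[1:, 1:, 0, :].astype(float)  # drop background row/col
    sums = glcm.sum(axis=(0, 1), keepdims=True)
    sums[sums == 0] = 1.0
    return glcm / sums


def _entropy(p: np.ndarray) -> float:
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum()) if nz.size else 0.0


def haralick_statistics(p: np.ndarray) -> np.ndarray:
    """The 14 Haralick statistics of one normalized symmetric GLCM.

    Statistics that are undefined on a degenerate matrix (zero marginal
    variance, zero entropies) are defined as 0 so vectors stay finite.
    """
    n = p.shape[0]
    i = np.arange(n, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    mu = float((i * px).sum())
    sigma2 = float(((i - mu) ** 2 * px).sum())
    sigma = np.sqrt(sigma2)

    asm = float((p**2).sum())
    contrast = float(((ii - jj) ** 2 * p).sum())
    if sigma > 0:
        correlation = float(((ii - mu) * (jj - mu) * p).sum() / sigma2)
    else:
        correlation = 0.0
    variance = sigma2
    idm = float((p / (1.0 + (ii - jj) ** 2)).sum())

    # p_{x+y}(k), k = i+j in 0..2n-2 ; p_{x-y}(k), k = |i-j| in 0..n-1
    psum = np.bincount((ii + jj).astype(int).ravel(), weights=p.ravel(), minlength=2 * n - 1)
    pdiff = np.bincount(np.abs(ii - jj).astype(int).ravel(), weights=p.ravel(), minlength=n)
    k_sum = np.arange(2 * n - 1, dtype=float)
    k_diff = np.arange(n, dtype=float)
    sum_avg = float((k_sum * psum).sum())
    sum_var = float(((k_sum - sum_avg) ** 2 * psum).sum())
    sum_ent = _entropy(psum)
    entropy = _entropy(p)
    diff_avg = float((k_diff * pdiff).sum())
    diff_var = float(((k_diff - diff_avg) ** 2 * pdiff).sum())
    diff_ent = _entropy(pdiff)

    hx = _entropy(px)
    outer = np.outer(px, px)
    log_outer = np.zeros_like(outer)
    np.log2(outer, out=log_outer, where=outer > 0)
    hxy1 = float(-(p * log_outer).sum())
    hxy2 = float(-(outer * log_outer).sum())
    imc1 = (entropy - hxy1) / hx if hx > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy)))))

    # maximal correlation coefficient: sqrt of the 2nd largest eigenvalue of
    # Q_ij = sum_k p_ik p_jk / (p_x(i) p_x(k)) (symmetric GLCM: p_y = p_x)
    nzi = px > 0
    if nzi.sum() >= 2:
        psub = p[np.ix_(nzi, nzi)]
        pxs = px[nzi]
        q = (psub / pxs[:, None]) @ (psub / pxs[None, :])
        eig = np.sort(np.real(np.linalg.eigvals(q)))
        mcc = float(np.sqrt(max(0.0, eig[-2])))
    else:
        mcc = 0.0

    return np.array(
        [asm, contrast, correlation, variance, idm, sum_avg, sum_var, sum_ent,
         entropy, diff_var, diff_ent, imc1, imc2, mcc]
    )


def extract_haralick(
    image: np.ndarray, mask: np.ndarray, levels: int = 32, distance: int = 1
) -> np.ndarray:
    """28 features: mean and range over the 4 offsets of each statistic."""
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 2:
        raise ValueError("mask must cover at least 2 pixels")
    glcm = masked_glcm(image, mask, levels, distance)
    per_offset = np.stack([haralick_statistics(glcm[:, :, a]) for a in range(glcm.shape[2])])
    return np.concatenate([per_offset.mean(axis=0), np.ptp(per_offset, axis=0)])


def haralick_names() -> list[str]:
    return [f"i-Haralick {s}[mean]" for s in HARALICK_STAT_NAMES] + [
        f"i-Haralick {s}[range]" for s in HARALICK_STAT_NAMES
    ]
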