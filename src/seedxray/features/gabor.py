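"""Gabor filter-bank responses over the masked seed region.

A bank of 4 spatial frequencies x 8 orientations of complex Gabor kernels
(one-octave bandwidth) is applied to the whole image; per filter the mean
response magnitude and the mean squared magnitude (energy density) are
taken over the mask (64 values), plus three pooled statistics: the total
energy J summed over the bank, and the mean and sd of the per-filter mean
magnitudes (67 in total).

Filtering runs in the Fourier domain with kernel spectra cached per
(image shape, bank) so repeated extraction over a dataset stays fast.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy import fft as sfft
from skimage.filters import gabor_kernel


@lru_cache(maxsize=8)
def _bank_spectra(
    shape: tuple[int, int], frequencies: tuple[float, ...], n_orientations: int
):
    """Precompute padded FFTs of every kernel in the bank (complex64)."""
    kernels = [
        gabor_kernel(f, theta=np.pi * o / n_orientations)
        for f in frequencies
        for o in range(n_orientations)
    ]
    kmax = max(max(k.shape) for k in kernels)
    n0 = sfft.next_fast_len(shape[0] + kmax - 1)
    n1 = sfft.next_fast_len(shape[1] + kmax - 1)
    spectra, halves = [], []
    for k in kernels:
        spectra.append(sfft.fft2(k.astype(np.complex64), s=(n0, n1)))
        halves.append((k.shape[0] // 2, k.shape[1] // 2))
    return (n0, n1), spectra, halves


def gabor_responses(
    image: np.ndarray, frequencies: tuple[float, ...], n_orientations: int
) -> list[np.ndarray]:
    """Complex response of every bank filter, same shape as the image."""
    img = np.asarray(image, dtype=np.float32)
    (n0, n1), spectra, halves = _bank_spectra(img.shape, tuple(frequencies), n_orientations)
    img_f = sfft.fft2(img.astype(np.complex64), s=(n0, n1))
    h, w = img.shape
    out = []
    for spec, (hy, hx) in zip(spectra, halves):
        full = sfft.ifft2(img_f * spec)
        out.append(full[hy : hy + h, hx : hx + w])
    return out


def extract_gabor(
    image: np.ndarray,
    mask: np.ndarray,
    frequencies: tuple[float, ...] = (0.08, 0.13, 0.20, 0.30),
    n_orientations: int = 8,
) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    responses = gabor_responses(image, tuple(frequencies), n_orientations)
    means, energies = [], []
    for resp in responses:
        mag = np.abs(resp[mask]).astype(float)
        means.append(mag.mean())
        energies.append((mag**2).mean())
    means = np.asarray(means)
    energies = np.asarray(energies)
    per_filter = np.stack([means, energies], axis=1).ravel()
    pooled = [energies.sum(), means.mean(), means.std()]
    return np.concatenate([per_filter, pooled])


def gabor_names(n_frequencies: int = 4, n_orientations: int = 8) -> list[str]:
    names = []
    for a in range(1, n_frequencies + 1):
        for b in range(1, n_orientations + 1):
            names.append(f"i-Gabor({a},{b})[mean]")
            names.append(f"i-Gabor({a},{b})[energy]")
    names += ["i-Gabor-J", "i-Gabor-Mean", "i-Gabor-SD"]
    return names
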