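"""Local Fourier texture features of the masked seed region.

The masked image (background zero-filled) is transformed with a 2D FFT and
the half-plane of spatial frequencies is partitioned into equal-width
radial bands over (0, 0.5] cycles/pixel, excluding the DC term.  Per band
two features are emitted: the share of total (non-DC) spectral energy
("Abs") and the energy-weighted circular mean phase in radians ("Ang").
"""

from __future__ import annotations

import numpy as np


def _radial_grid(shape: tuple[int, int]) -> np.ndarray:
    fy = np.fft.fftfreq(shape[0])[:, None]
    fx = np.fft.fftfreq(shape[1])[None, :]
    return np.hypot(fy, fx)


def extract_local_fft(image: np.ndarray, mask: np.ndarray, n_bands: int = 4) -> np.ndarray:
    img = np.asarray(image, dtype=float) * np.asarray(mask, dtype=bool)
    if not np.any(img):
        raise ValueError("masked image is identically zero")
    spec = np.fft.fft2(img)
    power = np.abs(spec) ** 2
    phase = np.angle(spec)
    rho = _radial_grid(img.shape)
    total = power[rho > 0].sum()
    edges = np.linspace(0.0, 0.5, n_bands + 1)
    abs_feats, ang_feats = [], []
    for b in range(n_bands):
        sel = (rho > edges[b]) & (rho <= edges[b + 1])
        if b == 0:
            sel &= rho > 0  # DC never contributes
        e = power[sel].sum()
        abs_feats.append(e / total if total > 0 else 0.0)
        if e > 0:
            z = (power[sel] * np.exp(1j * phase[sel])).sum()
            ang_feats.append(float(np.angle(z)))
        else:
            ang_feats.append(0.0)
    return np.array(abs_feats + ang_feats)


def fourier_names(n_bands: int = 4) -> list[str]:
    return [f"Fourier Abs ({u},1)" for u in range(1, n_bands + 1)] + [
        f"Fourier Ang ({u},1)[rad]" for u in range(1, n_bands + 1)
    ]
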