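"""Local binary patterns (8-point, uniform "u2" codes, multiple radii).

For every pixel, the 8 circularly arranged neighbors at radius ``d`` are
sampled with bilinear interpolation and compared with the center (strictly
greater -> bit 1, so a constant image yields the all-zeros code).  Patterns
with at most two 0/1 transitions around the circle are "uniform"; there are
58 of them for 8 points.  Per radius the feature is the 58-bin histogram of
uniform codes normalized over all counted pixels (non-uniform mass is kept
in the normalization but not emitted as a bin), plus two statistics pooled
over all radii: code-distribution energy and entropy.
"""

from __future__ import annotations

import numpy as np

#: comparison slack so interpolation roundoff on flat regions cannot flip bits
LBP_EPS = 1e-9

N_POINTS = 8
N_UNIFORM = 58  # uniform 8-bit patterns; index 58 = the pooled non-uniform bin


def _transitions(pattern: int, n: int = N_POINTS) -> int:
    bits = [(pattern >> k) & 1 for k in range(n)]
    return sum(bits[k] != bits[(k + 1) % n] for k in range(n))


def _uniform_lut() -> np.ndarray:
    """Map 8-bit pattern -> uniform rank (0..57, ascending by value) or 58."""
    uniform = [p for p in range(256) if _transitions(p) <= 2]
    lut = np.full(256, N_UNIFORM, dtype=np.int64)
    for rank, p in enumerate(uniform):
        lut[p] = rank
    return lut


_LUT = _uniform_lut()


def _neighbor_plane(padded: np.ndarray, r: int, dy: float, dx: float, shape) -> np.ndarray:
    """Bilinearly interpolated neighbor value for every pixel, via four
    integer-shifted views of the padded image."""
    h, w = shape
    fy, fx = int(np.floor(dy)), int(np.floor(dx))
    wy, wx = dy - fy, dx - fx

    def view(oy: int, ox: int) -> np.ndarray:
        return padded[r + oy : r + oy + h, r + ox : r + ox + w]

    if wy == 0 and wx == 0:
        return view(fy, fx).astype(float)
    return (
        (1 - wy) * (1 - wx) * view(fy, fx)
        + (1 - wy) * wx * view(fy, fx + 1)
        + wy * (1 - wx) * view(fy + 1, fx)
        + wy * wx * view(fy + 1, fx + 1)
    )


def lbp_code_image(image: np.ndarray, radius: int) -> np.ndarray:
    """Uniform-LBP code map (values 0..58); border pixels within ``radius``
    of the edge are marked -1 and never counted."""
    img = np.asarray(image, dtype=float)
    h, w = img.shape
    r = int(radius)
    if r < 1:
        raise ValueError("radius must be >= 1")
    padded = np.pad(img, r, mode="edge")
    pattern = np.zeros((h, w), dtype=np.int64)
    for k in range(N_POINTS):
        ang = 2 * np.pi * k / N_POINTS
        dy, dx = -r * np.sin(ang), r * np.cos(ang)
        # snap near-integer offsets so axial neighbors are exact lookups
        dy, dx = round(dy, 12), round(dx, 12)
        neighbor = _neighbor_plane(padded, r, dy, dx, (h, w))
        pattern |= ((neighbor - img) > LBP_EPS).astype(np.int64) << k
    codes = _LUT[pattern]
    codes[:r, :] = -1
    codes[-r:, :] = -1
    codes[:, :r] = -1
    codes[:, -r:] = -1
    return codes


def lbp_histogram(image: np.ndarray, mask: np.ndarray, radius: int) -> np.ndarray:
    """Normalized 59-bin code histogram (58 uniform bins + non-uniform rest)
    over the masked, border-valid pixels.  Sums to 1 when any pixel counts."""
    codes = lbp_code_image(image, radius)
    sel = np.asarray(mask, dtype=bool) & (codes >= 0)
    counts = np.bincount(codes[sel], minlength=N_UNIFORM + 1).astype(float)
    total = counts.sum()
    return counts / total if total > 0 else counts


def extract_lbp(
    image: np.ndarray, mask: np.ndarray, radii: tuple[int, ...] = (1, 2, 3, 4)
) -> np.ndarray:
    """234 features: 58 uniform-pattern shares per radius, plus pooled code
    energy (sum p^2) and entropy (bits) of the radius-averaged distribution."""
    hists = np.stack([lbp_histogram(image, mask, r) for r in radii])
    pooled = hists.mean(axis=0)
    energy = float((pooled**2).sum())
    nz = pooled[pooled > 0]
    entropy = float(-(nz * np.log2(nz)).sum()) if nz.size else 0.0
    return np.concatenate([hists[:, :N_UNIFORM].ravel(), [energy, entropy]])


def lbp_names(radii: tuple[int, ...] = (1, 2, 3, 4)) -> list[str]:
    names = [f"i-LBP({d},{h})[8,u2]" for d in radii for h in range(1, N_UNIFORM + 1)]
    names += ["i-LBP-Energy[8,u2]", "i-LBP-Entropy[8,u2]"]
    return names
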