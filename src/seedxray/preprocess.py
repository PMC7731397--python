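"""Cropping, seed masking and the three-stage intensity enhancement.

Each raw multi-seed scan is cropped into single-seed 224x224 radiographs.
Per seed, a binary foreground mask is computed by Otsu thresholding (the
seed is the bright side of the threshold), and three enhanced variants are
derived in sequence:

* set_A — max-normalized image (divide by the global maximum),
* set_B — standard-deviation scaling of set_A: z-scores mapped affinely
  into display range around 0.5 and clipped to [0, 1],
* set_C — 3x3 median filter of set_B (impulse-noise reduction).

All texture features downstream are extracted from this triplet.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.transform import resize

from .synthetic import IMAGE_SIZE, ParameterError, Radiograph

#: slope of the z-score -> display-range map in set_B; 0.15 spans about
#: +/-3.3 standard deviations across [0, 1] before clipping
SD_SCALE = 0.15


class DegenerateInputError(ValueError):
    """Raised for constant / zero images that admit no mask or enhancement."""


@dataclass(frozen=True)
class SeedMask:
    """Binary foreground mask: 1 = seed, 0 = background; one connected
    component, holes filled."""

    pixels: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=bool)
        if not px.any():
            raise DegenerateInputError("mask has empty foreground")
        object.__setattr__(self, "pixels", px)

    @property
    def area(self) -> int:
        return int(self.pixels.sum())


@dataclass(frozen=True)
class EnhancedTriplet:
    """The three derived images per seed (set_A, set_B, set_C)."""

    set_A: np.ndarray
    set_B: np.ndarray
    set_C: np.ndarray

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"A": self.set_A, "B": self.set_B, "C": self.set_C}


def crop_seeds(
    raw_scan: np.ndarray,
    boxes: list[tuple[int, int, int, int]],
    cultivar: str = "unknown",
    seed_ids: list[str] | None = None,
) -> list[Radiograph]:
    """Crop single-seed images from a multi-seed scan.

    boxes are (min_row, min_col, max_row, max_col), exclusive upper bounds.
    Crops that are not already 224x224 are resampled bilinearly.
    """
    raw_scan = np.asarray(raw_scan, dtype=float)
    out: list[Radiograph] = []
    for i, (r0, c0, r1, c1) in enumerate(boxes):
        if not (0 <= r0 < r1 <= raw_scan.shape[0] and 0 <= c0 < c1 <= raw_scan.shape[1]):
            raise ParameterError(f"box {i} {(r0, c0, r1, c1)} out of scan bounds {raw_scan.shape}")
        crop = raw_scan[r0:r1, c0:c1]
        if crop.shape != (IMAGE_SIZE, IMAGE_SIZE):
            crop = resize(crop, (IMAGE_SIZE, IMAGE_SIZE), order=1, anti_aliasing=False)
        crop = np.clip(crop, 0.0, 1.0)
        sid = seed_ids[i] if seed_ids is not None else f"crop{i:03d}"
        out.append(Radiograph(pixels=crop, seed_id=sid, cultivar=cultivar))
    return out


def compute_mask(image: Radiograph | np.ndarray) -> SeedMask:
    """Segment the seed by Otsu's threshold on a 256-bin histogram.

    The foreground is the threshold side containing the central pixel
    (polarity-aware: works for bright-seed and dark-seed conventions).
    Holes are filled and only the largest connected component is kept.
    """
    px = image.pixels if isinstance(image, Radiograph) else np.asarray(image, dtype=float)
    if np.ptp(px) == 0:
        raise DegenerateInputError("constant image admits no threshold")
    thr = threshold_otsu(px, nbins=256)
    center = px[px.shape[0] // 2, px.shape[1] // 2]
    fg = px > thr if center > thr else px <= thr
    fg = ndimage.binary_fill_holes(fg)
    labels = cc_label(fg, connectivity=2)
    if labels.max() == 0:
        raise DegenerateInputError("no foreground component after thresholding")
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    return SeedMask(pixels=labels == largest, threshold=float(thr))


def enhance_sets(image: Radiograph | np.ndarray, sd_scale: float = SD_SCALE) -> EnhancedTriplet:
    """Derive the set_A / set_B / set_C enhancement triplet."""
    px = image.pixels if isinstance(image, Radiograph) else np.asarray(image, dtype=float)
    peak = px.max()
    if peak <= 0:
        raise DegenerateInputError("zero-max image cannot be max-normalized")
    set_a = px / peak
    sd = set_a.std()
    if sd == 0:
        raise DegenerateInputError("zero-variance image cannot be sd-scaled")
    set_b = np.clip((set_a - set_a.mean()) / sd * sd_scale + 0.5, 0.0, 1.0)
    # 'nearest' mode replicates edge values, keeping the 224x224 contract
    set_c = ndimage.median_filter(set_b, size=3, mode="nearest")
    return EnhancedTriplet(set_A=set_a, set_B=set_b, set_C=set_c)
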