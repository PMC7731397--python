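"""Synthetic seed radiograph generator.

Renders 2D X-ray-projection-like images of single watermelon seeds so the
whole classification pipeline can be exercised and tested without access to
real scans.  A viable seed is drawn as a bright elliptical endosperm with a
brighter coat rim on a dark background; a nonviable / abnormal seed
additionally carries internal air spaces (dark blobs inside the endosperm)
and an irregular, perturbed outline.  Degradation is modelled as a Gaussian
point-spread blur followed by additive Gaussian noise.

The generator is *not* a physical X-ray transport simulation: intensities
are stylised attenuation maps, chosen so that the two classes differ in
exactly the morphological cues practitioners read off real radiographs
(uniform vs. cavitated endosperm, regular vs. deformed outline).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

IMAGE_SIZE = 224

VIABLE = "viable"
NONVIABLE = "nonviable_abnormal"
LABELS = (VIABLE, NONVIABLE)


class ParameterError(ValueError):
    """Raised when generator or pipeline parameters are out of range."""


@dataclass(frozen=True)
class Radiograph:
    """A single-seed grayscale radiograph.

    pixels are float intensities in [0, 1] on a fixed 224x224 grid; the
    seed is rendered brighter than the background (higher attenuation is
    displayed bright).
    """

    pixels: np.ndarray
    seed_id: str
    cultivar: str = "synthetic"
    label: str | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.shape != (IMAGE_SIZE, IMAGE_SIZE):
            raise ParameterError(
                f"radiograph must be {IMAGE_SIZE}x{IMAGE_SIZE}, got {px.shape}"
            )
        if not np.all(np.isfinite(px)):
            raise ParameterError("radiograph contains non-finite values")
        if px.min() < 0.0 or px.max() > 1.0:
            raise ParameterError("radiograph intensities must lie in [0, 1]")
        object.__setattr__(self, "pixels", px)
        if self.label is not None and self.label not in LABELS:
            raise ParameterError(f"unknown label {self.label!r}")


@dataclass(frozen=True)
class MorphologyParams:
    """Generative parameters for one seed class.

    air_space_fraction is the target fraction of endosperm area occupied by
    dark internal blobs; irregularity is the relative amplitude of a
    low-order sinusoidal perturbation of the seed outline.  Setting both to
    zero yields the viable-class generative regime regardless of label.
    """

    coat_intensity: float = 0.92
    endosperm_intensity: float = 0.65
    air_space_fraction: float = 0.0
    n_blobs: int = 3
    irregularity: float = 0.0
    noise_sd: float = 0.02
    blur_sigma: float = 1.0
    cultivar_shift: float = 0.0
    air_intensity: float = 0.18

    def validate(self) -> None:
        if not 0.0 < self.coat_intensity <= 1.0:
            raise ParameterError("coat_intensity must be in (0, 1]")
        if not 0.0 < self.endosperm_intensity <= 1.0:
            raise ParameterError("endosperm_intensity must be in (0, 1]")
        if not 0.0 <= self.air_space_fraction <= 0.5:
            raise ParameterError("air_space_fraction must be in [0, 0.5]")
        if self.n_blobs < 0:
            raise ParameterError("n_blobs must be >= 0")
        if self.irregularity < 0:
            raise ParameterError("irregularity must be >= 0")
        if self.noise_sd < 0 or self.blur_sigma < 0:
            raise ParameterError("noise_sd and blur_sigma must be >= 0")


def default_params(label: str) -> MorphologyParams:
    """Class defaults: viable seeds are uniform; nonviable seeds carry
    air spaces over ~15% of the endosperm and a deformed outline."""
    if label == VIABLE:
        return MorphologyParams()
    if label == NONVIABLE:
        return MorphologyParams(air_space_fraction=0.15, n_blobs=3, irregularity=0.08)
    raise ParameterError(f"unknown label {label!r}")


@dataclass
class GroundTruth:
    """Pixel-accurate masks from the renderer, used as test oracles."""

    seed_mask: np.ndarray
    endosperm_mask: np.ndarray
    endosperm_interior: np.ndarray  # endosperm eroded clear of the blurred coat edge
    air_mask: np.ndarray
    centroid: tuple[float, float]
    seed_area: int


def _ellipse_field(size: int, rng: np.random.Generator, irregularity: float):
    """Radial field r(x)/R(theta) for a randomly posed, optionally perturbed
    ellipse; values <= 1 are inside the outline."""
    cy = size / 2 + rng.uniform(-5, 5)
    cx = size / 2 + rng.uniform(-5, 5)
    # semi-axes 15-30% of the frame -> seed spans 30-60% of the image
    a = rng.uniform(0.15, 0.30) * size
    b = rng.uniform(0.15, 0.30) * size
    theta = rng.uniform(0, np.pi)
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    yr = (yy - cy) * np.cos(theta) - (xx - cx) * np.sin(theta)
    xr = (yy - cy) * np.sin(theta) + (xx - cx) * np.cos(theta)
    r = np.hypot(xr / a, yr / b)
    if irregularity > 0:
        ang = np.arctan2(yr / b, xr / a)
        lobes = rng.integers(3, 6)
        phase = rng.uniform(0, 2 * np.pi)
        r = r * (1.0 + irregularity * np.sin(lobes * ang + phase))
    return r, (cy, cx)


def _place_air_blobs(
    endosperm: np.ndarray, target_fraction: float, n_blobs: int, rng: np.random.Generator
) -> np.ndarray:
    """Dark internal cavities: random ellipses clipped to the endosperm,
    union-area calibrated to target_fraction by iterative radius scaling."""
    endo_area = int(endosperm.sum())
    if target_fraction <= 0 or n_blobs == 0 or endo_area == 0:
        return np.zeros_like(endosperm, dtype=bool)
    size = endosperm.shape[0]
    interior = ndimage.binary_erosion(endosperm, iterations=4)
    ys, xs = np.nonzero(interior if interior.any() else endosperm)
    idx = rng.integers(0, len(ys), size=n_blobs)
    centers = np.stack([ys[idx], xs[idx]], axis=1).astype(float)
    base_r = np.sqrt(target_fraction * endo_area / (np.pi * n_blobs))
    ecc = rng.uniform(0.6, 1.0, size=n_blobs)  # blob axis ratios
    angles = rng.uniform(0, np.pi, size=n_blobs)
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    scale = 1.0
    mask = np.zeros_like(endosperm, dtype=bool)
    for _ in range(6):
        mask = np.zeros_like(endosperm, dtype=bool)
        for (cy, cx), e, ang in zip(centers, ecc, angles):
            ra = base_r * scale / np.sqrt(e)
            rb = base_r * scale * np.sqrt(e)
            yr = (yy - cy) * np.cos(ang) - (xx - cx) * np.sin(ang)
            xr = (yy - cy) * np.sin(ang) + (xx - cx) * np.cos(ang)
            mask |= (xr / ra) ** 2 + (yr / rb) ** 2 <= 1.0
        mask &= endosperm
        got = mask.sum() / endo_area
        if abs(got - target_fraction) / target_fraction < 0.02:
            break
        scale *= np.sqrt(target_fraction / max(got, 1e-6))
    return mask


def _render(label: str, params: MorphologyParams, rng: np.random.Generator):
    size = IMAGE_SIZE
    r, centroid = _ellipse_field(size, rng, params.irregularity)
    seed_mask = r <= 1.0
    coat = (r <= 1.0) & (r > 0.82)
    endosperm = r <= 0.82

    background = 0.06
    img = np.full((size, size), background)
    endo_level = np.clip(params.endosperm_intensity + params.cultivar_shift, 0.0, 1.0)
    coat_level = np.clip(params.coat_intensity + params.cultivar_shift, 0.0, 1.0)
    img[endosperm] = endo_level
    img[coat] = coat_level

    if label == NONVIABLE and params.air_space_fraction > 0:
        air = _place_air_blobs(endosperm, params.air_space_fraction, params.n_blobs, rng)
        img[air] = params.air_intensity
    else:
        air = np.zeros_like(seed_mask)

    if params.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, params.blur_sigma)
    if params.noise_sd > 0:
        img = img + rng.normal(0.0, params.noise_sd, img.shape)
    img = np.clip(img, 0.0, 1.0)

    pad = max(3, int(np.ceil(3 * params.blur_sigma)))
    interior = ndimage.binary_erosion(endosperm, iterations=pad)
    truth = GroundTruth(
        seed_mask=seed_mask,
        endosperm_mask=endosperm,
        endosperm_interior=interior,
        air_mask=air,
        centroid=centroid,
        seed_area=int(seed_mask.sum()),
    )
    return img, truth


def generate_seed(
    label: str,
    params: MorphologyParams | None = None,
    rng_seed: int = 0,
    seed_id: str | None = None,
    cultivar: str = "synthetic",
) -> Radiograph:
    """Render one labelled seed radiograph, deterministic in rng_seed."""
    img, _ = generate_seed_with_truth(label, params, rng_seed, seed_id, cultivar)
    return img


def generate_seed_with_truth(
    label: str,
    params: MorphologyParams | None = None,
    rng_seed: int = 0,
    seed_id: str | None = None,
    cultivar: str = "synthetic",
) -> tuple[Radiograph, GroundTruth]:
    """As generate_seed, additionally returning the renderer's ground-truth
    masks (seed outline, endosperm, air spaces) for validation."""
    if label not in LABELS:
        raise ParameterError(f"unknown label {label!r}")
    if params is None:
        params = default_params(label)
    params.validate()
    rng = np.random.default_rng(int(rng_seed))
    img, truth = _render(label, params, rng)
    rad = Radiograph(
        pixels=img,
        seed_id=seed_id if seed_id is not None else f"seed{rng_seed:06d}",
        cultivar=cultivar,
        label=label,
    )
    return rad, truth


def generate_dataset(
    n_per_class: int,
    cultivars: Sequence[str] = ("synthetic",),
    params_by_cultivar: Mapping[str, Mapping[str, MorphologyParams]] | None = None,
    rng_seed: int = 0,
) -> tuple[list[Radiograph], pd.DataFrame]:
    """Generate a balanced labelled dataset.

    Returns exactly ``n_per_class`` seeds per class, cultivars assigned
    round-robin within each class, together with a manifest recording
    seed_id, cultivar, label and the per-image rng seed.  Regeneration with
    the same rng_seed is bit-identical: every image draws from its own
    child seed derived from (rng_seed, image index).
    """
    if n_per_class < 1:
        raise ParameterError("n_per_class must be >= 1")
    if len(cultivars) == 0:
        raise ParameterError("cultivar list must be nonempty")

    images: list[Radiograph] = []
    rows = []
    index = 0
    for label in LABELS:
        for i in range(n_per_class):
            cultivar = cultivars[i % len(cultivars)]
            if params_by_cultivar is not None and cultivar in params_by_cultivar:
                params = params_by_cultivar[cultivar][label]
            else:
                params = default_params(label)
            child_seed = np.random.SeedSequence((int(rng_seed), index)).generate_state(1)[0] % (2**31)
            seed_id = f"{label[:3]}{i:05d}"
            rad = generate_seed(label, params, int(child_seed), seed_id, cultivar)
            images.append(rad)
            rows.append(
                {
                    "seed_id": seed_id,
                    "cultivar": cultivar,
                    "label": label,
                    "rng_seed": int(child_seed),
                }
            )
            index += 1
    manifest = pd.DataFrame(rows)
    return images, manifest
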