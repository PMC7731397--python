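"""Assemble the full per-seed feature vector over the enhancement triplet."""

from __future__ import annotations

import numpy as np

from ..preprocess import EnhancedTriplet, SeedMask
from .config import ENHANCEMENT_SETS, FEATURES_PER_IMAGE, ConfigurationError, FeatureBankConfig
from .contrast import CONTRAST_NAMES, extract_contrast
from .fourier import extract_local_fft, fourier_names
from .gabor import extract_gabor, gabor_names
from .haralick import extract_haralick, haralick_names
from .intensity import INTENSITY_NAMES, extract_intensity
from .lbp import extract_lbp, lbp_names
from .vector import FeatureVector


def image_feature_names(config: FeatureBankConfig) -> list[str]:
    """The 348 per-image feature names, in extraction order, untagged."""
    return (
        list(INTENSITY_NAMES)
        + lbp_names(config.lbp_radii)
        + gabor_names(len(config.gabor_frequencies), config.gabor_n_orientations)
        + list(CONTRAST_NAMES)
        + haralick_names()
        + fourier_names(config.fft_bands)
    )


def extract_image_features(
    image: np.ndarray, mask: np.ndarray, config: FeatureBankConfig
) -> np.ndarray:
    """All 348 features of a single enhanced image."""
    parts = [
        extract_intensity(image, mask),
        extract_lbp(image, mask, config.lbp_radii),
        extract_gabor(image, mask, config.gabor_frequencies, config.gabor_n_orientations),
        extract_contrast(image, mask),
        extract_haralick(image, mask, config.glcm_levels, config.glcm_distance),
        extract_local_fft(image, mask, config.fft_bands),
    ]
    for part, (family, expected) in zip(parts, config.family_counts().items()):
        if part.shape[0] != expected:
            raise ConfigurationError(
                f"family {family!r} produced {part.shape[0]} features, expected {expected}"
            )
    return np.concatenate(parts)


def extract_all(
    triplet: EnhancedTriplet,
    mask: SeedMask | np.ndarray,
    config: FeatureBankConfig | None = None,
    seed_id: str = "",
) -> FeatureVector:
    """1044 named features per seed: 348 per enhancement set, set-tagged."""
    if config is None:
        config = FeatureBankConfig()
    mask_px = mask.pixels if isinstance(mask, SeedMask) else np.asarray(mask, dtype=bool)
    base_names = image_feature_names(config)
    names: list[str] = []
    values: list[np.ndarray] = []
    for set_letter in ENHANCEMENT_SETS:
        image = triplet.as_dict()[set_letter]
        if image.shape != mask_px.shape:
            raise ValueError("triplet and mask shapes differ")
        vals = extract_image_features(image, mask_px, config)
        if vals.shape[0] != FEATURES_PER_IMAGE:
            raise ConfigurationError(
                f"per-image feature count {vals.shape[0]} != {FEATURES_PER_IMAGE}"
            )
        names.extend(f"{n}[{set_letter}]" for n in base_names)
        values.append(vals)
    return FeatureVector(names=names, values=np.concatenate(values), seed_id=seed_id)
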