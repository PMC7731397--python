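"""Feature bank configuration.

The family totals (6 intensity, 234 LBP, 67 Gabor, 5 contrast, 28 Haralick,
8 Fourier = 348 per image) are a hard contract; every parameter that
produces them is configurable but the counts are validated at construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict


class ConfigurationError(ValueError):
    """Feature bank parameters inconsistent with the family count contract."""


FAMILY_COUNTS = {
    "intensity": 6,
    "lbp": 234,
    "gabor": 67,
    "contrast": 5,
    "haralick": 28,
    "fft": 8,
}

FEATURES_PER_IMAGE = sum(FAMILY_COUNTS.values())  # 348
ENHANCEMENT_SETS = ("A", "B", "C")
FEATURES_PER_SEED = FEATURES_PER_IMAGE * len(ENHANCEMENT_SETS)  # 1044


@dataclass(frozen=True)
class FeatureBankConfig:
    # LBP: 8-point uniform (u2) codes at four radii; 58 uniform-pattern bins
    # per radius plus pooled energy and entropy -> 4*58 + 2 = 234
    lbp_radii: tuple[int, ...] = (1, 2, 3, 4)
    lbp_points: int = 8
    # Gabor: 4 frequencies x 8 orientations, mean magnitude and energy per
    # filter, plus total energy J, pooled mean and pooled sd -> 64 + 3 = 67
    gabor_frequencies: tuple[float, ...] = (0.08, 0.13, 0.20, 0.30)
    gabor_n_orientations: int = 8
    # Haralick: GLCM at 4 offsets, distance 1, quantized within the mask;
    # 14 statistics summarized by mean and range over offsets -> 28
    glcm_levels: int = 32
    glcm_distance: int = 1
    # Fourier: 4 radial bands; magnitude-energy share and circular-mean
    # phase per band -> 8
    fft_bands: int = 4

    def __post_init__(self) -> None:
        if self.lbp_points != 8:
            raise ConfigurationError("only 8-point LBP neighborhoods are supported (u2, 58 bins)")
        if any(r < 1 for r in self.lbp_radii):
            raise ConfigurationError("LBP radii must be >= 1")
        if self.glcm_levels < 2:
            raise ConfigurationError("GLCM needs >= 2 gray levels")
        for name, n in self.family_counts().items():
            if n != FAMILY_COUNTS[name]:
                raise ConfigurationError(
                    f"family {name!r} would produce {n} features, contract is {FAMILY_COUNTS[name]}"
                )

    def family_counts(self) -> dict[str, int]:
        return {
            "intensity": 6,
            "lbp": len(self.lbp_radii) * 58 + 2,
            "gabor": len(self.gabor_frequencies) * self.gabor_n_orientations * 2 + 3,
            "contrast": 5,
            "haralick": 14 * 2,
            "fft": self.fft_bands * 2,
        }

    def to_dict(self) -> dict:
        return asdict(self)
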