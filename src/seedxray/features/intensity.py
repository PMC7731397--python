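"""Basic first-order intensity statistics over the masked seed region."""

from __future__ import annotations

import numpy as np
from scipy import stats

INTENSITY_NAMES = (
    "i-Intensity Mean",
    "i-Intensity SD",
    "i-Intensity Skewness",
    "i-Intensity Kurtosis",
    "i-Intensity Min",
    "i-Intensity Max",
)


def extract_intensity(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Mean, population sd, skewness, excess kurtosis, min and max of the
    masked pixels.  Skewness/kurtosis of a constant region are defined as 0."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    px = np.asarray(image, dtype=float)[mask]
    sd = px.std()
    if sd == 0:
        skew = kurt = 0.0
    else:
        skew = float(stats.skew(px))
        kurt = float(stats.kurtosis(px))  # Fisher: 0 for a normal sample
    return np.array([px.mean(), sd, skew, kurt, px.min(), px.max()])
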