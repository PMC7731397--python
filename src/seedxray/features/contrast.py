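"""Basic contrast measures of the masked seed region."""

from __future__ import annotations

import numpy as np

CONTRAST_NAMES = (
    "i-Contrast Michelson",
    "i-Contrast RMS",
    "i-Contrast Weber",
    "i-Contrast Range",
    "i-Contrast IQR",
)


def extract_contrast(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Michelson, RMS (sd), Weber (vs. background mean), range and IQR.

    Weber contrast compares the mean foreground intensity with the mean of
    the pixels outside the mask; it is 0 when there is no background or the
    background mean is 0.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    img = np.asarray(image, dtype=float)
    fg = img[mask]
    lo, hi = fg.min(), fg.max()
    michelson = (hi - lo) / (hi + lo) if (hi + lo) > 0 else 0.0
    rms = fg.std()
    bg = img[~mask]
    weber = (fg.mean() - bg.mean()) / bg.mean() if bg.size and bg.mean() > 0 else 0.0
    q75, q25 = np.percentile(fg, [75, 25])
    return np.array([michelson, rms, weber, hi - lo, q75 - q25])
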