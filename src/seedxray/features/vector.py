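"""Feature vector container and feature-name grammar.

Names encode family, parameters and enhancement set, e.g.::

    i-LBP(2,17)[8,u2][B]      # LBP, radius 2, uniform-pattern bin 17, set_B
    i-Gabor(3,5)[mean][A]     # Gabor, frequency 3, orientation 5, set_A
    i-Haralick Contrast[range][C]
    Fourier Ang (2,1)[rad][C]

The parser also accepts the published block-tag variants ``[Max-A]`` /
``[sd-A]`` in the final bracket, so reference selections can be summarized
with the same tooling.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class FeatureVector:
    """Named feature values for one seed; name<->value alignment is stable."""

    names: list[str]
    values: np.ndarray
    seed_id: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.names) != self.values.shape[0]:
            raise ValueError("names and values length mismatch")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")


def features_to_dataframe(vectors: list[FeatureVector]) -> pd.DataFrame:
    """One row per seed, columns = feature names, index = seed_id."""
    if not vectors:
        return pd.DataFrame()
    names = vectors[0].names
    for v in vectors[1:]:
        if v.names != names:
            raise ValueError("inconsistent feature names across seeds")
    return pd.DataFrame(
        np.stack([v.values for v in vectors]),
        index=[v.seed_id for v in vectors],
        columns=names,
    )


_SET_TAG = re.compile(r"\[(?:(?:Max|sd)-)?([ABC])\]\s*$")


def parse_feature_name(name: str) -> tuple[str, str]:
    """Return (family, enhancement_set) for a feature name.

    Families: intensity, lbp, gabor, contrast, haralick, fft.
    """
    m = _SET_TAG.search(name)
    if m is None:
        raise ValueError(f"feature name {name!r} has no enhancement-set tag")
    set_letter = m.group(1)
    if name.startswith("i-LBP"):
        family = "lbp"
    elif name.startswith("i-Gabor"):
        family = "gabor"
    elif name.startswith("Fourier"):
        family = "fft"
    elif name.startswith("i-Intensity"):
        family = "intensity"
    elif name.startswith("i-Contrast"):
        family = "contrast"
    elif name.startswith(("i-Haralick", "i-Tx")):
        family = "haralick"
    else:
        raise ValueError(f"feature name {name!r} matches no known family")
    return family, set_letter
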