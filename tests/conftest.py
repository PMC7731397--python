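"""Shared fixtures: synthetic datasets with extracted feature tables.

Heavy fixtures are session-scoped so the generator and extractor run once;
everything derives deterministically from fixed seeds.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import seedxray as sx
from seedxray.workflow import extract_dataset_features


@pytest.fixture(scope="session")
def single_seed():
    """One viable seed with its renderer ground truth."""
    return sx.generate_seed_with_truth(sx.VIABLE, rng_seed=7)


@pytest.fixture(scope="session")
def single_nonviable():
    params = sx.MorphologyParams(air_space_fraction=0.2, n_blobs=3, irregularity=0.08)
    return sx.generate_seed_with_truth(sx.NONVIABLE, params, rng_seed=7)


@pytest.fixture(scope="session")
def small_dataset():
    """20 seeds/class with labels and the full 1044-feature table."""
    images, manifest = sx.generate_dataset(20, ["a", "b"], rng_seed=11)
    features = extract_dataset_features(images)
    labels = manifest.set_index("seed_id")["label"].loc[features.index]
    return images, manifest, features, labels


@pytest.fixture(scope="session")
def alpha_features():
    """Feature tables for air-space fractions 0, 0.05, 0.15 and 0.3.

    The alpha=0 arm also zeroes outline irregularity, so the two class-
    conditional generative distributions coincide there.
    """
    out = {}
    for alpha in (0.0, 0.05, 0.15, 0.3):
        nonviable = sx.MorphologyParams(
            air_space_fraction=alpha,
            n_blobs=3,
            irregularity=0.08 if alpha > 0 else 0.0,
        )
        params = {
            c: {sx.VIABLE: sx.MorphologyParams(), sx.NONVIABLE: nonviable}
            for c in ("a", "b")
        }
        images, manifest = sx.generate_dataset(50, ["a", "b"], params, rng_seed=23)
        features = extract_dataset_features(images)
        labels = manifest.set_index("seed_id")["label"].loc[features.index]
        out[alpha] = (features, labels.to_numpy())
    return out
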