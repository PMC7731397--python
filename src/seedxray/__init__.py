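"""seedxray: seed-viability classification from 2D X-ray radiographs.

A conventional machine-vision pipeline — enhancement triplet, six texture
feature families (1044 features per seed), Fisher-score sequential forward
selection, cross-validated LDA/QDA/KNN classification — plus a synthetic
radiograph generator, six-fold geometric augmentation and a small
from-scratch ConvNet baseline.
"""

from importlib import resources

from .synthetic import (
    IMAGE_SIZE,
    LABELS,
    NONVIABLE,
    VIABLE,
    GroundTruth,
    MorphologyParams,
    ParameterError,
    Radiograph,
    default_params,
    generate_dataset,
    generate_seed,
    generate_seed_with_truth,
)
from .preprocess import (
    DegenerateInputError,
    EnhancedTriplet,
    SeedMask,
    compute_mask,
    crop_seeds,
    enhance_sets,
)
from .features import (
    FeatureBankConfig,
    FeatureVector,
    extract_all,
    features_to_dataframe,
    parse_feature_name,
)
from .selection import (
    FisherScoreSelector,
    SelectionTrace,
    fisher_score,
    sfs,
    summarize_selection,
)
from .classify import (
    CVReport,
    cross_validate,
    fit_knn,
    fit_lda,
    fit_qda,
    make_classifier,
    make_cv_evaluator,
    predict,
    reference_pipeline,
)
from .augment import AugmentationSpec, augment_six, build_augmented_dataset, split_dataset
from .workflow import (
    RunConfig,
    RunReport,
    extract_dataset_features,
    germination_summary,
    predict_new,
    run_pipeline,
)

__version__ = "0.1.0"


def reference_selected_features() -> list[str]:
    """The published 48-feature reference selection shipped with the package."""
    text = resources.files("seedxray").joinpath("data/reference_selected_features.txt").read_text()
    return [line.strip() for line in text.splitlines()
            if line.strip() and not line.startswith("#")]
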