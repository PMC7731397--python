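"""End-to-end pipeline orchestration and germination-table arithmetic.

The full run mirrors the seed-inspection workflow: build (or load) the
radiograph dataset, mask and enhance every seed, extract the 1044-feature
vectors, select features by Fisher-pruned sequential forward selection,
and cross-validate the LDA/QDA/KNN classifiers on the selected subset.
Every artifact is written next to a config hash so a run is reproducible
from its configuration and seeds alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import joblib
import numpy as np
import pandas as pd

from . import synthetic
from .augment import AugmentationSpec
from .classify import CVReport, cross_validate, make_classifier, make_cv_evaluator, predict
from .features import FeatureBankConfig, extract_all, features_to_dataframe
from .io import load_image
from .preprocess import compute_mask, enhance_sets
from .selection import SelectionTrace, sfs
from .synthetic import ParameterError, Radiograph

log = logging.getLogger("seedxray")

ARCHIVE_VERSION = 1


def _round_half_up(x: float, decimals: int = 0) -> float:
    factor = 10.0**decimals
    return float(np.floor(x * factor + 0.5) / factor)


def germination_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Germination rate per cultivar and overall, in integer percent.

    Expects columns cultivar, viable, nonviable and (optionally) total with
    viable + nonviable = total.  Rates are viable/total*100 rounded half-up,
    the overall row uses the summed counts.
    """
    required = {"cultivar", "viable", "nonviable"}
    if not required.issubset(table.columns):
        raise ParameterError(f"germination table needs columns {sorted(required)}")
    df = table.copy()
    if "total" not in df.columns:
        df["total"] = df["viable"] + df["nonviable"]
    if (df["total"] <= 0).any():
        raise ParameterError("row with zero total seeds")
    if not (df["viable"] + df["nonviable"] == df["total"]).all():
        raise ParameterError("viable + nonviable must equal total in every row")
    df["germination_rate"] = [
        int(_round_half_up(100.0 * v / t)) for v, t in zip(df["viable"], df["total"])
    ]
    overall = {
        "cultivar": "Overall",
        "viable": int(df["viable"].sum()),
        "nonviable": int(df["nonviable"].sum()),
        "total": int(df["total"].sum()),
    }
    overall["germination_rate"] = int(
        _round_half_up(100.0 * overall["viable"] / overall["total"])
    )
    return pd.concat([df, pd.DataFrame([overall])], ignore_index=True)


@dataclass
class RunConfig:
    """Everything needed to reproduce a full pipeline run."""

    n_per_class: int = 60
    cultivars: tuple[str, ...] = ("leehyunglim", "sambaechea", "choiganggul")
    rng_seed: int = 0
    feature_bank: FeatureBankConfig = field(default_factory=FeatureBankConfig)
    selection_max_k: int = 20
    selection_candidate_pool: int = 40
    selection_classifier: str = "lda"
    selection_cv_folds: int = 5
    cv_folds: int = 10
    classifiers: tuple[str, ...] = ("lda", "qda", "knn")
    augmentation: AugmentationSpec = field(default_factory=AugmentationSpec)

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


@dataclass
class RunReport:
    config_hash: str
    features: pd.DataFrame
    labels: pd.Series
    trace: SelectionTrace
    cv_reports: dict[str, CVReport]
    timings: dict[str, float]

    def summary_table(self) -> pd.DataFrame:
        """Classifier performance in the Mean / UCI / LCI layout."""
        rows = [
            {"classifier": name.upper(), "mean": round(r.mean, 1),
             "uci": round(r.uci, 1), "lci": round(r.lci, 1)}
            for name, r in self.cv_reports.items()
        ]
        return pd.DataFrame(rows)


def extract_dataset_features(
    images: list[Radiograph], config: FeatureBankConfig | None = None
) -> pd.DataFrame:
    """Mask (computed once per seed, on set_A) + enhancement + extraction."""
    if config is None:
        config = FeatureBankConfig()
    vectors = []
    for image in images:
        triplet = enhance_sets(image)
        mask = compute_mask(triplet.set_A)
        vectors.append(extract_all(triplet, mask, config, seed_id=image.seed_id))
    return features_to_dataframe(vectors)


def run_pipeline(
    config: RunConfig,
    out_dir: Path | None = None,
    images: list[Radiograph] | None = None,
    labels: pd.Series | None = None,
) -> RunReport:
    """Execute preprocess -> extract -> select -> cross-validate.

    Without explicit images, a balanced synthetic dataset is generated from
    config.rng_seed.  Artifacts (feature table, selection trace, CV summary,
    model archive) are written to out_dir when given, tagged with the config
    hash.  Reruns with the same config are identical.
    """
    chash = config.hash()
    timings: dict[str, float] = {}
    t0 = time.perf_counter()
    if images is None:
        images, manifest = synthetic.generate_dataset(
            config.n_per_class, list(config.cultivars), rng_seed=config.rng_seed
        )
        labels = manifest.set_index("seed_id")["label"]
    elif labels is None:
        labels = pd.Series({im.seed_id: im.label for im in images})
    timings["simulate"] = time.perf_counter() - t0
    log.info("run %s: %d images", chash, len(images))

    t0 = time.perf_counter()
    features = extract_dataset_features(images, config.feature_bank)
    labels = labels.loc[features.index]
    timings["extract"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    evaluator = make_cv_evaluator(
        config.selection_classifier, config.selection_cv_folds, config.rng_seed
    )
    trace = sfs(
        features,
        labels.to_numpy(),
        evaluator,
        max_k=min(config.selection_max_k, features.shape[1]),
        candidate_pool=config.selection_candidate_pool,
    )
    timings["select"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    selected = features[trace.best_features]
    cv_reports = {
        name: cross_validate(selected, labels.to_numpy(), name, config.cv_folds, config.rng_seed)
        for name in config.classifiers
    }
    timings["cross_validate"] = time.perf_counter() - t0

    report = RunReport(
        config_hash=chash,
        features=features,
        labels=labels,
        trace=trace,
        cv_reports=cv_reports,
        timings=timings,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        features.to_csv(out_dir / "features.csv")
        trace.to_json(out_dir / "selection_trace.json")
        report.summary_table().to_csv(out_dir / "cv_summary.csv", index=False)
        curve = pd.DataFrame(
            {"k": range(1, len(trace.cv_accuracy_at_step) + 1),
             "cv_accuracy": trace.cv_accuracy_at_step}
        )
        curve.to_csv(out_dir / "accuracy_vs_k.csv", index=False)
        (out_dir / "run.json").write_text(
            json.dumps({"config_hash": chash, "config": config.to_dict(),
                        "timings": timings}, indent=2, default=str)
        )
        save_model_archive(out_dir / "model.joblib", config, report)
    return report


def save_model_archive(path: Path, config: RunConfig, report: RunReport) -> None:
    """Persist the best classifier retrained on all data, with its config."""
    best = max(report.cv_reports, key=lambda k: report.cv_reports[k].mean)
    selected = report.features[report.trace.best_features]
    model = make_classifier(best).fit(selected, report.labels.to_numpy())
    joblib.dump(
        {
            "version": ARCHIVE_VERSION,
            "config_hash": report.config_hash,
            "config": config.to_dict(),
            "classifier": best,
            "selected_features": report.trace.best_features,
            "model": model,
        },
        path,
    )


def predict_new(archive_path: Path, image_paths: list[Path]) -> pd.DataFrame:
    """Classify new radiographs with an archived model.

    Unreadable images produce a per-row error entry; the run continues.
    """
    archive = joblib.load(archive_path)
    if archive.get("version") != ARCHIVE_VERSION:
        raise ParameterError(f"unsupported model archive version {archive.get('version')!r}")
    bank = FeatureBankConfig(**archive["config"]["feature_bank"])
    rows = []
    for path in image_paths:
        path = Path(path)
        try:
            px = load_image(path)
            rad = Radiograph(pixels=px, seed_id=path.stem)
            feats = extract_dataset_features([rad], bank)
            result = predict(archive["model"], feats).iloc[0]
            rows.append({"image": str(path), "predicted": result["predicted"],
                         "error": "", **{k: v for k, v in result.items() if k.startswith("p_")}})
        except Exception as exc:  # noqa: BLE001 - per-row error reporting
            rows.append({"image": str(path), "predicted": "", "error": str(exc)})
    return pd.DataFrame(rows)
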