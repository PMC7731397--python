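"""PNG / CSV / YAML input-output helpers."""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .preprocess import SeedMask
from .synthetic import Radiograph


def save_radiograph(image: Radiograph, directory: Path) -> Path:
    """Write an 8-bit grayscale PNG named {cultivar}_{seed_id}.png."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / f"{image.cultivar}_{image.seed_id}.png"
    iio.imwrite(path, np.round(image.pixels * 255).astype(np.uint8))
    return path


def save_dataset(images: list[Radiograph], manifest: pd.DataFrame, directory: Path) -> Path:
    directory = Path(directory)
    for image in images:
        save_radiograph(image, directory)
    manifest_path = directory / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    return manifest_path


def load_dataset(directory: Path) -> tuple[list[Radiograph], pd.DataFrame]:
    """Read back a dataset written by save_dataset."""
    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.csv")
    images = []
    for _, row in manifest.iterrows():
        px = iio.imread(directory / f"{row['cultivar']}_{row['seed_id']}.png")
        images.append(
            Radiograph(
                pixels=px.astype(float) / 255.0,
                seed_id=str(row["seed_id"]),
                cultivar=str(row["cultivar"]),
                label=row["label"] if "label" in row and pd.notna(row["label"]) else None,
            )
        )
    return images, manifest


def load_image(path: Path) -> np.ndarray:
    px = iio.imread(path)
    if px.ndim == 3:  # collapse incidental color channels
        px = px.mean(axis=-1)
    return px.astype(float) / 255.0


def save_mask(mask: SeedMask, path: Path) -> None:
    """Mask as 0/255 PNG with a JSON sidecar recording the threshold."""
    path = Path(path)
    iio.imwrite(path, (mask.pixels.astype(np.uint8)) * 255)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps({"threshold": mask.threshold, "area": mask.area}))


def load_config(path: Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def save_config(config: dict, path: Path) -> None:
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(config, sort_keys=False))
    else:
        path.write_text(json.dumps(config, indent=2))
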