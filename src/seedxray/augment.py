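"""Six-fold geometric augmentation and leakage-safe dataset splitting.

Every source radiograph yields exactly six variants — rotation, horizontal
reflection, x-translation, y-translation, x-scaling and y-scaling — so an
input set of n images becomes 6n augmented images.  Splitting into
train/validation/test is stratified by label and *grouped by source image*:
all variants of one seed land in the same partition, which prevents
augmentation leakage between partitions.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.transform import AffineTransform, rotate, warp

from .synthetic import IMAGE_SIZE, ParameterError, Radiograph

VARIANTS = ("rotation", "reflection", "translate-x", "translate-y", "scale-x", "scale-y")
PARTITIONS = ("train", "validation", "test")


@dataclass(frozen=True)
class AugmentationSpec:
    """Parameter ranges for the six variant slots (mild, label-preserving)."""

    rotation_deg: tuple[float, float] = (-25.0, 25.0)
    reflection_axis: str = "horizontal"
    translate_x_px: tuple[float, float] = (-10.0, 10.0)
    translate_y_px: tuple[float, float] = (-10.0, 10.0)
    scale_x: tuple[float, float] = (0.9, 1.1)
    scale_y: tuple[float, float] = (0.9, 1.1)
    rng_seed: int = 0

    def validate(self) -> None:
        if self.scale_x[0] <= 0 or self.scale_y[0] <= 0:
            raise ParameterError("scale factors must be positive")
        if self.reflection_axis not in ("horizontal", "vertical"):
            raise ParameterError("reflection_axis must be 'horizontal' or 'vertical'")


def _image_rng(spec: AugmentationSpec, seed_id: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence((int(spec.rng_seed), zlib.crc32(seed_id.encode())))
    )


def _fill_value(px: np.ndarray) -> float:
    border = np.concatenate([px[0, :], px[-1, :], px[:, 0], px[:, -1]])
    return float(np.median(border))


def _centered_scale(px: np.ndarray, sx: float, sy: float) -> np.ndarray:
    if sx == 1.0 and sy == 1.0:
        return px.copy()
    cy, cx = (np.asarray(px.shape) - 1) / 2.0
    shift = AffineTransform(translation=(-cx, -cy))
    scale = AffineTransform(scale=(sx, sy))
    back = AffineTransform(translation=(cx, cy))
    tf = shift + scale + back  # applied left to right
    return warp(px, tf.inverse, mode="constant", cval=_fill_value(px), preserve_range=True)


def _translate(px: np.ndarray, tx: float, ty: float) -> np.ndarray:
    if tx == 0.0 and ty == 0.0:
        return px.copy()
    tf = AffineTransform(translation=(tx, ty))
    return warp(px, tf.inverse, mode="constant", cval=_fill_value(px), preserve_range=True)


def augment_six(
    image: Radiograph, spec: AugmentationSpec | None = None
) -> tuple[list[Radiograph], pd.DataFrame]:
    """The six augmented variants of one radiograph plus their parameter log.

    Deterministic: variant parameters are drawn from a stream keyed by
    (spec.rng_seed, image.seed_id).  Degenerate draws (angle 0, shift 0,
    scale 1) reproduce the input bit-for-bit.
    """
    if spec is None:
        spec = AugmentationSpec()
    spec.validate()
    rng = _image_rng(spec, image.seed_id)
    px = image.pixels

    angle = float(rng.uniform(*spec.rotation_deg))
    tx = float(rng.uniform(*spec.translate_x_px))
    ty = float(rng.uniform(*spec.translate_y_px))
    sx = float(rng.uniform(*spec.scale_x))
    sy = float(rng.uniform(*spec.scale_y))

    if angle == 0.0:
        rotated = px.copy()
    else:
        rotated = rotate(px, angle, mode="constant", cval=_fill_value(px), preserve_range=True)
    mirrored = np.fliplr(px) if spec.reflection_axis == "horizontal" else np.flipud(px)

    arrays = [
        rotated,
        mirrored.copy(),
        _translate(px, tx, 0.0),
        _translate(px, 0.0, ty),
        _centered_scale(px, sx, 1.0),
        _centered_scale(px, 1.0, sy),
    ]
    params = [
        {"angle_deg": angle},
        {"axis": spec.reflection_axis},
        {"tx_px": tx},
        {"ty_px": ty},
        {"sx": sx},
        {"sy": sy},
    ]
    out, rows = [], []
    for variant, arr, par in zip(VARIANTS, arrays, params):
        arr = np.clip(np.asarray(arr, dtype=float), 0.0, 1.0)
        if arr.shape != (IMAGE_SIZE, IMAGE_SIZE):
            raise ParameterError("augmentation changed the image shape")
        sid = f"{image.seed_id}_{variant}"
        out.append(
            Radiograph(pixels=arr, seed_id=sid, cultivar=image.cultivar, label=image.label)
        )
        rows.append(
            {"seed_id": sid, "source_id": image.seed_id, "variant": variant,
             "label": image.label, "cultivar": image.cultivar, "params": par}
        )
    return out, pd.DataFrame(rows)


def build_augmented_dataset(
    images: list[Radiograph], spec: AugmentationSpec | None = None
) -> tuple[list[Radiograph], pd.DataFrame]:
    """6x augmentation of a whole set, with a source-linked manifest."""
    if not images:
        raise ParameterError("empty image list")
    all_images: list[Radiograph] = []
    manifests = []
    for image in images:
        variants, manifest = augment_six(image, spec)
        all_images.extend(variants)
        manifests.append(manifest)
    return all_images, pd.concat(manifests, ignore_index=True)


def split_dataset(
    manifest: pd.DataFrame,
    ratios: tuple[float, float, float] = (70.0, 15.0, 15.0),
    label_col: str = "label",
    group_col: str | None = "source_id",
    rng_seed: int = 0,
) -> pd.Series:
    """Assign each manifest row to train/validation/test.

    Stratified by ``label_col`` (per-class counts within one group of the
    exact ratio) and grouped by ``group_col``: rows sharing a group are
    never split across partitions.  Deterministic given rng_seed.
    """
    if abs(sum(ratios) - 100.0) > 1e-9:
        raise ParameterError("ratios must sum to 100")
    rng = np.random.default_rng(int(rng_seed))
    if group_col is not None and group_col in manifest.columns:
        groups = manifest.groupby(group_col, sort=True)
        group_ids = list(groups.groups)
        group_label = {g: df[label_col].iloc[0] for g, df in groups}
        for g, df in groups:
            if df[label_col].nunique() > 1:
                raise ParameterError(f"group {g!r} mixes labels; cannot stratify")
        group_size = {g: len(df) for g, df in groups}
    else:
        group_ids = list(manifest.index)
        group_label = {g: manifest.loc[g, label_col] for g in group_ids}
        group_size = {g: 1 for g in group_ids}

    labels = sorted({group_label[g] for g in group_ids})
    fracs = np.asarray(ratios, dtype=float) / 100.0
    assignment: dict = {}
    # leftover quota from earlier classes rolls forward so global partition
    # sizes land on the exact ratio even when per-class quotas are fractional
    carry = np.zeros(3)
    for lab in labels:
        members = [g for g in group_ids if group_label[g] == lab]
        if len(members) < 3:
            raise ParameterError(f"class {lab!r} has too few groups to split")
        rng.shuffle(members)
        n_items = sum(group_size[g] for g in members)
        quota = fracs * n_items + carry
        for g in members:
            part = int(np.argmax(quota))
            assignment[g] = PARTITIONS[part]
            quota[part] -= group_size[g]
        carry = quota

    if group_col is not None and group_col in manifest.columns:
        return manifest[group_col].map(assignment).rename("partition")
    return pd.Series([assignment[i] for i in manifest.index], index=manifest.index, name="partition")
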