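"""Readers and writers for on-disk artifacts.

Formats: PNG/JPEG images, PNG binary masks, superpixel index maps stored as
24-bit PNG with ``id = R + 256*G + 65536*B`` (plain 16-bit grayscale is also
accepted), per-superpixel label CSVs, and prediction CSVs in the one-row-per-
image, one-score-column-per-category submission style.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError

from .types import FEATURE_CLASSES, LESION_CLASSES, BinaryMask, LesionImage, LesionIndex, SuperpixelMap

__all__ = [
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "write_prediction_csv",
    "read_prediction_csv",
    "read_superpixel_annotations",
    "write_superpixel_annotations",
]


def read_image(path: str | Path) -> LesionImage:
    """Read a PNG/JPEG image, scaling 8-bit channels to [0, 1]."""
    path = Path(path)
    try:
        with Image.open(path) as img:
            arr = np.asarray(img.convert("RGB"), dtype=np.float64) / 255.0
    except (OSError, UnidentifiedImageError) as exc:
        raise IOError(f"cannot read image file {path}: {exc}") from exc
    return LesionImage(pixels=arr, image_id=path.stem)


def write_image(image: LesionImage, path: str | Path) -> None:
    arr = np.clip(np.rint(image.pixels * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="RGB").save(Path(path))


def read_mask(path: str | Path) -> BinaryMask:
    """Read a binary mask PNG; any value > half scale counts as lesion."""
    path = Path(path)
    try:
        with Image.open(path) as img:
            arr = np.asarray(img.convert("L"))
    except (OSError, UnidentifiedImageError) as exc:
        raise IOError(f"cannot read mask file {path}: {exc}") from exc
    return BinaryMask(pixels=(arr > 127).astype(np.uint8), image_id=path.stem)


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    Image.fromarray((mask.pixels * 255).astype(np.uint8), mode="L").save(Path(path))


def write_prediction_csv(records: list[tuple[str, LesionIndex]], path: str | Path) -> None:
    """Write one row per image: image_id plus one score column per category.

    Scores are printed with 6 decimal digits. Duplicate image ids are
    rejected.
    """
    seen: set[str] = set()
    for image_id, _ in records:
        if image_id in seen:
            raise ValueError(f"duplicate image_id {image_id!r} in prediction records")
        seen.add(image_id)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image_id", *LESION_CLASSES])
        for image_id, li in records:
            writer.writerow([image_id] + [f"{x:.6f}" for x in li.index])


def read_prediction_csv(path: str | Path) -> list[tuple[str, LesionIndex]]:
    records = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            idx = np.array([float(row[c]) for c in LESION_CLASSES])
            records.append((row["image_id"], LesionIndex(index=idx)))
    return records


def _decode_index_png(path: Path) -> np.ndarray:
    try:
        with Image.open(path) as img:
            if img.mode in ("I", "I;16", "I;16B", "L"):
                return np.asarray(img.convert("I"), dtype=np.int64)
            arr = np.asarray(img.convert("RGB"), dtype=np.int64)
    except (OSError, UnidentifiedImageError) as exc:
        raise IOError(f"cannot read superpixel index map {path}: {exc}") from exc
    r, g, b = arr[..., 0], arr[..., 1], arr[..., 2]
    return r + 256 * g + 65536 * b


def write_superpixel_annotations(
    spmap: SuperpixelMap,
    labels: dict[int, str],
    index_png_path: str | Path,
    label_csv_path: str | Path,
) -> None:
    """Write an index map as 24-bit PNG (id = R + 256·G + 65536·B) + label CSV."""
    ids = spmap.labels
    rgb = np.stack([ids % 256, (ids // 256) % 256, ids // 65536], axis=-1).astype(np.uint8)
    Image.fromarray(rgb, mode="RGB").save(Path(index_png_path))
    with open(label_csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["superpixel_id", "label"])
        for sp_id in sorted(labels):
            writer.writerow([sp_id, labels[sp_id]])


def read_superpixel_annotations(
    index_png_path: str | Path, label_csv_path: str | Path
) -> tuple[SuperpixelMap, dict[int, str]]:
    """Read a superpixel index map and its per-superpixel feature labels.

    Every superpixel id in the CSV must exist in the index map; labels are
    restricted to the five dermoscopic-feature categories.
    """
    ids = _decode_index_png(Path(index_png_path))
    spmap = SuperpixelMap(labels=ids)
    labels: dict[int, str] = {}
    with open(label_csv_path, newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            sp_id = int(row["superpixel_id"])
            label = row["label"].strip()
            if label not in FEATURE_CLASSES:
                raise ValueError(
                    f"unknown feature label {label!r} for superpixel {sp_id} "
                    f"(expected one of {FEATURE_CLASSES})"
                )
            labels[sp_id] = label
    missing = sorted(set(labels) - set(range(spmap.n_segments)))
    if missing:
        raise ValueError(f"superpixel ids in CSV missing from index map: {missing}")
    return spmap, labels
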