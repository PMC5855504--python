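"""End-to-end helpers tying generation, augmentation, training and inference.

These are the desk-scale workflows the CLI and the reproduction script run:
build dense training samples from (image, mask, class) triples, train the
paired DR/DM segmentation networks, and evaluate the full prediction path.
"""

from __future__ import annotations

import numpy as np

from .augmentation import build_mirror_set, build_rotation_set, ClassAngleSpec
from .lin_inference import predict
from .metrics import confusion, seg_metrics
from .networks import FCRN, FcrnConfig, build_fcrn
from .preprocessing import center_crop, center_crop_mask, resize_mask, resize_square
from .training import TrainConfig, train
from .types import LESION_CLASSES, BinaryMask, LesionImage, LesionIndex

__all__ = [
    "make_segmentation_samples",
    "train_lin_models",
    "evaluate_lin",
]


def make_segmentation_samples(
    items: list[tuple[LesionImage, BinaryMask, str]],
    crop_factor: float = 0.8,
    side: int = 64,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Center-crop + resize images and build 4-class per-pixel label maps.

    Labels: 0 = background, 1..3 = the lesion categories in
    :data:`dermlin.types.LESION_CLASSES` order.
    """
    samples = []
    for image, mask, cls in items:
        img = resize_square(center_crop(image, crop_factor), side)
        m = resize_mask(center_crop_mask(mask.pixels, crop_factor), side)
        label_map = m.astype(np.int64) * (LESION_CLASSES.index(cls) + 1)
        samples.append((img.pixels.transpose(2, 0, 1), label_map))
    return samples


def _by_class(items):
    grouped: dict[str, list] = {}
    for image, mask, cls in items:
        grouped.setdefault(cls, []).append((image, mask))
    return grouped


def train_lin_models(
    items: list[tuple[LesionImage, BinaryMask, str]],
    train_config: TrainConfig,
    fcrn_config: FcrnConfig | None = None,
    crop_factor: float = 0.8,
    side: int = 64,
    rotation_step: float | None = None,
    seed: int = 0,
) -> tuple[FCRN, FCRN, dict]:
    """Train the paired segmentation networks on DR and DM.

    With ``rotation_step`` set, each class is rotation-augmented at that
    step before training (the desk-scale stand-in for the per-class
    balancing steps); DM is always the seeded random mirror of DR.
    Returns (model_DR, model_DM, histories).
    """
    if rotation_step is not None:
        specs = {cls: ClassAngleSpec(cls, rotation_step) for cls in _by_class(items)}
        dr_by_class = build_rotation_set(_by_class(items), specs)
    else:
        dr_by_class = _by_class(items)
    dm_by_class = build_mirror_set(dr_by_class, seed=seed)

    def flatten(by_class):
        return [
            (img, mask, cls)
            for cls, pairs in by_class.items()
            for img, mask in pairs
        ]

    histories = {}
    models = []
    for name, by_class, model_seed in (("DR", dr_by_class, seed), ("DM", dm_by_class, seed + 1)):
        samples = make_segmentation_samples(flatten(by_class), crop_factor, side)
        model = build_fcrn(fcrn_config, seed=model_seed)
        model, history = train(model, samples, train_config)
        histories[name] = history
        models.append(model)
    return models[0], models[1], histories


def evaluate_lin(
    models: list[FCRN],
    items: list[tuple[LesionImage, BinaryMask, str]],
    scales: list[int],
) -> dict:
    """Run the full prediction path over held-out items.

    Returns mean per-image segmentation metrics, classification accuracy,
    and the per-image predictions.
    """
    per_image = []
    predictions: list[tuple[str, BinaryMask, LesionIndex, str]] = []
    n_correct = 0
    for image, truth, cls in items:
        mask, index = predict(models, image, scales)
        per_image.append(seg_metrics(confusion(mask, truth)))
        n_correct += index.predicted_class == cls
        predictions.append((image.image_id, mask, index, cls))
    mean_metrics = {
        key: float(np.nanmean([m[key] for m in per_image])) for key in per_image[0]
    }
    return {
        "seg": mean_metrics,
        "classification_accuracy": n_correct / len(items),
        "predictions": predictions,
    }
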