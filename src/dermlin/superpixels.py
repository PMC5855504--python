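"""Superpixel decomposition, 56×56 patch extraction, per-superpixel prediction.

Feature extraction is cast as classification of superpixel areas: the image
is subdivided with SLIC, the bounding box of each superpixel is cropped
(keeping surrounding context) and resized to 56×56, and the patch classifier
scores each patch over the five feature categories.
"""

from __future__ import annotations

import numpy as np
from skimage.segmentation import slic
from skimage.transform import resize as _sk_resize

from .nn.layers import Module
from .types import FEATURE_CLASSES, LesionImage, Patch, SuperpixelMap

__all__ = ["compute_superpixels", "extract_patch", "predict_features"]


def compute_superpixels(
    image: LesionImage, n_segments: int = 1000, compactness: float = 10.0
) -> SuperpixelMap:
    """SLIC superpixels, relabelled to a contiguous 0-based range.

    Segments are connected, exhaustive and mutually exclusive; the achieved
    count tracks ``n_segments`` approximately (SLIC merges tiny fragments).
    """
    if n_segments < 1:
        raise ValueError("n_segments must be at least 1")
    if n_segments == 1:
        return SuperpixelMap(labels=np.zeros(image.shape, dtype=np.int64))
    labels = slic(
        image.pixels, n_segments=n_segments, compactness=compactness,
        start_label=0, enforce_connectivity=True, channel_axis=-1,
    )
    _, contiguous = np.unique(labels, return_inverse=True)
    return SuperpixelMap(labels=contiguous.reshape(labels.shape))


def extract_patch(image: LesionImage, spmap: SuperpixelMap, sp_id: int) -> Patch:
    """Cut the tight bounding box of a superpixel and resize it to 56×56.

    The box crop retains pixels outside the superpixel so the classifier
    sees local context.
    """
    if image.shape != spmap.shape:
        raise ValueError(f"image {image.shape} and map {spmap.shape} shapes differ")
    if not 0 <= sp_id < spmap.n_segments:
        raise ValueError(f"unknown superpixel id {sp_id} (have 0..{spmap.n_segments - 1})")
    rows, cols = np.nonzero(spmap.labels == sp_id)
    box = image.pixels[rows.min() : rows.max() + 1, cols.min() : cols.max() + 1]
    if box.shape[:2] == (Patch.SIDE, Patch.SIDE):
        resized = box.copy()
    else:
        resized = _sk_resize(
            box, (Patch.SIDE, Patch.SIDE), order=1, mode="edge",
            anti_aliasing=False, preserve_range=True,
        )
    return Patch(pixels=np.clip(resized, 0.0, 1.0), superpixel_id=int(sp_id))


def _softmax(scores: np.ndarray) -> np.ndarray:
    shifted = scores - scores.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=1, keepdims=True)


def predict_features(
    model: Module,
    image: LesionImage,
    spmap: SuperpixelMap,
    batch_size: int = 64,
) -> dict[int, np.ndarray]:
    """Score every superpixel over the five feature classes.

    Returns ``{superpixel_id: probabilities}`` with each probability vector
    summing to 1; the hard label is the argmax over
    :data:`dermlin.types.FEATURE_CLASSES`.
    """
    model.set_training(False)
    patches = [extract_patch(image, spmap, i) for i in range(spmap.n_segments)]
    probs: dict[int, np.ndarray] = {}
    for start in range(0, len(patches), batch_size):
        chunk = patches[start : start + batch_size]
        xs = np.stack([p.pixels.transpose(2, 0, 1) for p in chunk])
        p = _softmax(model.forward(xs))
        for offset, patch in enumerate(chunk):
            probs[patch.superpixel_id] = p[offset]
    return probs


def predicted_labels(probs: dict[int, np.ndarray]) -> dict[int, str]:
    """Hard feature labels from per-superpixel probabilities."""
    return {i: FEATURE_CLASSES[int(np.argmax(p))] for i, p in probs.items()}
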