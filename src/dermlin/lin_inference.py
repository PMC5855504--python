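"""The full Lesion Indexing Network prediction path.

Two segmentation networks (trained on the rotation dataset DR and its
mirrored pair DM) each score the test image at several scales; all score
maps are bilinearly interpolated back to the original resolution and summed.
The summed 4-channel maps give the segmentation mask (per-pixel argmax
against background) and, through the LICU, the per-category lesion index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize

from .licu import compute_lesion_index, distance_map, normalize_coarse
from .nn.layers import Module
from .types import BinaryMask, CoarseMapStack, LesionImage, LesionIndex

__all__ = ["FusionResult", "fuse", "predict"]


@dataclass
class FusionResult:
    """Multi-scale, multi-model fusion output at the original resolution."""

    coarse: CoarseMapStack  # the 3 lesion channels of the summed maps
    background: np.ndarray  # H×W background channel of the summed maps
    mask: BinaryMask


def _run_at_scale(model: Module, image: LesionImage, scale: int) -> np.ndarray:
    """Score the image resized to scale×scale, back-interpolated to H×W."""
    h, w = image.shape
    resized = _sk_resize(
        image.pixels, (scale, scale), order=1, mode="reflect",
        anti_aliasing=scale < min(h, w), preserve_range=True,
    )
    x = np.clip(resized, 0.0, 1.0).transpose(2, 0, 1)[None]
    scores = model.forward(x)[0]  # (n_classes, scale, scale)
    up = np.stack([
        _sk_resize(ch, (h, w), order=1, mode="edge",
                   anti_aliasing=False, preserve_range=True)
        for ch in scores
    ])
    return up


def fuse(models: list[Module], image: LesionImage, scales: list[int]) -> FusionResult:
    """Sum interpolated score maps over every (model, scale) pair.

    The summed maps' lesion channels are the coarse classification maps and
    the segmentation mask is the per-pixel 4-way argmax being non-background.
    The result is invariant to the order of (model, scale) pairs.
    """
    if not models:
        raise ValueError("need at least one model")
    if not scales:
        raise ValueError("need at least one scale")
    for model in models:
        model.set_training(False)
        min_input = getattr(model, "min_input", 0)
        bad = [s for s in scales if s < min_input]
        if bad:
            raise ValueError(f"scales {bad} below the model's minimum input {min_input}")
    total: np.ndarray | None = None
    for model in models:
        for scale in scales:
            up = _run_at_scale(model, image, scale)
            total = up if total is None else total + up
    mask = (total.argmax(axis=0) != 0).astype(np.uint8)
    return FusionResult(
        coarse=CoarseMapStack(total[1:]),
        background=total[0],
        mask=BinaryMask(mask, image.image_id),
    )


def _largest_component(mask: BinaryMask) -> BinaryMask:
    labeled, n = ndimage.label(mask.pixels)
    if n <= 1:
        return mask
    sizes = ndimage.sum_labels(np.ones_like(labeled), labeled, index=np.arange(1, n + 1))
    keep = 1 + int(np.argmax(sizes))
    return BinaryMask((labeled == keep).astype(np.uint8), mask.image_id)


def predict(
    models: list[Module],
    image: LesionImage,
    scales: list[int],
    largest_component_only: bool = False,
) -> tuple[BinaryMask, LesionIndex]:
    """Segmentation mask and lesion index for one image.

    Fusion gives the mask and coarse maps; the LICU normalizes the coarse
    maps, weights them by border distance and averages over the lesion area.
    An all-background image yields an empty mask and the uniform index with
    its empty-lesion flag set.
    """
    fusion = fuse(models, image, scales)
    mask = _largest_component(fusion.mask) if largest_component_only else fusion.mask
    p = normalize_coarse(fusion.coarse)
    d = distance_map(mask)
    return mask, compute_lesion_index(p, d, mask)
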