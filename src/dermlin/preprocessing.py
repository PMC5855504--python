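"""Center-crop and proportional resize of lesion images.

The training pipeline crops a centered square whose side is a fraction of
the image height (0.8 by default), then resizes it to a fixed side. At test
time the same crop-then-resize order produces the multi-scale inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize

from .types import LesionImage

__all__ = ["CropSpec", "center_crop", "resize_square", "prepare_multiscale"]


@dataclass(frozen=True)
class CropSpec:
    factor: float = 0.8
    target_side: int = 64

    def __post_init__(self) -> None:
        if not 0.0 < self.factor <= 1.0:
            raise ValueError("crop factor must lie in (0, 1]")
        if self.target_side < 8:
            raise ValueError("target side must be at least 8")


def _crop_array(arr: np.ndarray, factor: float) -> np.ndarray:
    h, w = arr.shape[:2]
    side = min(int(np.floor(factor * h)), h, w)
    top = (h - side) // 2
    left = (w - side) // 2
    return arr[top : top + side, left : left + side]


def center_crop(image: LesionImage, factor: float = 0.8) -> LesionImage:
    """Crop a centered square of side ``floor(factor*H)``, clamped to min(W, H).

    Ties in centering are broken toward the top-left corner.
    """
    if not 0.0 < factor <= 1.0:
        raise ValueError("crop factor must lie in (0, 1]")
    return LesionImage(pixels=_crop_array(image.pixels, factor), image_id=image.image_id)


def center_crop_mask(mask: np.ndarray, factor: float = 0.8) -> np.ndarray:
    """Apply the same centered square crop to a 2-D mask / label map."""
    if not 0.0 < factor <= 1.0:
        raise ValueError("crop factor must lie in (0, 1]")
    return _crop_array(mask, factor)


def resize_square(image: LesionImage, target_side: int) -> LesionImage:
    """Bilinearly resize a square image to ``target_side`` × ``target_side``."""
    h, w = image.shape
    if h != w:
        raise ValueError(f"resize_square requires a square input, got {h}×{w}")
    if target_side < 8:
        raise ValueError("target side must be at least 8")
    if target_side == h:
        return LesionImage(pixels=image.pixels.copy(), image_id=image.image_id)
    out = _sk_resize(
        image.pixels, (target_side, target_side), order=1, mode="reflect",
        anti_aliasing=target_side < h, preserve_range=True,
    )
    return LesionImage(pixels=np.clip(out, 0.0, 1.0), image_id=image.image_id)


def resize_mask(mask: np.ndarray, target_side: int) -> np.ndarray:
    """Nearest-neighbour resize for masks / integer label maps."""
    if mask.shape[0] == mask.shape[1] == target_side:
        return mask.copy()
    out = _sk_resize(
        mask.astype(np.float64), (target_side, target_side), order=0,
        mode="edge", anti_aliasing=False, preserve_range=True,
    )
    return np.rint(out).astype(mask.dtype)


def prepare_multiscale(
    image: LesionImage, scales: list[int], factor: float = 0.8
) -> list[LesionImage]:
    """Crop once, then resize to each requested scale (order preserved)."""
    if not scales:
        raise ValueError("scales must be non-empty")
    if any(s < 8 for s in scales):
        raise ValueError("every scale must be at least 8")
    cropped = center_crop(image, factor)
    return [resize_square(cropped, s) for s in scales]
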