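"""Core in-memory containers shared across the pipeline.

Conventions: all image arrays are ``float64`` in ``[0, 1]`` with shape
``(H, W, 3)`` (row, col, channel), 0-based row/col coordinates. Masks and
label maps share the orientation of their paired image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: The three lesion categories, in fixed channel order.
LESION_CLASSES = ("melanoma", "seborrheic_keratosis", "nevus")

#: The five dermoscopic-feature categories for superpixel patches:
#: background, pigment network, negative network, milia-like cysts, streaks.
FEATURE_CLASSES = ("B", "PN", "NN", "MC", "S")


@dataclass
class LesionImage:
    """An RGB dermoscopy-style image with channel values in [0, 1]."""

    pixels: np.ndarray
    image_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"expected H×W×3 pixels, got shape {self.pixels.shape}")
        h, w = self.pixels.shape[:2]
        if h < 8 or w < 8:
            raise ValueError(f"image too small: {h}×{w} (need at least 8×8)")
        if self.pixels.min() < 0.0 or self.pixels.max() > 1.0:
            raise ValueError("channel values must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]


@dataclass
class BinaryMask:
    """A binary lesion mask; 1 = lesion, 0 = background."""

    pixels: np.ndarray
    image_id: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2:
            raise ValueError(f"expected H×W mask, got shape {arr.shape}")
        vals = np.unique(arr)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("mask values must be 0 or 1")
        self.pixels = arr.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class SuperpixelMap:
    """A per-pixel superpixel index map with labels 0..n_segments-1.

    Every id in the contiguous range must be present and every superpixel
    spatially connected (8-connectivity); both are validated on construction.
    """

    labels: np.ndarray
    n_segments: int = 0

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        if arr.ndim != 2:
            raise ValueError(f"expected H×W label map, got shape {arr.shape}")
        if arr.min() < 0:
            raise ValueError("superpixel ids must be non-negative")
        self.labels = arr.astype(np.int64)
        present = np.unique(self.labels)
        n = int(present[-1]) + 1
        if self.n_segments == 0:
            self.n_segments = n
        if len(present) != self.n_segments or present[0] != 0 or n != self.n_segments:
            raise ValueError(
                f"superpixel ids must form the contiguous range 0..{self.n_segments - 1}"
            )
        _validate_connectivity(self.labels)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


def _validate_connectivity(labels: np.ndarray) -> None:
    from scipy import ndimage

    for sp_id in np.unique(labels):
        region = labels == sp_id
        _, n_comp = ndimage.label(region, structure=np.ones((3, 3), dtype=int))
        if n_comp != 1:
            raise ValueError(f"superpixel {int(sp_id)} is not spatially connected")


@dataclass
class CoarseMapStack:
    """Per-class real-valued score maps, one H×W map per lesion category."""

    v: np.ndarray  # shape (3, H, W)

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=np.float64)
        if self.v.ndim != 3 or self.v.shape[0] != len(LESION_CLASSES):
            raise ValueError(f"expected (3, H, W) stack, got shape {self.v.shape}")
        if not np.all(np.isfinite(self.v)):
            raise ValueError("coarse maps must be finite")


@dataclass
class LesionIndex:
    """Final per-category lesion scores; they sum to 1 after renormalization."""

    index: np.ndarray  # shape (3,)
    predicted_class: str = ""
    empty_lesion: bool = False

    def __post_init__(self) -> None:
        self.index = np.asarray(self.index, dtype=np.float64)
        if self.index.shape != (len(LESION_CLASSES),):
            raise ValueError(f"expected 3 indices, got shape {self.index.shape}")
        if not self.predicted_class:
            self.predicted_class = LESION_CLASSES[int(np.argmax(self.index))]


@dataclass
class Patch:
    """A fixed-size 56×56 RGB patch cut around one superpixel."""

    pixels: np.ndarray
    superpixel_id: int
    label: str | None = None

    SIDE = 56

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.shape != (self.SIDE, self.SIDE, 3):
            raise ValueError(f"patch must be {self.SIDE}×{self.SIDE}×3, got {self.pixels.shape}")
        if self.label is not None and self.label not in FEATURE_CLASSES:
            raise ValueError(f"unknown feature label {self.label!r}")
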