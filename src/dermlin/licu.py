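"""Lesion Index Calculation Unit (LICU).

Refines coarse per-class score maps into a single per-category lesion index:

1. per-pixel normalization of the three coarse maps, ``p_i = (v_i − min_j
   v_j) / Σ_j (v_j − min_j v_j)`` (uniform 1/3 where all maps agree);
2. a distance map over the lesion mask — each lesion pixel's Euclidean
   distance to the nearest non-lesion (or image-edge) pixel, max-normalized
   so the deepest interior pixel has weight 1 — representing pixel
   importance, since the border area often looks skin-like and is less
   informative;
3. the distance-weighted mean of each normalized map over the lesion area,
   renormalized to sum to 1.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .types import LESION_CLASSES, BinaryMask, CoarseMapStack, LesionIndex

__all__ = ["normalize_coarse", "distance_map", "compute_lesion_index"]


def normalize_coarse(stack: CoarseMapStack) -> np.ndarray:
    """Per-pixel normalization of the coarse maps to a probability simplex.

    Returns a ``(3, H, W)`` array with every pixel summing to 1; pixels where
    all three maps are equal fall back to the uniform 1/3.
    """
    v = stack.v if isinstance(stack, CoarseMapStack) else np.asarray(stack, dtype=np.float64)
    if not np.all(np.isfinite(v)):
        raise ValueError("coarse maps must be finite")
    shifted = v - v.min(axis=0, keepdims=True)
    denom = shifted.sum(axis=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(denom > 0, shifted / denom, 1.0 / v.shape[0])
    return p


def distance_map(mask: BinaryMask) -> np.ndarray:
    """Border-distance weights over a lesion mask.

    For each lesion pixel, the Euclidean distance to the nearest non-lesion
    pixel (the image edge counts as non-lesion), divided by the maximum so
    the deepest interior pixel has weight exactly 1. Outside the lesion the
    map is 0; an empty mask yields an all-zero map.
    """
    m = mask.pixels if isinstance(mask, BinaryMask) else np.asarray(mask)
    if m.sum() == 0:
        return np.zeros(m.shape, dtype=np.float64)
    padded = np.pad(m.astype(bool), 1, constant_values=False)
    d = ndimage.distance_transform_edt(padded)[1:-1, 1:-1]
    return d / d.max()


def compute_lesion_index(
    p: np.ndarray, d: np.ndarray, mask: BinaryMask
) -> LesionIndex:
    """Distance-weighted average of normalized maps over the lesion area.

    ``index_i = mean over lesion pixels of p_i · d``, renormalized to sum to
    1. An empty lesion yields the uniform index with ``empty_lesion=True``.
    Ties in the argmax resolve to the lowest class id.
    """
    m = (mask.pixels if isinstance(mask, BinaryMask) else np.asarray(mask)).astype(bool)
    p = np.asarray(p, dtype=np.float64)
    d = np.asarray(d, dtype=np.float64)
    if p.shape[1:] != m.shape or d.shape != m.shape:
        raise ValueError(
            f"shape mismatch: maps {p.shape}, distance {d.shape}, mask {m.shape}"
        )
    n_cls = p.shape[0]
    if not m.any():
        return LesionIndex(index=np.full(n_cls, 1.0 / n_cls),
                           predicted_class=LESION_CLASSES[0], empty_lesion=True)
    raw = (p[:, m] * d[m]).mean(axis=1)
    total = raw.sum()
    index = raw / total if total > 0 else np.full(n_cls, 1.0 / n_cls)
    return LesionIndex(index=index, predicted_class=LESION_CLASSES[int(np.argmax(index))])
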