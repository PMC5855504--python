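"""Synthetic dermoscopy-like fixtures for every stage of the pipeline.

The generator emulates the statistical structure the pipeline assumes —
low-contrast elliptical lesions on skin-toned background, hair strokes and
ruler scale-marks, three lesion classes with distinct color/texture
signatures, and the heavy class imbalance of superpixel feature labels —
without imitating real lesion morphology. Everything is a pure function of
its spec (seed included).

Class signatures (documented, synthetic):

* melanoma — very dark brown, strong interior speckle, irregular border;
* seborrheic keratosis — mid warm brown, coarse bumpy texture, moderately
  irregular border;
* nevus — smooth reddish brown, near-regular elliptical border.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.draw import polygon as _draw_polygon

from .licu import distance_map
from .types import (
    FEATURE_CLASSES, LESION_CLASSES, BinaryMask, CoarseMapStack, LesionImage, SuperpixelMap,
)

__all__ = [
    "SynthSpec",
    "generate_lesion_dataset",
    "generate_feature_dataset",
    "generate_coarse_stacks",
]


@dataclass(frozen=True)
class SynthSpec:
    """Study conditions for the synthetic generators.

    ``contrast`` scales how far lesion colors depart from skin (1 = full
    class palette, small values emulate the low lesion/skin contrast of real
    dermoscopy); ``hair_density`` is the expected number of hair strokes per
    image divided by 3.
    """

    n_per_class: tuple[int, int, int] = (4, 4, 4)
    image_side: int = 96
    contrast: float = 0.6
    hair_density: float = 1.0
    scale_marks: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_side < 64:
            raise ValueError("image_side must be at least 64")
        if not 0.0 < self.contrast <= 1.0:
            raise ValueError("contrast must lie in (0, 1]")
        if self.hair_density < 0:
            raise ValueError("hair_density must be non-negative")


#: (base RGB color, speckle amplitude, speckle grain, border irregularity)
_CLASS_SIGNATURES = {
    "melanoma": (np.array([0.25, 0.15, 0.12]), 0.10, 1.0, 0.16),
    "seborrheic_keratosis": (np.array([0.45, 0.30, 0.20]), 0.07, 2.5, 0.10),
    "nevus": (np.array([0.55, 0.35, 0.28]), 0.02, 1.5, 0.04),
}

_SKIN = np.array([0.80, 0.60, 0.52])


def _blob_mask(side: int, rng: np.random.Generator, irregularity: float) -> np.ndarray:
    """A star-shaped (hence connected) lesion blob mask."""
    cy = side / 2 + rng.uniform(-0.08, 0.08) * side
    cx = side / 2 + rng.uniform(-0.08, 0.08) * side
    r0 = rng.uniform(0.18, 0.28) * side
    theta = np.linspace(0.0, 2 * np.pi, 720, endpoint=False)
    radius = np.ones_like(theta)
    for k in range(2, 7):
        amp = rng.normal(0.0, irregularity / k)
        phase = rng.uniform(0, 2 * np.pi)
        radius += amp * np.cos(k * theta + phase)
    radius = np.clip(radius, 0.4, 1.6) * r0
    rows = cy + radius * np.sin(theta)
    cols = cx + radius * np.cos(theta)
    rr, cc = _draw_polygon(rows, cols, shape=(side, side))
    mask = np.zeros((side, side), dtype=np.uint8)
    mask[rr, cc] = 1
    return mask


def _smooth_noise(shape, rng: np.random.Generator, sigma: float) -> np.ndarray:
    noise = rng.normal(0.0, 1.0, size=shape)
    smoothed = ndimage.gaussian_filter(noise, sigma=sigma)
    sd = smoothed.std()
    return smoothed / sd if sd > 0 else smoothed


def _add_hairs(img: np.ndarray, rng: np.random.Generator, n_hairs: int) -> None:
    side = img.shape[0]
    for _ in range(n_hairs):
        p0 = rng.uniform(0, side, size=2)
        p2 = rng.uniform(0, side, size=2)
        p1 = (p0 + p2) / 2 + rng.uniform(-0.3, 0.3, size=2) * side
        t = np.linspace(0, 1, 4 * side)[:, None]
        pts = (1 - t) ** 2 * p0 + 2 * t * (1 - t) * p1 + t**2 * p2
        rr = np.clip(pts[:, 0].astype(int), 0, side - 1)
        cc = np.clip(pts[:, 1].astype(int), 0, side - 1)
        img[rr, cc] = 0.55 * img[rr, cc] + 0.45 * np.array([0.12, 0.10, 0.09])


def _add_scale_marks(img: np.ndarray, rng: np.random.Generator) -> None:
    side = img.shape[0]
    edge = int(rng.integers(0, 4))
    offset = int(rng.integers(2, 6))
    for pos in range(4, side - 4, max(side // 12, 4)):
        tick = np.arange(offset, offset + max(side // 24, 2))
        if edge == 0:
            img[tick, pos] = 0.15
        elif edge == 1:
            img[side - 1 - tick, pos] = 0.15
        elif edge == 2:
            img[pos, tick] = 0.15
        else:
            img[pos, side - 1 - tick] = 0.15


def generate_lesion_dataset(
    spec: SynthSpec,
) -> list[tuple[LesionImage, BinaryMask, str]]:
    """Generate lesion images with exact masks and class labels.

    Each image holds one star-shaped blob lesion whose color/texture follows
    its class signature, blended toward skin by the contrast setting, plus
    optional hair strokes and ruler marks. Masks are the exact generating
    blobs and are single connected components.
    """
    rng = np.random.default_rng(spec.seed)
    side = spec.image_side
    out: list[tuple[LesionImage, BinaryMask, str]] = []
    counter = 0
    for cls, n in zip(LESION_CLASSES, spec.n_per_class):
        color, speckle_amp, grain, irregularity = _CLASS_SIGNATURES[cls]
        for _ in range(n):
            skin = _SKIN + rng.uniform(-0.04, 0.04, size=3)
            img = np.ones((side, side, 3)) * skin
            img += 0.02 * _smooth_noise((side, side), rng, sigma=side / 12)[..., None]
            mask = _blob_mask(side, rng, irregularity)
            texture = speckle_amp * _smooth_noise((side, side), rng, sigma=grain)
            lesion = np.clip(color + texture[..., None] * np.array([1.0, 0.8, 0.7]), 0, 1)
            alpha = spec.contrast * mask[..., None]
            img = img * (1 - alpha) + lesion * alpha
            n_hairs = int(rng.poisson(3.0 * spec.hair_density))
            if n_hairs:
                _add_hairs(img, rng, n_hairs)
            if spec.scale_marks:
                _add_scale_marks(img, rng)
            img = np.clip(img, 0.0, 1.0)
            image_id = f"synth_{cls}_{counter:04d}"
            out.append((LesionImage(img, image_id), BinaryMask(mask, image_id), cls))
            counter += 1
    return out


#: Default label frequencies for superpixel features, proportional to the
#: original (pre-balancing) patch imbalance: B ≫ PN ≫ MC > NN > S.
DEFAULT_FEATURE_FREQS = {"B": 90.0, "PN": 80.0, "NN": 3.0, "MC": 5.0, "S": 2.0}


def _grid_superpixels(side: int, cell: int) -> SuperpixelMap:
    n_cells = side // cell
    rows = np.minimum(np.arange(side) // cell, n_cells - 1)
    labels = rows[:, None] * n_cells + rows[None, :]
    # relabel to a contiguous range
    _, labels = np.unique(labels, return_inverse=True)
    return SuperpixelMap(labels=labels.reshape(side, side))


def _stamp_feature(img: np.ndarray, region: np.ndarray, label: str) -> None:
    """Stamp a distinctive texture for one feature class into a region."""
    rr, cc = np.nonzero(region)
    if label == "PN":  # reticular dark grid
        on_grid = (rr % 6 < 2) | (cc % 6 < 2)
        img[rr[on_grid], cc[on_grid]] -= 0.30
    elif label == "NN":  # inverted network: darkened field, light grid
        img[rr, cc] -= 0.18
        on_grid = (rr % 6 < 2) | (cc % 6 < 2)
        img[rr[on_grid], cc[on_grid]] += 0.40
    elif label == "MC":  # bright milia-like dots on a darkened field
        img[rr, cc] *= 0.6
        on_dot = (rr % 6 < 3) & (cc % 6 < 3)
        img[rr[on_dot], cc[on_dot]] = 0.95
    elif label == "S":  # parallel dark streaks
        on_streak = (rr + cc) % 7 < 2
        img[rr[on_streak], cc[on_streak]] -= 0.35
    np.clip(img, 0.0, 1.0, out=img)


def generate_feature_dataset(
    spec: SynthSpec,
    freqs: dict[str, float] | None = None,
    cell: int = 12,
) -> tuple[list[LesionImage], list[SuperpixelMap], list[dict[int, str]]]:
    """Generate images with superpixel maps and planted feature labels.

    Superpixels form a regular grid of ``cell``×``cell`` tiles; each is
    labelled by a seeded draw from ``freqs`` (default: the background-heavy
    imbalance above) and non-background tiles get their class texture
    stamped in exactly, so the label CSV matches the stamping.
    """
    if freqs is None:
        freqs = DEFAULT_FEATURE_FREQS
    probs = np.array([freqs.get(c, 0.0) for c in FEATURE_CLASSES], dtype=np.float64)
    probs /= probs.sum()
    rng = np.random.default_rng(spec.seed)
    base = generate_lesion_dataset(spec)
    images, spmaps, label_dicts = [], [], []
    for image, _mask, _cls in base:
        spmap = _grid_superpixels(spec.image_side, cell)
        img = image.pixels.copy()
        labels: dict[int, str] = {}
        drawn = rng.choice(len(FEATURE_CLASSES), size=spmap.n_segments, p=probs)
        for sp_id in range(spmap.n_segments):
            label = FEATURE_CLASSES[int(drawn[sp_id])]
            labels[sp_id] = label
            if label != "B":
                _stamp_feature(img, spmap.labels == sp_id, label)
        images.append(LesionImage(img, image.image_id))
        spmaps.append(spmap)
        label_dicts.append(labels)
    return images, spmaps, label_dicts


def generate_coarse_stacks(
    spec: SynthSpec,
    n_stacks: int | None = None,
    interior_margin: float = 0.3,
    border_band: float = 0.2,
    border_margin: float | None = None,
    noise_sd: float = 0.35,
) -> list[tuple[CoarseMapStack, BinaryMask, str]]:
    """Generate coarse-map stacks in the regime where distance weighting helps.

    The true class's score is raised by ``interior_margin`` on interior
    lesion pixels (normalized border distance ≥ ``border_band``) while a
    decoy class's score is raised by ``border_margin`` on the border band —
    emulating the strong wrong-class response the skin-like border area
    produces. With the default border margin at (7/3)× the interior margin
    and per-pixel noise comparable to the margins, the border band pulls a
    plain unweighted average toward the decoy while the distance-weighted
    average still recovers the true class. With zero margins the classes
    are indistinguishable (pure noise).
    """
    if border_margin is None:
        border_margin = interior_margin * 7.0 / 3.0
    rng = np.random.default_rng(spec.seed)
    if n_stacks is None:
        n_stacks = sum(spec.n_per_class)
    side = spec.image_side
    out: list[tuple[CoarseMapStack, BinaryMask, str]] = []
    for i in range(n_stacks):
        true_idx = i % len(LESION_CLASSES)
        decoy_idx = (true_idx + 1 + int(rng.integers(0, len(LESION_CLASSES) - 1))) % len(
            LESION_CLASSES
        )
        mask = _blob_mask(side, rng, irregularity=0.10)
        d = distance_map(BinaryMask(mask))
        interior = d >= border_band
        band = (mask > 0) & ~interior
        v = rng.normal(0.0, noise_sd, size=(len(LESION_CLASSES), side, side))
        v[true_idx][interior] += interior_margin
        v[decoy_idx][band] += border_margin
        out.append(
            (CoarseMapStack(v), BinaryMask(mask, f"stack_{i:04d}"), LESION_CLASSES[true_idx])
        )
    return out
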