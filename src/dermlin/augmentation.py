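"""Class-balanced rotation / mirror augmentation and patch-level balancing.

Lesion-level: each class gets a rotation step chosen so that all classes end
up with comparable counts (melanoma and seborrheic keratosis every 18°, the
much larger nevus class every 45°); the rotated dataset ``DR`` is then
randomly mirrored image-by-image to give its paired dataset ``DM``, and the
two train separate networks. Patch-level: over-represented feature classes
are randomly down-sampled to a cap, under-represented ones gain 90/180/270°
rotated copies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import rotate as _sk_rotate

from .types import BinaryMask, LesionImage, Patch

__all__ = [
    "ClassAngleSpec",
    "PatchAugmentSpec",
    "rotate_image",
    "build_rotation_set",
    "build_mirror_set",
    "augment_patches",
]

#: A training sample: an image, optionally paired with its mask.
Sample = LesionImage | tuple[LesionImage, BinaryMask]


@dataclass(frozen=True)
class ClassAngleSpec:
    """Rotation step for one lesion class; must divide 360 evenly."""

    class_name: str
    step_degrees: float

    def __post_init__(self) -> None:
        if self.step_degrees <= 0 or (360.0 / self.step_degrees) % 1 != 0:
            raise ValueError(
                f"rotation step {self.step_degrees}° must divide 360 evenly"
            )


@dataclass(frozen=True)
class PatchAugmentSpec:
    """Per-class patch balancing: optional down-sample cap and/or rotations."""

    sample_cap: int | None = None
    rotation_angles: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.sample_cap is not None and self.sample_cap <= 0:
            raise ValueError("sample cap must be positive")
        if not set(self.rotation_angles) <= {90, 180, 270}:
            raise ValueError("rotation angles must be a subset of {90, 180, 270}")


def _rotate_array(arr: np.ndarray, angle: float, order: int) -> np.ndarray:
    """Rotate keeping shape; right angles are exact index permutations."""
    if angle % 90 == 0:
        return np.ascontiguousarray(np.rot90(arr, k=int(angle // 90) % 4))
    out = _sk_rotate(
        arr.astype(np.float64), angle, resize=False, order=order,
        mode="reflect", preserve_range=True,
    )
    if order == 0:
        return np.rint(out).astype(arr.dtype)
    return np.clip(out, 0.0, 1.0)


def rotate_image(image: LesionImage, angle: float) -> LesionImage:
    """Rotate counter-clockwise, preserving size; corners fill by reflection."""
    return LesionImage(pixels=_rotate_array(image.pixels, angle, order=1),
                       image_id=f"{image.image_id}_rot{int(angle)}")


def _rotate_sample(sample: Sample, angle: float) -> Sample:
    if isinstance(sample, LesionImage):
        return rotate_image(sample, angle)
    image, mask = sample
    return (
        rotate_image(image, angle),
        BinaryMask(pixels=_rotate_array(mask.pixels, angle, order=0),
                   image_id=f"{mask.image_id}_rot{int(angle)}"),
    )


def build_rotation_set(
    images_by_class: dict[str, list[Sample]],
    specs: dict[str, ClassAngleSpec] | list[ClassAngleSpec],
) -> dict[str, list[Sample]]:
    """Build the rotation-balanced dataset DR.

    Per class, every source sample yields exactly ``360/step`` rotated copies
    (the 0° original counts as one of them), so a class of ``n`` images with
    step ``s`` contributes ``n*360/s`` samples.
    """
    if isinstance(specs, list):
        specs = {s.class_name: s for s in specs}
    missing = set(images_by_class) - set(specs)
    if missing:
        raise ValueError(f"no rotation spec for classes: {sorted(missing)}")
    out: dict[str, list[Sample]] = {}
    for cls, samples in images_by_class.items():
        step = specs[cls].step_degrees
        n_rot = int(round(360.0 / step))
        rotated: list[Sample] = []
        for sample in samples:
            for k in range(n_rot):
                rotated.append(_rotate_sample(sample, k * step) if k else sample)
        out[cls] = rotated
    return out


def _flip_sample(sample: Sample, axis: int) -> Sample:
    def flip_img(img: LesionImage) -> LesionImage:
        return LesionImage(pixels=np.ascontiguousarray(np.flip(img.pixels, axis=axis)),
                           image_id=f"{img.image_id}_flip{axis}")

    if isinstance(sample, LesionImage):
        return flip_img(sample)
    image, mask = sample
    return (flip_img(image),
            BinaryMask(pixels=np.ascontiguousarray(np.flip(mask.pixels, axis=axis)),
                       image_id=f"{mask.image_id}_flip{axis}"))


def build_mirror_set(
    dr: dict[str, list[Sample]], seed: int
) -> dict[str, list[Sample]]:
    """Mirror every DR sample along a seeded coin-flip axis (row or column).

    |DM| = |DR| class-by-class and element i of DM is the flip of element i
    of DR, so the pairing index is retained.
    """
    if not any(dr.values()):
        raise ValueError("DR must be non-empty")
    rng = np.random.default_rng(seed)
    out: dict[str, list[Sample]] = {}
    for cls in dr:
        axes = rng.integers(0, 2, size=len(dr[cls]))
        out[cls] = [_flip_sample(s, int(a)) for s, a in zip(dr[cls], axes)]
    return out


def _rotate_patch(patch: Patch, angle: int) -> Patch:
    return Patch(pixels=np.ascontiguousarray(np.rot90(patch.pixels, k=angle // 90)),
                 superpixel_id=patch.superpixel_id, label=patch.label)


def augment_patches(
    patches_by_class: dict[str, list[Patch]],
    specs: dict[str, PatchAugmentSpec],
    seed: int,
) -> dict[str, list[Patch]]:
    """Balance the patch dataset by random down-sampling and right-angle rotation.

    Classes with a ``sample_cap`` are down-sampled uniformly without
    replacement to exactly the cap; classes with rotation angles gain one
    rotated copy per angle per patch (count multiplied by 1+len(angles)).
    """
    missing = set(patches_by_class) - set(specs)
    if missing:
        raise ValueError(f"no augmentation spec for classes: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    out: dict[str, list[Patch]] = {}
    for cls, patches in patches_by_class.items():
        spec = specs[cls]
        selected = list(patches)
        if spec.sample_cap is not None:
            if spec.sample_cap > len(selected):
                raise ValueError(
                    f"sample cap {spec.sample_cap} exceeds class size "
                    f"{len(selected)} for {cls!r}"
                )
            keep = rng.choice(len(selected), size=spec.sample_cap, replace=False)
            selected = [selected[i] for i in sorted(keep)]
        augmented = list(selected)
        for angle in spec.rotation_angles:
            augmented.extend(_rotate_patch(p, angle) for p in selected)
        out[cls] = augmented
    return out


#: Rotation steps matching the class-balancing scheme for the three lesion
#: categories (degrees).
DEFAULT_LESION_SPECS = {
    "melanoma": ClassAngleSpec("melanoma", 18.0),
    "seborrheic_keratosis": ClassAngleSpec("seborrheic_keratosis", 18.0),
    "nevus": ClassAngleSpec("nevus", 45.0),
}
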