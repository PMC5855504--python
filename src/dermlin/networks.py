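"""Builders for the segmentation network family and the Lesion Feature Network.

Two architectures live here:

* A fully-convolutional residual encoder–decoder ("FCRN") producing per-pixel
  class scores at input resolution. The residual block family covers plain
  identity-shortcut blocks, bottlenecks, and Residual-in-Residual (RiR)
  blocks whose residual branch itself stacks residual units. A ``tiny``
  preset (≤12 weighted layers) is the desk-scale workhorse; ``full``
  approximates the ~88-weighted-layer RiR configuration.
* The Lesion Feature Network ("LFN"): 12 convolutional trunk layers in 4
  stages of (3×3, 1×1, 3×3) convolutions, batch-normalized before each
  rectifier, max pooling after stages 1–3, global average pooling after
  stage 4, and a single fully connected layer to 5 feature classes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .nn.layers import (
    BatchNorm2d, Conv2d, GlobalAvgPool, Linear, MaxPool2d, Module,
    NearestUpsample, Param, ReLU, Residual, Sequential,
)

__all__ = [
    "StageSpec", "FcrnConfig", "LFN_PRESETS", "build_lfn", "build_fcrn",
    "plain_block", "bottleneck_block", "rir_block", "conv_layer_count",
    "save_checkpoint", "load_checkpoint",
]


@dataclass(frozen=True)
class StageSpec:
    """One LFN stage: a tuple of (n_kernels, kernel_size) convolutions."""

    convs: tuple[tuple[int, int], ...]


#: Channel widths per stage for the three LFN variants.
LFN_PRESETS: dict[str, tuple[int, int, int, int]] = {
    "lfn": (16, 32, 64, 128),
    "narrow": (16, 16, 16, 32),
    "wide": (32, 64, 64, 128),
}


def lfn_stage_specs(preset: str) -> list[StageSpec]:
    widths = LFN_PRESETS[preset]
    return [StageSpec(convs=((w, 3), (w, 1), (w, 3))) for w in widths]


class LFN(Module):
    """Superpixel-patch classifier: 56×56×3 → 5 class scores."""

    N_CLASSES = 5
    INPUT_SIDE = 56

    def __init__(self, preset: str, rng: np.random.Generator):
        if preset not in LFN_PRESETS:
            raise ValueError(f"unknown LFN preset {preset!r}; choose from {sorted(LFN_PRESETS)}")
        self.preset = preset
        widths = LFN_PRESETS[preset]
        layers: list[Module] = []
        in_ch = 3
        for stage_idx, w in enumerate(widths):
            for kernel in (3, 1, 3):
                layers += [Conv2d(in_ch, w, kernel, rng), BatchNorm2d(w), ReLU()]
                in_ch = w
            if stage_idx < 3:
                layers.append(MaxPool2d())
        self.trunk = Sequential(layers)
        self.pool = GlobalAvgPool()
        self.fc = Linear(widths[-1], self.N_CLASSES, rng)

    def children(self) -> list[Module]:
        return [self.trunk, self.pool, self.fc]

    def params(self) -> list[Param]:
        return self.trunk.params() + self.fc.params()

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[1:] != (3, self.INPUT_SIDE, self.INPUT_SIDE):
            raise ValueError(f"LFN expects N×3×56×56 input, got {x.shape}")
        return self.fc(self.pool(self.trunk(x)))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return self.trunk.backward(self.pool.backward(self.fc.backward(dout)))


def build_lfn(preset: str = "lfn", seed: int = 0) -> LFN:
    """Build a Lesion Feature Network variant (``lfn``, ``narrow`` or ``wide``)."""
    return LFN(preset, np.random.default_rng(seed))


def plain_block(channels: int, rng: np.random.Generator) -> Residual:
    """Identity-shortcut block: x + Conv(ReLU(BN(Conv(ReLU(BN(x))))))."""
    return Residual(Sequential([
        BatchNorm2d(channels), ReLU(), Conv2d(channels, channels, 3, rng),
        BatchNorm2d(channels), ReLU(), Conv2d(channels, channels, 3, rng),
    ]))


def bottleneck_block(channels: int, rng: np.random.Generator) -> Residual:
    """Bottleneck block: 1×1 reduce, 3×3, 1×1 restore, pre-activation order."""
    mid = max(channels // 2, 1)
    return Residual(Sequential([
        BatchNorm2d(channels), ReLU(), Conv2d(channels, mid, 1, rng),
        BatchNorm2d(mid), ReLU(), Conv2d(mid, mid, 3, rng),
        BatchNorm2d(mid), ReLU(), Conv2d(mid, channels, 1, rng),
    ]))


def rir_block(channels: int, rng: np.random.Generator) -> Residual:
    """Residual-in-Residual: an outer identity shortcut wrapping inner
    bottleneck residual units plus a transition convolution.

    The branch ends in a convolution, so with all weights zero the whole
    block is exactly the identity map.
    """
    return Residual(Sequential([
        bottleneck_block(channels, rng),
        bottleneck_block(channels, rng),
        BatchNorm2d(channels), ReLU(), Conv2d(channels, channels, 3, rng),
    ]))


_BLOCK_BUILDERS = {"plain": plain_block, "bottleneck": bottleneck_block, "rir": rir_block}


@dataclass(frozen=True)
class FcrnConfig:
    """Configuration of the fully-convolutional residual segmenter.

    ``n_classes`` counts background plus lesion categories (4 by default:
    background + melanoma + seborrheic keratosis + nevus, so one network
    yields segmentation and coarse classification simultaneously).
    """

    n_classes: int = 4
    block_type: str = "plain"
    depth_preset: str = "tiny"
    base_channels: int = 8

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be at least 2")
        if self.block_type not in _BLOCK_BUILDERS:
            raise ValueError(f"unknown block type {self.block_type!r}")
        if self.depth_preset not in ("tiny", "full"):
            raise ValueError(f"unknown depth preset {self.depth_preset!r}")


#: (number of stride-2 stages, residual blocks per stage) per depth preset.
_DEPTHS = {"tiny": (2, 1), "full": (3, 4)}


class FCRN(Module):
    """Encoder–decoder with residual blocks; per-pixel class scores.

    Accepts any input at least ``min_input`` on a side; internally the input
    is edge-padded to a multiple of the total stride and the score maps are
    cropped back, so the output spatial shape always equals the input's.
    """

    def __init__(self, config: FcrnConfig, rng: np.random.Generator):
        self.config = config
        n_down, blocks_per_stage = _DEPTHS[config.depth_preset]
        self.n_down = n_down
        self.min_input = 16 if config.depth_preset == "tiny" else 64
        block = _BLOCK_BUILDERS[config.block_type]
        c = config.base_channels

        enc: list[Module] = [Conv2d(3, c, 3, rng), BatchNorm2d(c), ReLU()]
        widths = [c]
        for _ in range(n_down):
            c2 = c * 2
            enc += [Conv2d(c, c2, 3, rng, stride=2), BatchNorm2d(c2), ReLU()]
            enc += [block(c2, rng) for _ in range(blocks_per_stage)]
            c = c2
            widths.append(c)
        dec: list[Module] = []
        for w_out in reversed(widths[:-1]):
            dec += [NearestUpsample(2), Conv2d(c, w_out, 3, rng), BatchNorm2d(w_out), ReLU()]
            c = w_out
        head = Conv2d(c, config.n_classes, 1, rng)
        self.body = Sequential(enc + dec + [head])
        self._pad: tuple[int, int] = (0, 0)
        self._in_shape: tuple[int, ...] = ()

    def children(self) -> list[Module]:
        return [self.body]

    def params(self) -> list[Param]:
        return self.body.params()

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, ch, h, w = x.shape
        if ch != 3:
            raise ValueError(f"expected 3 input channels, got {ch}")
        if h < self.min_input or w < self.min_input:
            raise ValueError(
                f"input {h}×{w} below the model's minimum {self.min_input}×{self.min_input}"
            )
        m = 2 ** self.n_down
        ph, pw = (-h) % m, (-w) % m
        self._pad = (ph, pw)
        self._in_shape = x.shape
        if ph or pw:
            x = np.pad(x, ((0, 0), (0, 0), (0, ph), (0, pw)), mode="edge")
        out = self.body(x)
        return out[:, :, :h, :w]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        ph, pw = self._pad
        if ph or pw:
            dout = np.pad(dout, ((0, 0), (0, 0), (0, ph), (0, pw)))
        dx = self.body.backward(dout)
        n, c, h, w = self._in_shape
        # gradient contributions that fell on the edge padding are dropped
        return dx[:, :, :h, :w]


def build_fcrn(config: FcrnConfig | None = None, seed: int = 0) -> FCRN:
    """Build a fully-convolutional residual segmentation network."""
    if config is None:
        config = FcrnConfig()
    return FCRN(config, np.random.default_rng(seed))


def _walk(module: Module):
    yield module
    for child in module.children():
        yield from _walk(child)


def conv_layer_count(module: Module, trunk_only: bool = False) -> int:
    """Number of convolutional layers in a model (LFN ``trunk_only`` excludes
    nothing — the trunk is where all its convolutions live)."""
    root = module.trunk if trunk_only and isinstance(module, LFN) else module
    return sum(1 for m in _walk(root) if isinstance(m, Conv2d))


def weighted_layer_count(module: Module) -> int:
    """Convolutional plus fully connected layer count."""
    return sum(1 for m in _walk(module) if isinstance(m, (Conv2d, Linear)))


def save_checkpoint(model: Module, path: str | Path, meta: dict | None = None) -> None:
    """Serialize parameters and batch-norm running statistics to ``.npz``."""
    state: dict[str, np.ndarray] = {}
    for i, p in enumerate(model.params()):
        state[f"param_{i}"] = p.value
    for i, bn in enumerate(m for m in _walk(model) if isinstance(m, BatchNorm2d)):
        state[f"bn_{i}_mean"] = bn.running_mean
        state[f"bn_{i}_var"] = bn.running_var
    if meta:
        state["_meta"] = np.frombuffer(repr(meta).encode(), dtype=np.uint8)
    np.savez(path, **state)


def load_checkpoint(model: Module, path: str | Path) -> None:
    """Load a checkpoint written by :func:`save_checkpoint` into ``model``."""
    with np.load(path) as data:
        for i, p in enumerate(model.params()):
            value = data[f"param_{i}"]
            if value.shape != p.value.shape:
                raise ValueError(
                    f"checkpoint parameter {i} has shape {value.shape}, "
                    f"model expects {p.value.shape}"
                )
            p.value = value.astype(np.float64)
        for i, bn in enumerate(m for m in _walk(model) if isinstance(m, BatchNorm2d)):
            bn.running_mean = data[f"bn_{i}_mean"].astype(np.float64)
            bn.running_var = data[f"bn_{i}_var"].astype(np.float64)
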