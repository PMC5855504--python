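"""Layer primitives with explicit forward/backward passes (NCHW, float64)."""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param", "Module", "Sequential", "Conv2d", "BatchNorm2d", "ReLU",
    "MaxPool2d", "NearestUpsample", "GlobalAvgPool", "Linear", "Residual",
]


class Param:
    """A trainable tensor and its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)


class Module:
    """Base class: forward caches whatever backward needs."""

    training: bool = True

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def set_training(self, mode: bool) -> None:
        self.training = mode
        for child in self.children():
            child.set_training(mode)

    def children(self) -> list["Module"]:
        return []

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)

    def n_params(self) -> int:
        return sum(p.value.size for p in self.params())


class Sequential(Module):
    def __init__(self, layers: list[Module]):
        self.layers = list(layers)

    def children(self) -> list[Module]:
        return self.layers

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout


class Conv2d(Module):
    """2-D convolution via im2col; 'same' padding unless overridden."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, zero_init: bool = False):
        self.in_ch, self.out_ch, self.k, self.stride = in_ch, out_ch, kernel, stride
        self.pad = kernel // 2
        fan_in = in_ch * kernel * kernel
        if zero_init:
            w = np.zeros((out_ch, fan_in))
        else:
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, fan_in))
        self.w = Param(w)          # (out_ch, in_ch*k*k)
        self.b = Param(np.zeros(out_ch))
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        k, s, p = self.k, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        ho, wo = win.shape[2], win.shape[3]
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)
        out = cols @ self.w.value.T + self.b.value
        self._cache = (cols, x.shape, ho, wo)
        return out.reshape(n, ho, wo, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, x_shape, ho, wo = self._cache
        n, c, h, w = x_shape
        k, s, p = self.k, self.stride, self.pad
        dmat = dout.transpose(0, 2, 3, 1).reshape(n * ho * wo, self.out_ch)
        self.w.grad += dmat.T @ cols
        self.b.grad += dmat.sum(axis=0)
        dcols = (dmat @ self.w.value).reshape(n, ho, wo, c, k, k).transpose(0, 3, 4, 5, 1, 2)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p))
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + s * ho : s, j : j + s * wo : s] += dcols[:, :, i, j]
        return dxp[:, :, p : p + h, p : p + w] if p else dxp


class BatchNorm2d(Module):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, n_ch: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = Param(np.ones(n_ch))
        self.beta = Param(np.zeros(n_ch))
        self.eps, self.momentum = eps, momentum
        self.running_mean = np.zeros(n_ch)
        self.running_var = np.ones(n_ch)
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        self._cache = (xhat, inv_std, x.shape)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv_std, x_shape = self._cache
        n, c, h, w = x_shape
        m = n * h * w
        self.gamma.grad += (dout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.gamma.value[None, :, None, None]
        if not self.training:
            return dxhat * inv_std[None, :, None, None]
        sum_dxhat = dxhat.sum(axis=(0, 2, 3))[None, :, None, None]
        sum_dxhat_xhat = (dxhat * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
        return (inv_std[None, :, None, None] / m) * (m * dxhat - sum_dxhat - xhat * sum_dxhat_xhat)


class ReLU(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool2d(Module):
    """2×2 max pooling, stride 2; inputs must have even spatial dims."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"MaxPool2d needs even spatial dims, got {h}×{w}")
        win = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = win.reshape(n, c, h // 2, w // 2, 4)
        self._argmax = flat.argmax(axis=-1)
        self._in_shape = x.shape
        return flat.max(axis=-1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._in_shape
        dflat = np.zeros((n, c, h // 2, w // 2, 4))
        np.put_along_axis(dflat, self._argmax[..., None], dout[..., None], axis=-1)
        win = dflat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return win.reshape(n, c, h, w)


class NearestUpsample(Module):
    """Integer-factor nearest-neighbour upsampling."""

    def __init__(self, factor: int = 2):
        self.factor = factor

    def forward(self, x: np.ndarray) -> np.ndarray:
        f = self.factor
        return x.repeat(f, axis=2).repeat(f, axis=3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = dout.shape
        f = self.factor
        return dout.reshape(n, c, h // f, f, w // f, f).sum(axis=(3, 5))


class GlobalAvgPool(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._in_shape
        return np.broadcast_to(dout[:, :, None, None] / (h * w), self._in_shape).copy()


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        self.w = Param(rng.normal(0.0, np.sqrt(2.0 / in_features),
                                  size=(out_features, in_features)))
        self.b = Param(np.zeros(out_features))

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w.value.T + self.b.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.w.grad += dout.T @ self._x
        self.b.grad += dout.sum(axis=0)
        return dout @ self.w.value


class Residual(Module):
    """Identity-shortcut residual wrapper: y = x + branch(x).

    With the branch ending in a convolution, zeroing all branch weights
    makes the block an exact identity map.
    """

    def __init__(self, branch: Module):
        self.branch = branch

    def children(self) -> list[Module]:
        return [self.branch]

    def params(self) -> list[Param]:
        return self.branch.params()

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x + self.branch.forward(x)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout + self.branch.backward(dout)
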