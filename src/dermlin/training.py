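"""Softmax losses (plain, class-weighted, per-pixel) and the SGD training loop.

The patch classifier is trained with a class-weighted softmax loss — each
sample's cross-entropy term is multiplied by the weight of its true class,
paying more attention to rare dermoscopic features. The canonical weights
for the five patch classes (B, PN, NN, MC, S) are (1, 1, 5, 3, 8). The
segmentation network trains with a per-pixel softmax loss over 4 classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn.layers import Module
from .nn.optim import SGD

__all__ = [
    "ClassWeights", "TrainConfig", "LFN_CLASS_WEIGHTS",
    "softmax_loss", "weighted_softmax_loss", "per_pixel_loss", "train",
]


@dataclass(frozen=True)
class ClassWeights:
    """One positive weight per class."""

    w: tuple[float, ...]

    def __post_init__(self) -> None:
        if any(x <= 0 for x in self.w):
            raise ValueError("all class weights must be positive")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.w, dtype=np.float64)


#: Patch-class weights for (B, PN, NN, MC, S).
LFN_CLASS_WEIGHTS = ClassWeights((1.0, 1.0, 5.0, 3.0, 8.0))


@dataclass
class TrainConfig:
    lr: float = 0.01
    momentum: float = 0.9
    lr_decay_gamma: float = 0.1
    lr_step_epochs: int = 5
    batch_size: int = 128
    max_epochs: int = 10
    seed: int = 0
    class_weights: ClassWeights | None = None

    def __post_init__(self) -> None:
        if self.lr < 0:
            raise ValueError("learning rate must be non-negative")
        if not 0.0 <= self.momentum < 1.0:
            raise ValueError("momentum must lie in [0, 1)")
        if self.batch_size < 1:
            raise ValueError("batch size must be at least 1")


def _stable_log_softmax(f: np.ndarray) -> np.ndarray:
    shifted = f - f.max(axis=1, keepdims=True)
    return shifted - np.log(np.exp(shifted).sum(axis=1, keepdims=True))


def _check_scores(f: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    f = np.asarray(f, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    if f.ndim != 2:
        raise ValueError(f"scores must be N×K, got shape {f.shape}")
    if f.shape[1] < 2:
        raise ValueError("need at least 2 classes")
    if y.shape != (f.shape[0],):
        raise ValueError("labels must be one integer per row of scores")
    if y.min() < 0 or y.max() >= f.shape[1]:
        raise ValueError("labels out of range")
    return f, y


def softmax_loss(f: np.ndarray, y: np.ndarray) -> float:
    """Mean cross-entropy, computed with max-subtraction stabilization."""
    f, y = _check_scores(f, y)
    log_p = _stable_log_softmax(f)
    return float(-log_p[np.arange(len(y)), y].mean())


def weighted_softmax_loss(f: np.ndarray, y: np.ndarray, weights: ClassWeights) -> float:
    """Cross-entropy with each sample's term scaled by its class weight.

    Reduces exactly to :func:`softmax_loss` at unit weights; linear in the
    weight vector for fixed scores and labels.
    """
    f, y = _check_scores(f, y)
    w = weights.as_array()
    if w.shape != (f.shape[1],):
        raise ValueError(f"need one weight per class, got {w.shape} for K={f.shape[1]}")
    log_p = _stable_log_softmax(f)
    return float((-w[y] * log_p[np.arange(len(y)), y]).mean())


def per_pixel_loss(score_maps: np.ndarray, label_map: np.ndarray) -> float:
    """Mean per-pixel softmax loss over dense score maps.

    Accepts ``(K, H, W)`` with ``(H, W)`` labels, or batched ``(N, K, H, W)``
    with ``(N, H, W)`` labels; equals :func:`softmax_loss` on the flattened
    pixel list.
    """
    score_maps = np.asarray(score_maps, dtype=np.float64)
    label_map = np.asarray(label_map)
    if score_maps.ndim == 3:
        score_maps = score_maps[None]
        label_map = label_map[None]
    if score_maps.ndim != 4 or label_map.shape != (
        score_maps.shape[0], score_maps.shape[2], score_maps.shape[3]
    ):
        raise ValueError(
            f"score maps {score_maps.shape} and labels {label_map.shape} do not match"
        )
    k = score_maps.shape[1]
    flat_f = score_maps.transpose(0, 2, 3, 1).reshape(-1, k)
    return softmax_loss(flat_f, label_map.reshape(-1))


def _loss_and_grad(
    f: np.ndarray, y: np.ndarray, weights: np.ndarray | None
) -> tuple[float, np.ndarray]:
    n, k = f.shape
    log_p = _stable_log_softmax(f)
    p = np.exp(log_p)
    rows = np.arange(n)
    w = np.ones(n) if weights is None else weights[y]
    loss = float((-w * log_p[rows, y]).mean())
    grad = p * w[:, None]
    grad[rows, y] -= w
    return loss, grad / n


def _batch_loss_grad(scores, y_batch, weights):
    """Dispatch dense (per-pixel) vs. flat (per-sample) labels."""
    if y_batch.ndim == 3:  # (N, H, W) label maps against (N, K, H, W) scores
        n, k, h, w = scores.shape
        flat = scores.transpose(0, 2, 3, 1).reshape(-1, k)
        loss, g = _loss_and_grad(flat, y_batch.reshape(-1), weights)
        return loss, g.reshape(n, h, w, k).transpose(0, 3, 1, 2)
    return _loss_and_grad(scores, y_batch, weights)


def train(
    model: Module,
    dataset: list[tuple[np.ndarray, np.ndarray | int]],
    config: TrainConfig,
    validation: list[tuple[np.ndarray, np.ndarray | int]] | None = None,
) -> tuple[Module, dict[str, list[float]]]:
    """Train a model with SGD + momentum and a step learning-rate schedule.

    ``dataset`` is a list of ``(input, target)`` pairs with inputs in CHW
    layout; targets are class integers (classifier) or ``(H, W)`` label maps
    (dense segmentation). If no explicit validation set is given, 20% of the
    data is held out by a seeded shuffle. Returns the model and a history
    with per-epoch training and validation losses.
    """
    if not dataset:
        raise ValueError("dataset must be non-empty")
    rng = np.random.default_rng(config.seed)
    if validation is None:
        order = rng.permutation(len(dataset))
        n_train = max(1, int(round(0.8 * len(dataset))))
        train_set = [dataset[i] for i in order[:n_train]]
        validation = [dataset[i] for i in order[n_train:]]
    else:
        train_set = list(dataset)

    weights = config.class_weights.as_array() if config.class_weights else None
    optimizer = SGD(model.params(), lr=config.lr, momentum=config.momentum)
    history: dict[str, list[float]] = {"train_loss": [], "val_loss": [], "lr": []}

    for epoch in range(config.max_epochs):
        lr = config.lr * config.lr_decay_gamma ** (epoch // config.lr_step_epochs)
        optimizer.lr = lr
        model.set_training(True)
        order = rng.permutation(len(train_set))
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            xs = np.stack([np.asarray(train_set[i][0], dtype=np.float64) for i in idx])
            ys = np.stack([np.asarray(train_set[i][1]) for i in idx])
            optimizer.zero_grad()
            scores = model.forward(xs)
            loss, grad = _batch_loss_grad(scores, ys, weights)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: loss={loss!r} "
                    f"(lr={lr}, batch of {len(idx)})"
                )
            model.backward(grad)
            optimizer.step()
            epoch_loss += loss
            n_batches += 1
        history["train_loss"].append(epoch_loss / max(n_batches, 1))
        history["lr"].append(lr)
        history["val_loss"].append(evaluate_loss(model, validation, weights))
    model.set_training(False)
    return model, history


def evaluate_loss(
    model: Module,
    dataset: list[tuple[np.ndarray, np.ndarray | int]],
    weights: np.ndarray | None = None,
    batch_size: int = 32,
) -> float:
    """Mean loss over a dataset in evaluation mode (running BN statistics)."""
    if not dataset:
        return float("nan")
    model.set_training(False)
    total, count = 0.0, 0
    for start in range(0, len(dataset), batch_size):
        chunk = dataset[start : start + batch_size]
        xs = np.stack([np.asarray(x, dtype=np.float64) for x, _ in chunk])
        ys = np.stack([np.asarray(y) for _, y in chunk])
        loss, _ = _batch_loss_grad(model.forward(xs), ys, weights)
        total += loss * len(chunk)
        count += len(chunk)
    return total / count
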