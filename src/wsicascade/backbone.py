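"""Pluggable binary tile classifier: contract, training loop, surrogate CNN.

The pipeline is backbone-agnostic: any object satisfying the
:class:`TileClassifier` contract (a calibrated two-class probability per
299x299 RGB tile plus named internal activation layers for explainability)
can drive the cascade.  The original study fine-tuned InceptionResNet-V2;
its hyperparameters are recorded in :data:`REFERENCE_CONFIGS` as a
reference configuration.  The shipped implementation is
:class:`SmallConvNet`, a compact convolutional network written on numpy
(im2col convolutions, manual backpropagation) that trains on one CPU in
seconds-to-minutes — small enough for desk-scale experiments yet exposing
the same surface (probabilities, frozen layers, spatial ReLU activations
and their gradients) as a full-size backbone.

Architecture of SmallConvNet:

    input 299x299x3 uint8 -> [0,1] floats
    fixed 13x13 average pool (stride 13)      -> 23x23x3
    n conv blocks: 3x3 same conv + ReLU       -> 23x23xC_i   (named relu_i)
    global average pool -> dense -> softmax over the class pair

Training uses SGD with momentum on binary cross-entropy; the first
``frozen_layers`` conv blocks receive no updates (the classification head
always trains).
"""

from __future__ import annotations

import abc
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .errors import ValidationError
from .preprocess import AugmentationConfig, apply_augmentation, sample_augmentation
from .tiles import TILE_SIZE, TileRecord

#: canonical class-name pairs for the two cascade stages
TUMOR_CLASSES = ("healthy", "cancerous")
EGFR_CLASSES = ("WT", "EGFR")


class TileClassifier(abc.ABC):
    """Binary tile classifier contract.

    ``class_names`` fixes the probability column order; inference must be
    deterministic for fixed weights and input.
    """

    class_names: tuple[str, str]

    @abc.abstractmethod
    def predict_proba(self, tiles: Sequence[TileRecord] | np.ndarray) -> np.ndarray:
        """(N, 2) probabilities, rows summing to 1, columns per class_names."""

    @property
    def activation_layer_names(self) -> list[str]:
        """Named spatial activation layers, shallowest first (may be empty)."""
        return []


@dataclass(frozen=True)
class TrainingConfig:
    """Optimization settings for fitting a tile classifier."""

    learning_rate: float = 0.001
    momentum: float = 0.9
    batch_size: int = 32
    max_epochs: int = 50
    patience: int = 5
    frozen_layers: int = 0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be > 0")
        if self.batch_size < 1:
            raise ValidationError("batch_size must be >= 1")
        if self.frozen_layers < 0:
            raise ValidationError("frozen_layers must be >= 0")


#: Hyperparameters of the original full-size backbones (InceptionResNet-V2),
#: recorded as reference metadata; the frozen-layer counts refer to that
#: architecture's native layer enumeration and are not applicable to the
#: surrogate CNN.
REFERENCE_CONFIGS: dict[str, TrainingConfig] = {
    "tumor": TrainingConfig(learning_rate=0.001, momentum=0.9, batch_size=128, frozen_layers=471),
    "egfr": TrainingConfig(learning_rate=0.001, momentum=0.9, batch_size=64, frozen_layers=1),
}


def _tiles_to_array(tiles: Sequence[TileRecord] | np.ndarray) -> np.ndarray:
    if isinstance(tiles, np.ndarray):
        arr = tiles
    else:
        arr = np.stack([t.pixels for t in tiles]) if len(tiles) else np.empty((0, TILE_SIZE, TILE_SIZE, 3), np.uint8)
    if arr.ndim != 4 or arr.shape[3] != 3:
        raise ValidationError("expected (N, S, S, 3) tile batch")
    return arr.astype(np.float64) / 255.0


def _im2col3(x: np.ndarray) -> np.ndarray:
    """3x3 same-padding patch matrix: (B,H,W,C) -> (B,H,W,9C)."""
    b, h, w, c = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    cols = np.empty((b, h, w, 9 * c), dtype=x.dtype)
    k = 0
    for di in range(3):
        for dj in range(3):
            cols[..., k * c : (k + 1) * c] = xp[:, di : di + h, dj : dj + w, :]
            k += 1
    return cols


def _col2im3(dcols: np.ndarray, c: int) -> np.ndarray:
    """Adjoint of :func:`_im2col3`."""
    b, h, w, _ = dcols.shape
    dxp = np.zeros((b, h + 2, w + 2, c), dtype=dcols.dtype)
    k = 0
    for di in range(3):
        for dj in range(3):
            dxp[:, di : di + h, dj : dj + w, :] += dcols[..., k * c : (k + 1) * c]
            k += 1
    return dxp[:, 1 : h + 1, 1 : w + 1, :]


class SmallConvNet(TileClassifier):
    """Compact numpy CNN implementing the TileClassifier contract."""

    def __init__(
        self,
        class_names: tuple[str, str],
        channels: Sequence[int] = (8, 16),
        input_size: int = TILE_SIZE,
        pool: int | None = None,
        seed: int = 0,
    ) -> None:
        if pool is None:
            # divisor of input_size whose working grid is closest to 23x23
            divisors = [d for d in range(1, input_size + 1) if input_size % d == 0 and input_size // d >= 4]
            pool = min(divisors, key=lambda d: abs(input_size / d - 23))
        if input_size % pool != 0:
            raise ValidationError(f"input_size {input_size} not divisible by pool {pool}")
        self.class_names = tuple(class_names)
        self.channels = tuple(int(c) for c in channels)
        self.input_size = int(input_size)
        self.pool = int(pool)
        self.spatial = input_size // pool

        rng = np.random.default_rng(seed)
        self.conv_w: list[np.ndarray] = []
        self.conv_b: list[np.ndarray] = []
        c_in = 3
        for c_out in self.channels:
            # He initialization for ReLU blocks
            self.conv_w.append(rng.normal(0.0, np.sqrt(2.0 / (9 * c_in)), (9 * c_in, c_out)))
            self.conv_b.append(np.zeros(c_out))
            c_in = c_out
        self.head_w = rng.normal(0.0, np.sqrt(1.0 / c_in), (c_in, 2))
        self.head_b = np.zeros(2)

    # ---- structure -------------------------------------------------------

    @property
    def n_blocks(self) -> int:
        return len(self.channels)

    @property
    def activation_layer_names(self) -> list[str]:
        return [f"relu_{i + 1}" for i in range(self.n_blocks)]

    def parameter_groups(self) -> list[dict[str, np.ndarray]]:
        """Conv blocks in enumeration order from the input, then the head."""
        groups = [{"W": w, "b": b} for w, b in zip(self.conv_w, self.conv_b)]
        groups.append({"W": self.head_w, "b": self.head_b})
        return groups

    # ---- forward / backward ---------------------------------------------

    def _downsample(self, x: np.ndarray) -> np.ndarray:
        b = x.shape[0]
        s, p = self.spatial, self.pool
        return x.reshape(b, s, p, s, p, 3).mean(axis=(2, 4))

    def _forward(self, x: np.ndarray, pooled: bool = False) -> dict:
        """Forward pass caching everything the backward pass needs.

        ``pooled=True`` skips the fixed downsampling (input already at the
        working resolution) — a training-loop fast path.
        """
        a = x if pooled else self._downsample(x)
        cache = {"pooled": a, "cols": [], "acts": []}
        for w, b in zip(self.conv_w, self.conv_b):
            cols = _im2col3(a)
            z = cols @ w + b
            a = np.maximum(z, 0.0)
            cache["cols"].append(cols)
            cache["acts"].append(a)
        g = a.mean(axis=(1, 2))
        logits = g @ self.head_w + self.head_b
        logits = logits - logits.max(axis=1, keepdims=True)
        ez = np.exp(logits)
        probs = ez / ez.sum(axis=1, keepdims=True)
        cache.update(gap=g, logits=logits, probs=probs)
        return cache

    def _backward(
        self, cache: dict, dlogits: np.ndarray, collect_activation_grads: bool = False
    ) -> tuple[list[dict[str, np.ndarray]], list[np.ndarray]]:
        """Gradients of a scalar with ``d scalar / d logits = dlogits``.

        Returns per-group parameter gradients (conv blocks then head) and,
        optionally, the gradient w.r.t. each ReLU activation map.
        """
        g = cache["gap"]
        d_head_w = g.T @ dlogits
        d_head_b = dlogits.sum(axis=0)
        dg = dlogits @ self.head_w.T

        hw = self.spatial * self.spatial
        da = np.broadcast_to(dg[:, None, None, :], cache["acts"][-1].shape) / hw
        da = np.ascontiguousarray(da)

        conv_grads: list[dict[str, np.ndarray]] = [None] * self.n_blocks  # type: ignore[list-item]
        act_grads: list[np.ndarray] = [None] * self.n_blocks if collect_activation_grads else []  # type: ignore[list-item]
        for i in range(self.n_blocks - 1, -1, -1):
            if collect_activation_grads:
                act_grads[i] = da.copy()
            dz = da * (cache["acts"][i] > 0)
            cols = cache["cols"][i]
            dw = cols.reshape(-1, cols.shape[-1]).T @ dz.reshape(-1, dz.shape[-1])
            db = dz.sum(axis=(0, 1, 2))
            conv_grads[i] = {"W": dw, "b": db}
            if i > 0:
                c_prev = self.channels[i - 1]
                da = _col2im3(dz @ self.conv_w[i].T, c_prev)
        groups = conv_grads + [{"W": d_head_w, "b": d_head_b}]
        return groups, act_grads

    # ---- public API ------------------------------------------------------

    def predict_proba(self, tiles: Sequence[TileRecord] | np.ndarray) -> np.ndarray:
        x = _tiles_to_array(tiles)
        if x.shape[0] == 0:
            return np.empty((0, 2))
        if x.shape[1] != self.input_size or x.shape[2] != self.input_size:
            raise ValidationError(
                f"tile shape {x.shape[1:3]} does not match model input {self.input_size}"
            )
        return self._forward(x)["probs"]

    def activation_and_gradient(
        self, tile: TileRecord | np.ndarray, layer: str, class_index: int
    ) -> tuple[np.ndarray, np.ndarray]:
        """(activation, d pre-softmax logit / d activation) for one tile.

        Both arrays have the layer's native spatial shape (H, W, C).
        """
        names = self.activation_layer_names
        if layer not in names:
            raise ValidationError(f"unknown activation layer {layer!r}; have {names}")
        if not 0 <= class_index < 2:
            raise ValidationError("class_index must be 0 or 1")
        px = tile.pixels if isinstance(tile, TileRecord) else np.asarray(tile)
        x = _tiles_to_array(px[None])
        cache = self._forward(x)
        dlogits = np.zeros((1, 2))
        dlogits[0, class_index] = 1.0
        _, act_grads = self._backward(cache, dlogits, collect_activation_grads=True)
        i = names.index(layer)
        return cache["acts"][i][0], act_grads[i][0]

    # ---- serialization ---------------------------------------------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        meta = {
            "class_names": list(self.class_names),
            "channels": list(self.channels),
            "input_size": self.input_size,
            "pool": self.pool,
        }
        arrays = {"head_w": self.head_w, "head_b": self.head_b, "meta": np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)}
        for i, (w, b) in enumerate(zip(self.conv_w, self.conv_b)):
            arrays[f"conv_w_{i}"] = w
            arrays[f"conv_b_{i}"] = b
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "SmallConvNet":
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            net = cls(
                tuple(meta["class_names"]),
                channels=meta["channels"],
                input_size=meta["input_size"],
                pool=meta["pool"],
            )
            net.conv_w = [data[f"conv_w_{i}"] for i in range(len(meta["channels"]))]
            net.conv_b = [data[f"conv_b_{i}"] for i in range(len(meta["channels"]))]
            net.head_w = data["head_w"]
            net.head_b = data["head_b"]
        return net


def bce_loss(probs: np.ndarray, y: np.ndarray, eps: float = 1e-12) -> float:
    """Binary cross-entropy of the softmax pair against 0/1 labels."""
    p1 = np.clip(probs[:, 1], eps, 1 - eps)
    return float(-np.mean(y * np.log(p1) + (1 - y) * np.log(1 - p1)))


def train_classifier(
    train_tiles: Sequence[tuple[TileRecord, str]],
    val_tiles: Sequence[tuple[TileRecord, str]],
    config: TrainingConfig,
    augment: AugmentationConfig | None = None,
    builder: Callable[[tuple[str, str], int], TileClassifier] | None = None,
    class_names: tuple[str, str] = TUMOR_CLASSES,
) -> tuple[TileClassifier, list[dict]]:
    """Fit a tile classifier with SGD + momentum on binary cross-entropy.

    ``train_tiles``/``val_tiles`` are (tile, class-name) pairs; the first
    ``config.frozen_layers`` backbone parameter groups receive no updates.
    Early stopping monitors validation loss with the configured patience.
    Returns the fitted model and a per-epoch history of losses.
    """
    labels = sorted({lab for _, lab in train_tiles})
    if len(labels) < 2:
        raise ValidationError(f"training set contains a single class: {labels}")
    if set(labels) != set(class_names):
        raise ValidationError(f"training labels {labels} do not match class pair {class_names}")

    if builder is None:
        builder = lambda names, seed: SmallConvNet(names, seed=seed)
    model = builder(class_names, config.rng_seed)
    if not isinstance(model, SmallConvNet):
        raise ValidationError("the built-in training loop supports SmallConvNet backbones")
    if config.frozen_layers > model.n_blocks:
        raise ValidationError(
            f"frozen_layers={config.frozen_layers} exceeds backbone depth {model.n_blocks}"
        )

    rng = np.random.default_rng(config.rng_seed)
    name_to_idx = {n: i for i, n in enumerate(class_names)}
    y_train = np.array([name_to_idx[lab] for _, lab in train_tiles])
    y_val = np.array([name_to_idx[lab] for _, lab in val_tiles]) if len(val_tiles) else None

    def _pool_chunked(tiles: Sequence[TileRecord], chunk: int = 32) -> np.ndarray:
        parts = [
            model._downsample(_tiles_to_array(tiles[i : i + chunk]))
            for i in range(0, len(tiles), chunk)
        ]
        return np.concatenate(parts)

    # fast path: without augmentation the fixed downsampling is applied once
    x_train_pooled = None
    if augment is None:
        x_train_pooled = _pool_chunked([t for t, _ in train_tiles])
    x_val = _pool_chunked([t for t, _ in val_tiles]) if len(val_tiles) else None

    groups = model.parameter_groups()
    velocity = [{k: np.zeros_like(v) for k, v in grp.items()} for grp in groups]
    frozen = set(range(config.frozen_layers))  # head (last group) is never frozen

    history: list[dict] = []
    best_val = np.inf
    best_state: list[dict[str, np.ndarray]] | None = None
    bad_epochs = 0
    n = len(train_tiles)

    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            if x_train_pooled is not None:
                x = x_train_pooled[idx]
            else:
                batch = [
                    apply_augmentation(train_tiles[i][0], sample_augmentation(augment, rng))
                    for i in idx
                ]
                x = model._downsample(_tiles_to_array(batch))
            y = y_train[idx]
            cache = model._forward(x, pooled=True)
            probs = cache["probs"]
            epoch_loss += bce_loss(probs, y)
            n_batches += 1
            onehot = np.zeros_like(probs)
            onehot[np.arange(len(y)), y] = 1.0
            dlogits = (probs - onehot) / len(y)
            grads, _ = model._backward(cache, dlogits)
            for gi, (grp, grd) in enumerate(zip(model.parameter_groups(), grads)):
                if gi in frozen:
                    continue
                for k in grp:
                    velocity[gi][k] = config.momentum * velocity[gi][k] - config.learning_rate * grd[k]
                    grp[k] += velocity[gi][k]

        entry = {"epoch": epoch, "train_loss": epoch_loss / max(n_batches, 1)}
        if x_val is not None and len(x_val):
            val_probs = model._forward(x_val, pooled=True)["probs"]
            val_loss = bce_loss(val_probs, y_val)
            entry["val_loss"] = val_loss
            entry["val_accuracy"] = float(np.mean(val_probs.argmax(axis=1) == y_val))
            if val_loss < best_val - 1e-9:
                best_val = val_loss
                best_state = [{k: v.copy() for k, v in grp.items()} for grp in model.parameter_groups()]
                bad_epochs = 0
            else:
                bad_epochs += 1
        history.append(entry)
        if x_val is not None and bad_epochs > config.patience:
            break

    if best_state is not None:
        for grp, saved in zip(model.parameter_groups(), best_state):
            for k in grp:
                grp[k][...] = saved[k]
    return model, history


def predict_proba(model: TileClassifier, tiles: Sequence[TileRecord]) -> np.ndarray:
    """Order-preserving batch prediction through the classifier contract."""
    return model.predict_proba(tiles)
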