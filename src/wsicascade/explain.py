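"""HD-CAM explainability: multilayer Grad-CAM with depth-weighted fusion.

Grad-CAM localizes the image regions driving a class score: channel
weights are the spatially averaged gradients of the pre-softmax class
logit with respect to a spatial ReLU activation, the map is the rectified
weighted activation sum.  HD-CAM extends this across the last ten ReLU
layers of the backbone: each layer's map is min-max normalized, bilinearly
upsampled to the tile resolution, and the maps are fused by a weighted sum
whose weights grow linearly with depth (w_i proportional to i, shallowest
i = 1), emphasizing increasingly abstract features.  The fused map is
min-max normalized again.

Explanations are computed on the tiles the classifier predicts correctly
with the highest confidence, so interpretability is assessed under
maximal model certainty.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skimage import transform as sktransform

from .backbone import SmallConvNet, TileClassifier
from .cascade import TileVote
from .errors import ValidationError
from .tiles import TILE_SIZE, TileRecord


@dataclass(frozen=True)
class CamMap:
    """Single-layer Grad-CAM map at native and tile resolution."""

    layer: str
    native: np.ndarray  # (h, w) in [0, 1]
    upsampled: np.ndarray  # (tile, tile) in [0, 1]
    all_zero: bool


@dataclass(frozen=True)
class HDCamResult:
    """Fused multilayer explanation for one tile."""

    slide_id: str
    cell: tuple[int, int]
    layer_maps: tuple[CamMap, ...]  # shallowest -> deepest
    fusion_weights: tuple[float, ...]
    combined: np.ndarray  # (tile, tile) in [0, 1]
    predicted_class: str
    predicted_probability: float


def _minmax(m: np.ndarray) -> tuple[np.ndarray, bool]:
    lo, hi = float(m.min()), float(m.max())
    if hi <= lo:
        # all-constant (incl. all-zero) maps stay flat at zero
        return np.zeros_like(m), True
    return (m - lo) / (hi - lo), False


def linear_fusion_weights(n: int) -> np.ndarray:
    """w_i proportional to depth rank i = 1..n, normalized to sum 1."""
    if n < 1:
        raise ValidationError("need at least one layer")
    w = np.arange(1, n + 1, dtype=np.float64)
    return w / w.sum()


def grad_cam(
    model: TileClassifier,
    tile: TileRecord | np.ndarray,
    layer: str,
    target_class: int | str,
    tile_size: int = TILE_SIZE,
) -> CamMap:
    """Grad-CAM of ``target_class`` at one named activation layer."""
    if not isinstance(model, SmallConvNet):
        raise ValidationError("grad_cam requires a backbone exposing activation gradients")
    if isinstance(target_class, str):
        if target_class not in model.class_names:
            raise ValidationError(f"unknown class {target_class!r}")
        target_class = model.class_names.index(target_class)

    act, grad = model.activation_and_gradient(tile, layer, target_class)
    alpha = grad.mean(axis=(0, 1))  # spatially averaged gradients
    raw = np.maximum((act * alpha[None, None, :]).sum(axis=2), 0.0)
    native, flat = _minmax(raw)
    up = sktransform.resize(native, (tile_size, tile_size), order=1, mode="edge", anti_aliasing=False)
    if flat:
        warnings.warn(f"Grad-CAM at {layer!r} is all-zero (saturated or dead head)", stacklevel=2)
    return CamMap(layer=layer, native=native, upsampled=up, all_zero=flat)


def hd_cam(
    model: TileClassifier,
    tile: TileRecord,
    target_class: int | str | None = None,
    n_layers: int = 10,
    tile_size: int = TILE_SIZE,
) -> HDCamResult:
    """Fused Grad-CAM over the last ``n_layers`` ReLU activation layers."""
    layers = model.activation_layer_names
    if not layers:
        raise ValidationError("model exposes no activation layers")
    if len(layers) < n_layers:
        warnings.warn(
            f"model has {len(layers)} eligible layers < requested {n_layers}; using all",
            stacklevel=2,
        )
    used = layers[-n_layers:] if len(layers) >= n_layers else layers

    probs = model.predict_proba([tile])[0]
    if target_class is None:
        target_class = int(np.argmax(probs))
    elif isinstance(target_class, str):
        target_class = model.class_names.index(target_class)

    maps = tuple(grad_cam(model, tile, layer, target_class, tile_size) for layer in used)
    weights = linear_fusion_weights(len(used))
    combined = np.zeros((tile_size, tile_size))
    for w, m in zip(weights, maps):
        combined += w * m.upsampled
    combined, _ = _minmax(combined)
    return HDCamResult(
        slide_id=tile.slide_id,
        cell=tile.cell,
        layer_maps=maps,
        fusion_weights=tuple(weights.tolist()),
        combined=combined,
        predicted_class=model.class_names[target_class],
        predicted_probability=float(probs[target_class]),
    )


def select_top_confident_correct(
    votes: Sequence[tuple[TileVote, str]],
    k: int,
) -> list[TileVote]:
    """The k most confident correctly predicted votes of each class.

    ``votes`` pairs each vote with its ground-truth class name.  Ties are
    broken by (grid_row, grid_col).  Fewer than k correct tiles in a class
    returns all of them with a warning.
    """
    correct = [(v, t) for v, t in votes if v.decision == t]
    out: list[TileVote] = []
    for cls in sorted({t for _, t in votes}):
        cls_votes = [v for v, t in correct if t == cls]
        cls_votes.sort(key=lambda v: (-v.confidence, v.grid_row, v.grid_col))
        if len(cls_votes) < k:
            warnings.warn(
                f"only {len(cls_votes)} correct tiles for class {cls!r} (requested {k})",
                stacklevel=2,
            )
        out.extend(cls_votes[:k])
    return out
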