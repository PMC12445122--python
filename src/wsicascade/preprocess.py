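"""Stain normalization and the training-time augmentation sampler.

Stain normalization uses Reinhard-style mean/SD transfer in CIELAB: tile
channel statistics are moved onto a reference profile fitted from a tile
population, which damps inter-center H&E staining differences.  The
augmentation sampler draws, per tile, a geometric jitter (translation,
scale, rotation), optional color offsets (hue, saturation, brightness) and
an optional Gaussian blur with sigma = 1 + U[0, 1); color and blur apply
only to the mutation-classifier stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from skimage import color as skcolor
from skimage import filters as skfilters
from skimage import transform as sktransform

from .errors import ValidationError
from .tiles import TILE_SIZE, TileRecord

#: floor for channel standard deviations (constant-color degenerate case)
SD_FLOOR = 1e-6


@dataclass(frozen=True)
class StainProfile:
    """Per-channel mean/SD of a reference tile population in LAB space."""

    means: tuple[float, float, float]
    stds: tuple[float, float, float]
    color_space: str = "lab"

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.stds):
            raise ValidationError("stain profile SDs must be positive")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {"means": list(self.means), "stds": list(self.stds), "color_space": self.color_space},
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "StainProfile":
        d = json.loads(Path(path).read_text())
        return cls(tuple(d["means"]), tuple(d["stds"]), d.get("color_space", "lab"))


def _tiles_to_lab(tiles: Sequence[TileRecord]) -> np.ndarray:
    stacked = np.concatenate([t.pixels.reshape(-1, 3) for t in tiles]).astype(np.float64) / 255.0
    return skcolor.rgb2lab(stacked.reshape(1, -1, 3)).reshape(-1, 3)


def fit_stain_profile(tiles: Sequence[TileRecord]) -> StainProfile:
    """Channel means/SDs over all pixels of all tiles, in LAB space."""
    if len(tiles) == 0:
        raise ValidationError("cannot fit a stain profile from zero tiles")
    lab = _tiles_to_lab(tiles)
    means = lab.mean(axis=0)
    stds = np.maximum(lab.std(axis=0), SD_FLOOR)
    return StainProfile(tuple(means.tolist()), tuple(stds.tolist()))


def normalize_stain(tile: TileRecord, target: StainProfile) -> TileRecord:
    """Reinhard mean/SD transfer of the tile's LAB statistics onto ``target``."""
    rgb = tile.pixels.astype(np.float64) / 255.0
    lab = skcolor.rgb2lab(rgb)
    mu = lab.reshape(-1, 3).mean(axis=0)
    sd = np.maximum(lab.reshape(-1, 3).std(axis=0), SD_FLOOR)
    out = (lab - mu) / sd * np.asarray(target.stds) + np.asarray(target.means)
    # keep L in its valid range before the inverse transform
    out[..., 0] = np.clip(out[..., 0], 0.0, 100.0)
    rgb_out = np.clip(skcolor.lab2rgb(out), 0.0, 1.0)
    return TileRecord(
        slide_id=tile.slide_id,
        grid_row=tile.grid_row,
        grid_col=tile.grid_col,
        origin_x=tile.origin_x,
        origin_y=tile.origin_y,
        pixels=np.round(rgb_out * 255.0).astype(np.uint8),
    )


@dataclass(frozen=True)
class AugmentationConfig:
    """Per-stage augmentation ranges.

    Geometric jitter applies to both classifier stages; the color offsets
    and synthetic blur only to the mutation-classifier stage
    (``color_enabled``/``blur_enabled``).  The hue range is deliberately
    asymmetric ([0.03, 0.04]); all draws are uniform within their range.
    """

    pixel_translation_range: tuple[float, float] = (-10.0, 10.0)
    scale_range: tuple[float, float] = (0.5, 1.5)
    rotation_range: tuple[float, float] = (-90.0, 90.0)
    hue_range: tuple[float, float] = (0.03, 0.04)
    saturation_range: tuple[float, float] = (-0.05, 0.05)
    brightness_range: tuple[float, float] = (-0.1, 0.1)
    color_enabled: bool = True
    blur_enabled: bool = True

    def __post_init__(self) -> None:
        for name in (
            "pixel_translation_range",
            "scale_range",
            "rotation_range",
            "hue_range",
            "saturation_range",
            "brightness_range",
        ):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValidationError(f"{name}: low > high")

    @classmethod
    def tumor(cls) -> "AugmentationConfig":
        """Geometric-only augmentation used for the tumor classifier."""
        return cls(color_enabled=False, blur_enabled=False)

    @classmethod
    def egfr(cls) -> "AugmentationConfig":
        """Full geometric + color + blur augmentation for the mutation classifier."""
        return cls(color_enabled=True, blur_enabled=True)


@dataclass(frozen=True)
class AugmentationSample:
    """One concrete draw from an :class:`AugmentationConfig`."""

    dx: float
    dy: float
    scale: float
    rotation_deg: float
    hue_offset: float | None
    saturation_offset: float | None
    brightness_offset: float | None
    blur_sigma: float | None

    @classmethod
    def identity(cls) -> "AugmentationSample":
        return cls(0.0, 0.0, 1.0, 0.0, None, None, None, None)


def sample_augmentation(config: AugmentationConfig, rng: np.random.Generator) -> AugmentationSample:
    """Independent uniform draws within each configured range."""
    u = lambda lo_hi: float(rng.uniform(*lo_hi))
    dx = u(config.pixel_translation_range)
    dy = u(config.pixel_translation_range)
    scale = u(config.scale_range)
    rot = u(config.rotation_range)
    if config.color_enabled:
        hue = u(config.hue_range)
        sat = u(config.saturation_range)
        bright = u(config.brightness_range)
    else:
        hue = sat = bright = None
    sigma = 1.0 + float(rng.uniform(0.0, 1.0)) if config.blur_enabled else None
    return AugmentationSample(dx, dy, scale, rot, hue, sat, bright, sigma)


def apply_augmentation(tile: TileRecord, sample: AugmentationSample) -> TileRecord:
    """Apply geometric jitter, then color offsets, then blur.

    The geometric transform scales and rotates about the tile center and
    then translates; resampling is bilinear with reflective border fill, so
    the output stays 299x299 uint8.
    """
    img = tile.pixels.astype(np.float64) / 255.0
    size = img.shape[0]

    geometric = not (
        sample.dx == 0.0 and sample.dy == 0.0 and sample.scale == 1.0 and sample.rotation_deg == 0.0
    )
    if geometric:
        center = (size - 1) / 2.0
        shift = sktransform.SimilarityTransform(translation=(-center, -center))
        core = sktransform.SimilarityTransform(
            scale=sample.scale, rotation=np.deg2rad(sample.rotation_deg)
        )
        unshift = sktransform.SimilarityTransform(
            translation=(center + sample.dx, center + sample.dy)
        )
        tform = shift + core + unshift
        img = sktransform.warp(img, tform.inverse, order=1, mode="reflect", preserve_range=True)

    if sample.hue_offset is not None or sample.saturation_offset is not None:
        hsv = skcolor.rgb2hsv(img)
        if sample.hue_offset is not None:
            hsv[..., 0] = np.mod(hsv[..., 0] + sample.hue_offset, 1.0)
        if sample.saturation_offset is not None:
            hsv[..., 1] = np.clip(hsv[..., 1] + sample.saturation_offset, 0.0, 1.0)
        img = skcolor.hsv2rgb(hsv)
    if sample.brightness_offset is not None:
        img = img + sample.brightness_offset

    if sample.blur_sigma is not None:
        img = skfilters.gaussian(img, sigma=sample.blur_sigma, channel_axis=-1, mode="reflect")

    img = np.clip(img, 0.0, 1.0)
    return TileRecord(
        slide_id=tile.slide_id,
        grid_row=tile.grid_row,
        grid_col=tile.grid_col,
        origin_x=tile.origin_x,
        origin_y=tile.origin_y,
        pixels=np.round(img * 255.0).astype(np.uint8),
    )
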