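"""Slide abstraction, deterministic tiling and label-grid reassembly.

A whole-slide image is processed as a non-overlapping grid of fixed-size
RGB tiles (299 px to match the classifier input).  Coordinates are 0-based
and half-open; the grid is row-major.  Partial edge tiles are dropped rather
than padded, so the tiled area is exactly
``[0, tile_size * n_cols) x [0, tile_size * n_rows)``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .errors import ConflictError, TilingError, ValidationError

TILE_SIZE = 299


class Label(str, Enum):
    """Cascade label vocabulary used throughout the pipeline."""

    HEALTHY = "HEALTHY"
    EGFR = "EGFR"
    WT = "WT"
    ABSTAIN = "ABSTAIN"
    BACKGROUND = "BACKGROUND"
    EMPTY = "EMPTY"

    def __str__(self) -> str:  # TSV-friendly
        return self.value


#: Labels a classifier can emit for a tissue tile.
CLASS_LABELS = (Label.HEALTHY, Label.EGFR, Label.WT)


class SlideImage:
    """RGB slide with lazy region access.

    ``reader(x, y, w, h)`` must return a ``(h, w, 3)`` uint8 array.  Plain
    raster images are wrapped via :meth:`from_array` / :meth:`from_file`;
    pyramidal formats can be adapted by supplying a level-0 region reader.
    """

    def __init__(
        self,
        slide_id: str,
        width: int,
        height: int,
        reader: Callable[[int, int, int, int], np.ndarray],
        source_center: str | None = None,
    ) -> None:
        if width < 1 or height < 1:
            raise ValidationError(f"slide {slide_id!r}: non-positive dimensions")
        self.slide_id = slide_id
        self.width = int(width)
        self.height = int(height)
        self._reader = reader
        self.source_center = source_center

    def region(self, x: int, y: int, w: int, h: int) -> np.ndarray:
        """Return the RGB uint8 region ``[y, y+h) x [x, x+w)``."""
        if x < 0 or y < 0 or x + w > self.width or y + h > self.height:
            raise ValidationError(
                f"region ({x},{y},{w},{h}) outside slide {self.slide_id!r} "
                f"({self.width}x{self.height})"
            )
        out = np.asarray(self._reader(x, y, w, h))
        if out.shape != (h, w, 3) or out.dtype != np.uint8:
            raise ValidationError("slide reader returned a malformed region")
        return out

    @classmethod
    def from_array(
        cls,
        pixels: np.ndarray,
        slide_id: str = "slide",
        source_center: str | None = None,
    ) -> "SlideImage":
        arr = np.asarray(pixels)
        if arr.ndim != 3 or arr.shape[2] != 3:
            raise ValidationError("expected an (H, W, 3) RGB array")
        arr = arr.astype(np.uint8, copy=False)
        h, w = arr.shape[:2]
        return cls(slide_id, w, h, lambda x, y, rw, rh: arr[y : y + rh, x : x + rw], source_center)

    @classmethod
    def from_file(cls, path: str | Path, slide_id: str | None = None) -> "SlideImage":
        from PIL import Image

        path = Path(path)
        with Image.open(path) as im:
            arr = np.asarray(im.convert("RGB"))
        return cls.from_array(arr, slide_id or path.stem)

    def grid_shape(self, tile_size: int = TILE_SIZE) -> tuple[int, int]:
        """(n_rows, n_cols) of the full tiling grid."""
        return self.height // tile_size, self.width // tile_size


@dataclass(frozen=True)
class TileRecord:
    """One tile of the slide grid with its pixel payload."""

    slide_id: str
    grid_row: int
    grid_col: int
    origin_x: int
    origin_y: int
    pixels: np.ndarray = field(repr=False, compare=False)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3 or px.dtype != np.uint8:
            raise ValidationError("tile pixels must be (S, S, 3) uint8")

    @property
    def cell(self) -> tuple[int, int]:
        return self.grid_row, self.grid_col


@dataclass(frozen=True)
class RoiRect:
    """Axis-aligned region of interest in slide pixel coordinates (half-open)."""

    slide_id: str
    x: int
    y: int
    w: int
    h: int

    def validate(self, slide: SlideImage) -> None:
        if self.w <= 0 or self.h <= 0:
            raise ValidationError(f"ROI on {self.slide_id!r}: non-positive extent")
        if self.slide_id != slide.slide_id:
            raise ValidationError("ROI belongs to a different slide")
        if self.x < 0 or self.y < 0 or self.x + self.w > slide.width or self.y + self.h > slide.height:
            raise ValidationError("ROI extends outside the slide bounds")

    def contains_tile(self, origin_x: int, origin_y: int, tile_size: int) -> bool:
        return (
            origin_x >= self.x
            and origin_y >= self.y
            and origin_x + tile_size <= self.x + self.w
            and origin_y + tile_size <= self.y + self.h
        )


@dataclass
class LabelGrid:
    """2D categorical grid of cascade labels aligned to the slide tiling."""

    slide_id: str
    cells: np.ndarray  # (n_rows, n_cols) object array of Label

    @property
    def n_rows(self) -> int:
        return self.cells.shape[0]

    @property
    def n_cols(self) -> int:
        return self.cells.shape[1]

    def counts(self) -> dict[Label, int]:
        out: dict[Label, int] = {lab: 0 for lab in Label}
        for lab in self.cells.flat:
            out[lab] += 1
        return out

    def copy(self) -> "LabelGrid":
        return LabelGrid(self.slide_id, self.cells.copy())

    @classmethod
    def filled(cls, slide_id: str, n_rows: int, n_cols: int, fill: Label = Label.EMPTY) -> "LabelGrid":
        # np.full would coerce the str-enum to a plain str
        cells = np.empty((n_rows, n_cols), dtype=object)
        cells[:] = fill
        return cls(slide_id, cells)


def tile_slide(
    slide: SlideImage,
    tile_size: int = TILE_SIZE,
    rois: Sequence[RoiRect] | None = None,
) -> list[TileRecord]:
    """Extract all grid-aligned tiles fully inside the slide (and any ROI).

    Tiles are returned in deterministic row-major order.  When ``rois`` is
    given, a tile is kept only if it lies entirely within at least one ROI,
    which guarantees label purity of ROI-derived tiles.
    """
    if tile_size < 1:
        raise ValidationError("tile_size must be >= 1")
    if slide.width < tile_size or slide.height < tile_size:
        raise TilingError(
            f"slide {slide.slide_id!r} ({slide.width}x{slide.height}) is smaller "
            f"than the tile size {tile_size}"
        )
    if rois is not None:
        for roi in rois:
            roi.validate(slide)

    n_rows, n_cols = slide.height // tile_size, slide.width // tile_size
    records: list[TileRecord] = []
    for r in range(n_rows):
        for c in range(n_cols):
            ox, oy = c * tile_size, r * tile_size
            if rois is not None and not any(roi.contains_tile(ox, oy, tile_size) for roi in rois):
                continue
            records.append(
                TileRecord(
                    slide_id=slide.slide_id,
                    grid_row=r,
                    grid_col=c,
                    origin_x=ox,
                    origin_y=oy,
                    pixels=slide.region(ox, oy, tile_size, tile_size),
                )
            )
    return records


def is_background(
    tile: TileRecord,
    saturation_threshold: float = 0.08,
    tissue_fraction: float = 0.10,
) -> bool:
    """True iff the tile carries too little saturated (tissue-like) content.

    A pixel counts as tissue when its HSV saturation exceeds
    ``saturation_threshold``; the tile is background when the tissue pixel
    fraction falls below ``tissue_fraction``.  Needed only for whole-slide
    runs without hand-drawn ROIs.
    """
    if not (0.0 <= saturation_threshold <= 1.0 and 0.0 <= tissue_fraction <= 1.0):
        raise ValidationError("thresholds must lie in [0, 1]")
    rgb = tile.pixels.astype(np.float64) / 255.0
    mx = rgb.max(axis=2)
    mn = rgb.min(axis=2)
    sat = np.where(mx > 0, (mx - mn) / np.maximum(mx, 1e-12), 0.0)
    return float(np.mean(sat > saturation_threshold)) < tissue_fraction


def reassemble_grid(
    slide: SlideImage,
    tile_labels: Mapping[tuple[int, int], Label] | Iterable[tuple[TileRecord, Label]],
    tile_size: int = TILE_SIZE,
    background_cells: Iterable[tuple[int, int]] = (),
) -> LabelGrid:
    """Place per-tile labels back onto the slide grid.

    ``tile_labels`` maps grid cells (or TileRecords) to labels; unlabeled
    tiled cells become EMPTY and cells listed in ``background_cells`` become
    BACKGROUND.  A cell given two labels raises :class:`ConflictError`.
    """
    n_rows, n_cols = slide.grid_shape(tile_size)
    grid = LabelGrid.filled(slide.slide_id, n_rows, n_cols, Label.EMPTY)

    if isinstance(tile_labels, Mapping):
        items = list(tile_labels.items())
    else:
        items = [(t.cell, lab) for t, lab in tile_labels]

    seen: set[tuple[int, int]] = set()
    for cell, lab in items:
        r, c = cell
        if not (0 <= r < n_rows and 0 <= c < n_cols):
            raise ValidationError(f"cell {cell} outside the {n_rows}x{n_cols} grid")
        if cell in seen:
            raise ConflictError(f"duplicate label for cell {cell}")
        seen.add(cell)
        grid.cells[r, c] = Label(lab)

    for cell in background_cells:
        r, c = cell
        if cell in seen:
            raise ConflictError(f"cell {cell} is both labeled and background")
        grid.cells[r, c] = Label.BACKGROUND
    return grid


def write_tile_manifest(
    path: str | Path,
    tiles: Sequence[TileRecord],
    labels: Mapping[tuple[int, int], Label] | None = None,
) -> None:
    """Write a TSV manifest: slide_id, grid_row, grid_col, origin_x, origin_y, label."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["slide_id", "grid_row", "grid_col", "origin_x", "origin_y", "label"])
        for t in tiles:
            lab = labels.get(t.cell, Label.EMPTY) if labels else Label.EMPTY
            w.writerow([t.slide_id, t.grid_row, t.grid_col, t.origin_x, t.origin_y, str(lab)])


def read_tile_manifest(path: str | Path) -> list[dict]:
    with open(path, newline="") as fh:
        return [dict(row) for row in csv.DictReader(fh, delimiter="\t")]
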