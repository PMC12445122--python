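"""Label-grid heatmaps with categorical 3x3 smoothing.

The spatial distribution of cascade labels over a slide is rendered as a
color map (EGFR red, WT green, healthy pale blue, abstain gray,
background/empty white).  Before rendering, a 3x3 modal filter — the
categorical analog of a median filter, and identical to it for the binary
EGFR/WT case under a 0/1 encoding — suppresses isolated misclassified
tiles.  Smoothing is visualization-only by default; a config flag lets it
feed aggregation instead.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .tiles import CLASS_LABELS, Label, LabelGrid

#: rendering palette (RGB uint8)
PALETTE: dict[Label, tuple[int, int, int]] = {
    Label.EGFR: (220, 20, 60),
    Label.WT: (34, 139, 34),
    Label.HEALTHY: (173, 216, 230),
    Label.ABSTAIN: (128, 128, 128),
    Label.BACKGROUND: (255, 255, 255),
    Label.EMPTY: (255, 255, 255),
}

#: labels that participate in the modal vote
_VOTABLE = set(CLASS_LABELS)  # HEALTHY, EGFR, WT


@dataclass(frozen=True)
class HeatmapRender:
    """Rendered heatmap plus its legend metadata."""

    slide_id: str
    image: np.ndarray  # (n_rows*block, n_cols*block, 3) uint8
    block_size: int
    palette: dict[str, tuple[int, int, int]]
    grid_shape: tuple[int, int]

    def save(self, png_path: str | Path, sidecar_path: str | Path | None = None) -> None:
        from PIL import Image

        Image.fromarray(self.image).save(png_path)
        if sidecar_path is not None:
            Path(sidecar_path).write_text(
                json.dumps(
                    {
                        "slide_id": self.slide_id,
                        "grid_shape": list(self.grid_shape),
                        "block_size": self.block_size,
                        "palette": {k: list(v) for k, v in self.palette.items()},
                    },
                    indent=2,
                )
            )


def smooth_label_grid(grid: LabelGrid) -> LabelGrid:
    """3x3 modal smoothing over the tissue labels.

    Each HEALTHY/EGFR/WT cell is replaced by the most frequent such label
    in its 3x3 neighborhood (truncated at borders); ties keep the original
    label.  ABSTAIN, BACKGROUND and EMPTY cells never change and never
    vote.  Smoothing therefore never introduces a label absent from the
    input grid.
    """
    cells = grid.cells
    n_rows, n_cols = cells.shape
    out = cells.copy()
    for r in range(n_rows):
        for c in range(n_cols):
            if cells[r, c] not in _VOTABLE:
                continue
            counts: dict[Label, int] = {}
            for rr in range(max(r - 1, 0), min(r + 2, n_rows)):
                for cc in range(max(c - 1, 0), min(c + 2, n_cols)):
                    lab = cells[rr, cc]
                    if lab in _VOTABLE:
                        counts[lab] = counts.get(lab, 0) + 1
            best = max(counts.values())
            winners = [lab for lab, k in counts.items() if k == best]
            if len(winners) == 1:
                out[r, c] = winners[0]
            # ties keep the original label
    return LabelGrid(grid.slide_id, out)


def render_heatmap(grid: LabelGrid, block_size: int = 8) -> HeatmapRender:
    """Deterministic palette rendering: one ``block_size`` square per cell."""
    if block_size < 1:
        raise ValidationError("block_size must be >= 1")
    n_rows, n_cols = grid.cells.shape
    img = np.empty((n_rows, n_cols, 3), dtype=np.uint8)
    for r in range(n_rows):
        for c in range(n_cols):
            img[r, c] = PALETTE[grid.cells[r, c]]
    img = np.repeat(np.repeat(img, block_size, axis=0), block_size, axis=1)
    return HeatmapRender(
        slide_id=grid.slide_id,
        image=img,
        block_size=block_size,
        palette={str(k): v for k, v in PALETTE.items()},
        grid_shape=(n_rows, n_cols),
    )
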