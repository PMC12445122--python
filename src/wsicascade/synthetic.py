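"""Seeded synthetic multi-center slide cohorts with planted ground truth.

Real H&E cohorts for this pipeline are private, so every stage is
exercised on synthetic slides: each slide is a grid of textured tiles with
a planted per-tile class (healthy, WT tumor, EGFR tumor), a slide-level
mutational status, and a center tag that adds a center-specific stain
shift (emulating inter-laboratory staining heterogeneity).  Textures are
parametric blob/noise fields — controllably separable rather than
realistic: a class-specific base color with Gaussian pixel noise plus
randomly placed darker chromatin-like blobs whose density and color also
differ by class.

Mutated-slide heterogeneity is modeled by drawing, per slide, the fraction
of tumor tiles that carry the mutant texture: EGFR slides draw from a
high-mean Beta (default Beta(8, 2)), WT slides from a low-mean Beta
(default Beta(1, 9)) so that some mutant-looking tiles occur even in
wild-type tumors.  Mutant tiles are placed uniformly at random among the
tumor tiles.  Everything is bit-exactly reproducible from the spec seed.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from skimage import draw as skdraw

from .backbone import EGFR_CLASSES, TUMOR_CLASSES, TileClassifier
from .errors import ValidationError
from .tiles import Label, LabelGrid, SlideImage, TileRecord

Color = tuple[float, float, float]


@dataclass(frozen=True)
class TextureParams:
    """Parametric texture of one tile class."""

    base_color: Color
    blob_color: Color
    blob_density: float  # expected blobs per tile (Poisson mean)
    blob_radius: float  # mean radius, px
    noise_sd: float  # per-pixel Gaussian noise, intensity units


#: default class textures: pale eosin-like healthy tissue vs two purple
#: tumor morphologies separated in hue and chromatin-blob density
DEFAULT_TEXTURES: dict[Label, TextureParams] = {
    Label.HEALTHY: TextureParams((232.0, 205.0, 222.0), (214.0, 175.0, 200.0), 3.0, 12.0, 6.0),
    Label.WT: TextureParams((170.0, 122.0, 186.0), (112.0, 62.0, 132.0), 10.0, 10.0, 6.0),
    Label.EGFR: TextureParams((118.0, 92.0, 192.0), (58.0, 40.0, 122.0), 18.0, 8.0, 6.0),
}

#: per-center additive RGB stain shifts (center index -> offset)
DEFAULT_CENTER_SHIFTS: tuple[Color, ...] = ((0.0, 0.0, 0.0), (8.0, 4.0, -6.0), (-6.0, 6.0, 8.0))


def mutant_count(fraction: float, n_tumor: int) -> int:
    """Fraction-to-count conversion with round-half-up (deterministic)."""
    if not 0.0 <= fraction <= 1.0:
        raise ValidationError("mutant fraction must lie in [0, 1]")
    return int(math.floor(fraction * n_tumor + 0.5))


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Study conditions for a synthetic cohort."""

    n_egfr_slides: int = 30
    n_wt_slides: int = 30
    grid_shape: tuple[int, int] = (5, 5)
    tile_size: int = 299
    tumor_fraction: float = 0.6
    egfr_mutant_beta: tuple[float, float] = (8.0, 2.0)
    wt_mutant_beta: tuple[float, float] = (1.0, 9.0)
    n_centers: int = 3
    center_shifts: tuple[Color, ...] = DEFAULT_CENTER_SHIFTS
    textures: dict[Label, TextureParams] = field(default_factory=lambda: dict(DEFAULT_TEXTURES))
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_egfr_slides < 0 or self.n_wt_slides < 0:
            raise ValidationError("slide counts must be non-negative")
        if not 0.0 < self.tumor_fraction <= 1.0:
            raise ValidationError("tumor_fraction must lie in (0, 1]")
        if self.n_centers < 1 or self.n_centers > len(self.center_shifts):
            raise ValidationError("n_centers must fit the provided center shifts")
        for lab in (Label.HEALTHY, Label.WT, Label.EGFR):
            if lab not in self.textures:
                raise ValidationError(f"missing texture for {lab}")


def _render_tile_pixels(
    label: Label,
    texture: TextureParams,
    center_shift: Color,
    rng: np.random.Generator,
    tile_size: int,
) -> np.ndarray:
    shift = np.asarray(center_shift)
    img = np.empty((tile_size, tile_size, 3), dtype=np.float64)
    img[:] = np.asarray(texture.base_color) + shift
    img += rng.normal(0.0, texture.noise_sd, img.shape)
    n_blobs = rng.poisson(texture.blob_density)
    blob_rgb = np.asarray(texture.blob_color) + shift
    for _ in range(n_blobs):
        cy, cx = rng.uniform(0, tile_size, 2)
        radius = rng.uniform(0.5, 1.5) * texture.blob_radius
        rr, cc = skdraw.disk((cy, cx), radius, shape=(tile_size, tile_size))
        img[rr, cc] = blob_rgb + rng.normal(0.0, texture.noise_sd, (len(rr), 3))
    return np.clip(img, 0.0, 255.0).astype(np.uint8)


@dataclass
class SyntheticSlide:
    """One synthetic slide: planted truth plus lazily rendered pixels."""

    slide_id: str
    center: int
    true_status: str  # "EGFR" | "WT"
    truth: LabelGrid
    drawn_mutant_fraction: float
    mutant_fraction: float  # realized n_mutant / n_tumor
    n_tumor: int
    n_mutant: int
    spec: SyntheticCohortSpec
    slide_index: int

    def image(self) -> SlideImage:
        """Render the slide pixels (deterministic in the cohort seed)."""
        rows, cols = self.truth.cells.shape
        ts = self.spec.tile_size
        pixels = np.empty((rows * ts, cols * ts, 3), dtype=np.uint8)
        shift = self.spec.center_shifts[self.center]
        for r in range(rows):
            for c in range(cols):
                lab = self.truth.cells[r, c]
                rng = np.random.default_rng(
                    np.random.SeedSequence([self.spec.rng_seed, self.slide_index, r, c])
                )
                pixels[r * ts : (r + 1) * ts, c * ts : (c + 1) * ts] = _render_tile_pixels(
                    lab, self.spec.textures[lab], shift, rng, ts
                )
        return SlideImage.from_array(pixels, self.slide_id, source_center=f"center_{self.center}")

    def truth_tiles(self) -> list[tuple[TileRecord, Label]]:
        """Tiles of the rendered slide paired with their planted labels."""
        from .tiles import tile_slide

        img = self.image()
        tiles = tile_slide(img, self.spec.tile_size)
        return [(t, self.truth.cells[t.grid_row, t.grid_col]) for t in tiles]


def generate_cohort(spec: SyntheticCohortSpec) -> tuple[list[SyntheticSlide], list[dict]]:
    """Generate the cohort's slides and a truth manifest.

    Slides alternate EGFR/WT status and rotate through the centers; all
    randomness derives from ``spec.rng_seed``.
    """
    statuses = ["EGFR"] * spec.n_egfr_slides + ["WT"] * spec.n_wt_slides
    slides: list[SyntheticSlide] = []
    manifest: list[dict] = []
    rows, cols = spec.grid_shape
    n_tiles = rows * cols
    n_tumor = mutant_count(spec.tumor_fraction, n_tiles)  # same rounding rule
    if n_tumor < 1:
        raise ValidationError("tumor_fraction leaves no tumor tiles on the grid")

    for idx, status in enumerate(statuses):
        rng = np.random.default_rng(np.random.SeedSequence([spec.rng_seed, idx, 12648599]))
        a, b = spec.egfr_mutant_beta if status == "EGFR" else spec.wt_mutant_beta
        drawn = float(rng.beta(a, b))
        n_mut = mutant_count(drawn, n_tumor)

        flat = rng.permutation(n_tiles)
        tumor_cells = flat[:n_tumor]
        mutant_cells = set(tumor_cells[:n_mut].tolist())
        cells = np.empty((rows, cols), dtype=object)
        cells[:] = Label.HEALTHY
        for pos in tumor_cells:
            r, c = divmod(int(pos), cols)
            cells[r, c] = Label.EGFR if int(pos) in mutant_cells else Label.WT

        slide_id = f"synthetic_{status.lower()}_{idx:03d}"
        slide = SyntheticSlide(
            slide_id=slide_id,
            center=idx % spec.n_centers,
            true_status=status,
            truth=LabelGrid(slide_id, cells),
            drawn_mutant_fraction=drawn,
            mutant_fraction=n_mut / n_tumor,
            n_tumor=n_tumor,
            n_mutant=n_mut,
            spec=spec,
            slide_index=idx,
        )
        slides.append(slide)
        manifest.append(
            {
                "slide_id": slide_id,
                "center": slide.center,
                "true_status": status,
                "drawn_mutant_fraction": drawn,
                "mutant_fraction": slide.mutant_fraction,
                "n_tumor": n_tumor,
                "n_mutant": n_mut,
                "grid_rows": rows,
                "grid_cols": cols,
            }
        )
    return slides, manifest


def write_manifest(path: str | Path, manifest: Sequence[dict]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=list(manifest[0].keys()), delimiter="\t")
        w.writeheader()
        w.writerows(manifest)


def generate_labeled_tiles(
    spec: SyntheticCohortSpec,
    n_per_class: int,
    classes: Sequence[Label] = (Label.HEALTHY, Label.WT, Label.EGFR),
    seed_salt: int = 7_777_777,
) -> list[tuple[TileRecord, Label]]:
    """Standalone labeled tiles (ROI-style) cycling through the centers.

    Used to build training/validation sets without rendering full slides;
    the seed stream is disjoint from the cohort slides' stream.
    """
    out: list[tuple[TileRecord, Label]] = []
    for ci, lab in enumerate(classes):
        for j in range(n_per_class):
            center = j % spec.n_centers
            rng = np.random.default_rng(np.random.SeedSequence([spec.rng_seed, seed_salt, ci, j]))
            px = _render_tile_pixels(
                lab, spec.textures[lab], spec.center_shifts[center], rng, spec.tile_size
            )
            out.append(
                (
                    TileRecord(
                        slide_id=f"roi_{lab.value.lower()}_{j:04d}",
                        grid_row=0,
                        grid_col=0,
                        origin_x=0,
                        origin_y=0,
                        pixels=px,
                    ),
                    lab,
                )
            )
    return out


class OracleClassifier(TileClassifier):
    """Rule-based classifier reading the planted texture statistics.

    Classifies a tile by the nearest class centroid of its mean RGB color
    (centroids estimated from freshly rendered reference tiles across all
    centers) and emits a configurable confidence, which lets tests
    exercise the cascade's gates and abstention logic.
    """

    def __init__(
        self,
        class_names: tuple[str, str],
        centroids: dict[str, np.ndarray],
        confidence: float = 1.0,
    ) -> None:
        if not 0.5 < confidence <= 1.0:
            raise ValidationError("oracle confidence must lie in (0.5, 1]")
        self.class_names = tuple(class_names)
        self._centroids = {k: np.asarray(v, dtype=np.float64) for k, v in centroids.items()}
        self.confidence = confidence
        #: texture label -> probability-column index
        self._column: dict[str, int] = {}

    def _set_columns(self, mapping: dict[str, int]) -> None:
        self._column = dict(mapping)

    def predict_proba(self, tiles) -> np.ndarray:
        n = len(tiles)
        probs = np.empty((n, 2))
        for i in range(n):
            px = tiles[i].pixels if isinstance(tiles[i], TileRecord) else np.asarray(tiles[i])
            mean = px.reshape(-1, 3).mean(axis=0)
            nearest = min(self._centroids, key=lambda k: float(np.linalg.norm(mean - self._centroids[k])))
            col = self._column[nearest]
            probs[i] = 1.0 - self.confidence
            probs[i, col] = self.confidence
        return probs


def _class_centroids(spec: SyntheticCohortSpec, n_ref: int = 4) -> dict[str, np.ndarray]:
    cents: dict[str, np.ndarray] = {}
    for li, lab in enumerate((Label.HEALTHY, Label.WT, Label.EGFR)):
        means = []
        for center in range(spec.n_centers):
            for j in range(n_ref):
                rng = np.random.default_rng(
                    np.random.SeedSequence([spec.rng_seed, 31337, li, center, j])
                )
                px = _render_tile_pixels(
                    lab, spec.textures[lab], spec.center_shifts[center], rng, spec.tile_size
                )
                means.append(px.reshape(-1, 3).mean(axis=0))
        cents[lab.value] = np.mean(means, axis=0)
    return cents


def oracle_models(
    spec: SyntheticCohortSpec, confidence: float = 1.0
) -> tuple[OracleClassifier, OracleClassifier]:
    """(tumor, egfr) oracles for a cohort spec.

    The tumor oracle maps healthy texture to "healthy" and both tumor
    textures to "cancerous"; the EGFR oracle distinguishes the two tumor
    textures.  With separable default textures and confidence 1.0 these
    recover the planted truth exactly.
    """
    cents = _class_centroids(spec)
    tumor = OracleClassifier(TUMOR_CLASSES, cents, confidence)
    tumor._set_columns({Label.HEALTHY.value: 0, Label.WT.value: 1, Label.EGFR.value: 1})
    egfr = OracleClassifier(
        EGFR_CLASSES, {k: v for k, v in cents.items() if k != Label.HEALTHY.value}, confidence
    )
    egfr._set_columns({Label.WT.value: 0, Label.EGFR.value: 1})
    return tumor, egfr
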