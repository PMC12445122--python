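"""Two-stage cascade decision logic with confidence-based abstention.

Every tissue tile first passes the tumor classifier; tiles called
cancerous continue to the EGFR-mutation classifier, so each tile ends up
HEALTHY, EGFR, WT — or ABSTAIN when the deciding vote's confidence does
not exceed the vote-confidence threshold (default 0.90, strict).  The
stage-2 *training set* is built with a stricter inclusion gate: only tiles
the tumor model calls cancerous with probability >= 0.95 (inclusive) are
kept and weakly labeled with their slide's mutational status.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .backbone import EGFR_CLASSES, TUMOR_CLASSES, TileClassifier
from .errors import ValidationError
from .tiles import Label, RoiRect, SlideImage, TileRecord, is_background, reassemble_grid, tile_slide


@dataclass(frozen=True)
class CascadeConfig:
    """Gates of the two-stage decision logic.

    ``stage2_inclusion_gate`` (inclusive >=) filters tiles into the weakly
    labeled stage-2 training set; ``vote_confidence_threshold`` (strict >)
    must be exceeded for a vote to count toward tile-level metrics.  The
    test-time tumor decision is plain argmax.  By default the AI-mutation
    Ratio is a plain voting process over argmax decisions — low-confidence
    votes abstain from metrics but still vote for the ratio; set
    ``abstain_excluded_from_ratio`` to drop them there too.
    """

    stage2_inclusion_gate: float = 0.95
    vote_confidence_threshold: float = 0.90
    abstain_excluded_from_ratio: bool = False

    def __post_init__(self) -> None:
        for name in ("stage2_inclusion_gate", "vote_confidence_threshold"):
            v = getattr(self, name)
            if not 0.5 < v <= 1.0:
                raise ValidationError(f"{name} must lie in (0.5, 1]")


@dataclass(frozen=True)
class TileVote:
    """One classifier vote for one tile at one cascade stage."""

    slide_id: str
    grid_row: int
    grid_col: int
    stage: str  # "tumor" | "egfr"
    class_names: tuple[str, str]
    probabilities: tuple[float, float]
    confidence: float
    decision: str
    abstained: bool

    @property
    def cell(self) -> tuple[int, int]:
        return self.grid_row, self.grid_col


def _make_vote(
    tile: TileRecord, stage: str, names: tuple[str, str], probs: np.ndarray, threshold: float
) -> TileVote:
    k = int(np.argmax(probs))
    conf = float(probs[k])
    return TileVote(
        slide_id=tile.slide_id,
        grid_row=tile.grid_row,
        grid_col=tile.grid_col,
        stage=stage,
        class_names=names,
        probabilities=(float(probs[0]), float(probs[1])),
        confidence=conf,
        decision=names[k],
        abstained=conf <= threshold,
    )


def _check_models(tumor_model: TileClassifier, egfr_model: TileClassifier) -> None:
    if tuple(tumor_model.class_names) != TUMOR_CLASSES:
        raise ValidationError(
            f"tumor model classes {tumor_model.class_names} != {TUMOR_CLASSES}"
        )
    if tuple(egfr_model.class_names) != EGFR_CLASSES:
        raise ValidationError(f"EGFR model classes {egfr_model.class_names} != {EGFR_CLASSES}")


def classify_tiles_cascade(
    tiles: Sequence[TileRecord],
    tumor_model: TileClassifier,
    egfr_model: TileClassifier,
    config: CascadeConfig = CascadeConfig(),
) -> tuple[list[Label], list[dict[str, TileVote]]]:
    """Run the cascade over a batch of tiles.

    Returns final labels plus, per tile, the stage votes ("tumor" always;
    "egfr" whenever stage 2 ran).  Stage 2 runs exactly on the tiles whose
    tumor argmax is cancerous — never on healthy-argmax tiles — and its
    vote is recorded even when stage 1 abstained, for audit.
    """
    _check_models(tumor_model, egfr_model)
    if len(tiles) == 0:
        return [], []

    tumor_probs = tumor_model.predict_proba(tiles)
    cancer_idx = [i for i in range(len(tiles)) if int(np.argmax(tumor_probs[i])) == 1]
    egfr_probs: dict[int, np.ndarray] = {}
    if cancer_idx:
        probs2 = egfr_model.predict_proba([tiles[i] for i in cancer_idx])
        egfr_probs = {i: probs2[j] for j, i in enumerate(cancer_idx)}

    thr = config.vote_confidence_threshold
    labels: list[Label] = []
    votes: list[dict[str, TileVote]] = []
    for i, tile in enumerate(tiles):
        record = {"tumor": _make_vote(tile, "tumor", TUMOR_CLASSES, tumor_probs[i], thr)}
        v1 = record["tumor"]
        if i in egfr_probs:
            record["egfr"] = _make_vote(tile, "egfr", EGFR_CLASSES, egfr_probs[i], thr)
        if v1.abstained:
            labels.append(Label.ABSTAIN)
        elif v1.decision == TUMOR_CLASSES[0]:
            labels.append(Label.HEALTHY)
        else:
            v2 = record["egfr"]
            labels.append(Label.ABSTAIN if v2.abstained else Label(v2.decision))
        votes.append(record)
    return labels, votes


def final_label(record: dict[str, TileVote], config: CascadeConfig = CascadeConfig()) -> Label:
    """Recover the cascade label from a tile's stage-vote record."""
    v1 = record["tumor"]
    thr = config.vote_confidence_threshold
    if v1.confidence <= thr:
        return Label.ABSTAIN
    if v1.decision == TUMOR_CLASSES[0]:
        return Label.HEALTHY
    v2 = record["egfr"]
    if v2.confidence <= thr:
        return Label.ABSTAIN
    return Label(v2.decision)


def voting_label(record: dict[str, TileVote]) -> Label:
    """Argmax voting label of a tile, ignoring confidence.

    Used by the slide-level ratio: tumor argmax healthy -> HEALTHY, else
    the stage-2 argmax class.
    """
    v1 = record["tumor"]
    if v1.decision == TUMOR_CLASSES[0]:
        return Label.HEALTHY
    return Label(record["egfr"].decision)


def classify_tile_cascade(
    tile: TileRecord,
    tumor_model: TileClassifier,
    egfr_model: TileClassifier,
    config: CascadeConfig = CascadeConfig(),
) -> tuple[Label, dict[str, TileVote]]:
    """Single-tile convenience wrapper around :func:`classify_tiles_cascade`."""
    labels, votes = classify_tiles_cascade([tile], tumor_model, egfr_model, config)
    return labels[0], votes[0]


def build_stage2_training_set(
    slides: Sequence[tuple[SlideImage, str]],
    tumor_model: TileClassifier,
    config: CascadeConfig = CascadeConfig(),
    rois: dict[str, Sequence[RoiRect]] | None = None,
    tile_size: int = 299,
) -> list[tuple[TileRecord, str]]:
    """Weakly labeled stage-2 training tiles.

    ``slides`` pairs each slide with its slide-level mutational status
    ("EGFR" or "WT").  Every tile the tumor model calls cancerous with
    probability >= ``stage2_inclusion_gate`` is kept and labeled with its
    slide's status; individual tiles may well not carry the mutation —
    this label noise is intrinsic to the weak-labeling strategy.
    """
    out: list[tuple[TileRecord, str]] = []
    for slide, status in slides:
        if status not in EGFR_CLASSES:
            raise ValidationError(f"slide status must be one of {EGFR_CLASSES}, got {status!r}")
        tiles = tile_slide(slide, tile_size, rois.get(slide.slide_id) if rois else None)
        if not tiles:
            continue
        probs = tumor_model.predict_proba(tiles)
        for tile, p in zip(tiles, probs):
            if p[1] >= config.stage2_inclusion_gate:
                out.append((tile, status))
    if not out:
        warnings.warn("no tiles passed the stage-2 inclusion gate", stacklevel=2)
    return out


def run_slide(
    slide: SlideImage,
    tumor_model: TileClassifier,
    egfr_model: TileClassifier,
    config: CascadeConfig = CascadeConfig(),
    tile_size: int = 299,
    rois: Sequence[RoiRect] | None = None,
    background_filter: bool = False,
    saturation_threshold: float = 0.08,
    tissue_fraction: float = 0.10,
):
    """Tile a slide, run the cascade, and reassemble the label grid.

    Background tiles (when ``background_filter`` is on) are labeled
    BACKGROUND before any model call.  Returns ``(votes, grid)`` where
    ``votes`` is the per-tissue-tile list of stage-vote dicts.
    """
    tiles = tile_slide(slide, tile_size, rois)
    background_cells = []
    tissue_tiles = []
    for t in tiles:
        if background_filter and is_background(t, saturation_threshold, tissue_fraction):
            background_cells.append(t.cell)
        else:
            tissue_tiles.append(t)

    labels, votes = classify_tiles_cascade(tissue_tiles, tumor_model, egfr_model, config)
    grid = reassemble_grid(
        slide,
        {t.cell: lab for t, lab in zip(tissue_tiles, labels)},
        tile_size,
        background_cells=background_cells,
    )
    return votes, grid


def read_vote_table(path, config: CascadeConfig = CascadeConfig()) -> list[dict[str, TileVote]]:
    """Read a per-slide TSV vote table back into stage-vote records."""
    import csv

    records: list[dict[str, TileVote]] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            thr = config.vote_confidence_threshold
            p1 = (float(row["p_healthy"]), float(row["p_cancerous"]))
            rec = {
                "tumor": TileVote(
                    row["slide_id"], int(row["grid_row"]), int(row["grid_col"]),
                    "tumor", TUMOR_CLASSES, p1, max(p1),
                    TUMOR_CLASSES[int(np.argmax(p1))], max(p1) <= thr,
                )
            }
            if row["p_wt"]:
                p2 = (float(row["p_wt"]), float(row["p_egfr"]))
                rec["egfr"] = TileVote(
                    row["slide_id"], int(row["grid_row"]), int(row["grid_col"]),
                    "egfr", EGFR_CLASSES, p2, max(p2),
                    EGFR_CLASSES[int(np.argmax(p2))], max(p2) <= thr,
                )
            records.append(rec)
    return records


def write_vote_table(path, votes: Sequence[dict[str, TileVote]], labels: Sequence[Label] | None = None) -> None:
    """TSV audit table: one row per tile with both stages' probabilities."""
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(
            [
                "slide_id", "grid_row", "grid_col",
                "p_healthy", "p_cancerous", "tumor_confidence",
                "p_wt", "p_egfr", "egfr_confidence", "label",
            ]
        )
        for i, record in enumerate(votes):
            v1 = record["tumor"]
            v2 = record.get("egfr")
            w.writerow(
                [
                    v1.slide_id, v1.grid_row, v1.grid_col,
                    f"{v1.probabilities[0]:.6f}", f"{v1.probabilities[1]:.6f}", f"{v1.confidence:.6f}",
                    f"{v2.probabilities[0]:.6f}" if v2 else "",
                    f"{v2.probabilities[1]:.6f}" if v2 else "",
                    f"{v2.confidence:.6f}" if v2 else "",
                    str(labels[i]) if labels is not None else "",
                ]
            )
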