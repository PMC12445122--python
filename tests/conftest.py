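"""Shared fixtures: deterministic tiles, stub classifiers, tiny cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from wsicascade import (
    EGFR_CLASSES,
    TUMOR_CLASSES,
    SlideImage,
    TileClassifier,
    TileRecord,
)


def make_tile(
    color=(200, 120, 180),
    size: int = 299,
    slide_id: str = "s",
    row: int = 0,
    col: int = 0,
    noise_rng: np.random.Generator | None = None,
    noise_sd: float = 0.0,
) -> TileRecord:
    px = np.full((size, size, 3), color, dtype=np.float64)
    if noise_rng is not None and noise_sd > 0:
        px = px + noise_rng.normal(0, noise_sd, px.shape)
    return TileRecord(
        slide_id=slide_id,
        grid_row=row,
        grid_col=col,
        origin_x=col * size,
        origin_y=row * size,
        pixels=np.clip(px, 0, 255).astype(np.uint8),
    )


class StubClassifier(TileClassifier):
    """Emits a fixed probability pair per tile cell and counts calls."""

    def __init__(self, class_names, probs_by_cell, default=(0.5, 0.5)):
        self.class_names = tuple(class_names)
        self.probs_by_cell = dict(probs_by_cell)
        self.default = default
        self.n_calls = 0
        self.tiles_seen: list[tuple[int, int]] = []

    def predict_proba(self, tiles):
        self.n_calls += 1
        out = []
        for t in tiles:
            cell = t.cell if isinstance(t, TileRecord) else None
            self.tiles_seen.append(cell)
            out.append(self.probs_by_cell.get(cell, self.default))
        return np.asarray(out, dtype=np.float64)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def tumor_stub():
    def build(probs_by_cell, default=(0.5, 0.5)):
        return StubClassifier(TUMOR_CLASSES, probs_by_cell, default)

    return build


@pytest.fixture
def egfr_stub():
    def build(probs_by_cell, default=(0.5, 0.5)):
        return StubClassifier(EGFR_CLASSES, probs_by_cell, default)

    return build


@pytest.fixture(scope="session")
def small_spec():
    """Tiny synthetic cohort spec (46 px tiles) shared across tests."""
    from wsicascade import SyntheticCohortSpec

    return SyntheticCohortSpec(
        n_egfr_slides=3, n_wt_slides=3, grid_shape=(3, 3), tile_size=46, rng_seed=7
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    from wsicascade import generate_cohort

    return generate_cohort(small_spec)


@pytest.fixture(scope="session")
def small_oracles(small_spec):
    from wsicascade import oracle_models

    return oracle_models(small_spec)
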