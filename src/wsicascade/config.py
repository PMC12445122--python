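"""Pipeline configuration: one YAML-serializable object holding every knob.

All thresholds of the decision logic live here (and only here): the
stage-2 training inclusion gate (0.95), the vote-confidence threshold
(0.90), the AI-mutation Ratio slide threshold (0.25), the tile size (299)
and the number of fused explanation layers (10).  Stage logic receives
them through this object, never as hard-coded literals.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .backbone import TrainingConfig
from .cascade import CascadeConfig
from .errors import ValidationError
from .preprocess import AugmentationConfig
from .synthetic import SyntheticCohortSpec


@dataclass(frozen=True)
class CohortConfig:
    """Synthetic-cohort parameters (see :class:`SyntheticCohortSpec`)."""

    n_egfr_slides: int = 30
    n_wt_slides: int = 30
    grid_rows: int = 5
    grid_cols: int = 5
    tumor_fraction: float = 0.6
    egfr_mutant_beta: tuple[float, float] = (8.0, 2.0)
    wt_mutant_beta: tuple[float, float] = (1.0, 9.0)
    n_centers: int = 3
    n_train_slides_per_class: int = 8
    n_train_tiles_per_class: int = 100
    n_val_tiles_per_class: int = 30


@dataclass(frozen=True)
class TrainSection:
    """Surrogate-backbone training settings for both cascade stages."""

    learning_rate: float = 0.05
    momentum: float = 0.9
    batch_size: int = 32
    max_epochs: int = 30
    patience: int = 5
    channels: tuple[int, ...] = (8, 16)
    augment: bool = False


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    tile_size: int = 299
    cohort: CohortConfig = field(default_factory=CohortConfig)
    train: TrainSection = field(default_factory=TrainSection)
    stage2_inclusion_gate: float = 0.95
    vote_confidence_threshold: float = 0.90
    ratio_threshold: float = 0.25
    heatmap_block: int = 8
    explain_n_layers: int = 10
    explain_top_k: int = 3
    n_heatmap_slides: int = 3

    def __post_init__(self) -> None:
        if self.seed < 0 or self.seed >= 2**31:
            raise ValidationError("seed must fit in a signed 32-bit integer")
        if not 0.0 < self.ratio_threshold < 1.0:
            raise ValidationError("ratio_threshold must lie in (0, 1)")
        # delegate range checks
        self.cascade_config()

    # ---- derived objects -------------------------------------------------

    def derived_seed(self, salt: int) -> int:
        """Declared seed derivation: every stage seed comes from the global
        seed through a SeedSequence with a stage-specific salt."""
        return int(np.random.SeedSequence([self.seed, salt]).generate_state(1)[0] % (2**31))

    def cohort_spec(self) -> SyntheticCohortSpec:
        c = self.cohort
        return SyntheticCohortSpec(
            n_egfr_slides=c.n_egfr_slides,
            n_wt_slides=c.n_wt_slides,
            grid_shape=(c.grid_rows, c.grid_cols),
            tile_size=self.tile_size,
            tumor_fraction=c.tumor_fraction,
            egfr_mutant_beta=c.egfr_mutant_beta,
            wt_mutant_beta=c.wt_mutant_beta,
            n_centers=c.n_centers,
            rng_seed=self.derived_seed(1),
        )

    def training_cohort_spec(self) -> SyntheticCohortSpec:
        """Disjoint training cohort used only for stage-2 weak labeling."""
        c = self.cohort
        return SyntheticCohortSpec(
            n_egfr_slides=c.n_train_slides_per_class,
            n_wt_slides=c.n_train_slides_per_class,
            grid_shape=(c.grid_rows, c.grid_cols),
            tile_size=self.tile_size,
            tumor_fraction=c.tumor_fraction,
            egfr_mutant_beta=c.egfr_mutant_beta,
            wt_mutant_beta=c.wt_mutant_beta,
            n_centers=c.n_centers,
            rng_seed=self.derived_seed(2),
        )

    def cascade_config(self) -> CascadeConfig:
        return CascadeConfig(
            stage2_inclusion_gate=self.stage2_inclusion_gate,
            vote_confidence_threshold=self.vote_confidence_threshold,
        )

    def training_config(self, stage: str) -> TrainingConfig:
        salt = {"tumor": 3, "egfr": 4}[stage]
        return TrainingConfig(
            learning_rate=self.train.learning_rate,
            momentum=self.train.momentum,
            batch_size=self.train.batch_size,
            max_epochs=self.train.max_epochs,
            patience=self.train.patience,
            rng_seed=self.derived_seed(salt),
        )

    def augmentation_config(self, stage: str) -> AugmentationConfig | None:
        if not self.train.augment:
            return None
        return AugmentationConfig.tumor() if stage == "tumor" else AugmentationConfig.egfr()

    # ---- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "cohort" in d and isinstance(d["cohort"], dict):
            c = dict(d["cohort"])
            for k in ("egfr_mutant_beta", "wt_mutant_beta"):
                if k in c and isinstance(c[k], list):
                    c[k] = tuple(c[k])
            d["cohort"] = CohortConfig(**c)
        if "train" in d and isinstance(d["train"], dict):
            t = dict(d["train"])
            if "channels" in t and isinstance(t["channels"], list):
                t["channels"] = tuple(t["channels"])
            d["train"] = TrainSection(**t)
        try:
            return cls(**d)
        except TypeError as e:
            raise ValidationError(f"invalid configuration: {e}") from e

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]
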