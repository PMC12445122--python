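"""End-to-end orchestration of the cascade workflow on synthetic cohorts.

Stages mirror the deployment workflow: simulate a multi-center cohort,
train the two surrogate tile classifiers (stage 1 on ROI-style labeled
tiles, stage 2 on weakly labeled tiles passing the 0.95 tumor gate), run
the cascade over every evaluation slide, aggregate AI-mutation Ratios at
the slide threshold, evaluate tile- and slide-level metrics, render
heatmaps and HD-CAM explanations.  A run directory receives every
artifact plus an immutable manifest (config hash, seed, package version).
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import __version__
from .aggregate import (
    RatioComparison,
    SlideSummary,
    classify_slide,
    compare_ratio_distributions,
    compute_mutation_ratio,
    write_slide_table,
)
from .backbone import (
    EGFR_CLASSES,
    TUMOR_CLASSES,
    SmallConvNet,
    TileClassifier,
    train_classifier,
)
from .cascade import build_stage2_training_set, run_slide, write_vote_table
from .config import PipelineConfig
from .errors import DependencyError, ValidationError
from .explain import hd_cam, select_top_confident_correct
from .heatmap import render_heatmap, smooth_label_grid
from .metrics import MetricsReport, compute_metrics, confusion
from .synthetic import (
    SyntheticSlide,
    generate_cohort,
    generate_labeled_tiles,
    oracle_models,
    write_manifest,
)
from .tiles import Label


@dataclass
class PipelineResult:
    """Everything a run computes, plus where artifacts were written."""

    config: PipelineConfig
    slide_summaries: list[SlideSummary] = field(default_factory=list)
    slide_metrics: MetricsReport | None = None
    tile_metrics: MetricsReport | None = None
    ratio_comparison: RatioComparison | None = None
    slide_accuracy: float | None = None
    training_history: dict = field(default_factory=dict)
    out_dir: Path | None = None


def _stage1_sets(config: PipelineConfig):
    """ROI-style labeled tiles for the tumor classifier (healthy vs cancerous)."""
    spec = config.cohort_spec()
    n_train = config.cohort.n_train_tiles_per_class
    n_val = config.cohort.n_val_tiles_per_class
    # cancerous tiles mix both tumor morphologies evenly
    half_t, half_v = n_train // 2, n_val // 2
    tiles = generate_labeled_tiles(
        spec, n_train + n_val, classes=(Label.HEALTHY,), seed_salt=101
    )
    tiles += generate_labeled_tiles(spec, half_t + half_v, classes=(Label.WT,), seed_salt=102)
    tiles += generate_labeled_tiles(spec, half_t + half_v, classes=(Label.EGFR,), seed_salt=103)

    def to_stage1(lab: Label) -> str:
        return TUMOR_CLASSES[0] if lab == Label.HEALTHY else TUMOR_CLASSES[1]

    healthy = [(t, to_stage1(l)) for t, l in tiles if l == Label.HEALTHY]
    wt = [(t, to_stage1(l)) for t, l in tiles if l == Label.WT]
    eg = [(t, to_stage1(l)) for t, l in tiles if l == Label.EGFR]
    train = healthy[:n_train] + wt[:half_t] + eg[:half_t]
    val = healthy[n_train:] + wt[half_t:] + eg[half_t:]
    return train, val


def train_models(config: PipelineConfig) -> tuple[TileClassifier, TileClassifier, dict]:
    """Train the surrogate tumor and EGFR classifiers per the config."""
    builder = lambda names, seed: SmallConvNet(
        names, channels=config.train.channels, input_size=config.tile_size, seed=seed
    )
    train1, val1 = _stage1_sets(config)
    tumor_model, hist1 = train_classifier(
        train1,
        val1,
        config.training_config("tumor"),
        augment=config.augmentation_config("tumor"),
        builder=builder,
        class_names=TUMOR_CLASSES,
    )

    # stage 2: weak labels from training slides through the inclusion gate
    train_slides, _ = generate_cohort(config.training_cohort_spec())
    pairs = [(s.image(), s.true_status) for s in train_slides]
    weak = build_stage2_training_set(
        pairs, tumor_model, config.cascade_config(), tile_size=config.tile_size
    )
    if len(weak) < 4 or len({lab for _, lab in weak}) < 2:
        raise ValidationError(
            "stage-2 training set is too small: the tumor classifier passes "
            f"{len(weak)} tiles at the {config.stage2_inclusion_gate} inclusion "
            "gate; train stage 1 longer (more epochs/tiles) or add training slides"
        )
    rng = np.random.default_rng(config.derived_seed(5))
    order = rng.permutation(len(weak))
    n_val2 = max(len(weak) // 5, 2)
    val2 = [weak[i] for i in order[:n_val2]]
    train2 = [weak[i] for i in order[n_val2:]]
    egfr_model, hist2 = train_classifier(
        train2,
        val2,
        config.training_config("egfr"),
        augment=config.augmentation_config("egfr"),
        builder=builder,
        class_names=EGFR_CLASSES,
    )
    return tumor_model, egfr_model, {"tumor": hist1, "egfr": hist2}


def evaluate_cohort(
    config: PipelineConfig,
    slides: Sequence[SyntheticSlide],
    tumor_model: TileClassifier,
    egfr_model: TileClassifier,
    out_dir: Path | None = None,
    n_heatmaps: int = 0,
) -> PipelineResult:
    """Run the cascade over a cohort and aggregate to slide level."""
    cconf = config.cascade_config()
    result = PipelineResult(config=config)
    tile_true: list[str] = []
    tile_pred: list[str] = []
    tile_conf: list[float] = []
    grids = []

    for slide in slides:
        img = slide.image()
        votes, grid = run_slide(img, tumor_model, egfr_model, cconf, tile_size=config.tile_size)
        grids.append(grid)
        summary = compute_mutation_ratio(
            votes, slide_id=slide.slide_id, config=cconf, true_label=slide.true_status
        )
        result.slide_summaries.append(classify_slide(summary, config.ratio_threshold))

        # tile-level tumor-gate evaluation: stage-1 votes against the
        # planted truth, low-confidence votes filtered out downstream
        for record in votes:
            v1 = record["tumor"]
            truth = slide.truth.cells[v1.grid_row, v1.grid_col]
            tile_true.append("healthy" if truth == Label.HEALTHY else "cancerous")
            tile_pred.append(v1.decision)
            tile_conf.append(v1.confidence)
        if out_dir is not None:
            write_vote_table(out_dir / f"votes_{slide.slide_id}.tsv", votes)

    # slide-level metrics on determinate slides (positive class: EGFR)
    det = [s for s in result.slide_summaries if s.predicted_label != "UNDETERMINED"]
    if det:
        cm, _ = confusion(
            [s.true_label for s in det], [s.predicted_label for s in det], Label.EGFR.value
        )
        ratios = [s.ai_mutation_ratio for s in det]
        truth01 = [1 if s.true_label == Label.EGFR.value else 0 for s in det]
        if len(set(truth01)) == 2:
            result.slide_metrics = compute_metrics(cm, scores=ratios, labels=truth01, level="slide")
        else:
            result.slide_metrics = compute_metrics(cm, level="slide")
        result.slide_accuracy = result.slide_metrics.accuracy

    if tile_true and len(set(tile_true)) == 2:
        cm_t, n_abs = confusion(
            tile_true,
            tile_pred,
            "cancerous",
            confidences=tile_conf,
            confidence_threshold=config.vote_confidence_threshold,
        )
        if cm_t.total:
            result.tile_metrics = compute_metrics(cm_t, n_abstained=n_abs, level="tile")

    egfr_ratios = [
        s.ai_mutation_ratio
        for s in result.slide_summaries
        if s.true_label == "EGFR" and s.ai_mutation_ratio is not None
    ]
    wt_ratios = [
        s.ai_mutation_ratio
        for s in result.slide_summaries
        if s.true_label == "WT" and s.ai_mutation_ratio is not None
    ]
    if egfr_ratios and wt_ratios:
        result.ratio_comparison = compare_ratio_distributions(egfr_ratios, wt_ratios)

    if out_dir is not None:
        write_slide_table(out_dir / "slide_summaries.tsv", result.slide_summaries)
        for grid in grids[:n_heatmaps]:
            smoothed = smooth_label_grid(grid)
            render = render_heatmap(smoothed, config.heatmap_block)
            render.save(
                out_dir / f"heatmap_{grid.slide_id}.png",
                out_dir / f"heatmap_{grid.slide_id}.json",
            )
    return result


def explain_slide(
    config: PipelineConfig,
    slide: SyntheticSlide,
    egfr_model: TileClassifier,
    out_dir: Path | None = None,
):
    """HD-CAM explanations for the top confident correct stage-2 tiles."""
    pairs = slide.truth_tiles()
    tumor_tiles = [(t, lab) for t, lab in pairs if lab in (Label.EGFR, Label.WT)]
    if not tumor_tiles:
        return []
    probs = egfr_model.predict_proba([t for t, _ in tumor_tiles])
    from .cascade import _make_vote  # reuse the vote constructor

    votes = [
        (_make_vote(t, "egfr", EGFR_CLASSES, p, config.vote_confidence_threshold), lab.value)
        for (t, lab), p in zip(tumor_tiles, probs)
    ]
    selected = select_top_confident_correct(votes, config.explain_top_k)
    by_cell = {t.cell: t for t, _ in tumor_tiles}
    results = []
    for v in selected:
        tile = by_cell[v.cell]
        res = hd_cam(egfr_model, tile, target_class=v.decision, n_layers=config.explain_n_layers)
        results.append(res)
        if out_dir is not None:
            from PIL import Image

            cam8 = (res.combined * 255).astype(np.uint8)
            Image.fromarray(tile.pixels).save(out_dir / f"tile_{slide.slide_id}_{v.grid_row}_{v.grid_col}.png")
            Image.fromarray(cam8).save(out_dir / f"hdcam_{slide.slide_id}_{v.grid_row}_{v.grid_col}.png")
    if out_dir is not None and results:
        (out_dir / "hdcam_meta.json").write_text(
            json.dumps(
                {
                    "n_layers": len(results[0].layer_maps),
                    "fusion_weights": list(results[0].fusion_weights),
                    "layers": [m.layer for m in results[0].layer_maps],
                },
                indent=2,
            )
        )
    return results


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path,
    use_oracles: bool = False,
    with_explanations: bool = True,
) -> PipelineResult:
    """Full workflow: simulate -> train -> infer -> aggregate -> evaluate.

    With ``use_oracles`` the trained surrogates are replaced by the
    rule-based oracle classifiers (planted-truth recovery mode).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    spec = config.cohort_spec()
    slides, manifest = generate_cohort(spec)
    write_manifest(out / "cohort_manifest.tsv", manifest)
    config.to_yaml(out / "config.yaml")

    history: dict = {}
    if use_oracles:
        tumor_model, egfr_model = oracle_models(spec)
    else:
        tumor_model, egfr_model, history = train_models(config)
        tumor_model.save(out / "tumor_model.npz")
        egfr_model.save(out / "egfr_model.npz")

    result = evaluate_cohort(
        config, slides, tumor_model, egfr_model, out_dir=out, n_heatmaps=config.n_heatmap_slides
    )
    result.training_history = history
    result.out_dir = out

    if with_explanations and not use_oracles and slides:
        egfr_slides = [s for s in slides if s.true_status == "EGFR"]
        explain_slide(config, egfr_slides[0] if egfr_slides else slides[0], egfr_model, out)

    summary = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "python": platform.python_version(),
        "n_slides": len(slides),
        "slide_accuracy": result.slide_accuracy,
        "slide_metrics": result.slide_metrics.as_dict() if result.slide_metrics else None,
        "tile_metrics": result.tile_metrics.as_dict() if result.tile_metrics else None,
        "wilcoxon_p": result.ratio_comparison.p_value if result.ratio_comparison else None,
        "use_oracles": use_oracles,
    }
    (out / "manifest.json").write_text(json.dumps(summary, indent=2))
    return result


def require_artifact(path: Path, producing_stage: str) -> Path:
    """Dependency check used by the CLI."""
    if not Path(path).exists():
        raise DependencyError(f"missing artifact {path}; run the {producing_stage!r} stage first")
    return Path(path)
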