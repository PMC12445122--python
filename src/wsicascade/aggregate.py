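"""Slide-level aggregation: AI-mutation Ratio, thresholding, group comparison.

The AI-mutation Ratio of a slide is the proportion of confidently
classified tumor tiles called EGFR:

    ratio = n_egfr / (n_egfr + n_wt)

A slide is called EGFR-mutated when its ratio reaches the classification
threshold (default 0.25, inclusive); the low threshold — relative to
majority voting — accounts for intratumoral heterogeneity, where only part
of a mutated tumor expresses recognizable mutant morphology.  Ratio
distributions of the EGFR and WT slide groups are compared with a
two-sided Wilcoxon rank-sum test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .cascade import CascadeConfig, TileVote, final_label, voting_label
from .errors import ValidationError
from .tiles import Label, LabelGrid

UNDETERMINED = "UNDETERMINED"

#: default slide-call threshold on the AI-mutation Ratio
RATIO_THRESHOLD = 0.25


@dataclass(frozen=True)
class SlideSummary:
    """Per-slide tallies, AI-mutation Ratio and labels."""

    slide_id: str
    n_healthy: int
    n_egfr: int
    n_wt: int
    n_abstain: int
    n_background: int
    ai_mutation_ratio: float | None
    predicted_label: str = UNDETERMINED
    true_label: str | None = None


def _labels_from(source) -> tuple[str, list[Label]]:
    """Accept a LabelGrid, a (slide_id, labels) pair, or vote records."""
    if isinstance(source, LabelGrid):
        return source.slide_id, [lab for lab in source.cells.flat]
    raise ValidationError("unsupported vote source")


def compute_mutation_ratio(
    votes: Sequence[dict[str, TileVote]] | Sequence[Label] | LabelGrid,
    slide_id: str | None = None,
    config: CascadeConfig = CascadeConfig(),
    true_label: str | None = None,
) -> SlideSummary:
    """Tally cascade labels for one slide and form the AI-mutation Ratio.

    ``votes`` may be the per-tile stage-vote records from the cascade, a
    plain sequence of final labels, or a reassembled :class:`LabelGrid`.
    With stage-vote records and the default config, every tumor tile's
    argmax vote counts toward the ratio (plain voting); with
    ``config.abstain_excluded_from_ratio`` — or with label/grid input,
    where low-confidence tiles already carry ABSTAIN — only confident
    votes enter numerator and denominator.  ``n_abstain`` always counts
    the low-confidence tiles.  The ratio is undefined (and the slide
    UNDETERMINED) when no tumor vote exists.
    """
    n_abstain: int | None = None  # set explicitly on the stage-vote path
    if isinstance(votes, LabelGrid):
        sid, labels = _labels_from(votes)
        if slide_id is not None and slide_id != sid:
            raise ValidationError("slide_id does not match the grid")
        slide_id = sid
    else:
        votes = list(votes)
        if votes and isinstance(votes[0], dict):
            sids = {v["tumor"].slide_id for v in votes}
            if len(sids) > 1:
                raise ValidationError(f"votes span multiple slides: {sorted(sids)}")
            inferred = sids.pop()
            if slide_id is not None and slide_id != inferred:
                raise ValidationError("slide_id does not match the votes")
            slide_id = inferred
            final = [final_label(v, config) for v in votes]
            n_abstain = sum(1 for lab in final if lab == Label.ABSTAIN)
            # plain voting counts every argmax decision; the strict variant
            # drops low-confidence tiles from the tally as well
            labels = final if config.abstain_excluded_from_ratio else [voting_label(v) for v in votes]
        else:
            labels = [Label(v) for v in votes]
        if slide_id is None:
            raise ValidationError("slide_id required when votes carry no identity")

    n = {lab: 0 for lab in Label}
    for lab in labels:
        n[lab] += 1
    if n_abstain is None:
        n_abstain = n[Label.ABSTAIN]

    denom = n[Label.EGFR] + n[Label.WT]
    ratio = n[Label.EGFR] / denom if denom > 0 else None
    return SlideSummary(
        slide_id=slide_id,
        n_healthy=n[Label.HEALTHY],
        n_egfr=n[Label.EGFR],
        n_wt=n[Label.WT],
        n_abstain=n_abstain,
        n_background=n[Label.BACKGROUND] + n[Label.EMPTY],
        ai_mutation_ratio=ratio,
        predicted_label=UNDETERMINED,
        true_label=true_label,
    )


def classify_slide(summary: SlideSummary, threshold: float = RATIO_THRESHOLD) -> SlideSummary:
    """Slide call from the AI-mutation Ratio at an inclusive threshold.

    ratio >= threshold -> EGFR; ratio < threshold -> WT; undefined ratio
    -> UNDETERMINED.  Returns a summary with ``predicted_label`` filled.
    """
    if not 0.0 < threshold < 1.0:
        raise ValidationError("threshold must lie in (0, 1)")
    if summary.ai_mutation_ratio is None:
        label = UNDETERMINED
    elif summary.ai_mutation_ratio >= threshold:
        label = str(Label.EGFR)
    else:
        label = str(Label.WT)
    return replace(summary, predicted_label=label)


@dataclass(frozen=True)
class RatioComparison:
    """Two-sided Wilcoxon rank-sum comparison of slide-ratio groups."""

    egfr_ratios: tuple[float, ...]
    wt_ratios: tuple[float, ...]
    statistic: float  # Mann-Whitney U of the EGFR group
    p_value: float
    method: str  # "exact" | "normal_approximation"
    degenerate: bool = False


def compare_ratio_distributions(
    egfr_ratios: Sequence[float], wt_ratios: Sequence[float]
) -> RatioComparison:
    """Wilcoxon rank-sum test between EGFR-slide and WT-slide ratios.

    Uses the exact null distribution when both groups have <= 8
    observations and no cross-group ties; otherwise the normal
    approximation with tie correction.  Two identical constant groups are
    flagged degenerate with p = 1.
    """
    x = np.asarray(egfr_ratios, dtype=np.float64)
    y = np.asarray(wt_ratios, dtype=np.float64)
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("both groups must be non-empty")

    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return RatioComparison(
            tuple(x), tuple(y), statistic=len(x) * len(y) / 2.0, p_value=1.0,
            method="degenerate", degenerate=True,
        )

    has_ties = len(np.unique(pooled)) < len(pooled)
    exact = len(x) <= 8 and len(y) <= 8 and not has_ties
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return RatioComparison(
        tuple(x), tuple(y),
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        method="exact" if exact else "normal_approximation",
    )


def summarize_slides(
    per_slide: Iterable[tuple[str, Sequence[Label], str | None]],
    threshold: float = RATIO_THRESHOLD,
) -> list[SlideSummary]:
    """Batch helper: (slide_id, labels, true_label) -> classified summaries."""
    out = []
    for slide_id, labels, truth in per_slide:
        s = compute_mutation_ratio(list(labels), slide_id=slide_id, true_label=truth)
        out.append(classify_slide(s, threshold))
    return out


def write_slide_table(path, summaries: Sequence[SlideSummary]) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(
            [
                "slide_id", "n_healthy", "n_egfr", "n_wt", "n_abstain", "n_background",
                "ai_mutation_ratio", "predicted_label", "true_label",
            ]
        )
        for s in summaries:
            w.writerow(
                [
                    s.slide_id, s.n_healthy, s.n_egfr, s.n_wt, s.n_abstain, s.n_background,
                    "" if s.ai_mutation_ratio is None else f"{s.ai_mutation_ratio:.6f}",
                    s.predicted_label, s.true_label or "",
                ]
            )
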