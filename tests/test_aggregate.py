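"""AI-mutation Ratio, slide thresholding and the rank-sum comparison."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wsicascade import (
    CascadeConfig,
    Label,
    ValidationError,
    classify_slide,
    compare_ratio_distributions,
    compute_mutation_ratio,
)
from wsicascade.aggregate import UNDETERMINED
from wsicascade.cascade import TileVote


def labels_of(n_egfr=0, n_wt=0, n_healthy=0, n_abstain=0):
    return (
        [Label.EGFR] * n_egfr
        + [Label.WT] * n_wt
        + [Label.HEALTHY] * n_healthy
        + [Label.ABSTAIN] * n_abstain
    )


def vote_record(slide_id, row, col, tumor_p, egfr_p=None, thr=0.90):
    def mk(stage, names, p):
        k = int(np.argmax(p))
        return TileVote(slide_id, row, col, stage, names, tuple(p), p[k], names[k], p[k] <= thr)

    rec = {"tumor": mk("tumor", ("healthy", "cancerous"), tumor_p)}
    if egfr_p is not None:
        rec["egfr"] = mk("egfr", ("WT", "EGFR"), egfr_p)
    return rec


class TestMutationRatio:
    def test_proportion_semantics(self):
        s = compute_mutation_ratio(labels_of(n_egfr=63, n_wt=37), slide_id="a")
        assert s.ai_mutation_ratio == pytest.approx(0.63)

    def test_zero_mutant(self):
        s = compute_mutation_ratio(labels_of(n_wt=50), slide_id="a")
        assert s.ai_mutation_ratio == 0.0

    def test_degenerate_slide_is_undetermined(self):
        s = compute_mutation_ratio(labels_of(n_healthy=40), slide_id="a")
        assert s.ai_mutation_ratio is None
        assert classify_slide(s).predicted_label == UNDETERMINED

    def test_mixed_slide_ids_rejected(self):
        votes = [
            vote_record("a", 0, 0, (0.1, 0.9), (0.1, 0.9)),
            vote_record("b", 0, 1, (0.1, 0.9), (0.1, 0.9)),
        ]
        with pytest.raises(ValidationError):
            compute_mutation_ratio(votes)

    def test_plain_voting_counts_low_confidence_argmax(self):
        """Default: argmax decisions vote; abstentions tallied separately."""
        votes = [
            vote_record("a", 0, 0, (0.05, 0.95), (0.2, 0.8)),  # EGFR vote, low conf
            vote_record("a", 0, 1, (0.05, 0.95), (0.95, 0.05)),  # confident WT
            vote_record("a", 0, 2, (0.97, 0.03)),  # healthy
        ]
        s = compute_mutation_ratio(votes)
        assert (s.n_egfr, s.n_wt, s.n_healthy, s.n_abstain) == (1, 1, 1, 1)
        assert s.ai_mutation_ratio == pytest.approx(0.5)

    def test_strict_config_drops_abstained_from_ratio(self):
        votes = [
            vote_record("a", 0, 0, (0.05, 0.95), (0.2, 0.8)),
            vote_record("a", 0, 1, (0.05, 0.95), (0.95, 0.05)),
        ]
        cfg = CascadeConfig(abstain_excluded_from_ratio=True)
        s = compute_mutation_ratio(votes, config=cfg)
        assert (s.n_egfr, s.n_wt, s.n_abstain) == (0, 1, 1)
        assert s.ai_mutation_ratio == 0.0

    @given(k=st.integers(min_value=1, max_value=20))
    @settings(max_examples=20, deadline=None)
    def test_ratio_scale_free(self, k):
        base = compute_mutation_ratio(labels_of(n_egfr=3, n_wt=5), slide_id="a")
        scaled = compute_mutation_ratio(labels_of(n_egfr=3 * k, n_wt=5 * k), slide_id="a")
        assert scaled.ai_mutation_ratio == pytest.approx(base.ai_mutation_ratio)
        assert classify_slide(scaled).predicted_label == classify_slide(base).predicted_label


class TestClassifySlide:
    @pytest.mark.parametrize(
        "ratio,expected",
        [(0.63, "EGFR"), (0.13, "WT"), (0.25, "EGFR"), (0.2499, "WT"), (0.98, "EGFR")],
    )
    def test_threshold_inclusive(self, ratio, expected):
        n = 10_000
        s = compute_mutation_ratio(
            labels_of(n_egfr=round(ratio * n), n_wt=n - round(ratio * n)), slide_id="a"
        )
        assert classify_slide(s, 0.25).predicted_label == expected

    @given(
        n_egfr=st.integers(min_value=0, max_value=50),
        n_wt=st.integers(min_value=1, max_value=50),
        t1=st.floats(min_value=0.05, max_value=0.95),
        t2=st.floats(min_value=0.05, max_value=0.95),
    )
    @settings(max_examples=60, deadline=None)
    def test_monotone_in_threshold(self, n_egfr, n_wt, t1, t2):
        """Lowering the threshold never flips an EGFR call to WT."""
        lo, hi = sorted((t1, t2))
        s = compute_mutation_ratio(labels_of(n_egfr=n_egfr, n_wt=n_wt), slide_id="a")
        if classify_slide(s, hi).predicted_label == "EGFR":
            assert classify_slide(s, lo).predicted_label == "EGFR"

    def test_invalid_threshold(self):
        s = compute_mutation_ratio(labels_of(n_egfr=1, n_wt=1), slide_id="a")
        with pytest.raises(ValidationError):
            classify_slide(s, 0.0)


def ranksum_permutation_p(x, y):
    """Independent oracle: exact two-sided p by full enumeration of group
    assignments of the pooled ranks."""
    pooled = sorted(x + y)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}  # no ties by construction
    w_obs = sum(ranks[v] for v in x)
    n = len(x)
    ws = [sum(idx) for idx in itertools.combinations(range(1, len(pooled) + 1), n)]
    mean_w = np.mean(ws)
    extreme = sum(1 for w in ws if abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-9)
    return extreme / len(ws)


class TestRatioComparison:
    def test_worked_exact_example(self):
        cmp = compare_ratio_distributions([1, 2, 3], [4, 5, 6])
        assert cmp.method == "exact"
        assert cmp.p_value == pytest.approx(0.1)

    def test_identical_groups_degenerate(self):
        cmp = compare_ratio_distributions([0.3, 0.3], [0.3, 0.3])
        assert cmp.p_value == 1.0 and cmp.degenerate

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            compare_ratio_distributions([], [0.1])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_exact_matches_full_permutation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = list(rng.permutation(20)[:4].astype(float))
        y = list(rng.permutation(40)[:4].astype(float) + 0.5)
        cmp = compare_ratio_distributions(x, y)
        assert cmp.method == "exact"
        assert cmp.p_value == pytest.approx(ranksum_permutation_p(x, y), abs=1e-12)

    @pytest.mark.parametrize("n1,n2", [(9, 9), (10, 12), (12, 8)])
    def test_normal_approximation_close_to_exact(self, n1, n2):
        from scipy import stats

        rng = np.random.default_rng(5)
        x = list(rng.normal(0.6, 0.2, n1))
        y = list(rng.normal(0.4, 0.2, n2))
        cmp = compare_ratio_distributions(x, y)
        assert cmp.method == "normal_approximation"
        exact = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
        assert abs(cmp.p_value - exact) < 0.02
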