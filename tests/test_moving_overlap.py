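"""Moving overlap enrichment vs an explicit set-enumeration oracle."""

import numpy as np
import pandas as pd
import pytest

from _oracles import brute_force_scores
from pol3atlas.moving_overlap import (
    RankedList,
    max_enrichment_scores,
    moving_overlap,
    permutation_null,
    ranked_list_from_scores,
    select_enhanced,
)


def _random_lists(rng, g, k, min_len=None):
    genes = [f"g{i:03d}" for i in range(g)]
    lists = []
    for j in range(k):
        length = int(rng.integers(min_len or max(2, g // 2), g + 1))
        order = rng.permutation(g)[:length]
        lists.append(
            RankedList(f"exp{j}", [genes[i] for i in order], g)
        )
    return lists


class TestMovingOverlap:
    def test_two_list_worked_example(self):
        # G=10, top-3 sets share 2 genes: expected 0.9, enrichment 2/0.9
        a = RankedList("a", ["g0", "g1", "g2", "g5"], 10)
        b = RankedList("b", ["g1", "g2", "g9", "g6"], 10)
        prof = moving_overlap([a, b], n_max=3)
        assert prof.observed[2] == 2
        assert prof.expected[2] == pytest.approx(0.9)
        assert prof.enrichment[2] == pytest.approx(2 / 0.9)

    def test_saturation_at_full_universe(self):
        genes = [f"g{i}" for i in range(8)]
        rng = np.random.default_rng(0)
        lists = [
            RankedList(f"e{j}", [genes[i] for i in rng.permutation(8)], 8)
            for j in range(3)
        ]
        prof = moving_overlap(lists)
        assert prof.observed[-1] == 8
        assert prof.expected[-1] == pytest.approx(8.0)
        assert prof.enrichment[-1] == pytest.approx(1.0)

    def test_identical_lists_closed_form(self):
        genes = [f"g{i}" for i in range(20)]
        lists = [RankedList(f"e{j}", list(genes), 20) for j in range(3)]
        prof = moving_overlap(lists)
        for n, enr in zip(prof.cutoffs, prof.enrichment):
            assert enr == pytest.approx((20 / n) ** 2)

    def test_observed_monotone_and_bounded(self):
        rng = np.random.default_rng(12)
        lists = _random_lists(rng, 40, 3)
        prof = moving_overlap(lists)
        assert np.all(np.diff(prof.observed) >= 0)
        assert np.all(prof.observed <= prof.cutoffs)

    def test_single_list_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            moving_overlap([RankedList("a", ["g0"], 5)])

    def test_universe_mismatch_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            moving_overlap(
                [RankedList("a", ["g0"], 5), RankedList("b", ["g0"], 6)]
            )

    def test_n_max_beyond_shortest_rejected(self):
        with pytest.raises(ValueError, match="n_max"):
            moving_overlap(
                [RankedList("a", ["g0"], 5), RankedList("b", ["g0", "g1"], 5)],
                n_max=2,
            )


class TestMaxEnrichmentScores:
    def test_gene_absent_from_lists_scores_zero(self):
        a = RankedList("a", ["g0", "g1"], 10)
        b = RankedList("b", ["g1", "g2"], 10)
        scores = max_enrichment_scores([a, b]).set_index("gene_id")
        assert scores.loc["g0", "max_enrichment"] == 0.0
        assert scores.loc["g0", "best_combination"] == ""

    def test_consensus_top_gene_scores_universe_power(self):
        # gene first in all k lists: observed(1)=1, expected G*(1/G)^k
        g = 25
        genes = [f"g{i}" for i in range(g)]
        rng = np.random.default_rng(3)
        lists = []
        for j in range(3):
            rest = [genes[i] for i in 1 + rng.permutation(g - 1)]
            lists.append(RankedList(f"e{j}", ["g0"] + rest, g))
        scores = max_enrichment_scores(lists).set_index("gene_id")
        assert scores.loc["g0", "max_enrichment"] >= g ** 2

    def test_planted_prefix_matches_bruteforce_exactly(self):
        rng = np.random.default_rng(42)
        g = 20
        genes = [f"g{i:03d}" for i in range(g)]
        consensus = genes[:4]
        lists = []
        for j in range(5):
            tail = [genes[i] for i in 4 + rng.permutation(g - 4)]
            head = [consensus[i] for i in rng.permutation(4)]
            lists.append(RankedList(f"e{j}", head + tail, g))
        scores = max_enrichment_scores(lists)
        oracle = brute_force_scores(lists)
        for _, row in scores.iterrows():
            exp = oracle[row["gene_id"]]
            assert row["max_enrichment"] == pytest.approx(exp[0], rel=1e-12)
            assert tuple(
                row["best_combination"].split("+") if row["best_combination"]
                else ()
            ) == exp[2]
            assert row["best_n"] == exp[3]

    def test_label_permutation_equivariance(self):
        rng = np.random.default_rng(8)
        lists = _random_lists(rng, 30, 3)
        scores = max_enrichment_scores(lists).set_index("gene_id")
        mapping = {f"g{i:03d}": f"h{(i * 7) % 30:03d}" for i in range(30)}
        relabeled = [
            RankedList(l.experiment_id, [mapping[g] for g in l.gene_ids],
                       l.universe_size)
            for l in lists
        ]
        scores2 = max_enrichment_scores(relabeled).set_index("gene_id")
        for gid, new in mapping.items():
            if gid in scores.index:
                assert scores.loc[gid, "max_enrichment"] == pytest.approx(
                    scores2.loc[new, "max_enrichment"]
                )

    def test_explicit_combination_subset(self):
        rng = np.random.default_rng(21)
        lists = _random_lists(rng, 15, 3)
        combos = [("exp0", "exp1")]
        scores = max_enrichment_scores(lists, combinations=combos)
        oracle = brute_force_scores(lists, combos=combos)
        for _, row in scores.iterrows():
            assert row["max_enrichment"] == pytest.approx(
                oracle[row["gene_id"]][0], rel=1e-12
            )

    def test_restricted_n_grid(self):
        rng = np.random.default_rng(33)
        lists = _random_lists(rng, 24, 3)
        grid = [1, 5, 9]
        scores = max_enrichment_scores(lists, n_grid=grid)
        oracle = brute_force_scores(lists, n_grid=grid)
        for _, row in scores.iterrows():
            assert row["max_enrichment"] == pytest.approx(
                oracle[row["gene_id"]][0], rel=1e-12
            )


class TestSelectEnhanced:
    def test_empty_when_all_scores_zero(self):
        scores = pd.DataFrame(
            {"gene_id": ["a"], "max_enrichment": [0.0],
             "best_combination": [""], "best_n": [0]}
        )
        assert len(select_enhanced(scores)) == 0

    def test_threshold_boundary_inclusive(self):
        scores = pd.DataFrame(
            {"gene_id": ["a", "b", "c"], "max_enrichment": [5.0, 3.0, 2.9],
             "best_combination": [""] * 3, "best_n": [0] * 3}
        )
        out = select_enhanced(scores, threshold=3)
        assert out["gene_id"].tolist() == ["a", "b"]


def test_ranked_list_from_scores_orders_losses_first():
    table = pd.DataFrame({"gene_id": ["a", "b", "c"], "score": [1.0, -2.0, 0.0]})
    rl = ranked_list_from_scores("x", table, 10)
    assert rl.gene_ids == ["b", "c", "a"]


def test_permutation_null_quantiles_stable_and_inflated():
    rng = np.random.default_rng(0)
    genes = [f"g{i:04d}" for i in range(1000)]
    lists = [
        RankedList(f"e{j}", [genes[i] for i in rng.permutation(1000)], 1000)
        for j in range(4)
    ]
    null_a = permutation_null(lists, n_permutations=100, seed=1)
    null_b = permutation_null(lists, n_permutations=100, seed=2)
    q95_a = np.quantile(null_a, 0.95)
    q95_b = np.quantile(null_b, 0.95)
    # maxima of observed/expected ratios are inflated at small cutoffs
    assert q95_a > 1.0
    assert q95_b > 1.0
    assert abs(q95_a - q95_b) / q95_a < 0.2
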