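"""Identity ratio, per-gene correlation screen and paired ratio test."""

import itertools

import numpy as np
import pytest
from scipy import stats

from pol3atlas.identity_correlation import (
    RatioSeries,
    aggregate_by_group,
    compute_ratio,
    correlate_genes,
    paired_ratio_test,
)
from pol3atlas.occupancy import RankMatrix, rank_normalize
from pol3atlas.quant import CountMatrix, SampleMeta


def _expr(g, gl, sample_ids=None, extra=None):
    sample_ids = sample_ids or [f"s{i}" for i in range(len(g))]
    gene_ids = ["POLR3G", "POLR3GL"]
    rows = [g, gl]
    if extra:
        for gid, vals in extra.items():
            gene_ids.append(gid)
            rows.append(vals)
    return CountMatrix(
        gene_ids, [SampleMeta(s, assay="rnaseq") for s in sample_ids],
        np.array(rows),
    )


def _rank_matrix(columns: np.ndarray, sample_ids, gene_ids=None) -> RankMatrix:
    gene_ids = gene_ids or [f"g{i}" for i in range(columns.shape[0])]
    return RankMatrix(
        gene_ids, [SampleMeta(s, assay="atac") for s in sample_ids], columns
    )


class TestComputeRatio:
    def test_equal_expression_gives_zero(self):
        rs = compute_ratio(_expr([4, 9], [4, 9]))
        assert rs.ratio.tolist() == [0.0, 0.0]

    def test_log2_of_four(self):
        rs = compute_ratio(_expr([8], [2]))
        assert rs.ratio[0] == 2.0

    def test_zero_denominator_excluded_with_reason(self):
        rs = compute_ratio(_expr([8, 8], [2, 0]))
        assert rs.sample_ids == ["s0"]
        assert rs.excluded == [("s1", "zero POLR3GL expression")]

    def test_pseudocount_policy_retains_all(self):
        rs = compute_ratio(_expr([8, 8], [2, 0]), zero_policy="pseudocount",
                           pseudocount=0.5)
        assert rs.sample_ids == ["s0", "s1"]
        assert rs.ratio[1] == pytest.approx(np.log2(8.5 / 0.5))

    def test_missing_gene_rejected(self):
        with pytest.raises(KeyError, match="POLR3GL"):
            compute_ratio(
                CountMatrix(["POLR3G"], [SampleMeta("s0")], np.array([[1]]))
            )


class TestCorrelateGenes:
    def test_identical_vector_gives_r_one(self):
        y = np.array([0.1, 0.4, 0.7, 1.0])
        rs = RatioSeries([f"s{i}" for i in range(4)], y)
        acc = _rank_matrix(y[None, :], rs.sample_ids)
        out = correlate_genes(rs, acc)
        assert out["r"].iloc[0] == pytest.approx(1.0)
        assert 0 < out["p"].iloc[0] <= 1e-10

    def test_orthogonal_vectors_give_zero_r(self):
        rs = RatioSeries(["a", "b", "c", "d"], np.array([1.0, -1.0, 1.0, -1.0]))
        acc = _rank_matrix(np.array([[1.0, 1.0, 0.0, 0.0]]), rs.sample_ids)
        out = correlate_genes(rs, acc)
        assert out["r"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_hand_vectors_match_scipy(self):
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([2.0, 1, 4, 3, 6])
        rs = RatioSeries([f"s{i}" for i in range(5)], x)
        acc = _rank_matrix(y[None, :] / 6.0, rs.sample_ids)
        out = correlate_genes(rs, acc)
        r_ref, p_ref = stats.pearsonr(x, y)
        assert out["r"].iloc[0] == pytest.approx(r_ref)
        assert out["p"].iloc[0] == pytest.approx(p_ref)
        assert out["r"].iloc[0] == pytest.approx(0.8220, abs=1e-4)

    def test_affine_invariance(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=8)
        mat = rng.uniform(size=(5, 8))
        rs1 = RatioSeries([f"s{i}" for i in range(8)], y)
        rs2 = RatioSeries([f"s{i}" for i in range(8)], 3.0 * y - 7.0)
        acc = _rank_matrix(mat, rs1.sample_ids)
        out1, out2 = correlate_genes(rs1, acc), correlate_genes(rs2, acc)
        assert np.allclose(out1["r"], out2["r"])

    def test_zero_variance_gene_missing_with_warning(self):
        rs = RatioSeries(["a", "b", "c"], np.array([1.0, 2.0, 3.0]))
        acc = _rank_matrix(np.array([[0.5, 0.5, 0.5]]), rs.sample_ids)
        with pytest.warns(UserWarning, match="zero-variance"):
            out = correlate_genes(rs, acc)
        assert np.isnan(out["r"].iloc[0])

    def test_fewer_than_three_matched_samples_rejected(self):
        rs = RatioSeries(["a", "b", "x"], np.zeros(3))
        acc = _rank_matrix(np.zeros((1, 2)), ["a", "b"])
        with pytest.raises(ValueError, match=">=3 matched"):
            correlate_genes(rs, acc)

    def test_id_normalizer_matches_suffixed_ids(self):
        y = np.array([0.0, 0.5, 1.0])
        rs = RatioSeries(["A_rna", "B_rna", "C_rna"], y)
        acc = _rank_matrix(y[None, :], ["A_atac", "B_atac", "C_atac"])
        out = correlate_genes(
            rs, acc, id_normalizer=lambda s: s.split("_")[0]
        )
        assert out["r"].iloc[0] == pytest.approx(1.0)

    def test_null_r_scales_as_inverse_sqrt_n(self):
        rng = np.random.default_rng(9)
        n = 16
        mat = rng.normal(size=(400, n))
        rs = RatioSeries([f"s{i}" for i in range(n)], rng.normal(size=n))
        acc = _rank_matrix(
            (mat - mat.min()) / (mat.max() - mat.min()), rs.sample_ids
        )
        out = correlate_genes(rs, acc)
        # E|r| under the null is ~ sqrt(2/pi)/sqrt(n-1)
        expected = np.sqrt(2 / np.pi) / np.sqrt(n - 1)
        assert out["r"].abs().mean() == pytest.approx(expected, rel=0.25)


class TestAggregateByGroup:
    def test_singleton_groups_match_per_sample_screen(self):
        rng = np.random.default_rng(4)
        y = rng.normal(size=4)
        mat = rng.uniform(size=(3, 4))
        ids = [f"s{i}" for i in range(4)]
        rs = RatioSeries(ids, y, grouping={s: s for s in ids})
        acc = _rank_matrix(mat, ids)
        per_sample = correlate_genes(rs, acc)
        per_group = aggregate_by_group(rs, acc)
        assert np.allclose(per_sample["r"], per_group["r"])

    def test_replicates_collapse_to_their_means(self):
        ids = [f"s{i}" for i in range(6)]
        y = np.array([1.0, 1.2, 2.0, 2.2, 3.0, 3.2])
        mat = np.array([[0.1, 0.3, 0.4, 0.6, 0.7, 0.9]])
        groups = {ids[i]: f"grp{i // 2}" for i in range(6)}
        rs = RatioSeries(ids, y, grouping=groups)
        out = aggregate_by_group(rs, _rank_matrix(mat, ids))
        r_ref, _ = stats.pearsonr([1.1, 2.1, 3.1], [0.2, 0.5, 0.8])
        assert out["r"].iloc[0] == pytest.approx(r_ref)

    def test_too_few_groups_rejected(self):
        ids = ["a", "b"]
        rs = RatioSeries(ids, np.array([1.0, 2.0]),
                         grouping={"a": "g1", "b": "g2"})
        with pytest.raises(ValueError, match=">=3 usable groups"):
            aggregate_by_group(rs, _rank_matrix(np.zeros((1, 2)), ids))


def _paired_series(diffs):
    ids, ratios, paired, cond = [], [], {}, {}
    for i, d in enumerate(diffs):
        t, n = f"t{i}", f"n{i}"
        ids += [t, n]
        ratios += [1.0 + d, 1.0]
        paired[t] = paired[n] = f"p{i}"
        cond[t], cond[n] = "tumor", "normal"
    return RatioSeries(ids, np.array(ratios), paired_id=paired, condition=cond)


class TestPairedRatioTest:
    def test_all_positive_differences_exact(self):
        res = paired_ratio_test(_paired_series([1.0, 2.0, 3.0]))
        assert res.pvalue == pytest.approx(0.25)
        # oracle: enumerate all 8 sign assignments of |d| = {1,2,3}
        stat_obs = sum(d for d in [1, 2, 3])
        tail = sum(
            1
            for signs in itertools.product([-1, 1], repeat=3)
            if abs(sum(s * d for s, d in zip(signs, [1, 2, 3]))) >= stat_obs
        )
        assert res.pvalue == pytest.approx(tail / 8)

    def test_sign_flip_same_pvalue(self):
        up = paired_ratio_test(_paired_series([1.0, 2.0, 3.0]))
        down = paired_ratio_test(_paired_series([-1.0, -2.0, -3.0]))
        assert up.pvalue == down.pvalue

    def test_degenerate_pairing_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            paired_ratio_test(_paired_series([0.0, 0.0]))

    def test_zero_differences_dropped(self):
        res = paired_ratio_test(_paired_series([0.0, 1.0, 2.0, 3.0]))
        assert res.n_pairs == 3
        assert res.pvalue == pytest.approx(0.25)

    def test_large_sample_uses_normal_approximation(self):
        rng = np.random.default_rng(6)
        diffs = rng.normal(1.0, 0.5, size=40)
        res = paired_ratio_test(_paired_series(diffs.tolist()))
        ref = stats.wilcoxon(diffs, method="approx", correction=True)
        assert res.pvalue == pytest.approx(ref.pvalue)


def test_planted_genes_dominate_correlation_screen(small_sim):
    sim = small_sim
    table = correlate_genes(
        compute_ratio(sim.expr), rank_normalize(sim.atac)
    ).set_index("gene_id")
    planted = sorted(sim.truth.enhanced_gene_ids)
    q90 = table["r"].quantile(0.9)
    assert (table.loc[planted, "r"] > q90).all()
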