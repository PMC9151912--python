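"""Differential occupancy/abundance between conditions.

Fold changes are computed on counts-per-million with a pseudocount, and
significance comes from a two-sided exact conditional binomial test: given
the total count of a gene in the two pooled conditions, the count in
condition B is Binomial(total, libB/(libA+libB)) under the null of equal
concentration. This is the dispersion->0 limit of the negative-binomial
exact test used for sequencing counts; the limitation is recorded in the
output header written by :func:`write_diff_tsv`.

Genes are ranked by "degree of loss": ascending log2 fold change, with the
cross-experiment median (or mean) used when several experiments are
combined.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .quant import CountMatrix

__all__ = [
    "log2_fold_change",
    "exact_count_test",
    "bh_adjust",
    "diff_table",
    "median_fc_rank",
    "top_fraction",
    "write_diff_tsv",
]

_CPM = 1e6


def log2_fold_change(a, b, lib_a, lib_b, pseudocount: float = 0.5):
    """log2 CPM fold change of condition B over condition A.

    ``log2(((b/lib_b)*1e6 + p) / ((a/lib_a)*1e6 + p))``; the pseudocount
    keeps the value finite at zero counts. Accepts scalars or arrays.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    lib_a = np.asarray(lib_a, dtype=float)
    lib_b = np.asarray(lib_b, dtype=float)
    if np.any(lib_a <= 0) or np.any(lib_b <= 0):
        raise ValueError("library sizes must be > 0")
    cpm_a = np.asarray(a, dtype=float) / lib_a * _CPM
    cpm_b = np.asarray(b, dtype=float) / lib_b * _CPM
    out = np.log2((cpm_b + pseudocount) / (cpm_a + pseudocount))
    return out if out.ndim else float(out)


def exact_count_test(a: int, b: int, lib_a: float, lib_b: float) -> float:
    """Two-sided exact conditional binomial test for a pair of counts.

    Conditional on n = a + b, the count b is Binomial(n, q) with
    q = lib_b/(lib_a + lib_b) under the null of equal concentration; the
    two-sided p-value sums P(X = x) over all outcomes no more probable
    than the observed one. n = 0 carries no information and returns 1.
    """
    if a < 0 or b < 0:
        raise ValueError("counts must be nonnegative")
    if lib_a <= 0 or lib_b <= 0:
        raise ValueError("library sizes must be > 0")
    n = int(a) + int(b)
    if n == 0:
        return 1.0
    q = lib_b / (lib_a + lib_b)
    p = float(stats.binomtest(int(b), n, q, alternative="two-sided").pvalue)
    # extreme outcomes underflow to 0.0; keep p in (0, 1]
    return min(max(p, float(np.finfo(float).tiny)), 1.0)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR, order-preserving with the input."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def diff_table(
    cm: CountMatrix,
    condition_a: str,
    condition_b: str,
    *,
    by: str = "condition",
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-gene differential table between two sample groups.

    Samples are grouped by the metadata field ``by`` (``condition`` or
    ``factor``); replicates within a group are pooled by summation (the
    sufficient reduction for conditionally Poisson counts). Returns a
    DataFrame (gene_id, log2fc, pvalue, fdr) with log2fc of B over A.
    """
    def _cols(value: str) -> list[int]:
        cols = [
            j for j, s in enumerate(cm.samples) if getattr(s, by) == value
        ]
        if not cols:
            raise ValueError(f"no samples with {by} == {value!r}")
        return cols

    lib = cm.library_sizes()
    cols_a, cols_b = _cols(condition_a), _cols(condition_b)
    a = cm.counts[:, cols_a].sum(axis=1)
    b = cm.counts[:, cols_b].sum(axis=1)
    lib_a = float(lib[cols_a].sum())
    lib_b = float(lib[cols_b].sum())
    fc = log2_fold_change(a, b, lib_a, lib_b, pseudocount=pseudocount)
    pvals = np.array(
        [exact_count_test(int(ai), int(bi), lib_a, lib_b) for ai, bi in zip(a, b)]
    )
    return pd.DataFrame(
        {
            "gene_id": cm.gene_ids,
            "log2fc": fc,
            "pvalue": pvals,
            "fdr": bh_adjust(pvals),
        }
    )


def median_fc_rank(
    diff_tables: Sequence[pd.DataFrame], statistic: str = "median"
) -> pd.DataFrame:
    """Rank genes by the cross-experiment median (or mean) log2 fold change.

    All tables must share the same gene universe. The result (gene_id,
    score) is sorted ascending so the strongest losses come first; ties
    break by gene_id.
    """
    if statistic not in ("median", "mean"):
        raise ValueError("statistic must be 'median' or 'mean'")
    if not diff_tables:
        raise ValueError("need at least one differential table")
    universe = set(diff_tables[0]["gene_id"])
    for t in diff_tables[1:]:
        if set(t["gene_id"]) != universe:
            raise ValueError("differential tables cover different gene universes")
    wide = pd.concat(
        [t.set_index("gene_id")["log2fc"] for t in diff_tables], axis=1
    )
    score = wide.median(axis=1) if statistic == "median" else wide.mean(axis=1)
    out = (
        score.rename("score")
        .reset_index()
        .sort_values(["score", "gene_id"], kind="mergesort")
        .reset_index(drop=True)
    )
    return out


def top_fraction(ranked: pd.DataFrame, fraction: float) -> list[str]:
    """The first round(fraction * G) gene ids of a ranked table (min 1).

    Rounding is half-away-from-zero, e.g. 10% of 350 genes -> 35.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    g = len(ranked)
    n = max(1, int(np.floor(fraction * g + 0.5)))
    return list(ranked["gene_id"].iloc[:n])


def write_diff_tsv(table: pd.DataFrame, path) -> None:
    """Write a differential table with a header documenting the test."""
    with open(path, "w") as fh:
        fh.write(
            "# significance: two-sided exact conditional binomial test "
            "(Poisson-limit stand-in for a negative-binomial exact test); "
            "fdr: Benjamini-Hochberg\n"
        )
        table.to_csv(fh, sep="\t", index=False, float_format="%.6g")
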