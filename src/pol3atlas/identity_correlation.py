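"""Pol III complex-identity ratio and its correlation with accessibility.

POLR3G and POLR3GL are mutually exclusive paralogous subunits; the
log2(POLR3G/POLR3GL) expression ratio within a sample summarises which
complex identity dominates. Correlating this ratio, gene by gene, with
rank-normalized chromatin accessibility across samples screens for genes
whose accessibility tracks POLR3G availability. Aggregate (cell-type mean)
correlation and a paired tumor-vs-normal ratio test are also provided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .differential import bh_adjust
from .occupancy import RankMatrix
from .quant import CountMatrix

__all__ = [
    "RatioSeries",
    "compute_ratio",
    "correlate_genes",
    "aggregate_by_group",
    "paired_ratio_test",
    "PairedTestResult",
]

_TINY = np.finfo(float).tiny


@dataclass
class RatioSeries:
    """Per-sample log2 identity ratio with optional grouping/pairing labels."""

    sample_ids: list[str]
    ratio: np.ndarray
    grouping: dict[str, str] = field(default_factory=dict)
    paired_id: dict[str, str] = field(default_factory=dict)
    condition: dict[str, str] = field(default_factory=dict)
    excluded: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.ratio = np.asarray(self.ratio, dtype=float)
        if len(self.sample_ids) != len(self.ratio):
            raise ValueError("sample_ids and ratio lengths differ")
        if self.ratio.size and not np.all(np.isfinite(self.ratio)):
            raise ValueError("retained ratios must be finite")


def compute_ratio(
    expr: CountMatrix,
    gene_a: str = "POLR3G",
    gene_b: str = "POLR3GL",
    *,
    zero_policy: str = "exclude",
    pseudocount: float = 0.5,
    grouping: Mapping[str, str] | None = None,
    paired_id: Mapping[str, str] | None = None,
    condition: Mapping[str, str] | None = None,
) -> RatioSeries:
    """Per-sample log2(gene_a / gene_b) from a normalized expression matrix.

    ``zero_policy="exclude"`` drops samples where either gene is 0 (recorded
    in ``excluded`` with a reason); ``"pseudocount"`` instead adds
    ``pseudocount`` to both numerator and denominator.
    """
    if zero_policy not in ("exclude", "pseudocount"):
        raise ValueError("zero_policy must be 'exclude' or 'pseudocount'")
    for g in (gene_a, gene_b):
        if g not in expr.gene_ids:
            raise KeyError(f"gene {g!r} not present in expression matrix")
    va = expr.counts[expr.gene_ids.index(gene_a)].astype(float)
    vb = expr.counts[expr.gene_ids.index(gene_b)].astype(float)
    kept_ids: list[str] = []
    ratios: list[float] = []
    excluded: list[tuple[str, str]] = []
    for sid, a, b in zip(expr.sample_ids, va, vb):
        if zero_policy == "exclude":
            if a <= 0 or b <= 0:
                which = gene_a if a <= 0 else gene_b
                excluded.append((sid, f"zero {which} expression"))
                continue
            ratios.append(float(np.log2(a / b)))
        else:
            ratios.append(float(np.log2((a + pseudocount) / (b + pseudocount))))
        kept_ids.append(sid)
    sub = lambda m: {s: m[s] for s in kept_ids if m and s in m}  # noqa: E731
    return RatioSeries(
        kept_ids,
        np.array(ratios),
        grouping=sub(grouping or {}),
        paired_id=sub(paired_id or {}),
        condition=sub(condition or {}),
        excluded=excluded,
    )


def _pearson_by_gene(
    mat: np.ndarray, y: np.ndarray, gene_ids: Sequence[str]
) -> pd.DataFrame:
    """Vectorized per-row Pearson r of ``mat`` against ``y`` with t-test p."""
    n = len(y)
    yc = y - y.mean()
    sy = np.sqrt((yc**2).sum())
    xc = mat - mat.mean(axis=1, keepdims=True)
    sx = np.sqrt((xc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ yc) / (sx * sy)
    degenerate = (sx == 0) | (sy == 0)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance vector(s); r reported missing",
            stacklevel=3,
        )
        r = np.where(degenerate, np.nan, r)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / (1 - r**2))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isinf(t), 0.0, p)  # |r| == 1
    p = np.where(np.isnan(r), np.nan, np.clip(p, _TINY, 1.0))
    ok = ~np.isnan(p)
    fdr = np.full(len(r), np.nan)
    if ok.any():
        fdr[ok] = bh_adjust(p[ok])
    return pd.DataFrame(
        {"gene_id": list(gene_ids), "r": r, "p": p, "n": n, "fdr": fdr}
    )


def correlate_genes(
    rs: RatioSeries,
    acc: RankMatrix,
    *,
    id_normalizer: Callable[[str], str] | None = None,
) -> pd.DataFrame:
    """Per-gene Pearson correlation of accessibility with the identity ratio.

    Samples are matched by ID (optionally through ``id_normalizer`` applied
    to both sides); at least 3 matched samples are required. Two-sided p
    comes from the t distribution with n-2 df; a BH-adjusted column is
    appended for convenience (the per-gene screen itself is reported on raw
    p-values). Returns (gene_id, r, p, n, fdr).
    """
    norm = id_normalizer or (lambda s: s)
    acc_index = {norm(s): j for j, s in enumerate(acc.sample_ids)}
    pairs = [
        (i, acc_index[norm(s)])
        for i, s in enumerate(rs.sample_ids)
        if norm(s) in acc_index
    ]
    if len(pairs) < 3:
        raise ValueError(
            f"need >=3 matched samples between ratio series and accessibility, "
            f"got {len(pairs)}"
        )
    ridx, cidx = zip(*pairs)
    y = rs.ratio[list(ridx)]
    mat = acc.ranks[:, list(cidx)]
    return _pearson_by_gene(mat, y, acc.gene_ids)


def aggregate_by_group(
    rs: RatioSeries,
    acc: RankMatrix,
    groups: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Correlation over group (e.g. cell-type) means instead of samples.

    Ratios and accessibility columns are averaged within each group first;
    Pearson correlation then runs across the group means. Groups missing
    from either data type are dropped with a warning; >=3 usable groups are
    required.
    """
    labels = dict(groups) if groups is not None else dict(rs.grouping)
    if not labels:
        raise ValueError("no group labels supplied")
    acc_cols = {s: j for j, s in enumerate(acc.sample_ids)}
    by_group: dict[str, tuple[list[int], list[int]]] = {}
    for i, sid in enumerate(rs.sample_ids):
        if sid not in labels:
            continue
        g = labels[sid]
        by_group.setdefault(g, ([], []))[0].append(i)
        if sid in acc_cols:
            by_group[g][1].append(acc_cols[sid])
    usable: list[str] = []
    for g, (ri, ci) in sorted(by_group.items()):
        if not ri or not ci:
            warnings.warn(f"group {g!r} lacks samples in one data type; dropped",
                          stacklevel=2)
            continue
        usable.append(g)
    if len(usable) < 3:
        raise ValueError(f"need >=3 usable groups, got {len(usable)}")
    y = np.array([rs.ratio[by_group[g][0]].mean() for g in usable])
    mat = np.column_stack(
        [acc.ranks[:, by_group[g][1]].mean(axis=1) for g in usable]
    )
    return _pearson_by_gene(mat, y, acc.gene_ids)


class PairedTestResult(NamedTuple):
    statistic: float
    pvalue: float
    n_pairs: int


def paired_ratio_test(
    rs: RatioSeries,
    condition_a: str = "tumor",
    condition_b: str = "normal",
) -> PairedTestResult:
    """Two-sided Wilcoxon signed-rank test on paired identity-ratio shifts.

    Per participant (``paired_id``), the difference (ratio in
    ``condition_a``) - (ratio in ``condition_b``) is formed; zero
    differences are dropped. The exact null distribution is used for <= 25
    nonzero pairs, the normal approximation with continuity correction
    above. All-zero differences raise a degenerate-pairing error.
    """
    if not rs.paired_id or not rs.condition:
        raise ValueError("paired_ratio_test requires paired_id and condition labels")
    by_pair: dict[str, dict[str, float]] = {}
    for sid, val in zip(rs.sample_ids, rs.ratio):
        key = rs.paired_id.get(sid)
        cond = rs.condition.get(sid)
        if key is None or cond is None:
            continue
        by_pair.setdefault(key, {})[cond] = float(val)
    diffs = [
        d[condition_a] - d[condition_b]
        for d in by_pair.values()
        if condition_a in d and condition_b in d
    ]
    if not diffs:
        raise ValueError("no complete tumor/normal pairs found")
    nonzero = np.array([d for d in diffs if d != 0.0])
    if nonzero.size == 0:
        raise ValueError("degenerate pairing: all paired differences are zero")
    method = "exact" if nonzero.size <= 25 else "approx"
    res = stats.wilcoxon(
        nonzero, alternative="two-sided", method=method, correction=True
    )
    return PairedTestResult(float(res.statistic), float(res.pvalue), nonzero.size)
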