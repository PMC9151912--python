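"""Consensus Pol III occupancy calling from multi-subunit ChIP counts.

Individual ChIP experiments differ widely in signal-to-noise (antibody
efficiency varies between subunits), so raw counts are not comparable
across experiments. Each experiment's counts are therefore replaced by
min-max-scaled average ranks; the consensus occupancy score of a gene is
the median of its normalized ranks across the designated subunit
experiments, which is robust to a single weak antibody. The confidently
bound gene set is called either by thresholding the score or by taking
the top N genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations as _combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .quant import CountMatrix, SampleMeta

__all__ = [
    "RankMatrix",
    "OccupancyCall",
    "rank_normalize",
    "rank_normalize_values",
    "call_occupied",
    "subunit_correlations",
    "write_occupancy_tsv",
]


@dataclass
class RankMatrix:
    """Per-experiment normalized ranks in [0, 1], same layout as a CountMatrix."""

    gene_ids: list[str]
    samples: list[SampleMeta]
    ranks: np.ndarray

    def __post_init__(self) -> None:
        self.ranks = np.asarray(self.ranks, dtype=float)
        if self.ranks.shape != (len(self.gene_ids), len(self.samples)):
            raise ValueError("ranks shape inconsistent with gene/sample lists")
        if self.ranks.size and (self.ranks.min() < 0 or self.ranks.max() > 1):
            raise ValueError("normalized ranks must lie in [0, 1]")

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def column(self, sample_id: str) -> np.ndarray:
        return self.ranks[:, self.sample_ids.index(sample_id)]


@dataclass
class OccupancyCall:
    gene_id: str
    consensus_score: float
    occupied: bool


def rank_normalize_values(values: np.ndarray) -> np.ndarray:
    """Column-wise min-max-scaled average ranks of a genes x samples array.

    Per column, values become ascending average ranks (ties get the average
    of the tied positions) scaled to [0, 1] as ``(rank - 1) / (G - 1)``.
    Invariant under any strictly monotone per-column transform of the input.
    """
    values = np.asarray(values)
    g = values.shape[0]
    if g < 2:
        raise ValueError(f"rank normalization needs >=2 genes, got {g}")
    ranks = np.empty(values.shape, dtype=float)
    for j in range(values.shape[1]):
        ranks[:, j] = (stats.rankdata(values[:, j], method="average") - 1) / (g - 1)
    return ranks


def rank_normalize(
    cm: CountMatrix, subset: Sequence[str] | None = None
) -> RankMatrix:
    """Rank-normalize each experiment's counts over a gene subset.

    Genes outside ``subset`` are dropped before ranking; see
    :func:`rank_normalize_values` for the per-column transform.
    """
    if subset is not None:
        cm = cm.subset_genes(list(subset))
    return RankMatrix(
        list(cm.gene_ids), list(cm.samples), rank_normalize_values(cm.counts)
    )


def call_occupied(
    rm: RankMatrix,
    subunit_columns: Sequence[str],
    *,
    threshold: float | None = None,
    top_n: int | None = None,
) -> list[OccupancyCall]:
    """Call the consensus-occupied gene set from designated subunit columns.

    The consensus score is the median normalized rank across
    ``subunit_columns``. Exactly one calling mode must be given: a score
    threshold (occupied iff score >= threshold) or top-N selection (ties at
    the boundary broken by gene_id sort, for reproducibility).
    """
    if (threshold is None) == (top_n is None):
        raise ValueError("specify exactly one of threshold= or top_n=")
    if not subunit_columns:
        raise ValueError("subunit_columns must be nonempty")
    cols = [rm.sample_ids.index(s) for s in subunit_columns]
    scores = np.median(rm.ranks[:, cols], axis=1)
    if threshold is not None:
        occupied = scores >= threshold
    else:
        if top_n > len(rm.gene_ids):
            raise ValueError(
                f"top_n ({top_n}) exceeds gene count ({len(rm.gene_ids)})"
            )
        order = sorted(
            range(len(rm.gene_ids)),
            key=lambda i: (-scores[i], rm.gene_ids[i]),
        )
        occupied = np.zeros(len(rm.gene_ids), dtype=bool)
        occupied[order[:top_n]] = True
    return [
        OccupancyCall(g, float(s), bool(o))
        for g, s, o in zip(rm.gene_ids, scores, occupied)
    ]


def subunit_correlations(
    rm: RankMatrix, extra: RankMatrix | None = None
) -> pd.DataFrame:
    """Pairwise Pearson correlation between experiments' normalized ranks.

    Returns a tidy table (sample_a, sample_b, r, p, n) for every unordered
    column pair, with two-sided p from the t distribution with G-2 df.
    Zero-variance columns yield missing r with a warning. ``extra`` (for
    instance an accessibility rank matrix over the same genes) appends its
    columns to the comparison.
    """
    mats = [rm] if extra is None else [rm, extra]
    if extra is not None and extra.gene_ids != rm.gene_ids:
        raise ValueError("extra matrix must share the gene universe")
    names: list[str] = []
    columns: list[np.ndarray] = []
    for m in mats:
        names.extend(m.sample_ids)
        columns.extend(m.ranks[:, j] for j in range(m.ranks.shape[1]))
    if len(names) < 2:
        raise ValueError("need >=2 columns to correlate")
    rows = []
    for (ia, a), (ib, b) in _combinations(enumerate(names), 2):
        x, y = columns[ia], columns[ib]
        n = len(x)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            warnings.warn(
                f"zero-variance column in pair ({a}, {b}); r undefined",
                stacklevel=2,
            )
            rows.append({"sample_a": a, "sample_b": b, "r": np.nan,
                         "p": np.nan, "n": n})
            continue
        r, p = stats.pearsonr(x, y)
        rows.append({"sample_a": a, "sample_b": b, "r": float(r),
                     "p": float(p), "n": n})
    return pd.DataFrame(rows)


def write_occupancy_tsv(
    calls: Sequence[OccupancyCall],
    rm: RankMatrix,
    subunit_columns: Sequence[str],
    path,
) -> None:
    """Write calls plus per-subunit normalized ranks as TSV."""
    df = pd.DataFrame(
        {
            "gene_id": [c.gene_id for c in calls],
            "consensus_score": [c.consensus_score for c in calls],
            "occupied": [c.occupied for c in calls],
        }
    )
    for s in subunit_columns:
        df[f"rank_{s}"] = rm.column(s)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
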