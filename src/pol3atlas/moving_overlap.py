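"""Moving multi-experiment overlap enrichment over ranked gene lists.

Given k gene lists ranked by degree of loss (most affected first) over a
shared universe of G genes, a common top-n cutoff is swept across all
lists. At each cutoff the observed size of the intersection of the k
top-n sets is compared with the independence expectation
``G * (n/G)**k`` (the hypergeometric mean for k = 2, the product form in
general). A gene's maximum enrichment score is the highest
observed/expected ratio over all cutoffs and experiment combinations in
which the gene sits inside the intersection; genes scoring at or above a
fixed threshold (3 by default) form the enhanced repertoire.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations as _subsets
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RankedList",
    "OverlapProfile",
    "moving_overlap",
    "max_enrichment_scores",
    "select_enhanced",
    "permutation_null",
    "plot_profile",
    "ranked_list_from_scores",
]


@dataclass
class RankedList:
    """One experiment's genes ordered most-affected first, over G genes."""

    experiment_id: str
    gene_ids: list[str]
    universe_size: int

    def __post_init__(self) -> None:
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError(
                f"list {self.experiment_id!r} contains duplicate gene ids"
            )
        if len(self.gene_ids) > self.universe_size:
            raise ValueError(
                f"list {self.experiment_id!r} is longer than its universe "
                f"({len(self.gene_ids)} > {self.universe_size})"
            )

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass
class OverlapProfile:
    """Observed/expected intersection trajectory along the cutoff sweep."""

    list_ids: tuple[str, ...]
    universe_size: int
    cutoffs: np.ndarray
    observed: np.ndarray
    expected: np.ndarray
    enrichment: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n": self.cutoffs,
                "observed": self.observed,
                "expected": self.expected,
                "enrichment": self.enrichment,
            }
        )


def ranked_list_from_scores(
    experiment_id: str,
    table: pd.DataFrame,
    universe_size: int,
    *,
    ascending: bool = True,
    score_column: str = "score",
) -> RankedList:
    """Build a RankedList from a (gene_id, score) table.

    ``ascending=True`` puts the most negative scores (strongest loss)
    first; ties break by gene_id for determinism.
    """
    ordered = table.sort_values(
        [score_column, "gene_id"], ascending=[ascending, True], kind="mergesort"
    )
    return RankedList(experiment_id, list(ordered["gene_id"]), universe_size)


def _check_lists(lists: Sequence[RankedList]) -> int:
    if len(lists) < 2:
        raise ValueError("moving overlap needs at least 2 ranked lists")
    sizes = {l.universe_size for l in lists}
    if len(sizes) != 1:
        raise ValueError(f"lists declare different universe sizes: {sorted(sizes)}")
    return sizes.pop()


def _max_ranks(lists: Sequence[RankedList]) -> dict[str, int]:
    """For genes present in every list: the worst (largest) 1-based rank."""
    rank_maps = [
        {g: i + 1 for i, g in enumerate(l.gene_ids)} for l in lists
    ]
    common = set(rank_maps[0])
    for m in rank_maps[1:]:
        common &= set(m)
    return {g: max(m[g] for m in rank_maps) for g in common}


def _profile_arrays(
    lists: Sequence[RankedList], cutoffs: np.ndarray, g: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict[str, int]]:
    maxrank = _max_ranks(lists)
    k = len(lists)
    if maxrank:
        counts = np.bincount(
            list(maxrank.values()), minlength=int(cutoffs.max()) + 1
        )
        observed = np.cumsum(counts)[cutoffs]
    else:
        observed = np.zeros(len(cutoffs), dtype=np.int64)
    expected = g * (cutoffs / g) ** k
    with np.errstate(divide="ignore", invalid="ignore"):
        enrichment = np.where(observed > 0, observed / expected, 0.0)
    return observed.astype(np.int64), expected, enrichment, maxrank


def moving_overlap(
    lists: Sequence[RankedList], n_max: int | None = None
) -> OverlapProfile:
    """Sweep a common top-n cutoff across k ranked lists.

    For each cutoff n in 1..n_max: observed = size of the intersection of
    the k top-n sets; expected = G * (n/G)**k; enrichment = observed /
    expected, defined as 0 when the intersection is empty. ``n_max``
    defaults to the shortest list length and may not exceed it.
    """
    g = _check_lists(lists)
    shortest = min(len(l) for l in lists)
    if n_max is None:
        n_max = shortest
    if not 1 <= n_max <= shortest:
        raise ValueError(
            f"n_max must lie in [1, {shortest}] (shortest list), got {n_max}"
        )
    cutoffs = np.arange(1, n_max + 1)
    observed, expected, enrichment, _ = _profile_arrays(lists, cutoffs, g)
    return OverlapProfile(
        tuple(l.experiment_id for l in lists), g, cutoffs, observed, expected,
        enrichment,
    )


def max_enrichment_scores(
    lists: Sequence[RankedList],
    combinations: Iterable[Sequence[str]] | None = None,
    n_grid: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Per-gene maximum observed/expected score over combinations and cutoffs.

    Every experiment combination of size >= 2 (or the supplied ones) is
    swept over ``n_grid`` (default: 1..shortest list length within each
    combination). A gene inside the intersection of a combination's top-n
    sets is a candidate for that combination's enrichment at any cutoff
    n >= its worst rank; its score is the maximum over all candidates.
    Ties between combinations break toward fewer experiments, then
    lexicographic ids, then the smallest cutoff.

    Returns a DataFrame (gene_id, max_enrichment, best_combination, best_n)
    over the union of all listed genes; genes never inside a qualifying
    intersection score 0.
    """
    g = _check_lists(lists)
    by_id = {l.experiment_id: l for l in lists}
    if len(by_id) != len(lists):
        raise ValueError("duplicate experiment ids")
    if combinations is None:
        ids = sorted(by_id)
        combos = [
            tuple(c) for size in range(2, len(ids) + 1)
            for c in _subsets(ids, size)
        ]
    else:
        combos = []
        for c in combinations:
            c = tuple(sorted(c))
            if len(c) < 2:
                raise ValueError(f"combination {c} has fewer than 2 experiments")
            missing = [i for i in c if i not in by_id]
            if missing:
                raise KeyError(f"unknown experiment ids {missing}")
            combos.append(c)
    universe_genes = sorted({g_ for l in lists for g_ in l.gene_ids})
    best: dict[str, tuple[float, int, tuple[str, ...], int]] = {
        gid: (0.0, 0, (), 0) for gid in universe_genes
    }
    for combo in sorted(combos, key=lambda c: (len(c), c)):
        combo_lists = [by_id[i] for i in combo]
        shortest = min(len(l) for l in combo_lists)
        if shortest == 0:
            continue
        if n_grid is None:
            cutoffs = np.arange(1, shortest + 1)
        else:
            cutoffs = np.unique(np.asarray(list(n_grid), dtype=np.int64))
            cutoffs = cutoffs[(cutoffs >= 1) & (cutoffs <= shortest)]
            if cutoffs.size == 0:
                continue
        _, _, enrichment, maxrank = _profile_arrays(combo_lists, cutoffs, g)
        if not maxrank:
            continue
        # Suffix-max over the cutoff grid: a gene with worst rank m is in the
        # intersection at every grid cutoff >= m.
        suffix_val = np.empty(len(cutoffs))
        suffix_n = np.empty(len(cutoffs), dtype=np.int64)
        cur_val, cur_n = -np.inf, 0
        for i in range(len(cutoffs) - 1, -1, -1):
            if enrichment[i] >= cur_val:  # >= keeps the smallest n among ties
                cur_val, cur_n = enrichment[i], int(cutoffs[i])
            suffix_val[i] = cur_val
            suffix_n[i] = cur_n
        for gid, m in maxrank.items():
            i = int(np.searchsorted(cutoffs, m, side="left"))
            if i >= len(cutoffs):
                continue
            score, n_at = float(suffix_val[i]), int(suffix_n[i])
            cur = best[gid]
            if score > cur[0]:
                best[gid] = (score, len(combo), combo, n_at)
            # equal scores: earlier (smaller-k, lexicographically first,
            # smallest-n) combination wins; combos are visited in that order,
            # so nothing to do on ties.
    return pd.DataFrame(
        {
            "gene_id": universe_genes,
            "max_enrichment": [best[g_][0] for g_ in universe_genes],
            "best_combination": [
                "+".join(best[g_][2]) for g_ in universe_genes
            ],
            "best_n": [best[g_][3] for g_ in universe_genes],
        }
    )


def select_enhanced(
    scores: pd.DataFrame, threshold: float = 3.0
) -> pd.DataFrame:
    """Genes with max_enrichment >= threshold, sorted descending by score."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    hits = scores[scores["max_enrichment"] >= threshold]
    return hits.sort_values(
        ["max_enrichment", "gene_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


def permutation_null(
    lists: Sequence[RankedList],
    n_permutations: int = 1000,
    seed: int | None = None,
    combinations: Iterable[Sequence[str]] | None = None,
    n_grid: Sequence[int] | None = None,
) -> np.ndarray:
    """Empirical null of per-gene maximum enrichment scores.

    Each permutation shuffles the order of every list independently and
    recomputes :func:`max_enrichment_scores`. Returns an array of shape
    (n_permutations, n_union_genes); pool it to obtain null quantiles for
    the fixed-threshold selection.
    """
    _check_lists(lists)
    rng = np.random.default_rng(seed)
    out = []
    combos = list(combinations) if combinations is not None else None
    for _ in range(n_permutations):
        shuffled = [
            RankedList(
                l.experiment_id,
                [l.gene_ids[i] for i in rng.permutation(len(l.gene_ids))],
                l.universe_size,
            )
            for l in lists
        ]
        table = max_enrichment_scores(shuffled, combinations=combos, n_grid=n_grid)
        out.append(table["max_enrichment"].to_numpy())
    return np.array(out)


def plot_profile(profile: OverlapProfile, ax=None):
    """Convenience enrichment-vs-n line plot."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(profile.cutoffs, profile.enrichment, lw=1.5)
    ax.axhline(1.0, color="grey", ls="--", lw=0.8)
    ax.set_xlabel("top-n cutoff")
    ax.set_ylabel("observed / expected overlap")
    ax.set_title(" ∩ ".join(profile.list_ids))
    return ax
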