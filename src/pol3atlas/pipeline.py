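"""End-to-end integration: from simulated (or loaded) counts to the
POLR3G-enhanced gene repertoire.

The integration mirrors the analysis flow the package implements stage by
stage: consensus occupancy calling from multi-subunit ChIP, differential
ranking of POLR3G occupancy and small-RNA abundance between a
high-availability and a low-availability condition, the per-gene
identity-ratio/accessibility correlation screen, and finally the moving
overlap of the resulting ranked lists with a fixed maximum-enrichment
threshold.

Ranked lists entering the overlap are restricted to genes passing the
stage's significance filter (BH FDR < 0.05, in the loss direction for the
differential lists, positive correlation for the ratio screen) and then
ordered by effect size. Filtering first keeps the moving intersection
interpretable: with complete rankings every gene eventually enters every
intersection, and genes correlated with the top of two lists by chance
alone inherit large observed/expected ratios.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .differential import diff_table
from .identity_correlation import compute_ratio, correlate_genes
from .moving_overlap import (
    RankedList,
    max_enrichment_scores,
    select_enhanced,
)
from .occupancy import OccupancyCall, call_occupied, rank_normalize
from .synthetic_data import Simulation

__all__ = [
    "EnhancedRecovery",
    "occupancy_calls",
    "loss_ranked_list",
    "correlation_ranked_list",
    "identify_enhanced",
]

FDR_CUTOFF = 0.05


def occupancy_calls(
    sim: Simulation, condition: str | None = None, top_n: int | None = None
) -> list[OccupancyCall]:
    """Consensus occupancy calls from every subunit ChIP track.

    Each subunit experiment contributes its replicate columns from
    ``condition`` (default: the first, highest-availability condition);
    all contributing columns are rank-normalized per experiment and the
    consensus is the median across them.
    """
    cfg = sim.config
    condition = condition or cfg.conditions[0]
    top_n = top_n if top_n is not None else cfg.n_occupied
    # Stack the chosen condition's columns from every subunit experiment.
    first = next(iter(sim.chip.values()))
    gene_ids = first.gene_ids
    import numpy as np

    from .quant import CountMatrix

    cols, metas = [], []
    for sub, cm in sim.chip.items():
        for j, s in enumerate(cm.samples):
            if s.condition == condition:
                cols.append(cm.counts[:, j])
                metas.append(s)
    stacked = CountMatrix(list(gene_ids), metas, np.stack(cols, axis=1))
    rm = rank_normalize(stacked)
    return call_occupied(rm, rm.sample_ids, top_n=top_n)


def loss_ranked_list(
    cm, condition_a: str, condition_b: str, experiment_id: str,
    fdr_cutoff: float = FDR_CUTOFF,
) -> RankedList:
    """Ranked list of significant losses (B vs A), strongest loss first."""
    table = diff_table(cm, condition_a, condition_b)
    hits = table[(table["fdr"] < fdr_cutoff) & (table["log2fc"] < 0)]
    ordered = hits.sort_values(["log2fc", "gene_id"], kind="mergesort")
    return RankedList(experiment_id, list(ordered["gene_id"]), cm.n_genes)


def correlation_ranked_list(
    sim: Simulation, experiment_id: str = "identity_correlation",
    fdr_cutoff: float = FDR_CUTOFF,
) -> RankedList:
    """Ranked list of genes whose accessibility tracks the identity ratio."""
    ratio = compute_ratio(sim.expr)
    acc = rank_normalize(sim.atac)
    table = correlate_genes(ratio, acc)
    hits = table[(table["fdr"] < fdr_cutoff) & (table["r"] > 0)]
    ordered = hits.sort_values(
        ["r", "gene_id"], ascending=[False, True], kind="mergesort"
    )
    return RankedList(experiment_id, list(ordered["gene_id"]),
                      len(acc.gene_ids))


@dataclass
class EnhancedRecovery:
    selected: pd.DataFrame        # select_enhanced output
    scores: pd.DataFrame          # full max_enrichment_scores table
    lists: list[RankedList]
    recall: float
    precision: float


def identify_enhanced(
    sim: Simulation,
    threshold: float = 3.0,
    conditions: tuple[str, str] | None = None,
) -> EnhancedRecovery:
    """Run the integrated recovery of the planted enhanced gene set.

    Builds three ranked loss lists — POLR3G ChIP occupancy loss, small-RNA
    abundance loss (high- vs low-availability condition), and the
    identity-ratio correlation screen — and scores genes by maximum
    overlap enrichment across all list combinations.
    """
    cfg = sim.config
    if conditions is None:
        # Strongest availability contrast: highest vs lowest condition.
        ordered = sorted(cfg.conditions, key=lambda c: cfg.availability[c])
        cond_high, cond_low = ordered[-1], ordered[0]
    else:
        cond_high, cond_low = conditions
    lists = [
        loss_ranked_list(sim.chip["POLR3G"], cond_high, cond_low,
                         "chip_POLR3G"),
        loss_ranked_list(sim.smallrna, cond_high, cond_low, "smallrna"),
        correlation_ranked_list(sim),
    ]
    nonempty = [l for l in lists if len(l) > 0]
    if len(nonempty) < 2:
        empty = pd.DataFrame(
            columns=["gene_id", "max_enrichment", "best_combination", "best_n"]
        )
        return EnhancedRecovery(empty, empty, lists, 0.0, 0.0)
    scores = max_enrichment_scores(nonempty)
    selected = select_enhanced(scores, threshold=threshold)
    chosen = set(selected["gene_id"])
    truth = sim.truth.enhanced_gene_ids
    recall = len(chosen & truth) / len(truth) if truth else 0.0
    precision = len(chosen & truth) / len(chosen) if chosen else 0.0
    return EnhancedRecovery(selected, scores, nonempty, recall, precision)
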