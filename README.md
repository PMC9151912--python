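# pol3atlas

RNA polymerase III (Pol III) transcribes the short noncoding RNA genes —
tRNAs, 5S rRNA, U6, 7SK, 7SL, vault, Y and snaR RNAs among others. Two
mutually exclusive paralogous subunits, POLR3G (RPC7α) and POLR3GL (RPC7β),
define two Pol III complex "identities", and a subset of Pol III target
genes appears to depend specifically on POLR3G availability (snaR-A and
BC200/BCYRN1 being the canonical examples). `pol3atlas` is a pipeline for
epigenomics/regulatory-genomics analysts who want to go from gene-level
sequencing counts (multi-subunit ChIP, ATAC accessibility, small-RNA
abundance, expression) to:

1. a **consensus Pol III-occupied gene set**, called from the concordance of
   rank-normalized ChIP signal across subunit experiments;
2. **differential loss rankings** of occupancy/abundance between conditions
   (e.g. monocyte vs PMA-differentiated macrophage);
3. a **per-gene correlation screen** of chromatin accessibility against the
   within-sample log2(POLR3G/POLR3GL) identity ratio; and
4. a **moving multi-experiment overlap enrichment** that integrates the
   ranked lists and nominates the POLR3G-enhanced gene repertoire.

A seeded multi-assay simulator with planted ground truth makes the whole
pipeline testable end to end without any external data.

## The statistics in brief

**Rank normalization.** Within each experiment the per-gene counts `x` are
replaced by min–max-scaled average ranks, `(rank(x) − 1)/(G − 1) ∈ [0, 1]`,
equalizing signal-to-noise across antibodies. The consensus occupancy score
of a gene is the **median normalized rank** across subunit experiments;
the occupied set is the top *N* (or a score threshold).

**Differential loss.** Fold changes are counts-per-million with pseudocount
0.5: `log2((CPM_B + ½)/(CPM_A + ½))`. Significance is a two-sided exact
conditional binomial test — given `n = a + b`, under the null
`b ~ Binomial(n, lib_B/(lib_A + lib_B))`, with the p-value summing all
outcomes no more probable than the observed one (the dispersion→0 limit of
the negative-binomial exact tests used for sequencing counts), followed by
Benjamini–Hochberg correction. Genes are ranked by degree of loss
(ascending log2 fold change), with cross-experiment median or mean ranking
and top-fraction selection.

**Identity correlation.** Per sample, the ratio `log2(POLR3G/POLR3GL)`;
per gene, the Pearson correlation `r` of that ratio with rank-normalized
accessibility across matched samples, with two-sided p from
`t = r·√((n−2)/(1−r²))`. Aggregate (cell-type mean) correlation and a
paired Wilcoxon signed-rank tumor-vs-normal ratio test are included.

**Moving overlap.** For `k` ranked lists over a universe of `G` genes, a
common top-`n` cutoff is swept; at each cutoff the observed intersection
size is compared with the independence expectation `G·(n/G)^k`. Each gene's
**maximum enrichment score** is its highest observed/expected ratio over
all cutoffs and experiment combinations containing it; genes scoring ≥ 3
form the enhanced repertoire. An optional permutation null is provided.

## Worked example

```python
from pol3atlas.synthetic_data import SimConfig, simulate
from pol3atlas.pipeline import identify_enhanced, occupancy_calls

sim = simulate(SimConfig(seed=7))           # default study conditions
calls = occupancy_calls(sim)
print(f"occupied genes called: {sum(c.occupied for c in calls)}")

rec = identify_enhanced(sim, threshold=3.0)
print(f"genes with maximum enrichment >= 3: {len(rec.selected)}")
print(f"recall of planted enhanced set: {rec.recall:.2f}")
print(f"precision: {rec.precision:.2f}")
print(rec.selected.head(3).to_string(index=False))
```

prints

```
occupied genes called: 350
genes with maximum enrichment >= 3: 20
recall of planted enhanced set: 1.00
precision: 1.00
    gene_id  max_enrichment                          best_combination  best_n
URS00000373    62500.000000 chip_POLR3G+identity_correlation+smallrna       4
URS00000455    13888.888889 chip_POLR3G+identity_correlation+smallrna      12
URS00001019    13888.888889 chip_POLR3G+identity_correlation+smallrna      12
```

The default simulation plants 20 POLR3G-enhanced genes among 2000 (350 of
them Pol III-occupied) across three conditions with POLR3G availabilities
1.0 / 0.2 / 0.9. All 350 occupancy calls land on truly occupied genes, the
three significance-filtered ranked lists (POLR3G ChIP loss, small-RNA loss,
identity-ratio correlation) intersect almost exclusively on the planted
genes, and the threshold-3 selection recovers them with perfect precision
here. A gene sitting in the top 4 of all three lists reaches
`4 / (2000·(4/2000)³) = 62500`.

The same stages are exposed as a CLI (`pol3 annotate`, `pol3 count`,
`pol3 occupancy`, `pol3 diff`, `pol3 correlate`, `pol3 overlap`,
`pol3 simulate`); `pol3 simulate --out fixtures/` writes a complete input
bundle (gene BED, count TSVs, sample sheets, truth labels) to play with.

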