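# Methods

This note documents the models, parameter choices and numerical conventions
behind `pol3atlas`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Annotation handling

Consolidated noncoding-RNA annotations (RNAcentral-style BED, URS
identifiers) contain near-duplicate entries contributed by multiple source
databases. Two records are treated as duplicates when they lie on the same
chromosome and **both** their start and their end coordinates differ by at
most the merge tolerance (default 50 bp); duplicate pairs are closed
transitively (single linkage), and each group is replaced by one record
spanning the union, keeping the lexicographically smallest identifier (for
determinism), the union of source ids, and the majority gene class (ties
resolved toward the record with the smallest id). Strand and gene class are
deliberately ignored during merging — counting downstream is strand-blind,
and the merge criterion is purely coordinate-based; both behaviours are
configurable at the call site if a stricter policy is wanted.

Counting windows extend each gene by a fixed flank: 150 bp for ChIP and
ATAC (capturing signal spilling beyond the short gene bodies), 25 bp for
small-RNA counting. Coordinates are 0-based half-open throughout; flank
expansion clamps at position 0 and no chromosome-length table is required.

## Counting

A fragment contributes to a gene when it overlaps the gene's window by at
least 1 bp under half-open coordinates; a fragment overlapping several
windows increments each (short Pol III genes packed in clusters make any
single-assignment rule arbitrary; double counting is the transparent
choice and is documented in the output). Every supplied fragment counts
toward the sample's library size, including fragments on chromosomes
absent from the annotation. Counting uses an interval tree per chromosome
and is checked against a quadratic all-pairs oracle in the tests.

## Consensus occupancy

ChIP experiments for different Pol III subunits differ strongly in
antibody efficiency, so raw counts are not comparable across experiments.
Each experiment's counts are rank-normalized — ascending average ranks
(ties averaged) scaled as `(rank − 1)/(G − 1)` — and a gene's consensus
score is the **median** normalized rank across the designated subunit
experiments. The median is robust to a single weak antibody (POLR3GL ChIP
is characteristically weak at POLR3G-preferred genes). Note that a column
whose minimum value is tied does not attain 0 after scaling; the scale end
points are only guaranteed for untied extremes. Calling modes: score
threshold, or top-N with ties broken by gene id. Consensus scores are
invariant to any per-experiment strictly monotone transform of the counts,
which is property-tested.

## Differential loss

Fold changes are computed on counts-per-million with pseudocount 0.5,
which keeps zero counts finite and shrinks small-count ratios.
Significance uses a two-sided **exact conditional binomial test**: given a
gene's total count `n = a + b` in two pooled conditions, `b` is
`Binomial(n, lib_B/(lib_A+lib_B))` under the null of equal concentration,
and the p-value sums all outcomes no more probable than the one observed.
This is the dispersion→0 limit of the negative-binomial exact tests
standard for sequencing counts; it is exact under the package's own noise
model (below) but anticonservative on data with per-sample biological
overdispersion, which is stated in the header of every differential output
file. Replicates are pooled by summation (the sufficient statistic for
conditionally Poisson counts); no TMM-style compositional normalization is
applied, so when a large fraction of the library shifts between
conditions, unaffected genes acquire an apparent *gain* — the ranked lists
feeding the overlap therefore filter on the loss direction. p-values are
Benjamini–Hochberg adjusted.

Cross-experiment ranking uses the per-gene median (or mean) log2 fold
change, sorted ascending so the strongest losses lead; top-fraction
selection takes `round(fraction·G)` genes (half-away-from-zero, minimum
one), e.g. 10% of 350 ranked genes = 35.

## Identity-ratio correlation screen

The within-sample `log2(POLR3G/POLR3GL)` expression ratio is an
internally controlled readout of Pol III complex identity: it cancels
depth and is insensitive to global expression shifts. Samples with zero
expression of either paralog are excluded by default (a pseudocount
alternative is exposed) rather than fabricating extreme ratios in
POLR3G-silent cells; exclusions are recorded with reasons. Per gene,
Pearson `r` between the ratio and rank-normalized accessibility across
ID-matched samples, two-sided p from the t distribution with `n − 2`
degrees of freedom, requiring ≥ 3 matched samples. Zero-variance vectors
yield missing `r` with a warning. Raw p-values are the screen's primary
output (a BH column is appended for convenience only). Aggregate analysis
averages ratio and accessibility within groups (cell types) before
correlating, and requires ≥ 3 usable groups. The paired tumor/normal
comparison is a two-sided Wilcoxon signed-rank test on per-participant
ratio differences; zero differences are dropped, the exact distribution is
used for ≤ 25 nonzero pairs and the normal approximation with continuity
correction above.

## Moving overlap enrichment

For `k` ranked lists over a shared universe of `G` genes, a common top-`n`
cutoff sweeps `n = 1..n_max`; observed is the size of the intersection of
the `k` top-`n` sets and expected is the independence value `G·(n/G)^k`
(the hypergeometric mean for `k = 2`, the product form in general).
Enrichment is observed/expected, defined as 0 for empty intersections. A
gene's **maximum enrichment score** is the highest enrichment over all
combinations of ≥ 2 experiments and all cutoffs at which the gene is
inside the intersection; membership is in the *full* intersection of the
combination (a union-of-pairwise reading is possible but not implemented
as default). Ties between combinations resolve toward fewer experiments,
then lexicographic ids, then the smallest cutoff, making reported
provenance deterministic. The implementation reduces each combination to
per-gene worst ranks plus a suffix maximum over the cutoff grid and is
tested for exact agreement with a brute-force set-enumeration oracle.

The repertoire is selected at a fixed threshold (maximum enrichment ≥ 3,
boundary inclusive). Because ratio maxima are inflated at small cutoffs
even for random lists, a seeded permutation null (shuffle each list,
recompute scores) is provided for calibrating the threshold when wanted.

**Ranked-list construction for the integrated pipeline.** Lists entering
the overlap contain only genes passing the stage's significance filter
(BH FDR < 0.05; negative fold change for the loss lists, positive `r` for
the correlation screen), ordered by effect size. With complete unfiltered
rankings, any gene drifting into the top of two lists by chance inherits
the large enrichment generated by the true signal — the expected number of
such passengers at threshold `t` is roughly `m/(t − 1)` per combination
(`m` = true overlap size) *regardless of signal strength*, so a fixed
threshold cannot separate signal from rank noise on complete lists.
Filtering first makes the intersection trajectory carry only genes with
per-experiment evidence.

## Synthetic data

The generator emulates the structure the analysis assumes, with defaults
chosen as the standard study conditions:

| parameter | default | meaning |
|---|---|---|
| `n_genes` | 2000 | universe size G |
| `n_enhanced` | 20 | planted POLR3G-enhanced genes (subset of occupied) |
| `n_occupied` | 350 | Pol III-occupied genes (elevated ChIP signal) |
| `n_samples` | 6 | samples per condition per assay |
| `conditions` / `availability` | monocyte 1.0, macrophage 0.2, stimulated 0.9 | latent POLR3G availability `a_c` |
| `beta` | 2.0 | log2 effect of availability on enhanced genes |
| `baseline_mu` | 100 | background mean count |
| `dispersion` | 0.2 | NB dispersion (CV² of gene rates) |
| `occupied_boost` | 6 | ChIP/ATAC/small-RNA rate multiplier at occupied genes |
| `gl_dampening` | 0.3 | POLR3GL ChIP damping at enhanced genes |
| `availability_jitter` | 0.05 | per-sample sd around the condition value |
| `library_sigma` | 0.2 | lognormal sd of per-sample depth factors |

Per biological sample, availability `a_s` is the condition value plus
jitter, clipped to [0, 1], and is shared by every assay of that sample.
Enhanced genes' mean signal in the POLR3G ChIP, ATAC and small-RNA tracks
scales as `2^(β·a_s)`, so the expected differential log2 fold change
between conditions equals `β·Δa`; POLR3GL ChIP at enhanced genes is
dampened by a constant factor; other subunit tracks are
availability-independent. POLR3G expression rises linearly with
availability above a floor while POLR3GL stays flat, making the identity
ratio a monotone availability readout. A small set of super-accessible
non-Pol III background loci (20 genes at 50× rate) tops the ATAC scale, as
in real consolidated annotations where some ncRNA entries sit in broadly
accessible chromatin; without them, rank normalization pins the most
accessible occupied gene at rank 1.0 in every sample, and its correlation
with anything becomes undefined — a scale-saturation artifact, not a
biological statement.

**Noise model.** Each gene's biological rate per track is drawn once from
a Gamma distribution with CV² = dispersion; per-sample counts are Poisson
around that rate times a lognormal depth factor (and the availability
effect). Marginally across genes a count is negative binomial
NB(μ, dispersion); repeated measurements of one gene are conditionally
Poisson, which is exactly the regime in which the conditional binomial
test is calibrated. What is *not* simulated: per-sample biological excess
variability beyond the shared gene rate, fragment-level structure
(lengths, GC, mappability), promoter-type architecture, or any
compositional normalization challenge beyond the planted effect itself.
Passing recovery tests therefore demonstrates the statistical machinery is
correct under its own assumptions — not that the exact binomial test is
adequate for biologically replicated real data, where a dispersion-aware
test is preferable.

All randomness flows from a single integer seed through one generator in a
fixed call order, so equal seeds give bit-identical matrices and fixture
files.

## Problem sizes used in the test and acceptance runs

Unit and property tests run on small universes (tens to hundreds of
genes). Recovery and calibration runs use the default conditions
(G = 2000, 20 planted genes, three conditions × 6 samples) over 20 seeded
replicates; the oracle-equivalence check uses 50 random instances with
G ≤ 50 and k ≤ 5 where exhaustive set enumeration is convenient. These
sizes were chosen to exercise every code path at full structural
complexity while keeping a complete run of the suite and the acceptance
script in the minutes range on one CPU.

## Known limitations

- The exact count test is anticonservative under per-sample biological
  overdispersion (see above); it is a documented stand-in, not a
  replacement for dispersion-modelling tests.
- Library-size normalization only; strong compositional shifts bias
  unaffected genes toward apparent gains (mitigated by direction
  filtering, not removed).
- The moving overlap treats one common cutoff across lists; per-list
  cutoffs are out of scope.
- Sample matching between assays is by (optionally normalized) string
  equality of sample ids; no fuzzy matching.
- The annotation module does not resolve cross-database identifier
  mappings; merging is purely coordinate-based.
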