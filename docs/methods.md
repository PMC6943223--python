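# Methods

This note documents the statistical models, the numerical choices, and the
assumptions behind each stage of the pipeline, plus what the synthetic data
do and do not emulate.

## Count model and differential-expression screen

Counts are modelled as negative binomial: gene *i* in sample *j* has mean
`μ_ij = s_j q_i` and variance `μ_ij + α_i μ_ij²`, where `s_j` is a
sample-specific size factor, `q_i` the gene's true expression and `α_i`
the overdispersion. `α = 0` degenerates to Poisson.

**Size factors** are the median-of-ratios estimator: over genes with
strictly positive counts in every sample,
`s_j = median_i( k_ij / (∏_j k_ij)^{1/n} )`. The estimator is undefined
when no gene is positive everywhere; this is reported as an explicit
error rather than silently patched. Only ratios of size factors matter to
the analysis: scaling one sample's column by `c` moves its size-factor
*ratio* to every other sample by exactly `c` (the raw value moves by
`c^{1−1/n}` because the geometric means absorb `c^{1/n}`).

**Dispersion.** `estimate_dispersion` is the pooled method-of-moments
estimator on normalized counts: `α̂ = max(floor, (v̂ − m̂)/m̂²)` with `m̂` the
grand mean and `v̂` the pooled within-condition variance (pooling removes
the between-condition mean difference from the variance). The floor
(default 1e-8) only guards zero-variance genes.

At 3 + 3 replicates this per-gene estimate has ~4 degrees of freedom and
is extremely noisy; a screen that trusts it gene by gene is
anticonservative, because genes whose dispersion is underestimated get
spuriously small p-values. The screen therefore also fits a
**mean–dispersion trend** `α(μ) = a₁ + a₀/μ` by least squares on
equal-occupancy bin means of the raw (unclamped) per-gene estimates —
bin means are approximately unbiased even though individual estimates are
heavily skewed — and tests each gene at `max(α̂_gene, α(μ̂_gene))`. Genes
keep their own estimate whenever it exceeds the trend, so no estimate is
shrunk toward the curve; the rule is purely conservative. With the true
dispersion plugged in, the exact test's null `p ≤ 0.05` rate is 0.050;
with per-gene estimates alone it roughly doubles; with the trend-max rule
it sits inside the nominal band (the acceptance checks measure this). The
trend needs ≥ 50 genes; below that the per-gene estimates are used as-is.

**Exact conditional test.** For each gene the two condition sums
`(K_A, K_B)` are modelled as independent NB variables whose null means are
`q₀ Σ_{j∈c} s_j` (with `q₀` the pooled normalized mean) and whose
variances add the per-sample NB variances. Conditioning on the total
`T = K_A + K_B`, the two-sided p-value is the probability mass of all
splits `(a, T−a)` no more likely than the observed one, divided by the
total mass — computed in log space with a `1 + 1e-7` relative tolerance
for float ties. Enumeration is exact up to `T = 100 000`; above that a
normal approximation to the conditional split distribution (mean
`μ_A + (T−μ_A−μ_B)·v_A/(v_A+v_B)`, variance `v_A v_B/(v_A+v_B)`, with
continuity correction) is used and logged.

**Calling.** `log2fc = log2((mean_B + 1)/(mean_A + 1))` on normalized
condition means — the pseudocount keeps fold changes finite at zero
counts; direction is treatment (B) over control (A). BH adjustment is the
standard step-up; the dual rule `call = up/down` requires both
`fdr ≤ 0.05` and `|log2fc| ≥ 0.585` (≈ 1.5-fold), the screen's printed
thresholds. Genes with zero counts in every sample are dropped before
testing and listed in the result metadata.

## Enrichment

One-sided Fisher's exact test per gene set: `p = P(X ≥ overlap)` for
`X ~ Hypergeom(universe, set, DEGs)`. The background universe is the set
of *tested* genes (post zero-filter), the standard choice when nothing
more specific is known; gene sets are intersected with it before testing.
Up- and down-regulated DEG lists are tested separately, and BH runs
within one direction × collection. GO-like collections flag significance
on the raw p (`≤ 0.01`), pathway-like on the FDR (`≤ 0.05`). Results are
sorted by p with a lexicographic set-id tie-break so output order is
total. Flat sets only — no term-hierarchy (DAG) propagation.

## Interaction networks

The relation vocabulary is the KEGG-style six: `act`, `inh`, `exp`,
`dissociation` (directed — they have a natural source and target) and
`bin`, `com` (undirected — symmetric by nature; reversed duplicates
collapse to one edge). The network is the induced multigraph of the
relation table on the significant ids (DEGs at gene level; pathways at
enrichment `p ≤ 0.05` at pathway level). Self-loops are dropped;
relations touching ids outside the namespace are skipped with a warning
and counted (annotation mismatch is expected, not fatal); isolated
retained nodes stay in the network and are reported. Degree counts all
incident edges (in + out for directed types). Ranking is degree-descending
with lexicographic tie-break.

## Differential co-expression and hub calling

Expression for correlation is `log2(normalized count + 1)` using the
screen's size factors. The node set is the called DEGs that have nonzero
expression variance in **both** conditions, so the two condition networks
are built over one common node set and are directly comparable. Within
one condition, a pair of genes is linked iff `|r| ≥ 0.9` **and** the
two-sided correlation t-test `t = r√(n−2)/√(1−r²)` gives `p ≤ 0.05`; the
edge records `r` and its sign. At n = 3 the t-test alone is extremely
permissive (df = 1; the combined rule is effectively `|r| ≥ 0.997`, which
~5% of independent pairs pass), which is why both thresholds are applied
and why per-gene conclusions at n = 3 rest on the *difference* between
the two networks rather than on either network alone.

The k-core number of a gene — the largest k such that the gene survives
iterative deletion of all nodes of degree < k — is computed by the
standard peeling order (implemented in-package; the tests cross-check it
against an independent repeated-deletion oracle and networkx). Per gene,
`DifDegree = |degree_A − degree_B|` and `DifKcore = |kcore_A − kcore_B|`
are absolute differences: a hub lost and a hub gained are equally
reportable. **Core regulatory factors** are genes with `DifDegree ≥ 12`
and `DifKcore ≥ 8`. Network-level totals (nodes, edges, positive and
negative edge counts per condition) are always reported, and the identity
`positive + negative = total` is asserted on every run.

## Synthetic data

The generator emulates a small two-group RNA-seq screen at the count
level (no reads, no alignment):

- **Design**: 2 conditions × `n_replicates` (default 3, the study-scale
  design the pipeline targets).
- **Baseline means** log-uniform over `10^0.5 … 10^3.5` (typical bulk
  RNA-seq dynamic range).
- **Dispersion** single global `α = 0.05` by default — a typical
  cell-line bulk value; an optional lognormal per-gene spread exists but
  is off by default so tests stay interpretable.
- **Planted DEGs**: a rounded fraction (default 10%) of genes, split
  50/50 up/down, with condition-B mean = condition-A mean × `2^{±lfc}`
  (default magnitude 1).
- **Modules**: disjoint gene groups whose means, in the module's active
  condition only, are multiplied by a shared per-sample lognormal factor
  `exp(N(−σ²/2, σ))`, σ = 0.5 by default. The factor is mean-centred so
  planting a module does not bias marginal means. Module genes are drawn
  from the planted-DEG pool: the co-expression stage runs on called DEGs,
  so condition-specific modules must sit inside that set to be visible
  downstream. The first gene of each module is recorded as its hub.
- **Gene sets**: enriched sets draw ≥ 50% of members from planted DEGs,
  the rest (and all background sets) uniformly from the universe.
- **Relations**: uniform random typed edges without duplicate
  (source, target, type) triples, type drawn by configurable weights.

Everything is deterministic given the seed (one `numpy` Generator, fixed
draw order), including byte-identical GMT/TSV/JSON output.

What the synthetic data do **not** emulate: GC/length biases, batch
effects, library-preparation artifacts, correlated background structure
beyond the planted modules, annotation incompleteness, or realistic
gene-set overlap topology. Passing the recovery tests therefore shows the
*inference machinery* is correct and calibrated under the stated model,
not that any particular biological dataset meets that model.

## Problem sizes and numerical choices

The simulation-based checks use 2000 genes for calibration/recovery, 20
independent seeds for averaged recovery rates, and 1000-gene designs for
enrichment recovery — sizes at which the measured rates are stable to a
few percent while the whole suite stays fast. Exact-test enumeration is
`O(T)` per gene and vectorised; the `T > 10⁵` fallback practically never
triggers at these scales. Ties: BH is the statsmodels step-up;
enrichment and degree rankings break ties lexicographically; the exact
test counts float-tied splits via a `1 + 1e-7` factor. Degenerate inputs
(all-zero genes, zero-variance genes, empty DEG lists, empty relation
tables) are handled explicitly and surface in metadata rather than as
exceptions; truly undefined quantities (size factors with no all-positive
gene, correlation of a constant vector) raise errors that name the
condition.

## Known limitations

- Two-group designs only: no covariates, batch terms, or multi-factor
  models.
- The dispersion trend is a two-parameter `a₁ + a₀/μ` curve; datasets
  with more complex mean–variance structure would need a richer fit.
- At n = 3 the co-expression networks are individually noisy (see above);
  the differential metrics are the supported read-out.
- Gene identifiers are treated as opaque strings; no id mapping or
  annotation retrieval is performed.
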