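# difconet

Transcriptome-to-network analysis for two-condition RNA-seq experiments:
from a raw gene × sample count matrix to the genes whose *network position*
— not just expression level — changes between conditions.

The package re-implements, as a tested and reusable library, the analysis
chain commonly used to nominate central regulated pathways from a small
perturbation experiment (e.g. an overexpression cell model with 3 control
and 3 treatment replicates):

1. **Differential expression** — DESeq-style negative-binomial screen:
   median-of-ratios size factors `s_j = median_i(k_ij / (∏_j k_ij)^{1/n})`,
   per-gene method-of-moments dispersion α with variance `μ + αμ²`, an
   exact conditional NB test on the two condition sums, Benjamini–Hochberg
   FDR, and the dual call rule `|log2FC| ≥ 0.585` and `FDR ≤ 0.05`.
2. **Direction-split enrichment** — one-sided Fisher's exact test
   (hypergeometric upper tail `P(X ≥ overlap)`) of the up- and
   down-regulated DEG lists against GMT gene-set collections; GO-like
   collections call significance at `p ≤ 0.01`, pathway-like at
   `FDR ≤ 0.05`.
3. **Typed interaction networks** — induced subgraphs of a KEGG-style
   relation table (activation / inhibition / binding / compound /
   expression / dissociation) over the significant genes or pathways,
   ranked by degree to nominate hubs.
4. **Differential co-expression** — one hard-thresholded Pearson network
   per condition over the same DEG node set (edge iff `|r| ≥ 0.9` and the
   correlation t-test gives `p ≤ 0.05`), per-gene degree and k-core in
   each network, and **core regulatory factors** called at
   `DifDegree = |degree_A − degree_B| ≥ 12` and
   `DifKcore = |kcore_A − kcore_B| ≥ 8`.

A synthetic-data module generates count matrices, gene sets and relation
tables with planted ground truth (known DEGs, enriched sets,
condition-specific co-expression modules and hubs), so every stage is
verifiable offline, end to end.

## Worked example

```python
from difconet import (SimulationConfig, generate_counts, call_degs,
                      split_by_direction)

cm, truth = generate_counts(SimulationConfig(
    n_genes=1000, deg_fraction=0.1, lfc_magnitude=2.0, seed=7))
table = call_degs(cm)            # size factors -> dispersion -> exact test -> BH
up, down = split_by_direction(table)
```

`table` holds, per gene, the normalized condition means, `log2fc`
(treatment over control, pseudocount 1), the exact-test `p_value`, the BH
`fdr` and the `call`:

```
       base_mean_A  base_mean_B    log2fc   p_value       fdr call
gene
G0001   216.456481   229.234958  0.082380  0.827159  0.998412   ns
G0002  1915.939875  1388.596672 -0.464139  0.075206  0.496202   ns
G0003   477.901914   715.456980  0.581150  0.028364  0.247194   ns

called 51 up + 44 down of 1000 tested genes
sensitivity 0.91, false-discovery proportion 0.042
```

Of the 100 planted DEGs (|log2FC| = 2, 3 vs 3 replicates), 91% are
recovered and 4.2% of the 95 calls are false — the dual threshold holds
the realized FDR near its nominal 5%.

The `examples/` directory has one short script per capability
(`simulate_counts.py`, `deg_screen.py`, `enrichment.py`,
`interaction_network.py`, `differential_coexpression.py`,
`full_pipeline.py`); each prints the numbers it computes and one line on
what they mean.

The same stages are scriptable from the shell via the thin `difconet` CLI
(`difconet degs / enrich / coexp / run / simulate`); `difconet run
--config run.yaml` executes the whole pipeline and writes TSV / GMT /
GraphML / JSON artifacts plus a provenance record, byte-identical across
reruns at a fixed seed.

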