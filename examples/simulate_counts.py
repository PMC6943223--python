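"""Generate a synthetic two-condition RNA-seq count matrix with planted truth.

The generator draws negative-binomial counts (variance mu + alpha mu^2) for
3 + 3 replicates, plants 10% differentially expressed genes at a chosen
log2 fold change, and embeds condition-specific co-expression modules.
"""

from difconet import SimulationConfig, generate_counts

config = SimulationConfig(n_genes=500, deg_fraction=0.1, lfc_magnitude=2.0,
                          n_modules=2, module_size=8, seed=1)
cm, truth = generate_counts(config)

print(f"count matrix: {cm.counts.shape[0]} genes x {cm.counts.shape[1]} samples")
print(f"planted DEGs: {len(truth.deg_ids_up)} up, {len(truth.deg_ids_down)} down")
print(f"planted modules: {sorted(set(truth.module_membership.values()))}, "
      f"hubs {sorted(truth.hub_ids)}")
print(cm.counts.iloc[:5])
# Each row is a gene, each column a replicate (A = control, B = treatment);
# planted 'up' genes have condition-B means 4x their condition-A means.
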