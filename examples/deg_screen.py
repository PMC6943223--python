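"""Differential-expression screen: size factors, NB exact test, dual threshold.

Calls genes at |log2FC| >= 0.585 and FDR <= 0.05 and scores the calls
against the planted truth.
"""

from difconet import (SimulationConfig, call_degs, generate_counts,
                      split_by_direction)

cm, truth = generate_counts(SimulationConfig(n_genes=1000, deg_fraction=0.1,
                                             lfc_magnitude=2.0, seed=7))
table = call_degs(cm)
up, down = split_by_direction(table)
called = up | down
tp = len(called & truth.deg_ids)

print(table.head())
print(f"\ncalled {len(up)} up + {len(down)} down of {len(table)} tested genes")
print(f"sensitivity {tp / len(truth.deg_ids):.2f} "
      f"(planted DEGs recovered), false-discovery proportion "
      f"{(len(called) - tp) / len(called):.3f} (calls that were not planted)")
# log2fc is condition B over A; p comes from the exact conditional NB test
# on the two condition sums, fdr is the Benjamini-Hochberg adjustment.
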