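"""Typed interaction network over significant entities, ranked by degree.

Relations carry KEGG-style types (act/inh/bin/com/exp/dissociation); the
network is the induced subgraph on the significant ids, and degree ranking
nominates the most connected ("core") entities.
"""

import pandas as pd

from difconet import build_network, generate_relations, rank_by_degree

entities = [f"P{i:02d}" for i in range(12)]
relations = generate_relations(entities, n_edges=30, seed=5)

significant = pd.DataFrame({
    "id": entities[:8],
    "regulation": ["up"] * 4 + ["down"] * 4,
    "p_value": [0.001, 0.004, 0.01, 0.02, 0.03, 0.04, 0.05, 0.06],
})
net = build_network(significant, relations, p_threshold=0.05, level="pathway")

print(f"retained {net.graph.number_of_nodes()} of {len(significant)} entities "
      f"(p <= 0.05), {net.graph.number_of_edges()} edges, "
      f"{len(net.skipped_edges)} relations skipped")
for node, degree in rank_by_degree(net)[:5]:
    print(f"  {node}: degree {degree} ({net.graph.nodes[node]['regulation']})")
# The highest-degree node is the hub: the entity whose relations tie the
# most other significant entities together.
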