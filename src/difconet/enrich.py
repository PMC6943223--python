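"""Direction-split gene-set enrichment by one-sided Fisher's exact test.

For each gene set, a 2x2 table (in set vs not) x (DEG vs not) over the
background universe is tested one-sided for enrichment; the p-value equals
the hypergeometric upper tail P(X >= overlap).  FDR is Benjamini-Hochberg
across the sets of one direction x collection.  GO-like collections call
significance on the raw p (p <= 0.01); pathway-like collections on the FDR
(fdr <= 0.05), mirroring the two conventions of the screen this package
re-implements.
"""

from __future__ import annotations

from typing import Iterable

import pandas as pd
from scipy import stats

from .deg import bh_adjust
from .genesets import GeneSetCollection

GO_P_MAX = 0.01
PATHWAY_FDR_MAX = 0.05


def fisher_enrich(deg_ids: Iterable[str], collection: GeneSetCollection,
                  direction: str, p_max: float = GO_P_MAX,
                  fdr_max: float = PATHWAY_FDR_MAX) -> pd.DataFrame:
    """Enrichment of one DEG direction against every set in a collection.

    Returns a DataFrame sorted by p ascending (set id as tie-break) with
    columns set_id, overlap_count, set_size, n_degs, universe_size, p_value,
    fdr, direction, significant.
    """
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    degs = set(deg_ids)
    stray = degs - collection.universe
    if stray:
        raise ValueError(f"DEG gene(s) absent from the universe: {sorted(stray)[:5]}")
    m = len(collection.universe)
    n_degs = len(degs)
    rows = []
    for set_id in sorted(collection.sets):
        members = collection.sets[set_id]
        overlap = len(members & degs)
        # upper tail P(X >= overlap) of Hypergeom(M=m, n=|set|, N=n_degs)
        p = float(stats.hypergeom.sf(overlap - 1, m, len(members), n_degs))
        rows.append((set_id, overlap, len(members), n_degs, m, min(p, 1.0)))
    result = pd.DataFrame(
        rows,
        columns=["set_id", "overlap_count", "set_size", "n_degs", "universe_size", "p_value"],
    )
    result["fdr"] = bh_adjust(result["p_value"]) if len(result) else []
    result["direction"] = direction
    if collection.kind == "go_like":
        result["significant"] = result["p_value"] <= p_max
    else:
        result["significant"] = result["fdr"] <= fdr_max
    result = result.sort_values(["p_value", "set_id"], kind="mergesort").reset_index(drop=True)
    return result


def split_by_direction(deg_table: pd.DataFrame) -> tuple[set[str], set[str]]:
    """Partition called DEGs into (up ids, down ids); ns genes are excluded."""
    up = set(deg_table.index[deg_table["call"] == "up"])
    down = set(deg_table.index[deg_table["call"] == "down"])
    return up, down


def write_enrichment(result: pd.DataFrame, path) -> None:
    result.to_csv(path, sep="\t", index=False)
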