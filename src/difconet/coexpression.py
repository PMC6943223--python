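"""Differential co-expression networks and hub (core-regulator) calling.

One hard-thresholded Pearson network is built per condition over the same
gene set, on log2(normalized count + 1) expression.  A pair of genes is
linked when |r| >= r_min AND the two-sided correlation t-test gives
p <= alpha; the edge carries the coefficient and its sign.  Per gene and
per network the degree and the k-core number are computed; the absolute
between-condition differences (DifDegree, DifKcore) flag genes whose hub
status changes with the condition, and genes with DifDegree >= 12 and
DifKcore >= 8 are called core regulatory factors.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .counts import CountMatrix
from .deg import estimate_size_factors

DIF_DEGREE_MIN = 12
DIF_KCORE_MIN = 8


@dataclass
class CoexpressionNetwork:
    condition: str
    graph: nx.Graph

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def summary(self) -> dict:
        signs = [d["sign"] for _, _, d in self.graph.edges(data=True)]
        positive = sum(s == "positive" for s in signs)
        return {
            "condition": self.condition,
            "nodes": self.graph.number_of_nodes(),
            "edges": self.graph.number_of_edges(),
            "positive_edges": positive,
            "negative_edges": len(signs) - positive,
        }


@dataclass
class DifferentialNetworkReport:
    per_gene: pd.DataFrame
    summary_A: dict
    summary_B: dict

    def core_regulators(self) -> list[str]:
        return sorted(self.per_gene.index[self.per_gene["is_core_regulator"]])


def pearson(x, y) -> float:
    """Product-moment correlation of two equal-length vectors (n >= 3)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for a zero-variance vector")
    return float(np.corrcoef(x, y)[0, 1])


def _correlation_p(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p of the t-test t = r sqrt(n-2) / sqrt(1-r^2), df = n-2."""
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return np.where(np.abs(r) >= 1.0, 0.0, p)


def expression_matrix(cm: CountMatrix, size_factors: pd.Series | None = None) -> pd.DataFrame:
    """log2(normalized count + 1) expression, genes x samples."""
    if size_factors is None:
        size_factors = estimate_size_factors(cm)
    norm = cm.counts.to_numpy(dtype=float) / size_factors.reindex(cm.sample_ids).to_numpy()
    return pd.DataFrame(np.log2(norm + 1.0), index=cm.gene_ids, columns=cm.sample_ids)


def shared_variance_genes(cm: CountMatrix, genes, size_factors: pd.Series | None = None) -> list[str]:
    """Genes (from ``genes``) with non-zero expression variance in BOTH
    conditions — the shared node set that makes the two networks comparable."""
    expr = expression_matrix(cm, size_factors)
    genes = [g for g in genes if g in expr.index]
    keep = []
    var_ok = {}
    for label in ("A", "B"):
        cols = cm.samples_of(label)
        var_ok[label] = expr.loc[genes, cols].std(axis=1) > 0
    for g in genes:
        if var_ok["A"][g] and var_ok["B"][g]:
            keep.append(g)
    return keep


def build_condition_network(cm: CountMatrix, genes, condition: str,
                            r_min: float = 0.9, alpha: float = 0.05,
                            size_factors: pd.Series | None = None) -> CoexpressionNetwork:
    """Hard-thresholded Pearson network for one condition.

    ``genes`` is the shared node list (use :func:`shared_variance_genes` so
    both condition networks are node-matched).  Requires >= 3 samples in the
    condition.  Pairs where either gene has zero variance in this condition
    are excluded from edge formation but the genes stay as nodes.
    """
    cols = cm.samples_of(condition)
    if len(cols) < 3:
        raise ValueError(f"condition {condition} has {len(cols)} samples; need >= 3")
    missing = [g for g in genes if g not in cm.gene_ids]
    if missing:
        raise ValueError(f"gene(s) not in count matrix: {missing[:5]}")
    expr = expression_matrix(cm, size_factors).loc[list(genes), cols]
    x = expr.to_numpy()
    n = x.shape[1]
    sd = x.std(axis=1)
    g = nx.Graph(condition=condition)
    g.add_nodes_from(genes)
    ok = sd > 0
    if ok.sum() >= 2:
        idx = np.flatnonzero(ok)
        with np.errstate(invalid="ignore"):
            r_mat = np.corrcoef(x[idx])
        p_mat = _correlation_p(r_mat, n)
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                r = r_mat[a, b]
                if np.isfinite(r) and abs(r) >= r_min and p_mat[a, b] <= alpha:
                    g.add_edge(
                        genes[idx[a]], genes[idx[b]],
                        r=float(r), sign="positive" if r > 0 else "negative",
                    )
    return CoexpressionNetwork(condition=condition, graph=g)


def kcore_decomposition(net: CoexpressionNetwork | nx.Graph) -> dict[str, int]:
    """Core number per node by the standard peeling order.

    The core number of a node is the largest k such that the node survives
    iterative removal of all nodes of degree < k.  Implemented by peeling:
    at level k, repeatedly delete every node whose remaining degree is <= k
    and assign it core number k, then raise k.
    """
    graph = net.graph if isinstance(net, CoexpressionNetwork) else net
    degrees = dict(graph.degree())
    neighbors = {n: set(graph.neighbors(n)) for n in graph}
    core: dict[str, int] = {}
    remaining = set(graph.nodes)
    k = 0
    while remaining:
        peel = [n for n in remaining if degrees[n] <= k]
        if not peel:
            k += 1
            continue
        for n in peel:
            core[n] = k
            remaining.discard(n)
            for m in neighbors[n]:
                if m in remaining:
                    degrees[m] -= 1
                    neighbors[m].discard(n)
    return core


def differential_report(net_a: CoexpressionNetwork, net_b: CoexpressionNetwork,
                        dif_degree_min: int = DIF_DEGREE_MIN,
                        dif_kcore_min: int = DIF_KCORE_MIN) -> DifferentialNetworkReport:
    """Per-gene degree/k-core differences and core-regulator calls.

    Both networks must share one node set; a mismatch raises with the
    symmetric difference.  Also reports network-level totals (node, edge,
    positive- and negative-edge counts per condition).
    """
    if net_a.nodes != net_b.nodes:
        diff = sorted(net_a.nodes ^ net_b.nodes)
        raise ValueError(f"node sets differ; symmetric difference: {diff[:10]}")
    core_a = kcore_decomposition(net_a)
    core_b = kcore_decomposition(net_b)
    genes = sorted(net_a.nodes)
    rows = []
    for g in genes:
        da, db = net_a.graph.degree(g), net_b.graph.degree(g)
        ka, kb = core_a[g], core_b[g]
        rows.append((da, db, ka, kb, abs(da - db), abs(ka - kb)))
    per_gene = pd.DataFrame(
        rows,
        index=pd.Index(genes, name="gene"),
        columns=["degree_A", "degree_B", "kcore_A", "kcore_B", "dif_degree", "dif_kcore"],
    )
    per_gene["is_core_regulator"] = (
        (per_gene["dif_degree"] >= dif_degree_min) & (per_gene["dif_kcore"] >= dif_kcore_min)
    )
    assert (per_gene["kcore_A"] <= per_gene["degree_A"]).all()
    assert (per_gene["kcore_B"] <= per_gene["degree_B"]).all()
    return DifferentialNetworkReport(
        per_gene=per_gene, summary_A=net_a.summary(), summary_B=net_b.summary()
    )


def write_coexpression_network(net: CoexpressionNetwork, graphml_path: str | Path,
                               edges_path: str | Path) -> None:
    nx.write_graphml(net.graph, str(graphml_path))
    rows = sorted(
        (min(u, v), max(u, v), d["r"], d["sign"]) for u, v, d in net.graph.edges(data=True)
    )
    pd.DataFrame(rows, columns=["gene1", "gene2", "r", "sign"]).to_csv(
        edges_path, sep="\t", index=False
    )


def write_report(report: DifferentialNetworkReport, path: str | Path) -> None:
    report.per_gene.to_csv(path, sep="\t")
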