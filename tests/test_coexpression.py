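"""Co-expression networks, k-core decomposition, differential hub report."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from difconet import (CountMatrix, CoexpressionNetwork,
                      build_condition_network, differential_report,
                      generate_counts, kcore_decomposition, pearson,
                      shared_variance_genes, SimulationConfig)
from difconet.coexpression import _correlation_p
from oracles import kcore_brute, pearson_brute


def as_network(graph: nx.Graph, condition: str) -> CoexpressionNetwork:
    for _, _, d in graph.edges(data=True):
        d.setdefault("r", 0.95)
        d.setdefault("sign", "positive")
    return CoexpressionNetwork(condition=condition, graph=graph)


def counts_from_expression(expr: np.ndarray, n_a: int) -> CountMatrix:
    """Integer counts whose log-expression mirrors the given matrix."""
    counts = np.round(2.0 ** expr).astype(int)
    samples = [f"A{i}" for i in range(n_a)] + [f"B{i}" for i in range(expr.shape[1] - n_a)]
    return CountMatrix(
        pd.DataFrame(counts, index=[f"g{i}" for i in range(expr.shape[0])], columns=samples),
        pd.Series(["A"] * n_a + ["B"] * (expr.shape[1] - n_a), index=samples),
    )


class TestPearson:
    def test_affine_relations(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson(x, -x) == pytest.approx(-1.0)

    def test_known_value(self):
        assert pearson([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            x, y = rng.normal(size=(2, 9))
            assert pearson(x, y) == pytest.approx(pearson_brute(list(x), list(y)))

    def test_validation(self):
        with pytest.raises(ValueError):
            pearson([1, 2], [3, 4])
        with pytest.raises(ValueError, match="zero-variance"):
            pearson([1, 1, 1], [1, 2, 3])


class TestBuildConditionNetwork:
    def test_shared_latent_factor_gives_positive_edge(self):
        # two genes driven by one factor with vanishing noise
        rng = np.random.default_rng(0)
        factor = rng.normal(8, 1, size=6)
        expr = np.vstack([factor + rng.normal(0, 1e-3, 6) for _ in range(2)]
                         + [rng.normal(8, 1, size=(4, 6))])
        cm = counts_from_expression(expr, n_a=3)
        net = build_condition_network(cm, [f"g{i}" for i in range(6)], "A")
        assert net.graph.has_edge("g0", "g1")
        assert net.graph.edges["g0", "g1"]["sign"] == "positive"

    def test_null_edge_density_matches_monte_carlo(self):
        # independent genes at n=3: edge rule rate vs a direct MC estimate
        rng = np.random.default_rng(3)
        n_genes = 120
        expr = rng.normal(10, 1, size=(n_genes, 6))
        cm = counts_from_expression(expr, n_a=3)
        genes = [f"g{i}" for i in range(n_genes)]
        net = build_condition_network(cm, genes, "A", r_min=0.9, alpha=0.05)
        n_pairs = n_genes * (n_genes - 1) // 2
        density = net.graph.number_of_edges() / n_pairs

        draws = rng.normal(size=(20_000, 2, 3))
        r = np.array([np.corrcoef(a)[0, 1] for a in draws])
        p = _correlation_p(r, 3)
        mc = float(((np.abs(r) >= 0.9) & (p <= 0.05)).mean())
        se = np.sqrt(mc * (1 - mc) * (1 / n_pairs + 1 / 20_000))
        assert abs(density - mc) < 4 * se + 0.005

    def test_planted_module_denser_in_active_condition(self):
        # paired comparison over 20 seeds: module active in A only
        total_a = total_b = 0
        not_worse = 0
        for seed in range(20):
            cfg = SimulationConfig(n_genes=200, n_replicates=20, deg_fraction=0.2,
                                   lfc_magnitude=2.0, n_modules=1, module_size=8,
                                   module_condition="A", seed=300 + seed)
            cm, truth = generate_counts(cfg)
            module = sorted(truth.module_membership)
            nodes = shared_variance_genes(cm, module)
            edges_a = build_condition_network(cm, nodes, "A").graph.number_of_edges()
            edges_b = build_condition_network(cm, nodes, "B").graph.number_of_edges()
            total_a += edges_a
            total_b += edges_b
            not_worse += edges_a >= edges_b
        assert total_a > total_b
        assert not_worse >= 18

    def test_too_few_samples_rejected(self, small_cm):
        cond = small_cm.condition.copy()
        cm = CountMatrix(small_cm.counts.iloc[:, [0, 1, 3, 4, 5]], cond)
        with pytest.raises(ValueError, match="need >= 3"):
            build_condition_network(cm, list(cm.gene_ids), "A")

    def test_shared_variance_excludes_flat_genes(self, small_cm):
        counts = small_cm.counts.copy()
        counts.loc["gflat"] = [0, 0, 0, 20, 30, 40]  # no expression variance in A
        cm = CountMatrix(counts, small_cm.condition)
        nodes = shared_variance_genes(cm, list(cm.gene_ids))
        assert "gflat" not in nodes


class TestKcore:
    def test_triangle_all_two(self):
        assert set(kcore_decomposition(nx.complete_graph(3)).values()) == {2}

    def test_star_all_one(self):
        core = kcore_decomposition(nx.star_graph(6))
        assert set(core.values()) == {1}

    def test_erdos_renyi_matches_brute_force_and_networkx(self):
        g = nx.gnp_random_graph(12, 0.4, seed=5)
        ours = kcore_decomposition(g)
        adjacency = {n: set(g.neighbors(n)) for n in g}
        assert ours == kcore_brute(adjacency)
        assert ours == nx.core_number(g)

    def test_isolated_nodes_core_zero(self):
        g = nx.Graph()
        g.add_nodes_from(["a", "b"])
        g.add_edge("b", "c")
        assert kcore_decomposition(g) == {"a": 0, "b": 1, "c": 1}


class TestDifferentialReport:
    def test_identical_networks_yield_no_regulators(self):
        g = nx.gnp_random_graph(10, 0.5, seed=2)
        report = differential_report(as_network(g, "A"), as_network(g.copy(), "B"))
        assert (report.per_gene[["dif_degree", "dif_kcore"]] == 0).all().all()
        assert report.core_regulators() == []

    def test_clique_gene_below_thresholds_not_called(self):
        # 10-clique in A (degree 9, core 9), isolated in B: 9 < 12
        g_a = nx.complete_graph(10)
        g_b = nx.empty_graph(10)
        report = differential_report(as_network(g_a, "A"), as_network(g_b, "B"))
        row = report.per_gene.loc[0]
        assert (row["dif_degree"], row["dif_kcore"]) == (9, 9)
        assert not row["is_core_regulator"]

    def test_high_degree_clique_gene_called(self):
        # hub: 10-clique (core 9) plus 5 extra partners -> degree 14
        g_a = nx.complete_graph(10)
        g_a.add_edges_from((0, 10 + i) for i in range(5))
        g_b = nx.empty_graph(15)
        report = differential_report(as_network(g_a, "A"), as_network(g_b, "B"))
        row = report.per_gene.loc[0]
        assert (row["dif_degree"], row["dif_kcore"]) == (14, 9)
        assert row["is_core_regulator"]
        assert report.core_regulators() == [0]

    def test_node_set_mismatch_reports_difference(self):
        g_a = nx.empty_graph(3)
        g_b = nx.empty_graph(4)
        with pytest.raises(ValueError, match="3"):
            differential_report(as_network(g_a, "A"), as_network(g_b, "B"))

    def test_kcore_bounded_by_degree_and_sign_totals(self, sim_default):
        _, cm, truth = sim_default
        nodes = shared_variance_genes(cm, sorted(truth.deg_ids))
        net_a = build_condition_network(cm, nodes, "A")
        net_b = build_condition_network(cm, nodes, "B")
        report = differential_report(net_a, net_b)
        pg = report.per_gene
        assert (pg["kcore_A"] <= pg["degree_A"]).all()
        assert (pg["kcore_B"] <= pg["degree_B"]).all()
        for summary, net in ((report.summary_A, net_a), (report.summary_B, net_b)):
            assert summary["positive_edges"] + summary["negative_edges"] == summary["edges"]
            assert summary["edges"] == net.graph.number_of_edges()

    def test_condition_swap_leaves_dif_metrics_unchanged(self, sim_default):
        _, cm, truth = sim_default
        nodes = shared_variance_genes(cm, sorted(truth.deg_ids))
        net_a = build_condition_network(cm, nodes, "A")
        net_b = build_condition_network(cm, nodes, "B")
        fwd = differential_report(net_a, net_b)
        swapped_cm = cm.swap_conditions()
        s_a = build_condition_network(swapped_cm, nodes, "A")
        s_b = build_condition_network(swapped_cm, nodes, "B")
        rev = differential_report(s_a, s_b)
        pd.testing.assert_series_equal(fwd.per_gene["degree_A"], rev.per_gene["degree_B"],
                                       check_names=False)
        pd.testing.assert_frame_equal(
            fwd.per_gene[["dif_degree", "dif_kcore", "is_core_regulator"]],
            rev.per_gene[["dif_degree", "dif_kcore", "is_core_regulator"]],
        )
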