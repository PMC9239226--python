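import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from raresoil.core import CommunityTable
from raresoil.network import (
    CooccurrenceNetwork,
    build_network,
    degree_support_regression,
    export_network,
    node_support_scores,
)
from raresoil.partition import AbundanceClasses, ThresholdScheme


def make_classes(table, labels):
    return AbundanceClasses(
        phylotype_ids=list(table.phylotype_ids),
        dataset_relabund=np.full(table.n_phylotypes, 0.01),
        label=labels,
        scheme=ThresholdScheme(),
        group=table.group,
    )


def engineered_network(rng, extra_cols=0, n=40):
    """Two perfectly co-occurring phylotypes plus independent noise."""
    shared = rng.integers(1, 100, size=n)
    cols = [shared + 1, shared * 2 + 2]  # identical ranks
    for _ in range(2 + extra_cols):
        cols.append(rng.integers(1, 100, size=n))
    counts = np.column_stack(cols)
    table = CommunityTable(
        sample_ids=[f"s{i}" for i in range(n)],
        phylotype_ids=[f"p{j}" for j in range(counts.shape[1])],
        counts=counts,
        group="bacteria",
    )
    classes = make_classes(table, ["abundant"] * counts.shape[1])
    return table, classes


class TestBuildNetwork:
    def test_perfect_cooccurrence_edge(self, rng):
        table, classes = engineered_network(rng)
        net = build_network({"bacteria": table}, {"bacteria": classes}, "abundant",
                            prevalence_min=0.0)
        assert net.graph.has_edge("p0", "p1")
        assert np.isclose(net.graph.edges["p0", "p1"]["rho"], 1.0)

    def test_rho_exactly_at_threshold_excluded(self):
        # spearman rho between these rank patterns is exactly 0.6
        a = np.array([1, 2, 3, 4, 5])
        b = np.array([3, 2, 1, 4, 5])
        assert np.isclose(stats.spearmanr(a, b).statistic, 0.6)
        # large constant buffer column keeps per-sample relative abundances
        # rank-identical to the raw counts (avoids 2-column closure)
        buffer = np.full(5, 1000)
        table = CommunityTable(
            sample_ids=[f"s{i}" for i in range(5)],
            phylotype_ids=["p0", "p1", "p2"],
            counts=np.column_stack([a, b, buffer]),
            group="fungi",
        )
        classes = make_classes(table, ["rare", "rare", "abundant"])
        net = build_network({"fungi": table}, {"fungi": classes}, "rare",
                            prevalence_min=0.0, q_max=2.0)
        assert net.n_edges == 0

    def test_independent_phylotypes_no_edges(self, rng):
        zero_edge_runs = 0
        for s in range(5):
            local = np.random.default_rng(1234 + s)
            counts = local.integers(1, 100, size=(30, 50))
            table = CommunityTable(
                [f"s{i}" for i in range(30)], [f"p{j}" for j in range(50)], counts, "fungi"
            )
            classes = make_classes(table, ["rare"] * 50)
            net = build_network({"fungi": table}, {"fungi": classes}, "rare",
                                prevalence_min=0.0)
            zero_edge_runs += net.n_edges == 0
        assert zero_edge_runs >= 4

    def test_too_few_candidates_error(self, rng):
        table, classes = engineered_network(rng)
        with pytest.raises(ValueError, match="candidate"):
            build_network({"bacteria": table}, {"bacteria": classes}, "rare",
                          prevalence_min=0.0)

    def test_degree_sum_is_twice_edges(self, rng):
        table, classes = engineered_network(rng, extra_cols=10)
        net = build_network({"bacteria": table}, {"bacteria": classes}, "abundant",
                            prevalence_min=0.0, rho_min=0.0, q_max=1.01)
        assert sum(d for _, d in net.graph.degree()) == 2 * net.n_edges

    def test_deterministic(self, rng):
        table, classes = engineered_network(rng, extra_cols=5)
        net1 = build_network({"bacteria": table}, {"bacteria": classes}, "abundant",
                             prevalence_min=0.0)
        net2 = build_network({"bacteria": table}, {"bacteria": classes}, "abundant",
                             prevalence_min=0.0)
        assert set(net1.graph.edges) == set(net2.graph.edges)


class TestNodeSupport:
    def test_self_correlation(self, rng):
        table, classes = engineered_network(rng)
        net = build_network({"bacteria": table}, {"bacteria": classes}, "abundant",
                            prevalence_min=0.0)
        mf = net.abundances["p2"].to_numpy()
        node_support_scores(net, mf)
        assert np.isclose(net.graph.nodes["p2"]["support_score"], 1.0)
        assert net.graph.nodes["p2"]["display"]

    def test_negative_not_displayed(self, rng):
        table, classes = engineered_network(rng)
        net = build_network({"bacteria": table}, {"bacteria": classes}, "abundant",
                            prevalence_min=0.0)
        mf = -net.abundances["p2"].to_numpy()
        node_support_scores(net, mf)
        assert np.isclose(net.graph.nodes["p2"]["support_score"], -1.0)
        assert not net.graph.nodes["p2"]["display"]

    def test_pearson_formula_oracle(self, rng):
        table, classes = engineered_network(rng, extra_cols=3)
        net = build_network({"bacteria": table}, {"bacteria": classes}, "abundant",
                            prevalence_min=0.0)
        mf = rng.normal(size=40)
        node_support_scores(net, mf)
        for node in net.nodes:
            ref = stats.pearsonr(net.abundances[node], mf).statistic
            assert np.isclose(net.graph.nodes[node]["support_score"], ref, atol=1e-12)


class TestDegreeSupport:
    def _net_with_degrees(self):
        g = nx.path_graph(6)  # degrees: 1,2,2,2,2,1
        g = nx.relabel_nodes(g, {i: f"p{i}" for i in range(6)})
        g.add_edge("p0", "p2")  # vary degrees a bit
        net = CooccurrenceNetwork(graph=g, label="abundant")
        return net

    def test_exact_line(self):
        net = self._net_with_degrees()
        for node in net.graph.nodes:
            net.graph.nodes[node]["support_score"] = 0.01 * net.graph.degree(node)
            net.graph.nodes[node]["display"] = True
        fit = degree_support_regression(net)
        assert np.isclose(fit.slope, 0.01)
        assert np.isclose(fit.r_squared, 1.0)

    def test_negative_slope(self):
        net = self._net_with_degrees()
        for node in net.graph.nodes:
            net.graph.nodes[node]["support_score"] = -0.01 * net.graph.degree(node)
            net.graph.nodes[node]["display"] = True
        assert degree_support_regression(net).slope < 0

    def test_null_independence(self):
        hits = 0
        n_rep = 100
        rng = np.random.default_rng(3)
        net = self._net_with_degrees()
        for _ in range(n_rep):
            for node in net.graph.nodes:
                net.graph.nodes[node]["support_score"] = rng.normal()
                net.graph.nodes[node]["display"] = True
            hits += degree_support_regression(net).p_value < 0.05
        assert hits <= 0.15 * n_rep

    def test_equal_degrees_error(self):
        g = nx.cycle_graph(4)  # all degree 2
        g = nx.relabel_nodes(g, {i: f"p{i}" for i in range(4)})
        net = CooccurrenceNetwork(graph=g, label="rare")
        for node in net.graph.nodes:
            net.graph.nodes[node]["support_score"] = 0.1
            net.graph.nodes[node]["display"] = True
        with pytest.raises(ValueError):
            degree_support_regression(net)


class TestExport:
    def test_files_written(self, rng, tmp_path):
        table, classes = engineered_network(rng, extra_cols=3)
        net = build_network({"bacteria": table}, {"bacteria": classes}, "abundant",
                            prevalence_min=0.0)
        node_support_scores(net, rng.normal(size=40))
        files = export_network(net, tmp_path / "net_abundant")
        for name in files:
            assert (tmp_path / name).exists()
        back = nx.read_graphml(tmp_path / "net_abundant.graphml")
        assert set(back.nodes) == set(net.graph.nodes)
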