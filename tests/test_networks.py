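import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coexkit import simulate
from coexkit.networks import (
    ConditionNetwork,
    EdgeRule,
    build_coexpression_network,
    core_number,
    correlation_with_pvalue,
    differential_topology,
    gene_act_network,
    node_degree,
    pathway_act_network,
    rank_topology_differences,
    topology_frame,
)


def brute_force_core(graph):
    """Exhaustive oracle: core(v) = max over induced subgraphs containing v
    of the subgraph's minimum degree."""
    nodes = list(graph.nodes())
    core = {v: 0 for v in nodes}
    for r in range(1, len(nodes) + 1):
        for subset in itertools.combinations(nodes, r):
            sub = graph.subgraph(subset)
            if sub.number_of_nodes() == 0:
                continue
            min_deg = min(d for _, d in sub.degree())
            for v in subset:
                core[v] = max(core[v], min_deg)
    return core


class TestCorrelation:
    def test_affine_gives_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        r, p = correlation_with_pvalue(x, 2 * x + 3)
        assert r == pytest.approx(1.0)
        assert p == 0.0

    def test_negation_gives_minus_one(self):
        x = np.array([1.0, 2.0, 5.0])
        r, p = correlation_with_pvalue(x, -x)
        assert r == pytest.approx(-1.0)
        assert p == 0.0

    def test_hand_computed_example(self):
        # x=(1..5), y=(2,1,4,3,6): cov=10/4, sx^2=10/4, sy^2=14.8/4
        # r = 10 / sqrt(10 * 14.8) = 0.82199...
        r, p = correlation_with_pvalue([1, 2, 3, 4, 5], [2, 1, 4, 3, 6])
        assert r == pytest.approx(0.82199, abs=1e-5)
        # p from t = r*sqrt(3/(1-r^2)) on 3 df
        from scipy import stats

        t = 0.8219949365267865 * np.sqrt(3 / (1 - 0.8219949365267865**2))
        assert p == pytest.approx(2 * stats.t.sf(t, df=3), rel=1e-9)

    def test_zero_variance_is_missing(self):
        r, p = correlation_with_pvalue([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert np.isnan(r) and np.isnan(p)

    def test_matches_scipy(self, rng):
        from scipy import stats

        for _ in range(25):
            n = int(rng.integers(4, 30))
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            r, p = correlation_with_pvalue(x, y)
            expected = stats.pearsonr(x, y)
            assert r == pytest.approx(expected.statistic, abs=1e-12)
            assert p == pytest.approx(expected.pvalue, rel=1e-8)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            correlation_with_pvalue([1, 2], [1, 2])
        with pytest.raises(ValueError):
            correlation_with_pvalue([1, 2, np.nan], [1, 2, 3])


class TestCoexpressionNetwork:
    def test_identical_rows_linked(self):
        expr = pd.DataFrame(
            [[1.0, 2.0, 3.0, 4.0]] * 2 + [[5.0, 3.0, 1.0, 4.0]],
            index=["a", "b", "c"],
            columns=[f"s{i}" for i in range(4)],
        )
        with pytest.warns(UserWarning, match="powerless"):
            net = build_coexpression_network(expr, "treated", EdgeRule(0.8, 0.05))
        assert net.graph.has_edge("a", "b")
        assert net.graph.edges["a", "b"]["r"] == pytest.approx(1.0)

    def test_requires_three_samples(self):
        expr = pd.DataFrame([[1.0, 2.0]], index=["a"], columns=["s1", "s2"])
        with pytest.raises(ValueError, match="3 samples"):
            build_coexpression_network(expr, "x")

    def test_symmetry_and_simplicity(self, rng):
        expr = pd.DataFrame(
            rng.normal(size=(15, 10)), index=[f"g{i}" for i in range(15)]
        )
        net = build_coexpression_network(expr, "c", EdgeRule(0.5, 0.2))
        graph = net.graph
        for u, v in graph.edges():
            assert graph.has_edge(v, u)
            assert u != v

    def test_null_edge_density_below_alpha(self, rng):
        # i.i.d. noise: |r|>=0 threshold leaves p<alpha as the only rule, so
        # edge density must be below alpha on average
        n_genes, n_samples = 40, 20
        densities = []
        for seed in range(5):
            local = np.random.default_rng(seed)
            expr = pd.DataFrame(
                local.normal(size=(n_genes, n_samples)),
                index=[f"g{i}" for i in range(n_genes)],
            )
            net = build_coexpression_network(expr, "c", EdgeRule(0.0, 0.05))
            n_pairs = n_genes * (n_genes - 1) / 2
            densities.append(net.graph.number_of_edges() / n_pairs)
        assert np.mean(densities) < 0.07

    def test_planted_module_pattern(self):
        # module genes: mutually connected in treated, isolated in control
        params = simulate.SimulationParams(
            n_genes=30, n_per_group=20, baseline_mean=300.0,
            dispersion=0.02, frac_up=0.0, frac_down=0.0,
            module_sizes=(6,), module_condition=(simulate.TREATED,), seed=13,
        )
        matrix, truth = simulate.generate_counts(params)
        members = sorted(truth.module_members[0][0])
        expr = np.log2(matrix.counts + 1.0)
        rule = EdgeRule(0.8, 0.05)
        treated = build_coexpression_network(
            expr[matrix.samples_for(simulate.TREATED)], "treated", rule
        )
        control = build_coexpression_network(
            expr[matrix.samples_for(simulate.CONTROL)], "control", rule
        )
        deg_t = node_degree(treated)
        deg_c = node_degree(control)
        assert min(deg_t[g] for g in members) >= len(members) - 2
        assert max(deg_c[g] for g in members) <= 1


class TestDegreeAndCore:
    def test_isolated_node(self):
        graph = nx.Graph()
        graph.add_node("a")
        assert node_degree(graph)["a"] == 0
        assert core_number(graph)["a"] == 0

    def test_complete_39_node_graph(self):
        graph = nx.complete_graph(39)
        degrees = node_degree(graph)
        assert set(degrees.values()) == {38}
        assert set(core_number(graph).values()) == {38}

    def test_handshake(self, rng):
        graph = nx.gnp_random_graph(25, 0.2, seed=4)
        degrees = node_degree(graph)
        assert sum(degrees.values()) == 2 * graph.number_of_edges()

    def test_triangle_core(self):
        graph = nx.cycle_graph(3)
        assert set(core_number(graph).values()) == {2}

    def test_star_core(self):
        graph = nx.star_graph(5)
        assert set(core_number(graph).values()) == {1}

    def test_core_leq_degree(self, rng):
        for seed in range(10):
            graph = nx.gnp_random_graph(20, 0.3, seed=seed)
            degrees = node_degree(graph)
            cores = core_number(graph)
            assert all(cores[v] <= degrees[v] for v in graph.nodes())

    def test_matches_networkx(self):
        for seed in range(10):
            graph = nx.gnp_random_graph(30, 0.2, seed=seed)
            assert core_number(graph) == nx.core_number(graph)

    def test_matches_exhaustive_oracle_small(self):
        for seed in range(20):
            graph = nx.gnp_random_graph(7, 0.4, seed=seed)
            assert core_number(graph) == brute_force_core(graph)

    def test_self_loop_rejected(self):
        graph = nx.Graph()
        graph.add_edge("a", "a")
        with pytest.raises(ValueError):
            core_number(graph)


def _net(edges, nodes=(), condition="c"):
    graph = nx.Graph()
    graph.add_nodes_from(nodes)
    graph.add_edges_from(edges)
    return ConditionNetwork(condition=condition, graph=graph)


class TestDifferentialTopology:
    def test_printed_worked_examples(self):
        # per-condition (degree, kcore) pairs from the study's worked table
        control = {
            "G0S2": (0, 0), "HSD11B1": (0, 0), "HSD3B2": (0, 0),
            "CXCL5": (0, 0), "STAR": (6, 4), "FA2H": (9, 7), "DHCR7": (23, 21),
        }
        treated = {
            "G0S2": (38, 32), "HSD11B1": (38, 32), "HSD3B2": (38, 32),
            "CXCL5": (38, 32), "STAR": (37, 32), "FA2H": (31, 28),
            "DHCR7": (38, 32),
        }
        records = {r.gene: r for r in rank_topology_differences(control, treated)}
        assert records["STAR"].dif_degree == 31
        assert records["STAR"].dif_kcore == 28
        assert records["DHCR7"].dif_degree == 15
        assert records["DHCR7"].dif_kcore == 11
        assert records["G0S2"].dif_degree == 38
        assert records["G0S2"].dif_kcore == 32
        # biggest degree differences rank first
        ranked = rank_topology_differences(control, treated)
        assert [r.gene for r in ranked[:4]] == ["CXCL5", "G0S2", "HSD11B1", "HSD3B2"]

    def test_identical_networks_all_zero(self):
        net = _net([("a", "b"), ("b", "c")])
        records = differential_topology(net, net)
        assert all(r.dif_degree == 0 and r.dif_kcore == 0 for r in records)

    def test_missing_nodes_default_zero(self):
        control = _net([], nodes=["a"])
        treated = _net([("a", "b"), ("a", "c"), ("b", "c")])
        records = {r.gene: r for r in differential_topology(control, treated)}
        assert records["b"].degree_control == 0
        assert records["b"].kcore_control == 0
        assert records["b"].dif_degree == 2

    def test_rank_ordering_deterministic(self):
        control = {"a": (0, 0), "b": (0, 0), "c": (5, 2)}
        treated = {"a": (3, 2), "b": (3, 1), "c": (5, 2)}
        ranked = rank_topology_differences(control, treated)
        assert [r.gene for r in ranked] == ["a", "b", "c"]
        assert [r.rank for r in ranked] == [1, 2, 3]

    def test_frame_diff_columns_consistent(self):
        control = _net([("a", "b")])
        treated = _net([("a", "b"), ("a", "c"), ("b", "c")])
        frame = topology_frame(differential_topology(control, treated))
        assert (
            frame["dif_degree"]
            == frame["degree_treated"] - frame["degree_control"]
        ).all()
        assert (
            frame["dif_kcore"] == frame["kcore_treated"] - frame["kcore_control"]
        ).all()


class TestGeneActNetwork:
    def test_no_shared_relations(self):
        relations = nx.Graph()
        relations.add_edge("x", "y")
        sub, modules = gene_act_network(["a", "b"], relations)
        assert sub.number_of_edges() == 0
        assert modules == []

    def test_clique_module(self):
        # 4-clique among DEGs comes back as one module of size 4
        relations = nx.Graph()
        clique = ["HSD11B1", "AKR1C4", "SRD5A3", "HSD3B2"]
        relations.add_edges_from(itertools.combinations(clique, 2))
        relations.add_edge("other1", "other2")
        sub, modules = gene_act_network(clique + ["LONER"], relations)
        assert len(modules) == 1
        assert modules[0] == set(clique)

    def test_gene_order_invariance(self):
        relations = nx.Graph()
        relations.add_edges_from([("a", "b"), ("c", "d"), ("d", "e")])
        genes = ["a", "b", "c", "d", "e"]
        _, m1 = gene_act_network(genes, relations)
        _, m2 = gene_act_network(genes[::-1], relations)
        assert m1 == m2
        assert [len(m) for m in m1] == [3, 2]  # largest first


class TestPathwayActNetwork:
    def test_disjoint_pathways(self):
        sets = {"P1": {"a"}, "P2": {"b"}, "P3": {"c"}}
        graph, hubs = pathway_act_network(["P1", "P2", "P3"], sets)
        assert graph.number_of_edges() == 0
        assert all(d == 0 for _, d in hubs)

    def test_common_gene_triangle(self):
        sets = {"P1": {"g", "x"}, "P2": {"g", "y"}, "P3": {"g", "z"}}
        graph, hubs = pathway_act_network(["P1", "P2", "P3"], sets, min_shared=1)
        assert graph.number_of_edges() == 3
        assert {d for _, d in hubs} == {2}

    def test_hub_ranking(self):
        sets = {f"P{i}": {"hubgene", f"x{i}"} for i in range(1, 6)}
        sets["HUB"] = {"hubgene"} | {f"x{i}" for i in range(1, 6)}
        sets["P1"] = {"hubgene", "x1"}
        graph, hubs = pathway_act_network(list(sets), sets, min_shared=2)
        assert hubs[0][0] == "HUB"
        assert hubs[0][1] == 5

    def test_min_shared_threshold(self):
        sets = {"P1": {"a", "b"}, "P2": {"a", "c"}}
        graph, _ = pathway_act_network(["P1", "P2"], sets, min_shared=2)
        assert graph.number_of_edges() == 0

    def test_missing_set_error(self):
        with pytest.raises(KeyError):
            pathway_act_network(["nope"], {"P1": {"a"}})


@given(st.integers(min_value=0, max_value=2**15 - 1))
@settings(max_examples=60, deadline=None)
def test_core_peeling_equals_oracle_on_6_node_graphs(bits):
    # every labeled 6-node graph is a 15-bit mask over the edge list
    nodes = range(6)
    edges = list(itertools.combinations(nodes, 2))
    graph = nx.Graph()
    graph.add_nodes_from(nodes)
    for i, edge in enumerate(edges):
        if bits >> i & 1:
            graph.add_edge(*edge)
    assert core_number(graph) == brute_force_core(graph)
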