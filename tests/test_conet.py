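"""Co-occurrence network construction, centralities and keystone rule."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import _graph_oracle as oracle
from rotipop import (
    build_network,
    graph_metrics,
    keystone,
    node_metrics,
    spearman_matrix,
    stage_composition_tests,
)


def matrices_from_edges(nodes, strong_pairs):
    """rho/p matrices with rho=0.9, p=0.001 on listed pairs, else 0/1."""
    rho = pd.DataFrame(0.0, index=nodes, columns=nodes)
    p = pd.DataFrame(1.0, index=nodes, columns=nodes)
    np.fill_diagonal(rho.values, 1.0)
    np.fill_diagonal(p.values, 0.0)
    for a, b in strong_pairs:
        rho.loc[a, b] = rho.loc[b, a] = 0.9
        p.loc[a, b] = p.loc[b, a] = 0.001
    return rho, p


def graph_from_edges(nodes, edges):
    rho, p = matrices_from_edges(nodes, edges)
    return build_network(rho, p)


def random_graph(rng, n, p_edge):
    nodes = [f"v{i}" for i in range(n)]
    edges = [
        (nodes[i], nodes[j])
        for i in range(n)
        for j in range(i + 1, n)
        if rng.random() < p_edge
    ]
    return nodes, edges


class TestSpearmanMatrix:
    def test_monotone_pairs_are_plus_minus_one(self):
        ab = pd.DataFrame(
            [[1, 2, 3, 4, 5], [2, 4, 5, 7, 9], [9, 7, 5, 4, 2]],
            index=["x", "y", "z"],
        )
        rho, _ = spearman_matrix(ab)
        assert rho.loc["x", "y"] == pytest.approx(1.0)
        assert rho.loc["x", "z"] == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self, global_rng):
        from scipy.stats import rankdata

        ab = pd.DataFrame(global_rng.uniform(size=(5, 8)))
        rho, _ = spearman_matrix(ab)
        ranked = np.apply_along_axis(rankdata, 1, ab.to_numpy())
        ref = np.corrcoef(ranked)
        assert np.allclose(rho.to_numpy(), ref, atol=1e-12)

    def test_zero_variance_taxon_reported_missing(self):
        ab = pd.DataFrame(
            [[1, 2, 3, 4], [5, 5, 5, 5], [4, 3, 2, 1]], index=["x", "c", "y"]
        )
        rho, p = spearman_matrix(ab)
        assert np.isnan(rho.loc["c", "x"]) and np.isnan(p.loc["c", "y"])
        assert rho.loc["x", "y"] == pytest.approx(-1.0)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            spearman_matrix(pd.DataFrame([[1, 2, 3], [3, 2, 1]]))


class TestBuildNetwork:
    def test_abs_mode_keeps_negative_edges(self):
        nodes = ["a", "b", "c"]
        rho, p = matrices_from_edges(nodes, [("a", "b")])
        rho.loc["a", "c"] = rho.loc["c", "a"] = -0.9
        p.loc["a", "c"] = p.loc["c", "a"] = 0.001
        rho.loc["b", "c"] = rho.loc["c", "b"] = 0.1
        p.loc["b", "c"] = p.loc["c", "b"] = 0.001
        g = build_network(rho, p, use_abs=True)
        assert g.number_of_edges() == 2
        assert g.edges["a", "c"]["sign"] == -1
        g2 = build_network(rho, p, use_abs=False)
        assert not g2.has_edge("a", "c")

    def test_insignificant_p_gives_empty_network(self):
        nodes = ["a", "b"]
        rho = pd.DataFrame([[1.0, 0.9], [0.9, 1.0]], index=nodes, columns=nodes)
        p = pd.DataFrame([[0.0, 0.5], [0.5, 0.0]], index=nodes, columns=nodes)
        assert build_network(rho, p).number_of_edges() == 0

    def test_matches_mask_oracle(self, global_rng):
        n = 10
        nodes = [f"t{i}" for i in range(n)]
        r = global_rng.uniform(-1, 1, size=(n, n))
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        pv = global_rng.uniform(size=(n, n))
        pv = (pv + pv.T) / 2
        np.fill_diagonal(pv, 0.0)
        g = build_network(
            pd.DataFrame(r, index=nodes, columns=nodes),
            pd.DataFrame(pv, index=nodes, columns=nodes),
        )
        for i in range(n):
            for j in range(i + 1, n):
                expect = abs(r[i, j]) > 0.5 and pv[i, j] < 0.05
                assert g.has_edge(nodes[i], nodes[j]) == expect

    def test_edge_filtering_monotone_in_thresholds(self, global_rng):
        n = 12
        nodes = [f"t{i}" for i in range(n)]
        r = global_rng.uniform(-1, 1, size=(n, n))
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        pv = global_rng.uniform(size=(n, n))
        pv = (pv + pv.T) / 2
        np.fill_diagonal(pv, 0.0)
        rho = pd.DataFrame(r, index=nodes, columns=nodes)
        p = pd.DataFrame(pv, index=nodes, columns=nodes)
        loose = set(build_network(rho, p, rho_min=0.3, p_max=0.2).edges)
        tight = set(build_network(rho, p, rho_min=0.6, p_max=0.05).edges)
        assert tight <= loose


class TestNodeMetrics:
    def test_path_graph_middle_node(self):
        g = graph_from_edges(["a", "b", "c"], [("a", "b"), ("b", "c")])
        m = node_metrics(g)
        assert m.loc["b", "betweenness"] == 1.0
        assert m.loc["b", "closeness"] == 1.0
        assert m.loc["a", "betweenness"] == 0.0

    def test_complete_graph_k4(self):
        nodes = list("abcd")
        edges = [(a, b) for i, a in enumerate(nodes) for b in nodes[i + 1:]]
        m = node_metrics(graph_from_edges(nodes, edges))
        assert (m["degree"] == 1.0).all()
        assert (m["clustering"] == 1.0).all()
        assert (m["betweenness"] == 0.0).all()

    def test_matches_brute_force_on_random_graphs(self, global_rng):
        for _ in range(30):
            n = int(global_rng.integers(3, 13))
            nodes, edges = random_graph(global_rng, n, global_rng.uniform(0.15, 0.6))
            g = graph_from_edges(nodes, edges)
            m = node_metrics(g)
            adj = oracle.adjacency(nodes, edges)
            for name, ref in (
                ("degree", oracle.degree_centrality(adj)),
                ("closeness", oracle.closeness_centrality(adj)),
                ("betweenness", oracle.betweenness_centrality(adj)),
                ("clustering", oracle.clustering_coefficient(adj)),
            ):
                for v in nodes:
                    assert m.loc[v, name] == pytest.approx(ref[v], abs=1e-9), (
                        f"{name} mismatch at {v}"
                    )

    def test_isomorphism_invariance_under_relabeling(self, global_rng):
        nodes, edges = random_graph(global_rng, 9, 0.35)
        g = graph_from_edges(nodes, edges)
        mapping = dict(zip(nodes, np.roll(nodes, 3)))
        g2 = nx.relabel_nodes(g, mapping)
        m1 = node_metrics(g)
        m2 = node_metrics(g2)
        for v in nodes:
            assert np.allclose(m1.loc[v], m2.loc[mapping[v]])


class TestGraphMetrics:
    def test_complete_graph_k4(self):
        nodes = list("abcd")
        edges = [(a, b) for i, a in enumerate(nodes) for b in nodes[i + 1:]]
        gm = graph_metrics(graph_from_edges(nodes, edges))
        assert gm["avg_degree"] == 3.0
        assert gm["diameter"] == 1
        assert gm["avg_shortest_path"] == 1.0
        assert gm["avg_clustering"] == 1.0

    def test_path_graph_p4_hand_enumeration(self):
        g = graph_from_edges(list("abcd"), [("a", "b"), ("b", "c"), ("c", "d")])
        gm = graph_metrics(g)
        assert gm["diameter"] == 3
        assert gm["avg_shortest_path"] == pytest.approx(5 / 3)

    def test_empty_network_warns_and_zeroes(self):
        g = nx.Graph()
        g.add_nodes_from("abc")
        with pytest.warns(UserWarning, match="empty"):
            gm = graph_metrics(g)
        assert gm["avg_degree"] == 0.0 and gm["diameter"] == 0

    def test_matches_bfs_oracle(self, global_rng):
        for _ in range(15):
            nodes, edges = random_graph(global_rng, 10, 0.3)
            if not edges:
                continue
            gm = graph_metrics(graph_from_edges(nodes, edges))
            adj = oracle.adjacency(nodes, edges)
            dia, aspl = oracle.diameter_and_aspl(adj)
            assert gm["diameter"] == dia
            assert gm["avg_shortest_path"] == pytest.approx(aspl)


class TestKeystone:
    def test_star_hub_fails_low_betweenness_criterion(self):
        # S9: hub has max degree/closeness but also all the betweenness
        nodes = ["hub"] + [f"leaf{i}" for i in range(8)]
        edges = [("hub", l) for l in nodes[1:]]
        g = graph_from_edges(nodes, edges)
        rep = keystone(g, top_k=1)
        assert rep.selected == []
        assert not rep.table.loc["hub", "pass_betweenness"]
        assert rep.table.loc["hub", "pass_degree"]
        assert rep.table.loc["hub", "pass_closeness"]

    def test_all_isolated_no_keystones(self):
        g = nx.Graph()
        g.add_nodes_from("abcde")
        rep = keystone(g, top_k=2)
        assert rep.selected == []

    def test_constructed_winner_selected(self):
        # triangle core + pendant: core nodes share max degree/closeness and
        # the pendant's neighbour takes all betweenness
        edges = [("a", "b"), ("b", "c"), ("a", "c"), ("c", "d")]
        g = graph_from_edges(list("abcd"), edges)
        rep = keystone(g, top_k=2)
        # a and b: degree 2/3, closeness high, betweenness 0 -> keystones
        assert rep.selected == ["a", "b"]

    def test_round_trip_threshold_identity(self, global_rng):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            nodes, edges = random_graph(rng, 11, 0.35)
            g = graph_from_edges(nodes, edges)
            rep = keystone(g, top_k=4)
            assert rep.reapply() == rep.selected

    def test_top_k_clipped_with_warning(self):
        g = graph_from_edges(["a", "b"], [("a", "b")])
        with pytest.warns(UserWarning, match="clipped"):
            rep = keystone(g, top_k=20)
        assert rep.top_k == 2


class TestStageCompositionTests:
    def test_planted_stage_shift_detected(self, small_otu_table):
        table, truth = small_otu_table
        # the generator plants a strong T3/T4 shift on a genus block
        res = stage_composition_tests(table, by="stage", rank="genus", top_n=15)
        shifted_otus = next(
            e["otus"] for e in truth["effects"]
            if e["stage"] == "T3" and e["log_shift"] > 1
        )
        shifted_genera = {
            table.taxonomy[o].split(";")[5].replace("g__", "")
            for o in shifted_otus
        }
        flagged = set(res.index[res["significant"]])
        assert flagged & shifted_genera

    def test_constant_abundances_H_zero(self):
        from test_otu_pipeline import tiny_table

        counts = {f"s{i}": [10, 20, 30] for i in range(8)}
        t = tiny_table(counts)
        t.metadata["stage"] = ["T1"] * 4 + ["T2"] * 4
        res = stage_composition_tests(t, by="stage", rank="genus", top_n=3)
        assert (res["H"] == 0.0).all()

    def test_null_false_positive_rate_nominal(self):
        # no planted effect between invented halves: per-taxon flag rate ~ 5%
        from rotipop import OtuSimConfig, simulate_otu_table

        flags = total = 0
        for seed in range(25):
            cfg = OtuSimConfig(
                n_otus=30,
                n_samples_per_cell=3,
                groups=("G1",),
                stages=("T1", "T2", "T3", "T4"),
                depth_range=(2000, 2000),
                chloroplast_frac=0.0,
                seed=seed,
            )
            table, _ = simulate_otu_table(cfg)
            res = stage_composition_tests(table, by="stage", rank="genus",
                                          top_n=10)
            flags += int(res["significant"].sum())
            total += len(res)
        rate = flags / total
        assert rate < 0.12  # ~0.05 nominal with Monte-Carlo slack
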