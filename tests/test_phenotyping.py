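"""Community detection, betweenness, cluster summaries and render scaling."""

from itertools import combinations

import networkx as nx
import numpy as np
import pytest

from comorbnet import (ComorbidityNetwork, aggregate, betweenness,
                       cluster_summary, louvain, modularity,
                       render_attributes)


# ---------------------------------------------------------------------------
# independent oracles

def modularity_oracle(net, labels, gamma=1.0):
    """Q from the adjacency-matrix definition, written independently."""
    nodes = sorted(net.nodes)
    idx = {u: i for i, u in enumerate(nodes)}
    A = np.zeros((len(nodes), len(nodes)))
    for (u, v), w in net.edges.items():
        A[idx[u], idx[v]] = A[idx[v], idx[u]] = w
    k = A.sum(axis=1)
    two_m = A.sum()
    if two_m == 0:
        return 0.0
    q = 0.0
    for i, u in enumerate(nodes):
        for j, v in enumerate(nodes):
            if labels[u] == labels[v]:
                q += A[i, j] - gamma * k[i] * k[j] / two_m
    return q / two_m


def all_partitions(items):
    """Every set partition of `items` (Bell-number enumeration)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in all_partitions(rest):
        for i in range(len(smaller)):
            yield smaller[:i] + [smaller[i] + [first]] + smaller[i + 1:]
        yield smaller + [[first]]


def betweenness_oracle(net):
    """Brute-force: enumerate every simple path between every pair, keep the
    shortest, and split credit among interior nodes."""
    g = net.to_networkx()
    bc = {u: 0.0 for u in net.nodes}
    for s, t in combinations(sorted(net.nodes), 2):
        if not nx.has_path(g, s, t):
            continue
        paths = list(nx.all_simple_paths(g, s, t))
        shortest = min(len(p) for p in paths)
        sp = [p for p in paths if len(p) == shortest]
        for p in sp:
            for v in p[1:-1]:
                bc[v] += 1.0 / len(sp)
    return bc


# ---------------------------------------------------------------------------


class TestLouvain:
    def test_two_triangles_match_exhaustive_optimum(self, two_triangles):
        best_q, best = -2.0, None
        for part in all_partitions(sorted(two_triangles.nodes)):
            labels = {u: i for i, block in enumerate(part) for u in block}
            q = modularity_oracle(two_triangles, labels)
            if q > best_q + 1e-12:
                best_q, best = q, part
        found = louvain(two_triangles, seed=0)
        assert found.n_communities == 2
        blocks = {frozenset(found.members(c)) for c in range(2)}
        assert blocks == {frozenset(b) for b in best}
        assert found.modularity == pytest.approx(best_q, abs=1e-12)
        assert found.modularity == pytest.approx(0.5, abs=1e-12)

    def test_single_clique_is_one_community(self):
        net = aggregate([{"A00", "B00", "C00", "D00", "E00"}])
        assert louvain(net, seed=1).n_communities == 1

    def test_disjoint_blocks_recovered_exactly(self):
        """Two code blocks that never co-occur split exactly into blocks."""
        block1 = [{f"A{i:02d}", f"A{(i+1) % 8:02d}", "A00"} for i in range(8)]
        block2 = [{f"B{i:02d}", f"B{(i+1) % 6:02d}", "B00"} for i in range(6)]
        net = aggregate(block1 * 3 + block2 * 3)
        part = louvain(net, seed=0)
        labels_a = {part.assignment[u] for u in net.nodes if u.startswith("A")}
        labels_b = {part.assignment[u] for u in net.nodes if u.startswith("B")}
        assert len(labels_a) == 1 and len(labels_b) == 1
        assert labels_a != labels_b

    def test_not_worse_than_singletons(self, two_triangles):
        part = louvain(two_triangles, seed=4)
        singles = {u: i for i, u in enumerate(sorted(two_triangles.nodes))}
        assert part.modularity >= modularity(two_triangles, singles) - 1e-12

    def test_deterministic_given_seed(self, two_triangles):
        runs = [louvain(two_triangles, seed=7).assignment for _ in range(3)]
        assert runs[0] == runs[1] == runs[2]

    def test_community_ids_contiguous_from_zero(self, two_triangles):
        part = louvain(two_triangles, seed=2)
        assert set(part.assignment.values()) == set(range(part.n_communities))


class TestModularity:
    def test_all_in_one_is_zero(self, two_triangles):
        labels = {u: 0 for u in two_triangles.nodes}
        assert modularity(two_triangles, labels) == pytest.approx(0.0, abs=1e-15)

    def test_two_triangles_split_is_half(self, two_triangles):
        labels = {u: 0 if u in "ABC" else 1 for u in two_triangles.nodes}
        assert modularity(two_triangles, labels) == pytest.approx(0.5, abs=1e-15)

    def test_random_partitions_match_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(40):
            n = int(rng.integers(2, 7))
            net = ComorbidityNetwork()
            names = [f"N{i}" for i in range(n)]
            net.nodes.update(names)
            for u, v in combinations(names, 2):
                if rng.random() < 0.6:
                    net.add_edge(u, v, int(rng.integers(1, 6)))
            labels = {u: int(rng.integers(0, 3)) for u in names}
            gamma = float(rng.uniform(0.5, 2.0))
            assert modularity(net, labels, gamma) == pytest.approx(
                modularity_oracle(net, labels, gamma), abs=1e-12)

    def test_missing_node_errors(self, two_triangles):
        with pytest.raises(ValueError, match="missing"):
            modularity(two_triangles, {"A": 0})


class TestBetweenness:
    def test_complete_graph_all_zero(self):
        net = aggregate([{"A00", "B00", "C00", "D00"}])
        assert all(v == 0.0 for v in betweenness(net).values())

    def test_path_center(self):
        net = ComorbidityNetwork()
        net.add_edge("A", "B")
        net.add_edge("B", "C")
        assert betweenness(net)["B"] == 1.0

    def test_star_center_counts_leaf_pairs(self):
        net = ComorbidityNetwork()
        for leaf in "BCDE":
            net.add_edge("A", leaf)
        assert betweenness(net)["A"] == 6.0  # C(4,2) leaf pairs

    def test_matches_enumeration_on_small_graphs(self):
        """Spot-check against the path-enumeration oracle on random graphs
        with up to 6 nodes (the acceptance suite sweeps the full atlas)."""
        rng = np.random.default_rng(13)
        for _ in range(25):
            n = int(rng.integers(2, 7))
            net = ComorbidityNetwork()
            names = [f"N{i}" for i in range(n)]
            net.nodes.update(names)
            for u, v in combinations(names, 2):
                if rng.random() < 0.5:
                    net.add_edge(u, v)
            mine = betweenness(net)
            oracle = betweenness_oracle(net)
            for u in names:
                assert mine[u] == pytest.approx(oracle[u], abs=1e-9)

    def test_weighted_mode_prefers_heavy_edges(self):
        """With distance 1/weight, two strong co-occurrence links beat one
        weak direct link, making the middle diagnosis a bridge."""
        net = ComorbidityNetwork()
        net.add_edge("A", "B", 10)
        net.add_edge("B", "C", 10)
        net.add_edge("A", "C", 1)
        assert betweenness(net)["B"] == 0.0  # direct hop exists
        assert betweenness(net, use_weights=True)["B"] == 1.0

    def test_weighted_matches_networkx(self):
        rng = np.random.default_rng(21)
        net = ComorbidityNetwork()
        names = [f"N{i}" for i in range(8)]
        net.nodes.update(names)
        for u, v in combinations(names, 2):
            if rng.random() < 0.4:
                net.add_edge(u, v, int(rng.integers(1, 8)))
        g = net.to_networkx()
        for u, v, d in g.edges(data=True):
            d["dist"] = 1.0 / d["weight"]
        ref = nx.betweenness_centrality(g, normalized=False, weight="dist")
        mine = betweenness(net, use_weights=True)
        for u in names:
            assert mine[u] == pytest.approx(ref[u], abs=1e-9)


class TestClusterSummary:
    def test_single_patient_pink_cluster(self):
        net = aggregate([{"F03", "D64.8", "H91.8", "E05.9"}])
        summary = cluster_summary(net, {u: 0 for u in net.nodes})
        assert summary.node_count[0] == 4
        assert summary.intra_edges[0] == 6

    def test_node_share_of_sixty_in_174(self):
        net = ComorbidityNetwork()
        net.nodes.update(f"N{i}" for i in range(174))
        labels = {f"N{i}": (0 if i < 60 else 1) for i in range(174)}
        summary = cluster_summary(net, labels)
        assert summary.node_share_pct[0] == 34.48

    def test_descending_order_with_id_tiebreak(self):
        net = ComorbidityNetwork()
        net.nodes.update(["A", "B", "C", "D"])
        summary = cluster_summary(net, {"A": 2, "B": 1, "C": 0, "D": 0})
        assert summary.order == (0, 1, 2)

    def test_conservation_on_random_graph(self):
        rng = np.random.default_rng(17)
        net = ComorbidityNetwork()
        names = [f"N{i}" for i in range(30)]
        net.nodes.update(names)
        for u, v in combinations(names, 2):
            if rng.random() < 0.2:
                net.add_edge(u, v)
        labels = {u: int(rng.integers(0, 4)) for u in names}
        s = cluster_summary(net, labels)
        assert sum(s.node_count.values()) == net.n_nodes
        assert (sum(s.intra_edges.values())
                + sum(s.inter_matrix.values())) == net.n_edges
        # each rounded share deviates < 0.005 from its exact value
        tol = 0.005 * len(s.node_count) + 1e-9
        assert sum(s.node_share_pct.values()) == pytest.approx(100, abs=tol)


class TestRenderAttributes:
    def _net(self):
        net = ComorbidityNetwork()
        net.add_edge("A", "B", 1)
        net.add_edge("B", "C", 5)
        net.add_edge("C", "D", 10)
        return net

    def test_extremes_map_to_bounds(self):
        net = self._net()
        bc = betweenness(net)
        attrs = render_attributes(net, bc, {u: 0 for u in net.nodes})
        top = max(bc, key=bc.get)
        bottom = min(bc, key=bc.get)
        assert attrs.node_size[top] == 100.0
        assert attrs.node_size[bottom] == 1.0
        assert attrs.edge_width[("A", "B")] == pytest.approx(0.1)
        assert attrs.edge_width[("C", "D")] == pytest.approx(1.0)

    def test_degenerate_spans_map_to_minimum(self):
        net = aggregate([{"A00", "B00", "C00"}])  # all betweenness 0, weights 1
        attrs = render_attributes(net, betweenness(net),
                                  {u: 0 for u in net.nodes})
        assert set(attrs.node_size.values()) == {1.0}
        assert set(attrs.edge_width.values()) == {0.1}

    def test_monotone_in_metric(self):
        net = self._net()
        bc = betweenness(net)
        attrs = render_attributes(net, bc, {u: 0 for u in net.nodes})
        for u in net.nodes:
            for v in net.nodes:
                if bc[u] >= bc[v]:
                    assert attrs.node_size[u] >= attrs.node_size[v]
        for e in net.edges:
            for f in net.edges:
                if net.edges[e] >= net.edges[f]:
                    assert attrs.edge_width[e] >= attrs.edge_width[f]

    def test_missing_metric_errors(self):
        net = self._net()
        with pytest.raises(ValueError, match="missing"):
            render_attributes(net, {"A": 0.0}, {u: 0 for u in net.nodes})
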