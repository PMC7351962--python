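"""Kin networks: thresholding, node metrics against a brute-force oracle,
and attribute comparisons."""

import itertools
from collections import deque

import networkx as nx
import numpy as np
import pytest

from kinpods import (
    KinNetwork,
    build_kin_network,
    compare_node_attributes,
    node_metrics,
)
from kinpods.errors import ArgumentError, UntestableError
from kinpods.networks import percolation_threshold
from kinpods.relatedness import RelatednessMatrix


def brute_force_metrics(g: nx.Graph):
    """Independent oracle: enumerate all shortest paths explicitly.

    Returns (degree, betweenness with fractional credit and unordered pairs
    counted once, clustering) per node.
    """
    nodes = list(g.nodes)
    bc = {x: 0.0 for x in nodes}
    for s, t in itertools.combinations(nodes, 2):
        # BFS from s collecting all shortest paths to t
        dist = {s: 0}
        parents = {s: []}
        q = deque([s])
        while q:
            u = q.popleft()
            for v in g.neighbors(u):
                if v not in dist:
                    dist[v] = dist[u] + 1
                    parents[v] = [u]
                    q.append(v)
                elif dist[v] == dist[u] + 1:
                    parents[v].append(u)
        if t not in dist:
            continue
        paths = []
        stack = [(t, [t])]
        while stack:
            u, path = stack.pop()
            if u == s:
                paths.append(path)
                continue
            for p in parents[u]:
                stack.append((p, path + [p]))
        for path in paths:
            for mid in path[1:-1]:
                bc[mid] += 1.0 / len(paths)
    deg = {x: g.degree(x) for x in nodes}
    clus = {}
    for x in nodes:
        nbrs = list(g.neighbors(x))
        k = len(nbrs)
        if k < 2:
            clus[x] = 0.0
        else:
            links = sum(
                1 for a, b in itertools.combinations(nbrs, 2) if g.has_edge(a, b)
            )
            clus[x] = links / (k * (k - 1) / 2)
    return deg, bc, clus


class TestNodeMetricsFixedCases:
    def test_path_centre(self):
        m = node_metrics(KinNetwork.from_edges([("a", "b"), ("b", "c")]))
        assert (m.degree["b"], m.betweenness["b"], m.clustering["b"]) == (2, 1.0, 0.0)

    def test_triangle(self):
        m = node_metrics(
            KinNetwork.from_edges([("a", "b"), ("b", "c"), ("a", "c")])
        )
        for x in "abc":
            assert (m.degree[x], m.betweenness[x], m.clustering[x]) == (2, 0.0, 1.0)
        assert m.clustering_defined[x]

    def test_star_centre(self):
        edges = [("c", f"l{i}") for i in range(4)]
        m = node_metrics(KinNetwork.from_edges(edges))
        assert (m.degree["c"], m.betweenness["c"], m.clustering["c"]) == (4, 6.0, 0.0)
        assert not m.clustering_defined["l0"]


class TestMetricsAgainstOracle:
    @pytest.mark.parametrize("seed", range(20))
    def test_random_small_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 9))
        g = nx.gnp_random_graph(n, float(rng.uniform(0.2, 0.8)), seed=seed)
        net = KinNetwork(g, None, "manual")
        m = node_metrics(net)
        deg, bc, clus = brute_force_metrics(g)
        for x in g.nodes:
            assert m.degree[x] == deg[x]
            assert m.betweenness[x] == pytest.approx(bc[x], abs=1e-9)
            assert m.clustering[x] == pytest.approx(clus[x], abs=1e-9)

    def test_betweenness_conservation(self):
        """Total bc equals the sum over shortest paths of their fractional
        intermediate-vertex incidences."""
        g = nx.gnp_random_graph(8, 0.4, seed=99)
        m = node_metrics(KinNetwork(g, None, "manual"))
        _, bc, _ = brute_force_metrics(g)
        assert sum(m.betweenness.values()) == pytest.approx(sum(bc.values()))


def _matrix(ids, pairs, min_loci=8):
    n = len(ids)
    vals = np.full((n, n), np.nan)
    idx = {x: i for i, x in enumerate(ids)}
    for (a, b), v in pairs.items():
        vals[idx[a], idx[b]] = vals[idx[b], idx[a]] = v
    return RelatednessMatrix(ids, "r_QG", vals, np.full((n, n), 8), min_loci)


class TestBuildKinNetwork:
    def test_exclude_unrelated_keeps_only_related_edges(self):
        from kinpods.classify import RelationshipCall

        ids = [f"x{i}" for i in range(5)]
        pairs = {
            (a, b): 0.3 for a, b in itertools.combinations(ids, 2)
        }
        calls = []
        combos = list(itertools.combinations(ids, 2))
        for k, (a, b) in enumerate(combos):
            best = "U" if k < 4 else "FS"
            calls.append(RelationshipCall(a, b, {}, best, 0.0))
        net = build_kin_network(
            _matrix(ids, pairs), calls=calls, mode="exclude_unrelated"
        )
        assert net.graph.number_of_edges() == len(combos) - 4
        u_pairs = {frozenset((c.id1, c.id2)) for c in calls if c.best == "U"}
        for a, b in net.graph.edges:
            assert frozenset((a, b)) not in u_pairs

    def test_manual_threshold_above_max_isolates_everyone(self):
        ids = ["a", "b", "c"]
        pairs = {("a", "b"): 0.4, ("b", "c"): 0.2}
        net = build_kin_network(
            _matrix(ids, pairs), mode="manual", manual_threshold=0.9
        )
        assert net.graph.number_of_edges() == 0
        assert net.graph.number_of_nodes() == 3  # isolated nodes retained

    def test_manual_mode_requires_threshold(self):
        with pytest.raises(ArgumentError):
            build_kin_network(_matrix(["a", "b"], {("a", "b"): 0.5}), mode="manual")

    def test_low_loci_matrix_rejected(self):
        m = _matrix(["a", "b"], {("a", "b"): 0.5}, min_loci=6)
        with pytest.raises(ArgumentError, match="min_shared_loci"):
            build_kin_network(m, mode="manual", manual_threshold=0.1)

    def test_auto_threshold_splits_planted_families(self):
        rng = np.random.default_rng(5)
        ids = [f"x{i}" for i in range(12)]
        fam1, fam2 = ids[:6], ids[6:]
        pairs = {}
        for fam in (fam1, fam2):
            for a, b in itertools.combinations(fam, 2):
                pairs[(a, b)] = float(rng.normal(0.5, 0.05))
        pairs[(fam1[2], fam2[3])] = float(rng.normal(0.1, 0.05))  # spurious bridge
        net = build_kin_network(_matrix(ids, pairs), mode="auto_percolation")
        comps = sorted(sorted(c) for c in nx.connected_components(net.graph))
        assert comps == sorted([sorted(fam1), sorted(fam2)])

    def test_auto_threshold_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(8)
        ids = [f"x{i}" for i in range(10)]
        pairs = {
            (a, b): float(rng.uniform(0.01, 0.9))
            for a, b in itertools.combinations(ids, 2)
            if rng.random() < 0.5
        }
        edges = [(a, b, v) for (a, b), v in pairs.items()]
        t1 = percolation_threshold(ids, edges)
        # strictly increasing transform preserves weight order
        edges2 = [(a, b, v**3 + 2 * v) for a, b, v in edges]
        t2 = percolation_threshold(ids, edges2)
        kept1 = {(a, b) for a, b, v in edges if v >= t1}
        kept2 = {(a, b) for a, b, v, in [(a, b, v) for a, b, v in edges]
                 if (v**3 + 2 * v) >= t2}
        assert kept1 == kept2


class TestAttributeComparisons:
    def _net_with_attr(self, values):
        g = nx.path_graph(len(values))
        for i, v in enumerate(values):
            g.nodes[i]["sex"] = v
        return KinNetwork(g, None, "manual")

    def test_identical_metric_values_give_p_one(self):
        net = self._net_with_attr(["F", "F", "M", "M"])
        # path of 4: degrees 1,2,2,1 -> identical across the two levels?
        # use a cycle so every node has identical metrics
        g = nx.cycle_graph(6)
        for i in range(6):
            g.nodes[i]["sex"] = "F" if i < 3 else "M"
        net = KinNetwork(g, None, "manual")
        res = compare_node_attributes(net, node_metrics(net), "sex")
        for comp in res.values():
            assert comp.statistic == 0.0
            assert comp.p == 1.0

    def test_planted_degree_difference_detected(self):
        # one haplotype forms a clique (high k), the other a sparse path
        g = nx.Graph()
        clique = [f"c{i}" for i in range(6)]
        path = [f"p{i}" for i in range(6)]
        g.add_edges_from(itertools.combinations(clique, 2))
        g.add_edges_from(zip(path, path[1:]))
        g.add_edge(clique[0], path[0])
        for x in clique:
            g.nodes[x]["mtdna"] = "A"
        for x in path:
            g.nodes[x]["mtdna"] = "B"
        net = KinNetwork(g, None, "manual")
        res = compare_node_attributes(net, node_metrics(net), "mtdna")
        assert res["degree"].p < 0.05

    def test_single_level_untestable(self):
        net = self._net_with_attr(["F", "F", "F", "F"])
        with pytest.raises(UntestableError):
            compare_node_attributes(net, node_metrics(net), "sex")

    def test_three_levels_use_anova(self):
        g = nx.gnp_random_graph(9, 0.5, seed=3)
        for i in g.nodes:
            g.nodes[i]["age_class"] = ["adult", "juvenile", "calf"][i % 3]
        net = KinNetwork(g, None, "manual")
        res = compare_node_attributes(net, node_metrics(net), "age_class")
        assert all(c.test == "anova" for c in res.values())
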