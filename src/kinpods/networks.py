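"""Thresholded genetic-relatedness networks and node-level metrics.

Nodes are individuals; candidate edges carry pairwise relatedness as weight
(equivalently genetic distance d = 1 − r; only the weight order matters).
Three thresholding modes:

* ``auto_percolation`` — edges are added strongest-first and the threshold is
  placed at the percolation transition: the point maximising the
  susceptibility S = Σ s²·n_s / N over components excluding the largest
  (n_s components of size s among N nodes). Further edge removal beyond this
  point fragments the network into small components. The rule depends only
  on the order of the weights, so it is invariant to any monotone transform.
* ``exclude_unrelated`` — keep exactly the edges whose dyad classified as a
  close relationship (PO, FS or HS); requires relationship calls.
* ``manual`` — keep edges with r at or above a user threshold.

Metrics are computed on the unweighted thresholded graph: degree k,
unnormalised betweenness centrality bc (fractional credit across tied
shortest paths), and the clustering coefficient C (reported as 0, with an
explicit flag, for nodes of degree < 2).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
from scipy import stats

from .core import IndividualRecord
from .errors import ArgumentError, UntestableError
from .relatedness import RelatednessMatrix

MODES = ("auto_percolation", "exclude_unrelated", "manual")


@dataclass
class KinNetwork:
    graph: nx.Graph
    threshold: Optional[float]
    mode: str

    @property
    def nodes(self):
        return self.graph.nodes

    @property
    def edges(self):
        return self.graph.edges

    @classmethod
    def from_edges(cls, edges: Iterable[tuple], nodes: Optional[Iterable] = None,
                   mode: str = "manual", threshold: Optional[float] = None) -> "KinNetwork":
        """Build directly from (id1, id2[, weight]) tuples — mainly for
        small hand-constructed graphs."""
        g = nx.Graph()
        if nodes is not None:
            g.add_nodes_from(nodes)
        for e in edges:
            if len(e) == 3:
                g.add_edge(e[0], e[1], weight=float(e[2]))
            else:
                g.add_edge(e[0], e[1], weight=1.0)
        return cls(g, threshold, mode)

    def write_edgelist_csv(self, path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["id1", "id2", "r"])
            for a, b, d in sorted(self.graph.edges(data=True)):
                w.writerow([a, b, repr(d.get("weight", 1.0))])

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)


def _susceptibility(sizes: Sequence[int], n_nodes: int) -> float:
    """S = Σ s² n_s / N over components excluding the largest."""
    if len(sizes) <= 1:
        return 0.0
    sizes = sorted(sizes)
    return sum(s * s for s in sizes[:-1]) / n_nodes


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}
        self.size = {x: 1 for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return
        if self.size[ra] < self.size[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        self.size[ra] += self.size[rb]


def percolation_threshold(ids: Sequence[str],
                          edges: Sequence[Tuple[str, str, float]]) -> float:
    """Weight at the susceptibility peak when adding edges strongest-first.

    The last step attaining the maximal susceptibility is used, so the
    threshold keeps every edge down to (and including) the transition weight
    while still excluding the merge that collapses the components.
    """
    if not edges:
        raise ArgumentError("no edges to threshold")
    ordered = sorted(edges, key=lambda e: (-e[2], e[0], e[1]))
    uf = _UnionFind(ids)
    n = len(ids)
    best_s, best_weight = -1.0, ordered[0][2]
    for a, b, w in ordered:
        uf.union(a, b)
        comp_sizes = {}
        for x in ids:
            root = uf.find(x)
            comp_sizes[root] = comp_sizes.get(root, 0) + 1
        s = _susceptibility(list(comp_sizes.values()), n)
        if s >= best_s:  # >= : last step attaining the max
            best_s, best_weight = s, w
    return best_weight


def build_kin_network(matrix: RelatednessMatrix,
                      calls: Optional[Sequence] = None,
                      mode: str = "auto_percolation",
                      manual_threshold: Optional[float] = None,
                      node_attributes: Optional[Sequence[IndividualRecord]] = None,
                      require_min_loci: int = 7) -> KinNetwork:
    """Threshold a relatedness matrix into a network.

    The matrix must have been built with a shared-loci threshold of at least
    ``require_min_loci`` (default 7 — low-confidence relatedness at fewer
    loci produces spurious edges). Isolated individuals stay in the node set.
    """
    if mode not in MODES:
        raise ArgumentError(f"unknown mode {mode!r}")
    if matrix.min_shared_loci < require_min_loci:
        raise ArgumentError(
            f"matrix built with min_shared_loci={matrix.min_shared_loci}; "
            f"networks require >= {require_min_loci}"
        )
    all_edges = list(matrix.stored_pairs())
    if not matrix.ids:
        raise ArgumentError("empty matrix")

    threshold: Optional[float] = None
    if mode == "manual":
        if manual_threshold is None:
            raise ArgumentError("manual mode requires manual_threshold")
        threshold = float(manual_threshold)
        kept = [(a, b, w) for a, b, w in all_edges if w >= threshold]
    elif mode == "exclude_unrelated":
        if calls is None:
            raise ArgumentError("exclude_unrelated mode requires relationship calls")
        related = {
            frozenset((c.id1, c.id2)) for c in calls if c.best in ("PO", "FS", "HS")
        }
        kept = [(a, b, w) for a, b, w in all_edges if frozenset((a, b)) in related]
    else:
        threshold = percolation_threshold(matrix.ids, all_edges)
        kept = [(a, b, w) for a, b, w in all_edges if w >= threshold]

    g = nx.Graph()
    g.add_nodes_from(matrix.ids)
    for a, b, w in kept:
        g.add_edge(a, b, weight=w)
    if node_attributes is not None:
        for r in node_attributes:
            if r.id in g:
                g.nodes[r.id].update(
                    mtdna=r.mtdna or "", sex=r.sex, age_class=r.age_class
                )
    return KinNetwork(g, threshold, mode)


@dataclass
class NodeMetrics:
    degree: Dict[str, int]
    betweenness: Dict[str, float]
    clustering: Dict[str, float]
    clustering_defined: Dict[str, bool]


def node_metrics(network: KinNetwork) -> NodeMetrics:
    """Degree, unnormalised betweenness and clustering per node.

    Betweenness gives fractional credit across equal-length shortest paths
    and counts each unordered pair once, so it reduces to an integer path
    count when shortest paths are unique. C is 0 (flagged undefined) for
    nodes with fewer than two neighbours.
    """
    g = network.graph
    if g.number_of_nodes() == 0:
        raise ArgumentError("empty network")
    bc = nx.betweenness_centrality(g, normalized=False)
    clus = nx.clustering(g)
    deg = dict(g.degree())
    return NodeMetrics(
        degree={x: int(k) for x, k in deg.items()},
        betweenness={x: float(v) for x, v in bc.items()},
        clustering={x: float(clus[x]) if deg[x] >= 2 else 0.0 for x in g},
        clustering_defined={x: deg[x] >= 2 for x in g},
    )


@dataclass
class AttributeComparison:
    metric: str
    test: str
    levels: Dict[str, int]
    statistic: float
    p: float


def compare_node_attributes(network: KinNetwork, metrics: NodeMetrics,
                            attribute: str) -> Dict[str, AttributeComparison]:
    """Compare k, bc and C across the levels of a node attribute.

    Two levels use a Welch two-sample t-test, more use one-way ANOVA,
    matching the descriptive comparisons run on the field networks (e.g.
    whether bc differs among haplotypes or between the sexes). Nodes lacking
    the attribute are dropped; fewer than two usable levels, or any level
    with fewer than two nodes, is untestable. A metric with no variance at
    all yields statistic 0, p = 1.
    """
    groups: Dict[str, list] = {}
    for x, data in network.graph.nodes(data=True):
        level = data.get(attribute)
        if level not in (None, ""):
            groups.setdefault(str(level), []).append(x)
    groups = {k: v for k, v in groups.items() if len(v) >= 2}
    if len(groups) < 2:
        raise UntestableError(
            f"attribute {attribute!r} has fewer than 2 levels with >= 2 nodes"
        )
    levels = sorted(groups)
    out = {}
    for metric in ("degree", "betweenness", "clustering"):
        values = getattr(metrics, metric)
        samples = [np.array([values[x] for x in groups[l]], float) for l in levels]
        if np.ptp(np.concatenate(samples)) == 0:
            stat, p = 0.0, 1.0
            test = "t" if len(levels) == 2 else "anova"
        elif len(levels) == 2:
            stat, p = stats.ttest_ind(samples[0], samples[1], equal_var=False)
            test = "t"
        else:
            stat, p = stats.f_oneway(*samples)
            test = "anova"
        if np.isnan(p):
            stat, p = 0.0, 1.0
        out[metric] = AttributeComparison(
            metric=metric,
            test=test,
            levels={l: len(groups[l]) for l in levels},
            statistic=float(stat),
            p=float(p),
        )
    return out
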