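"""Independent brute-force oracles used only by the test suite.

Each oracle is deliberately naive (enumeration, no shared code with the
implementation under test) so that agreement is meaningful.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np

from bcrlineage.distances import LineageGraph
from bcrlineage.tree import LineageTree


def brute_force_mst_cost(graph: LineageGraph) -> int:
    """Minimum cost over ALL spanning trees, by exhaustive enumeration."""
    g = graph.graph
    nodes = list(g.nodes)
    n = len(nodes)
    if n == 1:
        return 0
    best = None
    edges = list(g.edges(data="weight"))
    for combo in itertools.combinations(edges, n - 1):
        sub = nx.Graph()
        sub.add_nodes_from(nodes)
        sub.add_edges_from((u, v) for u, v, _ in combo)
        if sub.number_of_edges() == n - 1 and nx.is_connected(sub):
            cost = sum(w for _, _, w in combo)
            if best is None or cost < best:
                best = cost
    assert best is not None, "graph is disconnected"
    return best


def scipy_mst_cost(graph: LineageGraph) -> int:
    """MST cost via scipy's csgraph implementation (independent route)."""
    from scipy.sparse import lil_matrix
    from scipy.sparse.csgraph import minimum_spanning_tree

    nodes = sorted(graph.graph.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    m = lil_matrix((len(nodes), len(nodes)))
    for u, v, d in graph.graph.edges(data="weight"):
        m[idx[u], idx[v]] = d
    return int(round(minimum_spanning_tree(m.tocsr()).sum()))


def random_connected_graph(rng: np.random.Generator, n: int,
                           extra_edges: int = 3, max_weight: int = 6
                           ) -> LineageGraph:
    """Random connected weighted graph with a root and random abundances."""
    labels = ["r"] + [f"g{i}" for i in range(1, n)]
    g = nx.Graph()
    g.add_nodes_from(labels)
    for i in range(1, n):
        j = int(rng.integers(0, i))
        g.add_edge(labels[i], labels[j],
                   weight=int(rng.integers(1, max_weight + 1)))
    for _ in range(extra_edges):
        i, j = rng.integers(0, n, size=2)
        if i != j and not g.has_edge(labels[i], labels[j]):
            g.add_edge(labels[int(i)], labels[int(j)],
                       weight=int(rng.integers(1, max_weight + 1)))
    abundances = {lab: int(rng.integers(1, 10)) for lab in labels}
    return LineageGraph(graph=g, root_label="r", abundances=abundances)


# ---------------------------------------------------------------------------
# exhaustive graph edit distance

def _node_key(tree: LineageTree, label: str, side: str) -> tuple:
    # mirrors the documented cross-tree identity rule: observed nodes match
    # by label, unobserved by sequence, sequence-less unobserved never match
    if tree.is_observed(label):
        return ("obs", label)
    seq = tree.seq(label)
    return ("useq", seq) if seq is not None else ("uid", side, label)


def exhaustive_ged(t1: LineageTree, t2: LineageTree) -> int:
    """Minimum edit cost over every injective partial node mapping.

    Cost of a mapping = node substitutions (key mismatch) + unmapped node
    deletions/insertions + edge deletions/insertions implied by the
    mapping.  This enumerates the full edit-script space for unit costs.
    """
    n1 = list(t1.nodes)
    n2 = list(t2.nodes)
    k1 = {x: _node_key(t1, x, "a") for x in n1}
    k2 = {x: _node_key(t2, x, "b") for x in n2}
    e1 = {(u, v) for u, v, _ in t1.edges()}
    e2 = {(u, v) for u, v, _ in t2.edges()}
    best = None
    for k in range(min(len(n1), len(n2)) + 1):
        for sub1 in itertools.combinations(n1, k):
            for sub2 in itertools.permutations(n2, k):
                f = dict(zip(sub1, sub2))
                cost = sum(1 for x in sub1 if k1[x] != k2[f[x]])
                cost += (len(n1) - k) + (len(n2) - k)
                mapped_edges = 0
                for (u, v) in e1:
                    if u in f and v in f and (f[u], f[v]) in e2:
                        mapped_edges += 1
                    else:
                        cost += 1          # edge deletion
                cost += len(e2) - mapped_edges  # edge insertions
                if best is None or cost < best:
                    best = cost
    return best
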