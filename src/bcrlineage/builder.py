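"""Abundance-aware minimum-spanning-tree construction (modified Prim).

The lineage tree is grown from the root as a hierarchical bi-objective
optimisation: the primary objective minimises the total edge weight (the
classical MST cost), the secondary maximises genotype abundance.  At each
step the frontier entry with the lowest edge weight is attached; among
equal-weight entries the one whose *candidate* node has the highest
abundance wins, and if that still ties, the one attached from the
highest-abundance tree node (the rule illustrated by clonal-expansion
reasoning: a heavily expanded genotype is the more plausible direct
ancestor).  Remaining ties fall back to lexicographic label order so the
output is fully deterministic.
"""

from __future__ import annotations

import heapq
import logging
from typing import Mapping, Optional

import networkx as nx

from .distances import LineageGraph
from .errors import ValidationError
from .tree import LineageTree

log = logging.getLogger(__name__)


def _entry_key(weight: int, cand_ab: int, from_ab: int, attach_from: str,
               node: str, use_abundance: bool) -> tuple:
    if use_abundance:
        return (weight, -cand_ab, -from_ab, attach_from, node)
    return (weight, attach_from, node)


def build_tree(
    graph: LineageGraph,
    use_abundance: bool = True,
    queue_discipline: str = "lazy",
    sequences: Optional[Mapping[str, str]] = None,
) -> LineageTree:
    """Grow the rooted lineage tree over all genotypes of ``graph``.

    Parameters
    ----------
    graph:
        Connected weighted genotype graph with a designated root.
    use_abundance:
        Apply the secondary (abundance-maximising) objective when edge
        weights tie.  Off, ties are broken purely lexicographically.
    queue_discipline:
        ``"lazy"`` (default) re-inserts a frontier node whenever a cheaper
        attachment is discovered, guaranteeing true MST cost.  ``"single"``
        inserts each node into the priority queue only once — a documented
        compatibility behaviour that can, on adversarial inputs, miss a
        cost-improving attachment found later.
    sequences:
        Optional label→sequence mapping attached to the tree nodes (needed
        downstream by the editors and the sequence-aware metrics).

    Returns
    -------
    LineageTree
        Spanning arborescence whose cost equals the MST cost of ``graph``
        (with the lazy queue).
    """
    g = graph.graph
    root = graph.root_label
    if len(g) > 1 and not nx.is_connected(g):
        raise ValidationError("genotype graph is disconnected")
    if queue_discipline not in ("lazy", "single"):
        raise ValidationError(f"unknown queue discipline {queue_discipline!r}")
    ab = graph.abundances
    tree = LineageTree(root, abundance=ab.get(root, 0))

    heap: list[tuple] = []
    queued: set[str] = set()
    counter = 0  # FIFO guard: keys are total orders already, but heapq
    # needs comparable tails when tuples are equal

    def push(attach_from: str, node: str) -> None:
        nonlocal counter
        if queue_discipline == "single" and node in queued:
            return
        queued.add(node)
        w = g.edges[attach_from, node]["weight"]
        key = _entry_key(w, ab.get(node, 0), ab.get(attach_from, 0),
                         attach_from, node, use_abundance)
        heapq.heappush(heap, (key, counter, attach_from, node))
        counter += 1

    for nb in sorted(g.neighbors(root)):
        push(root, nb)

    while len(tree) < len(g):
        if not heap:
            raise ValidationError("genotype graph is disconnected")
        key, _, attach_from, node = heapq.heappop(heap)
        if node in tree:  # stale entry
            continue
        w = g.edges[attach_from, node]["weight"]
        tree.add_node(node, abundance=ab.get(node, 0))
        tree.add_edge(attach_from, node, w)
        log.debug("attach %s under %s (weight=%d, abundance=%d)",
                  node, attach_from, w, ab.get(node, 0))
        for nb in sorted(g.neighbors(node)):
            if nb not in tree:
                push(node, nb)

    if sequences is not None:
        for n in tree.nodes:
            if n in sequences:
                tree.set_seq(n, sequences[n])
    return tree


def tree_cost(tree: LineageTree) -> int:
    """Total edge weight (the MST objective)."""
    return tree.cost()


def tree_depth(tree: LineageTree) -> int:
    """Maximum number of edges on a root-to-leaf path."""
    return tree.depth()
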