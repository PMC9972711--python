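"""Post-hoc tree editing: unobserved-ancestor insertion and depth reduction.

The greedy MST builder never reconsiders a choice, so two corrective edits
are applied to its output:

1. *Unobserved internal nodes.*  When two sister genotypes are closer to
   each other than either is to their parent, the natural explanation is an
   unsampled intermediate ancestor.  One is interposed and the three edge
   weights around it are redistributed by the update rule

       d_pi = max(d_pm - d_mn, d_pn - d_mn, 1)
       d_im = d_pm - d_pi
       d_in = d_pn - d_pi

   which conserves the parent-to-sister path lengths whenever the floor
   (the constant 1, keeping the new ancestor at least one mutation from
   its parent) is not the maximum.

2. *Depth reduction.*  Sub-trees are detached and reattached elsewhere
   whenever this strictly reduces the depth of the tree without increasing
   its total cost — a greedy move toward the most parsimonious shallow
   topology.  Unobserved nodes left with fewer than two children by a
   detachment are spliced out (they only exist to join sister branches).

Both edits iterate to a fixed point and are no-ops on trees that already
satisfy their conditions.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Optional

from .distances import DistanceMatrix, hamming
from .errors import ValidationError
from .tree import LineageTree

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SisterPair:
    """Two sisters ``m``, ``n`` under parent ``p`` with their distances.

    ``d_mn`` is the sequence distance between the sisters (from the
    distance matrix), not a path length in the tree.
    """

    parent: str
    m: str
    n: str
    d_pm: int
    d_pn: int
    d_mn: int


def update_weights(pair: SisterPair) -> tuple[int, int, int]:
    """Edge weights ``(d_pi, d_im, d_in)`` around an inserted ancestor ``i``.

    The parent-to-new-node weight is floored at 1 so the inferred ancestor
    is always at least one mutation away from the parent; in that floor
    branch the path-length conservation ``d_pi + d_im = d_pm`` no longer
    holds exactly.
    """
    d_pi = max(pair.d_pm - pair.d_mn, pair.d_pn - pair.d_mn, 1)
    return d_pi, pair.d_pm - d_pi, pair.d_pn - d_pi


def _node_dist(tree: LineageTree, matrix: Optional[DistanceMatrix],
               a: str, b: str) -> Optional[int]:
    """Sequence distance between two tree nodes.

    Prefers the precomputed matrix (observed genotypes); falls back to the
    attached — possibly reconstructed — sequences; ``None`` when neither
    source covers the pair.
    """
    if matrix is not None and a in matrix and b in matrix:
        return matrix.dist(a, b)
    sa, sb = tree.seq(a), tree.seq(b)
    if sa is not None and sb is not None:
        return hamming(sa, sb)
    return None


def _reconstruct_sequence(tree: LineageTree, parent: str, m: str, n: str
                          ) -> Optional[str]:
    """Parsimony sequence for an ancestor of sisters ``m``/``n`` under
    ``parent``: sister consensus where they agree, else the parent state."""
    sp, sm, sn = tree.seq(parent), tree.seq(m), tree.seq(n)
    if sp is None or sm is None or sn is None:
        return None
    return "".join(
        cm if cm == cn else cp for cp, cm, cn in zip(sp, sm, sn)
    )


def insert_unobserved_nodes(
    tree: LineageTree,
    matrix: Optional[DistanceMatrix] = None,
) -> LineageTree:
    """Interpose unobserved common ancestors wherever sisters are closer
    to each other than to their parent.

    The tree is traversed in pre-order; under each parent, sister pairs
    are scanned in lexicographic label order and at most one insertion is
    applied per parent per pass, repeating until no pair triggers.  The
    trigger is ``d_mn <= min(d_pm, d_pn)`` — the strictest reading of
    "closer to each other than to the parent".  Observed nodes and their
    abundances are never touched.
    """
    if matrix is None and all(tree.seq(n) is None for n in tree.nodes):
        raise ValidationError(
            "insert_unobserved_nodes needs a distance matrix or node sequences"
        )
    out = tree.copy()
    max_edits = 4 * len(out) + 20
    edits = 0
    while edits <= max_edits:
        pair = _find_trigger(out, matrix)
        if pair is None:
            break
        _apply_insertion(out, pair)
        edits += 1
    else:  # pragma: no cover - defensive bound
        log.warning("unobserved-node insertion stopped at the edit cap")
    return out


def _find_trigger(tree: LineageTree, matrix: Optional[DistanceMatrix]
                  ) -> Optional[SisterPair]:
    for p in tree.preorder():
        kids = sorted(tree.children(p))
        for m, n in itertools.combinations(kids, 2):
            d_pm = tree.weight(p, m)
            d_pn = tree.weight(p, n)
            d_mn = _node_dist(tree, matrix, m, n)
            if d_mn is None:
                if matrix is not None and (
                    tree.is_observed(m) and tree.is_observed(n)
                ):
                    raise ValidationError(
                        f"distance matrix does not cover pair ({m!r}, {n!r})"
                    )
                continue
            if d_mn <= min(d_pm, d_pn):
                pair = SisterPair(p, m, n, d_pm, d_pn, d_mn)
                d_pi, d_im, d_in = update_weights(pair)
                if d_im < 0 or d_in < 0:
                    # only possible when d_mn violates the triangle
                    # inequality w.r.t. the current edge weights
                    log.warning("skipping pair (%s, %s): update would yield "
                                "a negative weight", m, n)
                    continue
                return pair
    return None


def _apply_insertion(tree: LineageTree, pair: SisterPair) -> None:
    d_pi, d_im, d_in = update_weights(pair)
    label = tree.fresh_unobserved_label()
    seq = _reconstruct_sequence(tree, pair.parent, pair.m, pair.n)
    tree.remove_edge(pair.parent, pair.m)
    tree.remove_edge(pair.parent, pair.n)
    tree.add_node(label, abundance=0, seq=seq, observed=False)
    tree.add_edge(pair.parent, label, d_pi)
    tree.add_edge(label, pair.m, d_im)
    tree.add_edge(label, pair.n, d_in)
    log.debug("inserted %s above (%s, %s) with weights (%d, %d, %d)",
              label, pair.m, pair.n, d_pi, d_im, d_in)
    # a zero-weight edge to an unobserved child means the two inferred
    # ancestors coincide: merge them; an observed child keeps its
    # weight-0 edge (it is a real, distinct genotype record)
    for child, w in ((pair.m, d_im), (pair.n, d_in)):
        if w == 0 and not tree.is_observed(child):
            for gc in list(tree.children(child)):
                wgc = tree.weight(child, gc)
                tree.remove_edge(child, gc)
                tree.add_edge(label, gc, wgc)
            tree.remove_edge(label, child)
            tree.remove_node(child)
            log.debug("merged unobserved %s into %s (zero-weight edge)",
                      child, label)
        elif w == 0:
            log.debug("observed child %s at weight 0 under %s", child, label)


def _splice_degenerate_unobserved(tree: LineageTree, start: str,
                                  matrix: Optional[DistanceMatrix]) -> None:
    """Remove/splice unobserved ancestors left with < 2 children after a
    detachment, walking upward from ``start``."""
    node = start
    while node != tree.root and not tree.is_observed(node):
        kids = tree.children(node)
        parent = tree.parent(node)
        if len(kids) == 0:
            tree.remove_edge(parent, node)
            tree.remove_node(node)
        elif len(kids) == 1:
            child = kids[0]
            w = _node_dist(tree, matrix, parent, child)
            if w is None:
                w = tree.weight(parent, node) + tree.weight(node, child)
            tree.remove_edge(parent, node)
            tree.remove_edge(node, child)
            tree.remove_node(node)
            tree.add_edge(parent, child, w)
            break
        else:
            break
        node = parent


def _try_move(tree: LineageTree, v: str, u: str,
              matrix: Optional[DistanceMatrix]) -> Optional[LineageTree]:
    w_new = _node_dist(tree, matrix, u, v)
    if w_new is None:
        return None
    t = tree.copy()
    old_parent = t.parent(v)
    t.remove_edge(old_parent, v)
    t.add_edge(u, v, w_new)
    if old_parent in t:
        _splice_degenerate_unobserved(t, old_parent, matrix)
    return t


def reduce_depth(
    tree: LineageTree,
    matrix: Optional[DistanceMatrix] = None,
) -> LineageTree:
    """Greedy depth reduction at constant or decreasing cost.

    Every node (pre-order) is tentatively detached with its sub-tree and
    reattached under every other permissible node (pre-order); the first
    move that strictly reduces the tree depth without increasing the total
    cost is accepted, and the scan restarts on the edited tree.  The new
    edge weight is the sequence distance between the node and its new
    parent.  Terminates because the depth is a strictly decreasing
    non-negative integer across accepted moves.
    """
    out = tree.copy()
    while True:
        cur_depth = out.depth()
        cur_cost = out.cost()
        accepted = None
        order = out.preorder()
        for v in order[1:]:
            subtree = out.subtree_nodes(v)
            parent = out.parent(v)
            for u in order:
                if u in subtree or u == parent:
                    continue
                cand = _try_move(out, v, u, matrix)
                if cand is None:
                    continue
                if cand.depth() < cur_depth and cand.cost() <= cur_cost:
                    accepted = (v, u, cand)
                    break
            if accepted:
                break
        if not accepted:
            return out
        v, u, out = accepted
        log.debug("moved %s under %s (depth %d -> %d, cost %d -> %d)",
                  v, u, cur_depth, out.depth(), cur_cost, out.cost())
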