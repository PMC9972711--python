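"""The rooted lineage tree container.

A lineage tree is a rooted directed tree whose nodes are genotypes —
observed ones carry an abundance and (usually) a sequence, unobserved ones
are inferred intermediate ancestors with abundance 0 — and whose edge
weights are integer mutation counts.  Unlike a species phylogeny, observed
genotypes may sit at internal positions.

Backed by a :class:`networkx.DiGraph`; the wrapper enforces the
single-parent / single-root discipline and offers the traversals the
builder, editors and metrics need.
"""

from __future__ import annotations

import itertools
import re
from typing import Iterator, Optional

import networkx as nx

from .errors import ValidationError

#: Labels of unobserved (inferred) nodes follow this pattern when
#: serialized; together with abundance 0 it marks a node as unobserved.
UNOBSERVED_RE = re.compile(r"^U\d+$")


class LineageTree:
    """Rooted directed tree over observed and inferred genotypes."""

    def __init__(self, root_label: str, abundance: int = 0,
                 seq: Optional[str] = None, observed: bool = True) -> None:
        self._g = nx.DiGraph()
        self.root = root_label
        self._g.add_node(root_label, abundance=abundance, seq=seq,
                         observed=observed)

    # -- construction ------------------------------------------------------
    def add_node(self, label: str, *, abundance: int = 0,
                 seq: Optional[str] = None, observed: bool = True) -> None:
        if label in self._g:
            raise ValidationError(f"node {label!r} already in tree")
        self._g.add_node(label, abundance=abundance, seq=seq, observed=observed)

    def add_edge(self, parent: str, child: str, weight: int) -> None:
        if parent not in self._g or child not in self._g:
            raise ValidationError("both endpoints must be added before the edge")
        if self._g.in_degree(child) > 0:
            raise ValidationError(f"node {child!r} already has a parent")
        if weight < 0:
            raise ValidationError("edge weights must be non-negative")
        self._g.add_edge(parent, child, weight=int(weight))

    def remove_edge(self, parent: str, child: str) -> None:
        self._g.remove_edge(parent, child)

    def remove_node(self, label: str) -> None:
        if label == self.root:
            raise ValidationError("cannot remove the root")
        self._g.remove_node(label)

    # -- accessors ---------------------------------------------------------
    def __contains__(self, label: str) -> bool:
        return label in self._g

    def __len__(self) -> int:
        return self._g.number_of_nodes()

    @property
    def nodes(self) -> list[str]:
        return list(self._g.nodes)

    def edges(self) -> Iterator[tuple[str, str, int]]:
        for u, v, d in self._g.edges(data="weight"):
            yield u, v, d

    def parent(self, label: str) -> Optional[str]:
        preds = list(self._g.predecessors(label))
        return preds[0] if preds else None

    def children(self, label: str) -> list[str]:
        return list(self._g.successors(label))

    def weight(self, parent: str, child: str) -> int:
        return self._g.edges[parent, child]["weight"]

    def set_weight(self, parent: str, child: str, weight: int) -> None:
        self._g.edges[parent, child]["weight"] = int(weight)

    def abundance(self, label: str) -> int:
        return self._g.nodes[label]["abundance"]

    def seq(self, label: str) -> Optional[str]:
        return self._g.nodes[label].get("seq")

    def set_seq(self, label: str, seq: str) -> None:
        self._g.nodes[label]["seq"] = seq

    def is_observed(self, label: str) -> bool:
        return bool(self._g.nodes[label]["observed"])

    def leaves(self) -> list[str]:
        return [n for n in self.preorder() if self._g.out_degree(n) == 0]

    def observed_nodes(self) -> list[str]:
        return [n for n in self.preorder() if self.is_observed(n)]

    # -- traversals --------------------------------------------------------
    def preorder(self) -> list[str]:
        """Nodes in depth-first pre-order; children visited in label order."""
        out: list[str] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(sorted(self.children(node), reverse=True))
        return out

    def path_to_root(self, label: str) -> list[str]:
        """Labels from ``label`` up to (and including) the root."""
        path = [label]
        while (p := self.parent(path[-1])) is not None:
            path.append(p)
        return path

    def root_path(self, label: str) -> list[str]:
        """Labels from the root down to ``label`` (inclusive)."""
        return self.path_to_root(label)[::-1]

    def subtree_nodes(self, label: str) -> set[str]:
        return {label} | nx.descendants(self._g, label)

    def ancestors(self, label: str) -> list[str]:
        """Proper ancestors, nearest first."""
        return self.path_to_root(label)[1:]

    # -- summaries ---------------------------------------------------------
    def cost(self) -> int:
        """Sum of edge weights (total implied mutation count)."""
        return sum(w for _, _, w in self.edges())

    def depth(self) -> int:
        """Maximum number of edges on any root-to-leaf path."""
        depths = {self.root: 0}
        for node in self.preorder()[1:]:
            depths[node] = depths[self.parent(node)] + 1
        return max(depths.values())

    def node_depth(self, label: str) -> int:
        return len(self.path_to_root(label)) - 1

    # -- bookkeeping -------------------------------------------------------
    def copy(self) -> "LineageTree":
        t = LineageTree.__new__(LineageTree)
        t._g = self._g.copy()
        t.root = self.root
        return t

    def fresh_unobserved_label(self) -> str:
        used = {int(n[1:]) for n in self._g.nodes if UNOBSERVED_RE.match(n)}
        for k in itertools.count(1):
            if k not in used:
                return f"U{k}"
        raise AssertionError("unreachable")

    def validate(self, *, require_branching_unobserved: bool = False) -> None:
        """Check structural invariants; raise :class:`ValidationError`.

        With ``require_branching_unobserved`` every unobserved node must
        have at least two children (the contract for reconstructed trees;
        simulated ground truth may legitimately violate it).
        """
        g = self._g
        if self.root not in g:
            raise ValidationError("root missing from the tree")
        if g.in_degree(self.root) != 0:
            raise ValidationError("root has a parent")
        for n in g.nodes:
            if n != self.root and g.in_degree(n) != 1:
                raise ValidationError(f"node {n!r} has {g.in_degree(n)} parents")
        if not nx.is_arborescence(g) and len(g) > 1:
            raise ValidationError("graph is not a rooted tree")
        for n in g.nodes:
            if not g.nodes[n]["observed"]:
                if g.nodes[n]["abundance"] != 0:
                    raise ValidationError(f"unobserved node {n!r} has abundance > 0")
                if require_branching_unobserved and g.out_degree(n) < 2:
                    raise ValidationError(
                        f"unobserved node {n!r} has fewer than two children"
                    )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LineageTree):
            return NotImplemented
        if self.root != other.root or set(self.nodes) != set(other.nodes):
            return False
        if {(u, v, w) for u, v, w in self.edges()} != {
            (u, v, w) for u, v, w in other.edges()
        }:
            return False
        return all(
            self.abundance(n) == other.abundance(n)
            and self.is_observed(n) == other.is_observed(n)
            for n in self.nodes
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (f"LineageTree(root={self.root!r}, nodes={len(self)}, "
                f"cost={self.cost()}, depth={self.depth()})")


def is_unobserved_label(label: str, abundance: int) -> bool:
    """Serialized-form convention: a ``U<k>`` label with abundance 0."""
    return abundance == 0 and UNOBSERVED_RE.match(label) is not None
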