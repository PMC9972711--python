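"""Tree-comparison metrics for lineage reconstructions.

Four complementary distances between two rooted lineage trees over the
same genotype labels (typically a ground truth and a reconstruction):

``ged_tree``
    Exact graph edit distance — the minimum number of unit-cost node
    insertions/deletions/substitutions and edge insertions/deletions
    turning one tree into the other.  Exact computation is exponential,
    so trees beyond a small size bound are refused rather than silently
    approximated.
``ged_path``
    Path-based edit distance: for every leaf, the Levenshtein distance
    between its root-to-leaf label paths in the two trees (a leaf absent
    from one tree contributes its full path length), summed over the union
    of leaves.  Scales to trees of any size.
``mrca_distance``
    Mean normalised Hamming distance between the sequences of the most
    recent common ancestors of every shared observed node pair — 0 means
    every ancestral sequence was reconstructed perfectly.
``coar_distance``
    Correctness of ancestral reconstruction: leaf-averaged, Needleman–
    Wunsch-aligned dissimilarity of root-to-leaf paths, in [0, 1].

Node identity across trees is by genotype label.  Unobserved nodes carry
arbitrary labels, so for the graph edit distance they are matched by
sequence equality when sequences exist and treated as distinct otherwise;
the path metrics can drop them entirely (``skip_unobserved``), mirroring
how inferred intermediates are usually excluded from topology scoring.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

import networkx as nx
import numpy as np

from .distances import hamming, normalised_hamming
from .errors import ValidationError
from .tree import LineageTree

#: Largest tree (node count) accepted by the exact graph edit distance.
GED_EXACT_MAX_NODES = 12

#: Gap penalty of the path alignment: one fully mismatching node.
PATH_GAP_PENALTY = -1.0


@dataclass(frozen=True)
class MetricReport:
    """The four comparison metrics for one tree pair."""

    ged_tree: int
    ged_path: int
    mrca: float
    coar: float
    ged_path_no_unobserved: Optional[int] = None

    def as_dict(self) -> dict:
        d = {
            "ged_tree": self.ged_tree,
            "ged_path": self.ged_path,
            "mrca": self.mrca,
            "coar": self.coar,
        }
        if self.ged_path_no_unobserved is not None:
            d["ged_path_no_unobserved"] = self.ged_path_no_unobserved
        return d


# ---------------------------------------------------------------------------
# node identity across trees

def _node_key(tree: LineageTree, label: str, side: str) -> tuple:
    if tree.is_observed(label):
        return ("obs", label)
    seq = tree.seq(label)
    if seq is not None:
        return ("useq", seq)
    return ("uid", side, label)  # never matches across trees


def _keyed_digraph(tree: LineageTree, side: str) -> nx.DiGraph:
    g = nx.DiGraph()
    for n in tree.nodes:
        g.add_node(n, key=_node_key(tree, n, side))
    for u, v, _ in tree.edges():
        g.add_edge(u, v)
    return g


# ---------------------------------------------------------------------------
# graph edit distance

def ged_tree(t1: LineageTree, t2: LineageTree,
             max_nodes: int = GED_EXACT_MAX_NODES) -> int:
    """Exact graph edit distance between two lineage trees.

    Symmetric, and 0 exactly when the trees are label-isomorphic.  Trees
    with more than ``max_nodes`` nodes are refused (exact GED is
    exponential) unless they are label-isomorphic, which is checked first
    and costs nothing; use :func:`ged_path` for large trees.
    """
    g1 = _keyed_digraph(t1, "t1")
    g2 = _keyed_digraph(t2, "t2")
    if _isomorphic_by_key(g1, g2):
        return 0
    if max(len(g1), len(g2)) > max_nodes:
        raise ValidationError(
            f"exact graph edit distance is limited to {max_nodes} nodes "
            f"(got {len(g1)} and {len(g2)}); use ged_path for large trees"
        )
    cost = nx.graph_edit_distance(
        g1, g2,
        node_subst_cost=lambda a, b: 0 if a["key"] == b["key"] else 1,
        node_del_cost=lambda a: 1,
        node_ins_cost=lambda a: 1,
        edge_del_cost=lambda a: 1,
        edge_ins_cost=lambda a: 1,
    )
    return int(round(cost))


def _isomorphic_by_key(g1: nx.DiGraph, g2: nx.DiGraph) -> bool:
    k1 = [d["key"] for _, d in g1.nodes(data=True)]
    k2 = [d["key"] for _, d in g2.nodes(data=True)]
    if len(set(k1)) != len(k1) or len(set(k2)) != len(k2):
        return False  # ambiguous unobserved matching; let the search decide
    if set(k1) != set(k2):
        return False
    key1 = {n: d["key"] for n, d in g1.nodes(data=True)}
    key2 = {n: d["key"] for n, d in g2.nodes(data=True)}
    e1 = {(key1[u], key1[v]) for u, v in g1.edges}
    e2 = {(key2[u], key2[v]) for u, v in g2.edges}
    return e1 == e2


# ---------------------------------------------------------------------------
# path-based edit distance

def _leaf_path(tree: LineageTree, label: str, skip_unobserved: bool) -> list[str]:
    path = tree.root_path(label)[1:]  # below the root
    if skip_unobserved:
        path = [n for n in path if tree.is_observed(n)]
    return path


def _levenshtein(a: Sequence[str], b: Sequence[str]) -> int:
    n, m = len(a), len(b)
    prev = list(range(m + 1))
    for i in range(1, n + 1):
        cur = [i] + [0] * m
        for j in range(1, m + 1):
            cur[j] = min(
                prev[j - 1] + (a[i - 1] != b[j - 1]),
                prev[j] + 1,
                cur[j - 1] + 1,
            )
        prev = cur
    return prev[m]


def ged_path(t1: LineageTree, t2: LineageTree,
             skip_unobserved: bool = False) -> int:
    """Sum over the union of leaves of the label-path edit distance.

    A leaf present in both trees contributes the Levenshtein distance
    between its below-root label paths; a leaf missing from one tree
    contributes its whole path length.  With ``skip_unobserved`` inferred
    intermediate nodes are removed from the paths (and unobserved leaves
    ignored) before comparison.
    """
    def usable(tree: LineageTree, lab: str) -> bool:
        return not (skip_unobserved and not tree.is_observed(lab))

    leaves = {l for l in t1.leaves() if usable(t1, l)} | {
        l for l in t2.leaves() if usable(t2, l)}
    total = 0
    for lab in sorted(leaves):
        p1 = _leaf_path(t1, lab, skip_unobserved) if lab in t1 else None
        p2 = _leaf_path(t2, lab, skip_unobserved) if lab in t2 else None
        if p1 is not None and p2 is not None:
            total += _levenshtein(p1, p2)
        elif p1 is not None:
            total += len(p1)
        else:
            total += len(p2)
    return total


# ---------------------------------------------------------------------------
# ancestral-reconstruction metrics

def _require_sequences(*trees: LineageTree) -> None:
    missing = sorted(
        {n for t in trees for n in t.nodes if t.seq(n) is None}
    )
    if missing:
        raise ValidationError(
            f"nodes lacking a sequence (needed for ancestral metrics): {missing}"
        )


def _mrca(tree: LineageTree, i: str, j: str) -> str:
    anc_j = set(tree.path_to_root(j))
    for a in tree.path_to_root(i):
        if a in anc_j:
            return a
    raise AssertionError("rooted tree has no common ancestor")  # pragma: no cover


def mrca_distance(t1: LineageTree, t2: LineageTree) -> float:
    """All-pairs MRCA sequence distance, in [0, 1].

    For every unordered pair of non-root observed genotypes present in
    both trees, the most recent common ancestor is located in each tree
    and the normalised Hamming distance between the two ancestors'
    sequences is averaged over all pairs.  Because observed genotypes may
    be internal, all node pairs — not only leaf pairs — are scored.
    """
    _require_sequences(t1, t2)
    shared = sorted(
        (set(t1.observed_nodes()) - {t1.root})
        & (set(t2.observed_nodes()) - {t2.root})
    )
    pairs = list(itertools.combinations(shared, 2))
    if not pairs:
        raise ValidationError(
            "fewer than two shared observed non-root nodes; "
            "MRCA distance is undefined"
        )
    total = 0.0
    for i, j in pairs:
        a1 = _mrca(t1, i, j)
        a2 = _mrca(t2, i, j)
        total += normalised_hamming(t1.seq(a1), t2.seq(a2))
    return total / len(pairs)


@dataclass(frozen=True)
class NodePath:
    """A root-to-node (or node-to-root) path with attached sequences."""

    labels: tuple[str, ...]
    seqs: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.labels)

    @classmethod
    def from_tree(cls, tree: LineageTree, label: str) -> "NodePath":
        labels = tuple(tree.root_path(label))
        seqs = []
        for n in labels:
            s = tree.seq(n)
            if s is None:
                raise ValidationError(f"node {n!r} lacks a sequence")
            seqs.append(s)
        return cls(labels=labels, seqs=tuple(seqs))


def align_paths(p1: NodePath, p2: NodePath,
                gap_penalty: float = PATH_GAP_PENALTY) -> float:
    """Needleman–Wunsch score between two node paths.

    Aligning node ``u`` with node ``v`` scores the negative normalised
    Hamming distance of their sequences; a gap costs ``gap_penalty`` per
    position.  Identical paths score 0; every mismatch or gap drags the
    score below zero, never further than ``-max(len(p1), len(p2))``.
    """
    lengths = {len(s) for s in p1.seqs} | {len(s) for s in p2.seqs}
    if len(lengths) > 1:
        raise ValidationError(
            f"path sequences have unequal lengths {sorted(lengths)}"
        )
    L = lengths.pop()
    n, m = len(p1), len(p2)
    score = np.zeros((n + 1, m + 1))
    score[:, 0] = gap_penalty * np.arange(n + 1)
    score[0, :] = gap_penalty * np.arange(m + 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = -hamming(p1.seqs[i - 1], p2.seqs[j - 1]) / L
            score[i, j] = max(
                score[i - 1, j - 1] + sub,
                score[i - 1, j] + gap_penalty,
                score[i, j - 1] + gap_penalty,
            )
    return float(score[n, m])


def coar_distance(t1: LineageTree, t2: LineageTree) -> float:
    """Correctness of ancestral reconstruction, averaged over t1's leaves.

    For each leaf ``i`` of ``t1`` that exists in ``t2``, its root-to-leaf
    path is aligned against every root-to-leaf path of ``t2`` passing
    through ``i``; the best (maximum) alignment score ``s*`` against path
    ``p*`` yields ``COAR(i) = -s* / max(|p_i|, |p*|)``.  A leaf of ``t1``
    absent from ``t2`` contributes the worst case, 1.  The result lies in
    [0, 1] with 0 for a perfect reconstruction.
    """
    _require_sequences(t1, t2)
    leaves = t1.leaves()
    if not leaves:
        raise ValidationError("t1 has no leaves")
    total = 0.0
    for i in leaves:
        if i not in t2:
            total += 1.0
            continue
        p_i = NodePath.from_tree(t1, i)
        best_score = None
        best_len = 0
        for leaf2 in sorted(t2.subtree_nodes(i) & set(t2.leaves())):
            p_j = NodePath.from_tree(t2, leaf2)
            s = align_paths(p_i, p_j)
            if best_score is None or s > best_score:
                best_score = s
                best_len = len(p_j)
        if best_score is None:  # pragma: no cover - i is in t2, so its own
            total += 1.0        # subtree always contains at least one leaf
            continue
        total += -best_score / max(len(p_i), best_len)
    return total / len(leaves)


def compare_trees(t1: LineageTree, t2: LineageTree,
                  ged_max_nodes: int = GED_EXACT_MAX_NODES) -> MetricReport:
    """All four metrics (plus the unobserved-skipping path variant)."""
    return MetricReport(
        ged_tree=ged_tree(t1, t2, max_nodes=ged_max_nodes),
        ged_path=ged_path(t1, t2),
        mrca=mrca_distance(t1, t2),
        coar=coar_distance(t1, t2),
        ged_path_no_unobserved=ged_path(t1, t2, skip_unobserved=True),
    )
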