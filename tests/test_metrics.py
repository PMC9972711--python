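"""Tree-comparison metrics: GED variants, MRCA and COAR."""

from __future__ import annotations

import numpy as np
import pytest

from bcrlineage import (
    NodePath,
    ValidationError,
    align_paths,
    coar_distance,
    compare_trees,
    ged_path,
    ged_tree,
    mrca_distance,
)
from bcrlineage.tree import LineageTree

from conftest import mutate, random_lineage_tree, random_sequence
from _oracles import exhaustive_ged


def _chain(labels, seqs, weights=None):
    t = LineageTree(labels[0], abundance=1, seq=seqs[0])
    for i in range(1, len(labels)):
        t.add_node(labels[i], abundance=1, seq=seqs[i])
        t.add_edge(labels[i - 1], labels[i],
                   1 if weights is None else weights[i - 1])
    return t


# ---------------------------------------------------------------------------
# graph edit distance (exact)

def test_identical_trees_have_zero_everything(small_tree):
    other = small_tree.copy()
    report = compare_trees(small_tree, other)
    assert (report.ged_tree, report.ged_path, report.mrca, report.coar) == \
        (0, 0, 0.0, 0.0)
    assert report.ged_path_no_unobserved == 0


def test_extra_leaf_costs_one_node_plus_one_edge(rng):
    t1 = random_lineage_tree(rng, 4)
    t2 = t1.copy()
    t2.add_node("extra", abundance=1, seq=t2.seq(t2.root))
    t2.add_edge(t2.root, "extra", 1)
    assert ged_tree(t1, t2) == 2 == ged_tree(t2, t1)
    assert exhaustive_ged(t1, t2) == 2


def test_moved_leaf_costs_one_edge_deletion_plus_one_insertion():
    seqs = [random_sequence(np.random.default_rng(i), 12) for i in range(4)]
    t1 = LineageTree("r", abundance=1, seq=seqs[0])
    for lab, s in zip("abc", seqs[1:]):
        t1.add_node(lab, abundance=1, seq=s)
    t1.add_edge("r", "a", 1)
    t1.add_edge("r", "b", 1)
    t1.add_edge("a", "c", 1)
    t2 = t1.copy()
    t2.remove_edge("a", "c")
    t2.add_edge("b", "c", 1)
    assert ged_tree(t1, t2) == 2
    assert exhaustive_ged(t1, t2) == 2


def test_ged_matches_exhaustive_search_on_random_pairs():
    rng = np.random.default_rng(2024)
    for _ in range(25):
        t1 = random_lineage_tree(rng, int(rng.integers(2, 7)), seq_length=10)
        t2 = random_lineage_tree(rng, int(rng.integers(2, 7)), seq_length=10)
        assert ged_tree(t1, t2) == exhaustive_ged(t1, t2)
        assert ged_tree(t1, t2) == ged_tree(t2, t1)


def test_ged_tree_refuses_large_non_isomorphic_trees(rng):
    t1 = random_lineage_tree(rng, 14)
    t2 = random_lineage_tree(rng, 14)
    with pytest.raises(ValidationError, match="ged_path"):
        ged_tree(t1, t2)
    # ... but identical large trees short-circuit to 0
    assert ged_tree(t1, t1.copy()) == 0


# ---------------------------------------------------------------------------
# path-based edit distance

def test_dropped_intermediate_costs_one_deletion():
    L = 8
    s = [random_sequence(np.random.default_rng(i), L) for i in range(3)]
    t1 = _chain(["r", "a", "x"], s)
    t2 = LineageTree("r", abundance=1, seq=s[0])
    t2.add_node("x", abundance=1, seq=s[2])
    t2.add_edge("r", "x", 1)
    assert ged_path(t1, t2) == 1


def test_absent_leaf_contributes_its_full_path_length():
    s = [random_sequence(np.random.default_rng(i), 8) for i in range(4)]
    t1 = _chain(["r", "a", "b", "y"], s)   # y has 3 nodes below the root
    t2 = _chain(["r", "a", "b"], s[:3])
    assert ged_path(t1, t2) == 3


def test_zero_path_distance_means_identical_paths(rng):
    for _ in range(10):
        t1 = random_lineage_tree(rng, int(rng.integers(3, 12)))
        t2 = t1.copy()
        if ged_path(t1, t2) == 0:
            for leaf in t1.leaves():
                assert t1.root_path(leaf) == t2.root_path(leaf)


def test_skip_unobserved_variant_ignores_inferred_nodes(rng):
    s0 = random_sequence(rng, 10)
    t1 = LineageTree("r", abundance=1, seq=s0)
    t1.add_node("U1", abundance=0, seq=mutate(rng, s0, 1), observed=False)
    t1.add_edge("r", "U1", 1)
    t1.add_node("x", abundance=1, seq=mutate(rng, s0, 2))
    t1.add_edge("U1", "x", 1)
    t2 = LineageTree("r", abundance=1, seq=s0)
    t2.add_node("x", abundance=1, seq=t1.seq("x"))
    t2.add_edge("r", "x", 2)
    assert ged_path(t1, t2) == 1
    assert ged_path(t1, t2, skip_unobserved=True) == 0


# ---------------------------------------------------------------------------
# MRCA

def _fork(seqs):
    """root -> a (internal, child c), root -> b."""
    t = LineageTree("r", abundance=1, seq=seqs["r"])
    for lab, parent in (("a", "r"), ("b", "r"), ("c", "a")):
        t.add_node(lab, abundance=1, seq=seqs[lab])
        t.add_edge(parent, lab, 1)
    return t


def test_mrca_worked_example_one_thirtieth(rng):
    L = 20
    seqs = {lab: random_sequence(rng, L) for lab in "rabc"}
    t1 = _fork(seqs)
    seqs2 = dict(seqs)
    seqs2["a"] = mutate(rng, seqs["a"], 2)   # one internal sequence, 2/20
    t2 = _fork(seqs2)
    # shared non-root pairs: (a,b)->MRCA r/r: 0; (b,c)->r/r: 0;
    # (a,c)->a/a: 2/20.  Mean over 3 pairs = 1/30.
    assert mrca_distance(t1, t2) == pytest.approx(1 / 30)


def test_mrca_missing_sequence_lists_the_label(small_tree):
    broken = small_tree.copy()
    broken._g.nodes[broken.leaves()[0]]["seq"] = None
    with pytest.raises(ValidationError, match=broken.leaves()[0]):
        mrca_distance(small_tree, broken)


def test_mrca_never_decreases_as_an_internal_sequence_is_perturbed(rng):
    L = 30
    seqs = {lab: random_sequence(rng, L) for lab in "rabc"}
    t1 = _fork(seqs)
    previous = 0.0
    base = seqs["a"]
    for k in range(0, L + 1, 5):
        seqs2 = dict(seqs)
        s = list(base)
        for pos in range(k):   # deterministic cumulative perturbation
            s[pos] = "A" if base[pos] != "A" else "C"
        seqs2["a"] = "".join(s)
        current = mrca_distance(t1, _fork(seqs2))
        assert current >= previous - 1e-12
        previous = current


# ---------------------------------------------------------------------------
# path alignment and COAR

def test_identical_paths_score_zero(small_tree):
    leaf = small_tree.leaves()[0]
    p = NodePath.from_tree(small_tree, leaf)
    assert align_paths(p, p) == 0.0


def test_one_missing_node_costs_one_gap(rng):
    L = 12
    s = [random_sequence(rng, L) for _ in range(3)]
    long = NodePath(labels=("r", "a", "x"), seqs=tuple(s))
    short = NodePath(labels=("r", "x"), seqs=(s[0], s[2]))
    assert align_paths(long, short) == pytest.approx(-1.0)


def test_substitution_scores_negative_normalised_hamming():
    a = "A" * 30
    b = "C" * 3 + "A" * 27
    p1 = NodePath(labels=("x",), seqs=(a,))
    p2 = NodePath(labels=("y",), seqs=(b,))
    assert align_paths(p1, p2) == pytest.approx(-0.1)


def test_coar_extra_intermediate_node_normalises_by_longer_path(rng):
    L = 15
    r = random_sequence(rng, L)
    x = mutate(rng, r, 2)
    leaf = mutate(rng, x, 2)
    t1 = _chain(["r", "x", "leaf"], [r, x, leaf])
    t2 = LineageTree("r", abundance=1, seq=r)
    t2.add_node("x", abundance=1, seq=x)
    t2.add_edge("r", "x", 2)
    t2.add_node("U1", abundance=0, seq=x, observed=False)
    t2.add_edge("x", "U1", 1)
    t2.add_node("leaf", abundance=1, seq=leaf)
    t2.add_edge("U1", "leaf", 2)
    assert coar_distance(t1, t2) == pytest.approx(1 / 4)


def test_coar_leaf_absent_from_other_tree_is_worst_case(rng):
    L = 10
    r = random_sequence(rng, L)
    a = mutate(rng, r, 1)
    x = mutate(rng, a, 1)
    t1 = _chain(["r", "a", "x"], [r, a, x])
    t2 = _chain(["r", "a"], [r, a])
    assert coar_distance(t1, t2) == 1.0


def test_metrics_bounded_and_symmetric_on_random_pairs():
    rng = np.random.default_rng(77)
    for _ in range(10):
        t1 = random_lineage_tree(rng, int(rng.integers(3, 9)), seq_length=20)
        t2 = random_lineage_tree(rng, int(rng.integers(3, 9)), seq_length=20)
        assert ged_tree(t1, t2) == ged_tree(t2, t1)
        assert ged_path(t1, t2) == ged_path(t2, t1)
        assert 0.0 <= mrca_distance(t1, t2) <= 1.0
        assert 0.0 <= coar_distance(t1, t2) <= 1.0
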