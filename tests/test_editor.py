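"""Unobserved-ancestor insertion and depth reduction."""

from __future__ import annotations

import numpy as np
import pytest

from bcrlineage import (
    SisterPair,
    ValidationError,
    insert_unobserved_nodes,
    reduce_depth,
    update_weights,
)
from bcrlineage.distances import DistanceMatrix, build_matrix, hamming
from bcrlineage.records import SequenceRecord, collapse_genotypes
from bcrlineage.tree import LineageTree

from conftest import mutate, random_lineage_tree


def _matrix(labels, dists):
    n = len(labels)
    raw = np.zeros((n, n), dtype=np.int64)
    for (a, b), d in dists.items():
        i, j = labels.index(a), labels.index(b)
        raw[i, j] = raw[j, i] = d
    return DistanceMatrix(labels=list(labels), raw=raw, alignment_length=100)


# ---------------------------------------------------------------------------
# the edge-weight update rule

@pytest.mark.parametrize("d_pm, d_pn, d_mn, expected", [
    (5, 4, 2, (3, 2, 1)),   # regular branch: path lengths conserved
    (2, 2, 3, (1, 1, 1)),   # floor branch: both differences negative
    (1, 1, 1, (1, 0, 0)),   # degenerate: zero-weight edges to the sisters
])
def test_update_weights(d_pm, d_pn, d_mn, expected):
    pair = SisterPair("p", "m", "n", d_pm=d_pm, d_pn=d_pn, d_mn=d_mn)
    assert update_weights(pair) == expected


def test_update_weights_conserves_paths_outside_floor_branch():
    rng = np.random.default_rng(3)
    for _ in range(100):
        d_pm, d_pn = rng.integers(1, 20, size=2)
        d_mn = int(rng.integers(1, 20))
        d_pi, d_im, d_in = update_weights(
            SisterPair("p", "m", "n", int(d_pm), int(d_pn), d_mn))
        if d_pi > 1 or max(d_pm - d_mn, d_pn - d_mn) >= 1:
            assert d_pi + d_im == d_pm
            assert d_pi + d_in == d_pn


# ---------------------------------------------------------------------------
# ancestor insertion

def test_chain_tree_has_no_sisters_and_is_unchanged():
    t = LineageTree("r")
    t.add_node("a", abundance=1)
    t.add_edge("r", "a", 2)
    t.add_node("b", abundance=1)
    t.add_edge("a", "b", 2)
    m = _matrix(["r", "a", "b"], {("r", "a"): 2, ("a", "b"): 2, ("r", "b"): 4})
    assert insert_unobserved_nodes(t, m) == t


def test_worked_insertion_example():
    t = LineageTree("p")
    t.add_node("m", abundance=1)
    t.add_edge("p", "m", 5)
    t.add_node("n", abundance=1)
    t.add_edge("p", "n", 4)
    m = _matrix(["p", "m", "n"], {("p", "m"): 5, ("p", "n"): 4, ("m", "n"): 2})
    out = insert_unobserved_nodes(t, m)
    assert len(out) == 4
    (u,) = [x for x in out.nodes if not out.is_observed(x)]
    assert out.weight("p", u) == 3
    assert out.weight(u, "m") == 2
    assert out.weight(u, "n") == 1
    assert out.abundance(u) == 0


def test_no_insertion_when_sisters_are_far_apart():
    t = LineageTree("p")
    for c, w in (("m", 2), ("n", 3)):
        t.add_node(c, abundance=1)
        t.add_edge("p", c, w)
    m = _matrix(["p", "m", "n"], {("p", "m"): 2, ("p", "n"): 3, ("m", "n"): 5})
    assert insert_unobserved_nodes(t, m) == t


def test_insertion_reconstructs_a_parsimony_sequence():
    # sisters agree at their shared mutations, parent fills the rest
    p, m, n = "AAAAAA", "CCAAAA", "CCAATA"
    t = LineageTree("p", seq=p)
    t.add_node("m", abundance=1, seq=m)
    t.add_edge("p", "m", hamming(p, m))
    t.add_node("n", abundance=1, seq=n)
    t.add_edge("p", "n", hamming(p, n))
    table = collapse_genotypes(
        [SequenceRecord("p", p), SequenceRecord("m", m), SequenceRecord("n", n)],
        root_id="p")
    out = insert_unobserved_nodes(t, build_matrix(table))
    (u,) = [x for x in out.nodes if not out.is_observed(x)]
    assert out.seq(u) == "CCAAAA"  # sister consensus, parent elsewhere


def test_insertion_preserves_observed_nodes_and_abundances():
    rng = np.random.default_rng(17)
    for _ in range(10):
        t = random_lineage_tree(rng, int(rng.integers(4, 15)))
        out = insert_unobserved_nodes(t)
        obs_before = {(n, t.abundance(n)) for n in t.nodes if t.is_observed(n)}
        obs_after = {(n, out.abundance(n)) for n in out.nodes
                     if out.is_observed(n)}
        assert obs_before == obs_after


def test_insertion_is_idempotent():
    rng = np.random.default_rng(23)
    for _ in range(10):
        t = random_lineage_tree(rng, int(rng.integers(4, 12)))
        once = insert_unobserved_nodes(t)
        twice = insert_unobserved_nodes(once)
        assert twice == once


def test_insertion_requires_distances_or_sequences():
    t = LineageTree("r")  # no sequence anywhere
    with pytest.raises(ValidationError):
        insert_unobserved_nodes(t)


# ---------------------------------------------------------------------------
# depth reduction

def test_star_tree_is_already_minimal():
    t = LineageTree("r", seq="AAAA")
    for i, c in enumerate("abc"):
        t.add_node(c, abundance=1, seq=mutate(np.random.default_rng(i), "AAAA", 1))
        t.add_edge("r", c, 1)
    assert reduce_depth(t) == t


def test_chain_through_unobserved_node_is_flattened_at_equal_cost():
    # r -> U1 -> b with additive distances: moving b under r keeps the cost
    # once the now-childless unobserved U1 is pruned, and halves the depth
    r = "AAAAAAAA"
    u = "CCAAAAAA"                    # d(r, u) = 2
    b = "CCTTTAAA"                    # d(u, b) = 3, d(r, b) = 5 (additive)
    t = LineageTree("r", abundance=1, seq=r)
    t.add_node("U1", abundance=0, seq=u, observed=False)
    t.add_edge("r", "U1", hamming(r, u))
    t.add_node("b", abundance=1, seq=b)
    t.add_edge("U1", "b", hamming(u, b))
    old_cost = t.cost()
    out = reduce_depth(t)
    assert out.depth() == 1
    assert out.cost() == old_cost
    assert "U1" not in out
    assert out.parent("b") == "r"


def test_observed_chain_is_not_flattened_when_cost_would_grow():
    r = "AAAAAAAA"
    a = "CCAAAAAA"                    # d(r, a) = 2
    b = "CCTTAAAA"                    # d(a, b) = 2, d(r, b) = 4
    t = LineageTree("r", abundance=1, seq=r)
    t.add_node("a", abundance=1, seq=a)
    t.add_edge("r", "a", hamming(r, a))
    t.add_node("b", abundance=1, seq=b)
    t.add_edge("a", "b", hamming(a, b))
    out = reduce_depth(t)
    # moving b under r would add d(r,b) > d(a,b) while keeping r->a: cost up
    assert out == t


def test_depth_reduction_is_monotone_on_random_trees():
    rng = np.random.default_rng(31)
    for _ in range(15):
        t = random_lineage_tree(rng, int(rng.integers(4, 18)),
                                unobserved_prob=0.25)
        out = reduce_depth(t)
        assert out.depth() <= t.depth()
        assert out.cost() <= t.cost()
        # observed genotypes survive every move
        assert {n for n in t.nodes if t.is_observed(n)} <= set(out.nodes)


def test_depth_reduction_is_idempotent():
    rng = np.random.default_rng(37)
    for _ in range(8):
        t = random_lineage_tree(rng, int(rng.integers(4, 14)),
                                unobserved_prob=0.2)
        once = reduce_depth(t)
        assert reduce_depth(once) == once
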