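from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from bcrlineage.tree import LineageTree

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

BASES = "ACGT"


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(BASES), size=length))


def mutate(rng: np.random.Generator, seq: str, k: int) -> str:
    """Apply k substitutions at distinct positions, never restoring."""
    s = list(seq)
    for pos in rng.choice(len(s), size=k, replace=False):
        s[pos] = rng.choice([b for b in BASES if b != s[pos]])
    return "".join(s)


def random_lineage_tree(rng: np.random.Generator, n: int, seq_length: int = 30,
                        unobserved_prob: float = 0.0) -> LineageTree:
    """Random rooted tree with sequences; edge weight = parent-child
    Hamming distance by construction."""
    root_seq = random_sequence(rng, seq_length)
    tree = LineageTree("root", abundance=int(rng.integers(0, 5)),
                       seq=root_seq)
    labels = ["root"]
    u_count = 0
    for i in range(1, n):
        parent = labels[int(rng.integers(0, len(labels)))]
        k = int(rng.integers(1, min(4, seq_length)))
        seq = mutate(rng, tree.seq(parent), k)
        if rng.random() < unobserved_prob:
            u_count += 1
            label = f"U{u_count}"
            tree.add_node(label, abundance=0, seq=seq, observed=False)
        else:
            label = f"g{i}"
            tree.add_node(label, abundance=int(rng.integers(1, 9)), seq=seq)
        tree.add_edge(parent, label, k)
        labels.append(label)
    return tree


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def small_tree(rng) -> LineageTree:
    """Five observed nodes, sequences attached, two leaves."""
    return random_lineage_tree(rng, 5, seq_length=24)
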