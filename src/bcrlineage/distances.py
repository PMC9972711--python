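"""Hamming distances between genotypes and the weighted genotype graph.

Edge weights throughout the package are *raw* integer mismatch counts on
the shared alignment; the normalised distance (raw / alignment length) is
kept alongside because the ancestral-reconstruction metrics are defined on
the normalised scale.

Conventions: a gap aligned to a base is one mismatch, two aligned gaps
match, and ``N`` is a true fifth symbol — it mismatches every base and the
gap but matches itself, so the distance stays a metric (zero exactly on
identical strings).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import networkx as nx
import numpy as np

from .errors import ValidationError
from .records import GenotypeTable


def hamming(a: str, b: str) -> int:
    """Mismatch count between two equal-length aligned sequences."""
    if len(a) != len(b):
        raise ValidationError(
            f"hamming requires equal lengths, got {len(a)} and {len(b)}"
        )
    aa = np.frombuffer(a.upper().encode(), dtype=np.uint8)
    bb = np.frombuffer(b.upper().encode(), dtype=np.uint8)
    return int(np.count_nonzero(aa != bb))


def normalised_hamming(a: str, b: str) -> float:
    """Hamming distance divided by ``max(len(a), len(b))``."""
    if not a and not b:
        return 0.0
    return hamming(a, b) / max(len(a), len(b))


@dataclass
class DistanceMatrix:
    """Pairwise genotype distances on a shared alignment.

    ``raw`` holds integer mismatch counts, ``normalised`` the same divided
    by the alignment length.  Both are symmetric with a zero diagonal, and
    off-diagonal raw entries are >= 1 because genotypes are distinct.
    """

    labels: list[str]
    raw: np.ndarray
    alignment_length: int
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {lab: i for i, lab in enumerate(self.labels)}
        n = len(self.labels)
        if self.raw.shape != (n, n):
            raise ValidationError("distance matrix shape does not match labels")
        if not np.array_equal(self.raw, self.raw.T):
            raise ValidationError("distance matrix is not symmetric")
        if np.any(np.diag(self.raw) != 0):
            raise ValidationError("distance matrix diagonal is not zero")

    @property
    def normalised(self) -> np.ndarray:
        return self.raw / float(self.alignment_length)

    def dist(self, a: str, b: str) -> int:
        return int(self.raw[self._index[a], self._index[b]])

    def __contains__(self, label: str) -> bool:
        return label in self._index

    def to_tsv(self) -> str:
        lines = ["\t" + "\t".join(self.labels)]
        for lab, row in zip(self.labels, self.raw):
            lines.append(lab + "\t" + "\t".join(str(int(x)) for x in row))
        return "\n".join(lines) + "\n"


def build_matrix(table: GenotypeTable) -> DistanceMatrix:
    """All-pairs Hamming distances over the genotypes of ``table``."""
    seqs = [g.seq for g in table.genotypes]
    n = len(seqs)
    enc = np.vstack(
        [np.frombuffer(s.upper().encode(), dtype=np.uint8) for s in seqs]
    )
    raw = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        counts = (enc[i] != enc[i + 1:]).sum(axis=1)
        raw[i, i + 1:] = counts
        raw[i + 1:, i] = counts
    return DistanceMatrix(labels=table.labels, raw=raw,
                          alignment_length=table.alignment_length)


@dataclass
class LineageGraph:
    """Weighted undirected genotype graph fed to the tree builder."""

    graph: nx.Graph
    root_label: str
    abundances: dict[str, int]
    delta: Optional[float] = None

    @property
    def labels(self) -> list[str]:
        return list(self.graph.nodes)


def min_connecting_delta(matrix: DistanceMatrix) -> int:
    """Smallest threshold d such that keeping only edges of weight <= d
    leaves the genotype graph connected (the bottleneck of any MST)."""
    g = nx.Graph()
    n = len(matrix.labels)
    for i in range(n):
        for j in range(i + 1, n):
            g.add_edge(matrix.labels[i], matrix.labels[j],
                       weight=int(matrix.raw[i, j]))
    mst = nx.minimum_spanning_tree(g)
    return max((d["weight"] for _, _, d in mst.edges(data=True)), default=0)


def build_graph(
    matrix: DistanceMatrix,
    abundances: Mapping[str, int],
    root_label: str,
    delta: Optional[float] = None,
    prune_below: bool = False,
) -> LineageGraph:
    """Build the weighted genotype graph, optionally sparsified.

    With ``delta`` set, edges with raw weight strictly greater than
    ``delta`` are removed: dropping *long* edges sparsifies the graph while
    every MST edge of weight <= delta survives.  ``prune_below=True``
    instead removes edges with weight strictly *lower* than delta (kept as
    an explicit compatibility behaviour; it deletes the most informative
    edges and is rarely what you want).
    """
    if root_label not in matrix:
        raise ValidationError(f"root {root_label!r} not in distance matrix")
    if delta is not None and delta < 0:
        raise ValidationError("delta must be >= 0")
    g = nx.Graph()
    g.add_nodes_from(matrix.labels)
    n = len(matrix.labels)
    for i in range(n):
        for j in range(i + 1, n):
            w = int(matrix.raw[i, j])
            if delta is not None:
                if prune_below and w < delta:
                    continue
                if not prune_below and w > delta:
                    continue
            g.add_edge(matrix.labels[i], matrix.labels[j], weight=w)
    if len(g) > 1 and not nx.is_connected(g):
        comps = [sorted(c) for c in nx.connected_components(g)]
        hint = ""
        if delta is not None and not prune_below:
            hint = (f"; smallest delta preserving connectivity is "
                    f"{min_connecting_delta(matrix)}")
        raise ValidationError(
            f"pruning disconnects the genotype graph into {len(comps)} "
            f"components {comps}{hint}"
        )
    missing = [lab for lab in matrix.labels if lab not in abundances]
    if missing:
        raise ValidationError(f"abundances missing for labels: {missing}")
    return LineageGraph(
        graph=g,
        root_label=root_label,
        abundances={lab: int(abundances[lab]) for lab in matrix.labels},
        delta=delta,
    )
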