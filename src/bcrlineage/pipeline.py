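"""End-to-end reconstruction pipeline.

``reconstruct`` wires the stages together:
read → align → collapse genotypes → distance matrix → genotype graph →
abundance-aware MST → unobserved-ancestor insertion → depth reduction.
The three editing/objective switches (abundance objective, ancestor
insertion, depth reduction) default to on — the configuration that
performs best — and can be disabled individually.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

from . import editor
from .align import align_sequences
from .builder import build_tree
from .distances import DistanceMatrix, LineageGraph, build_graph, build_matrix
from .errors import ValidationError
from .records import GenotypeTable, SequenceRecord, collapse_genotypes
from .tree import LineageTree

log = logging.getLogger(__name__)


@dataclass
class ReconstructionResult:
    tree: LineageTree
    table: GenotypeTable
    matrix: DistanceMatrix
    graph: LineageGraph

    def summary(self) -> dict:
        return {
            "input_sequences": self.table.total_abundance(),
            "genotypes": len(self.table),
            "nodes": len(self.tree),
            "unobserved_nodes": sum(
                1 for n in self.tree.nodes if not self.tree.is_observed(n)
            ),
            "cost": self.tree.cost(),
            "depth": self.tree.depth(),
        }


def reconstruct(
    records: Sequence[SequenceRecord],
    root_id: str,
    *,
    use_abundance: bool = True,
    insert_unobserved: bool = True,
    depth_reduction: bool = True,
    delta: Optional[float] = None,
    prune_below: bool = False,
    aligner: str = "auto",
    aligner_binary: str = "mafft",
    queue_discipline: str = "lazy",
) -> ReconstructionResult:
    """Reconstruct a lineage tree from clonally related sequence records.

    Parameters
    ----------
    records:
        The observed sequences (one per read or pre-collapsed with
        abundances).  Must contain the record named by ``root_id`` — the
        inferred unmutated ancestor.
    root_id:
        Identifier of the root record.
    use_abundance, insert_unobserved, depth_reduction:
        The three pipeline switches; all default to on.
    delta:
        Optional graph-sparsification threshold (edges with raw weight
        greater than ``delta`` are dropped; see ``prune_below`` for the
        literal low-edge pruning variant).
    aligner:
        ``auto`` (align only if lengths differ), ``none``, ``builtin``, or
        ``external``.
    """
    if aligner == "auto":
        aligner = "none" if len({len(r.seq) for r in records}) == 1 else "builtin"
    aligned = align_sequences(records, mode=aligner, binary=aligner_binary)
    table = collapse_genotypes(aligned, root_id=root_id)
    log.info("collapsed %d records into %d genotypes", len(records), len(table))
    matrix = build_matrix(table)
    graph = build_graph(matrix, table.abundances(), table.root_label,
                        delta=delta, prune_below=prune_below)
    log.info("genotype graph: %d nodes, %d edges", len(graph.labels),
             graph.graph.number_of_edges())
    tree = build_tree(graph, use_abundance=use_abundance,
                      queue_discipline=queue_discipline,
                      sequences=table.sequences())
    log.info("built tree: cost=%d depth=%d", tree.cost(), tree.depth())
    if insert_unobserved:
        tree = editor.insert_unobserved_nodes(tree, matrix)
        log.info("after ancestor insertion: %d nodes", len(tree))
    if depth_reduction:
        tree = editor.reduce_depth(tree, matrix)
        log.info("after depth reduction: cost=%d depth=%d",
                 tree.cost(), tree.depth())
    tree.validate()
    return ReconstructionResult(tree=tree, table=table, matrix=matrix,
                                graph=graph)
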