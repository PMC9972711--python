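"""Synthetic B-cell lineage generator.

Emulates affinity maturation as a discrete branching process: starting
from a random unmutated ancestor, each node leaves a Poisson number of
descendants, each descendant acquires a Poisson number of point mutations
(optionally biased toward AID hot-spot motifs), and each resulting variant
is observed — sampled into the sequencing output — with a fixed
probability and a geometric copy number.  Every lineage carries its full
ground-truth tree, so reconstruction and metric code can be exercised
end-to-end without any external data.

The *easy regime* (:func:`easy_regime`) tightens the process into an
identifiable one — every node observed, every edge mutating at least one
previously untouched site — under which the true tree is the unique
minimum spanning tree of the genotype graph and must be recovered exactly.

What the generator deliberately does not model: selection and affinity,
insertions/deletions (alignment is trivial by construction), V(D)J
recombination of the root (the reconstruction is agnostic to how the
root arose), and class-switch recombination.
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .distances import hamming
from .errors import ValidationError
from .records import SequenceRecord
from .tree import LineageTree

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: AID-targeting motifs (WRC and its reverse complement GYW), used when
#: hot-spot bias is enabled.  Any alignment position covered by an
#: occurrence gets its mutation weight multiplied.
DEFAULT_HOTSPOT_MOTIFS = (
    "AAC", "AGC", "TAC", "TGC",  # WRC
    "GCA", "GCT", "GTA", "GTT",  # GYW
)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the branching-process simulator.

    Defaults produce clonal families whose depth (2–7) and size (roughly
    5–100 genotypes) sit in the range typical of germinal-center lineage
    studies.
    """

    root_length: int = 350            #: ancestor length in nucleotides
    offspring_mean: float = 1.5       #: Poisson mean children per node
    mutations_per_edge_mean: float = 2.0   #: Poisson mean mutations per edge
    max_generations: int = 7
    observation_rate: float = 0.8     #: probability a variant is sampled
    abundance_mean: float = 3.0       #: geometric mean copy number
    hotspot_motifs: tuple[str, ...] = DEFAULT_HOTSPOT_MOTIFS
    hotspot_multiplier: float = 1.0   #: 1.0 disables the bias
    seed: int = 0
    root_observed: bool = True
    unique_sites: bool = False        #: each mutation hits a fresh site
    min_mutations_per_edge: int = 0
    min_nodes: int = 6                #: condition on non-trivial lineages
    max_nodes: int = 500              #: hard cap on tree size

    def validate(self) -> None:
        if self.root_length < 1 or self.max_generations < 1 or self.max_nodes < 1:
            raise ValidationError("root_length, max_generations and max_nodes "
                                  "must be positive")
        if not 1 <= self.min_nodes <= self.max_nodes:
            raise ValidationError("min_nodes must be in [1, max_nodes]")
        if self.offspring_mean <= 0 or self.mutations_per_edge_mean < 0:
            raise ValidationError("offspring_mean must be > 0 and "
                                  "mutations_per_edge_mean >= 0")
        if not 0 <= self.observation_rate <= 1:
            raise ValidationError("observation_rate must be in [0, 1]")
        if self.abundance_mean < 1:
            raise ValidationError("abundance_mean must be >= 1")
        if self.hotspot_multiplier <= 0:
            raise ValidationError("hotspot_multiplier must be > 0")
        if self.min_mutations_per_edge < 0:
            raise ValidationError("min_mutations_per_edge must be >= 0")
        for m in self.hotspot_motifs:
            if not re.fullmatch("[ACGT]{3}", m):
                raise ValidationError(f"hot-spot motif {m!r} is not a 3-mer")


@dataclass
class SimulatedLineage:
    """Ground truth plus the observed sequencing output of one lineage."""

    truth: LineageTree
    records: list[SequenceRecord]
    config: SimConfig
    seed: int

    @property
    def root_id(self) -> str:
        return self.truth.root

    def observed_fasta(self) -> str:
        return "".join(
            f">{r.id}@{r.abundance}\n{r.seq}\n" for r in self.records
        )


def _site_weights(seq: str, cfg: SimConfig) -> np.ndarray:
    w = np.ones(len(seq))
    if cfg.hotspot_multiplier != 1.0:
        for motif in cfg.hotspot_motifs:
            start = 0
            while (idx := seq.find(motif, start)) != -1:
                w[idx:idx + 3] = cfg.hotspot_multiplier
                start = idx + 1
    return w


def simulate(config: SimConfig) -> SimulatedLineage:
    """Run the branching process and sample the observed records.

    Fully reproducible: the same config (including seed) always yields an
    identical lineage.  Edge weights of the truth tree equal the Hamming
    distance between the endpoint sequences by construction (mutated
    positions are distinct within an edge and never restore the original
    base).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    L = config.root_length
    root = "s0"
    # rejection-sample the branching process so lineages have at least
    # min_nodes genotypes (extinct two-node "lineages" carry no signal and
    # fall outside the size range of real clonal families)
    for _attempt in range(1000):
        root_seq_arr = rng.choice(BASES, size=L)
        seqs = {root: root_seq_arr}
        edges: list[tuple[str, str, int]] = []
        fresh_sites = list(range(L))  # only consumed in unique-sites mode
        counter = 1
        current = [root]
        for gen in range(config.max_generations):
            nxt: list[str] = []
            for node in current:
                k_children = int(rng.poisson(config.offspring_mean))
                if node == root and gen == 0:
                    k_children = max(1, k_children)
                for _ in range(k_children):
                    if counter >= config.max_nodes:
                        break
                    child = f"s{counter}"
                    counter += 1
                    n_mut = max(config.min_mutations_per_edge,
                                int(rng.poisson(config.mutations_per_edge_mean)))
                    child_seq = seqs[node].copy()
                    if n_mut > 0:
                        if config.unique_sites:
                            if n_mut > len(fresh_sites):
                                raise ValidationError(
                                    "root_length too small: ran out of fresh "
                                    "sites for unique-site mutations"
                                )
                            idx = rng.choice(len(fresh_sites), size=n_mut,
                                             replace=False)
                            positions = [fresh_sites[i] for i in sorted(idx)]
                            for pos in positions:
                                fresh_sites.remove(pos)
                        else:
                            w = _site_weights(child_seq.tobytes().decode(),
                                              config)
                            positions = rng.choice(L, size=min(n_mut, L),
                                                   replace=False, p=w / w.sum())
                        for pos in positions:
                            alt = [b for b in BASES if b != child_seq[pos]]
                            child_seq[pos] = rng.choice(alt)
                    seqs[child] = child_seq
                    edges.append((node, child, int(min(n_mut, L))))
                    nxt.append(child)
            current = nxt
            if not current:
                break
        if len(seqs) >= config.min_nodes:
            break
    else:  # pragma: no cover - requires absurd configs
        raise ValidationError(
            "could not grow a lineage of min_nodes genotypes in 1000 "
            "attempts; raise offspring_mean or lower min_nodes"
        )

    # observation and abundance sampling, in node order
    labels = sorted(seqs, key=lambda s: int(s[1:]))
    observed: dict[str, int] = {}
    for lab in labels:
        is_obs = rng.random() < config.observation_rate
        if lab == root and config.root_observed:
            is_obs = True
        if is_obs:
            observed[lab] = int(rng.geometric(1.0 / config.abundance_mean))

    truth = LineageTree(root, abundance=observed.get(root, 0),
                        seq=seqs[root].tobytes().decode(),
                        observed=root in observed)
    for parent, child, w in edges:
        truth.add_node(child, abundance=observed.get(child, 0),
                       seq=seqs[child].tobytes().decode(),
                       observed=child in observed)
        truth.add_edge(parent, child, w)

    records = [
        SequenceRecord(id=lab, seq=seqs[lab].tobytes().decode(),
                       abundance=observed[lab])
        for lab in labels if lab in observed
    ]
    return SimulatedLineage(truth=truth, records=records, config=config,
                            seed=config.seed)


def easy_regime(config: SimConfig) -> SimConfig:
    """Identifiable variant of ``config``: everything observed, every edge
    mutated at least once at fresh sites.

    Distinct nodes then have distinct sequences, inter-node distances are
    additive along the true tree, and the truth is the unique MST — so a
    correct builder must recover it exactly.
    """
    cfg = dataclasses.replace(
        config,
        observation_rate=1.0,
        root_observed=True,
        unique_sites=True,
        min_mutations_per_edge=max(1, config.min_mutations_per_edge),
    )
    # crude capacity check: expected mutations must fit the root length
    expected_nodes = min(
        config.max_nodes,
        int(sum(config.offspring_mean ** g
                for g in range(1, config.max_generations + 1))) + 1,
    )
    expected_mut = expected_nodes * max(1.0, config.mutations_per_edge_mean)
    if expected_mut > config.root_length:
        raise ValidationError(
            f"root_length {config.root_length} too small for ~{expected_nodes} "
            f"nodes with unique mutation sites; increase root_length or "
            f"shrink the tree"
        )
    return cfg
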