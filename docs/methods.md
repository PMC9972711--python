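# Methods

## Model and assumptions

A clonal family is a set of IGH sequences descended from one V(D)J
rearrangement; the unmutated ancestor is supplied by the caller (clonal
partitioning and germline inference happen upstream).  The reconstruction
assumes point mutations dominate — sequences are compared by Hamming
distance on a shared multiple alignment, so indels are handled by the
aligner, not modelled as evolutionary events — and that a genotype's read
abundance correlates with its clonal expansion, making abundant genotypes
preferred ancestors when the distance objective ties.

Genotypes are classes of *identical* aligned sequences.  The alternative
definition (same IGHV/IGHJ gene and CDR3) requires gene annotation and is
out of scope.

## Distances

Edge weights everywhere are raw integer mismatch counts; the normalised
distance (raw / alignment length) appears only inside the MRCA and COAR
metrics.  A normalised weight would break the editing update rule, whose
floor term "1" is one mutation.  Symbol conventions: gap–base mismatch,
gap–gap match, and `N` a true fifth symbol (matches itself only).  The
sparsification threshold δ removes edges *longer* than δ; dropping short
edges — the literal alternative, available as `prune_below=True` — would
delete exactly the edges an MST needs.  δ defaults to off (complete
graph); if pruning disconnects the graph the error reports the smallest
workable δ (the bottleneck weight of any MST).

The built-in aligner is a deterministic center-star progressive
Needleman–Wunsch (match 0, mismatch −1, gap −2), adequate for
near-identical clonal sequences; `mode="external"` shells out to a
MAFFT-style binary for data with complex indel structure.

## Tree construction

Modified Prim with a lazy priority queue: frontier entries are ordered by
(edge weight ↑, candidate abundance ↓, attach-side abundance ↓,
lexicographic labels), and stale entries are skipped on extraction.  Lazy
re-insertion guarantees the primary objective exactly (tree cost = MST
cost); the "insert each node only once" variant is kept behind
`queue_discipline="single"` because it can, on adversarial inputs, miss a
cheaper attachment discovered later.  The attach-side abundance appears in
the key so that when two equal-weight edges could claim the same
candidate, it joins the more expanded genotype regardless of labeling; the
lexicographic tail makes the output fully deterministic.

## Editing

**Ancestor insertion.**  Trigger d(m,n) ≤ min(d(p,m), d(p,n)) — the
strictest reading of "sisters closer to each other than to the parent" —
scanned pre-order, one insertion per parent per pass, to a fixed point.
The inserted node's sequence is reconstructed by parsimony (sister
consensus where the sisters agree, parent state elsewhere), which is what
lets the ancestral metrics score unobserved nodes.  With true Hamming
distances the update rule never produces negative weights (triangle
inequality); a zero-weight edge to an unobserved child merges the two
inferred ancestors, while an observed child keeps its weight-0 edge — it
is a real, distinct record.  Downstream weights are always recomputed from
sequences when sequences exist, so the floor branch (where
d_pi + d_im ≠ d_pm) cannot propagate inconsistency.

**Depth reduction.**  Any non-root node may be detached with its sub-tree
and reattached under any node outside it (both scanned pre-order,
first-improvement, rescan to fixed point); a move is accepted only if the
depth strictly decreases and the total cost does not increase, so
termination is immediate (depth is a decreasing non-negative integer).
The new edge weight is the sequence distance between the node and its new
parent.  Unobserved nodes left with fewer than two children by a
detachment are pruned or spliced out — they exist only to join sister
branches — and it is this splicing that lets a chain through an inferred
intermediate flatten at constant cost.

## Metrics

Node identity across trees is by genotype label; unobserved labels are
arbitrary, so for the graph edit distance unobserved nodes match by
sequence equality (never by label), and the path metrics can drop them via
`skip_unobserved`, mirroring the common practice of excluding inferred
intermediates from topology scoring.

* `ged_tree` counts unit-cost node insertions/deletions/substitutions and
  edge insertions/deletions (edge weights are not compared).  It is exact
  (networkx's exact edit-distance search with these costs) and therefore
  limited to 12 nodes; label-isomorphic pairs short-circuit to 0 at any
  size, larger non-trivial inputs are refused rather than approximated.
* `ged_path` sums, over the union of the two leaf sets, the Levenshtein
  distance between below-root label paths; a leaf absent from one tree
  contributes its whole path length.
* `mrca_distance` averages the normalised Hamming distance between MRCA
  sequences over all unordered pairs of shared observed non-root
  genotypes.  The root is excluded from the pair universe (its pairs are
  trivially ancestored by the root itself); all node pairs, not only leaf
  pairs, are scored because observed genotypes may be internal.
* `coar_distance` aligns each root-to-leaf path of the first tree against
  every root-to-leaf path of the second passing through that leaf, by
  Needleman–Wunsch over path nodes with substitution score
  −Hamming/L ∈ [−1, 0] and gap penalty −1 (one fully mismatching node);
  COAR(i) = −s*/max(|p_i|, |p*|) with the best-scoring path p*, and leaves
  absent from the other tree score the worst case, 1.  These constants and
  the max-length normalisation are this package's documented choices; they
  pin the metric to [0, 1] and make identical trees score exactly 0.

## Simulator

A discrete branching process: Poisson(offspring_mean) children per node
per generation, Poisson(λ) point mutations per edge at distinct positions
(substituted base never the original, so edge weight = Hamming distance
exactly), observation Bernoulli(observation_rate) with the root forced
observed, geometric copy numbers, optional WRC/GYW hot-spot weighting
(multiplier 1 = off, since the reconstruction ignores hot spots).
Defaults — root length 350 nt, offspring mean 1.5, λ = 2, ≤ 7
generations, observation rate 0.8, abundance mean 3 — are chosen so
lineages land in the depth (2–7) and size (≈6–100 genotypes) range
typical of germinal-center clonal-family benchmarks; the process is
rejection-sampled to at least 6 genotypes because extinct two-node
lineages carry no reconstruction signal.

The *easy regime* (observation rate 1, every edge ≥ 1 mutation at a
globally fresh site) makes distances additive along the true tree, whose
edges then each beat every alternative crossing the same cut strictly —
the truth is the unique MST, neither editor can trigger, and exact
recovery is a hard correctness requirement rather than a benchmark.  What
the simulator does not emulate: selection, indels, V(D)J recombination
realism, class switching, and sequencing error; passing the recovery tests
therefore demonstrates algorithmic correctness, not robustness to
real-repertoire noise.

## Numerical and degenerate-input choices

Ties everywhere resolve lexicographically after the documented keys, so
every pipeline stage is deterministic for a fixed input.  Single-genotype
inputs yield a one-node tree (cost 0, depth 0).  Test and acceptance
problem sizes (trees ≤ ~40 nodes for recovery, ≤ 9 nodes for brute-force
MST enumeration, ≤ 6 for exhaustive edit-script search) are chosen so the
independent oracles remain exactly enumerable.

## Known limitations

Hot/cold-spot-aware distances are not used by the reconstruction;
pairwise Levenshtein distances are deliberately rejected (quadratic in
practice and blind to column structure); exact GED does not scale past
small trees; the depth-reduction search is greedy first-improvement, not
a global optimisation over edit sequences.
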