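"""Exact recovery of identifiable simulated lineages.

In the 'easy regime' every variant is observed and every branch carries at
least one mutation at a fresh site, which makes the true tree the unique
minimum spanning tree of the genotype graph — so the reconstruction must
match it exactly.  This script runs ten such lineages and reports the
recovery rate.
"""

from bcrlineage import (SimConfig, easy_regime, ged_tree, reconstruct,
                        simulate)

perfect = 0
for seed in range(10):
    cfg = easy_regime(SimConfig(seed=seed, max_generations=5))
    sim = simulate(cfg)
    result = reconstruct(sim.records, sim.root_id)
    g = ged_tree(result.tree, sim.truth)
    print(f"seed {seed}: {len(sim.truth):3d} genotypes, "
          f"ged_tree = {g}")
    perfect += g == 0
print()
print(f"{perfect}/10 lineages recovered exactly (expected: all of them —")
print("in this regime any mismatch indicates a reconstruction bug).")
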