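"""Reconstruct a B-cell lineage tree from a handful of clonal sequences.

Builds a tiny clonal family in memory — an unmutated ancestor plus five
mutated variants, with read counts encoding clonal expansion — runs the
full pipeline and prints the tree.  Edge weights are mutation counts; the
@k suffix on each label is the genotype's abundance.
"""

from bcrlineage import SequenceRecord, reconstruct, write_tree

ROOT = "AGCTGACCTAGCATCGATCG"

records = [
    SequenceRecord("germline", ROOT),
    SequenceRecord("v1", "AGCTGACCTAGCATCGATGG", abundance=12),  # 1 mutation
    SequenceRecord("v2", "AGCTGACCAAGCATCGATGG", abundance=4),   # v1 + 1
    SequenceRecord("v3", "AGCTGACCAAGCTTCGATGG", abundance=2),   # v2 + 1
    SequenceRecord("v4", "AGCTGTCCTAGCATCGATCG", abundance=6),   # 1 mutation
    SequenceRecord("v5", "AGCTGTCCTAGCATCTATCG", abundance=1),   # v4 + 1
]

result = reconstruct(records, root_id="germline")

print("summary:", result.summary())
print(write_tree(result.tree, "newick").strip())
print()
print("Each parent-child edge spans the printed number of point mutations;")
print("the heavily expanded variants (v1, v4) sit directly under the root,")
print("and the rarer variants hang off the expanded ones they derive from.")
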