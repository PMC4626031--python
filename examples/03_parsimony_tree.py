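"""Mutation-annotated parsimony tree with recurrence annotation.

Three lineages of one haplogroup: two share a non-founding mutation (np 500)
and are joined under an internal node; a recurrent transition at np 16049
appears on two branches and is flagged."""

from bovmt import VariantProfile, annotate_recurrence, build_tree, to_newick
from bovmt.classify import HaplogroupNode, HaplogroupTree
from bovmt.phylo import branch_table

backbone = HaplogroupTree([HaplogroupNode("HG", None, ("1000",))])
profiles = [
    VariantProfile.from_labels("s1", ["1000", "500", "16049", "700"]),
    VariantProfile.from_labels("s2", ["1000", "500", "900"]),
    VariantProfile.from_labels("s3", ["1000", "16049"]),
]
tree = build_tree(profiles, backbone, {p.sample_id: "HG" for p in profiles})
annotate_recurrence(tree)
print(to_newick(tree))
print(branch_table(tree).to_string(index=False))
# branch lengths are mutation counts; '*' marks recurrent mutations (np 16049
# arose twice) and '@' would mark reversions to the reference allele.
# n_b (samples below a branch) and l_b (its mutation count) feed rho/sigma.
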