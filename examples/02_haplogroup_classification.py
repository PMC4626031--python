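"""Haplogroup assignment from diagnostic motifs.

Loads the default taurine motif configuration, builds a profile carrying the
Q1 founding motif plus two private mutations, and classifies it."""

from bovmt import (
    VariantProfile,
    classify_profile,
    founding_set,
    load_haplogroup_config,
)

tree = load_haplogroup_config()
print(f"haplogroup config: {len(tree)} nodes, root {tree.root!r}")
print("Q full motif:", " ".join(sorted(founding_set("Q", tree))),
      " (15953G separates Q from T)")

labels = sorted(founding_set("Q1", tree)) + ["1234", "8888"]  # motif + privates
profile = VariantProfile.from_labels("Domiaty_Q1", labels)
res = classify_profile(profile, tree)
print(f"{res.sample_id}: haplogroup {res.haplogroup} "
      f"(matched {res.matched}, mismatched {res.mismatched}, score {res.score})")
# matched/mismatched count motif sites present/absent in the profile; private
# mutations never change the assignment.
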