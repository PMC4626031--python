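"""Variant notation and calling against the reference.

Builds a mitogenome carrying a handful of known changes, calls its variant
profile back from the raw sequence, and shows the shorthand notation and the
hypervariable-site filter."""

from bovmt import (
    VariantProfile,
    apply_profile,
    call_variants,
    filter_hypervariable,
    load_reference,
    restrict_region,
)
from bovmt.variants import _call_aligned

ref = load_reference()
print(f"reference: {ref.id}, {ref.length} bp (np coordinates are 1-based)")

# a transition at np 2536, the Q-diagnostic C->G transversion at np 15953,
# a heteroplasmic transition at np 8000, and two hypervariable-site indels
profile = VariantProfile.from_labels(
    "demo", ["2536", "15953G", "8000h", "364+G", "221+C"], ref=ref)
ref_aln, seq_aln = apply_profile(ref, profile)
called = _call_aligned(ref_aln, seq_aln, ref, "demo")
print("called profile: ", " ".join(called.labels))

filtered = filter_hypervariable(called)
print("after hypervariable filter:", " ".join(filtered.labels))

coding = restrict_region(filtered, exclude_heteroplasmic=True)
print("coding region, no heteroplasmies:", " ".join(coding.labels))
# The filter removes the np 364 G insertion and tract-length changes scored at
# np 221/1600; dating then uses only coding-region (np 364-15791) substitutions.
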