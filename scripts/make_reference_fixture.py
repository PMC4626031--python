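"""Regenerate the packaged synthetic reference stand-in.

The packaged ``brs_synthetic.fasta`` is a deterministic synthetic sequence of
the bovine reference length (16,338 bp) with realistic base composition and
the structural features the variant notation relies on: a C homopolymer tract
ending at np 221, an A tract ending at np 1600, a non-G base at np 364 (so the
hypervariable G insertion anchors there) and C at np 15953 (so the
Q-diagnostic 15953G is a C->G transversion).  It is not the GenBank V00654
sequence.  Run from the repository root:

    python scripts/make_reference_fixture.py
"""

from pathlib import Path

import numpy as np

L = 16338
OUT = Path(__file__).resolve().parent.parent / "src" / "bovmt" / "data" / "brs_synthetic.fasta"


def main() -> None:
    rng = np.random.default_rng(20151104)
    bases = np.array(list("ACGT"))
    p = np.array([0.333, 0.259, 0.132, 0.276])  # approximate bovine mtDNA composition
    seq = rng.choice(bases, size=L, p=p)

    def setnp(pos: int, b: str) -> None:  # 1-based np
        seq[pos - 1] = b

    for i in range(215, 222):  # C tract ending at np 221
        setnp(i, "C")
    setnp(214, "A"); setnp(222, "T")
    for i in range(1594, 1601):  # A tract ending at np 1600
        setnp(i, "A")
    setnp(1593, "C"); setnp(1601, "G")
    setnp(364, "A"); setnp(363, "C"); setnp(365, "T")
    setnp(15953, "C")
    # break any other homopolymer of length >= 6 outside the scored tracts
    s = seq.copy()
    run = 1
    for i in range(1, L):
        if s[i] == s[i - 1]:
            run += 1
            if run >= 6 and not (215 <= i + 1 <= 221 or 1594 <= i + 1 <= 1600):
                s[i] = bases[(np.where(bases == s[i])[0][0] + 1) % 4]
                run = 1
        else:
            run = 1
    lines = ["".join(s[i:i + 70]) for i in range(0, L, 70)]
    with open(OUT, "w") as fh:
        fh.write(">V00654_synthetic synthetic stand-in for the bovine "
                 "reference sequence (16,338 bp)\n")
        fh.write("\n".join(lines) + "\n")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
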