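"""Mitogenome variants relative to the bovine reference sequence (BRS).

Every variant is expressed in the field's standard shorthand against the
16,338-bp bovine reference (GenBank V00654), using 1-based "np" (nucleotide
position) coordinates: a bare position denotes a transition, a trailing base a
transversion to that base, ``+X`` an insertion of X after the position, ``d``
a single-position deletion, and a trailing ``h`` heteroplasmy.  The packaged
reference shipped with this module is a synthetic stand-in with the same
length and the structural features the notation relies on; any 16,338-bp
sequence can be supplied as a custom reference.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "VariantKind",
    "Variant",
    "VariantProfile",
    "Region",
    "ReferenceGenome",
    "CODING_REGION",
    "TRANSITION_PARTNER",
    "load_reference",
    "parse_variant_label",
    "format_variant_label",
    "call_variants",
    "apply_profile",
    "filter_hypervariable",
    "restrict_region",
    "read_fasta",
    "write_fasta",
    "read_variant_tsv",
    "write_variant_tsv",
]

TRANSITION_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}
PURINES = frozenset("AG")

#: IUPAC two-base ambiguity codes used to encode heteroplasmic positions.
IUPAC_TWO = {
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
}
_CODE_FOR_PAIR = {v: k for k, v in IUPAC_TWO.items()}

_LABEL_RE = re.compile(r"^(\d+)(?:([ACGT])|\+([ACGT]+)|(d))?(h)?$")

REFERENCE_LENGTH = 16338


class VariantKind(str, Enum):
    TRANSITION = "transition"
    TRANSVERSION = "transversion"
    INSERTION = "insertion"
    DELETION = "deletion"


@dataclass(frozen=True)
class Region:
    """A closed 1-based interval of np coordinates."""

    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid region bounds {self.start}..{self.end}")

    def __contains__(self, position: int) -> bool:
        return self.start <= position <= self.end

    def __len__(self) -> int:
        return self.end - self.start + 1


#: The coding region used for dating (np 364-15791 inclusive, 15,428 sites).
CODING_REGION = Region("coding", 364, 15791)

#: Canonical np at which length variation of the hypervariable homopolymer
#: tracts is scored (C tract at np 221, A tract at np 1600).
TRACT_POSITIONS = (221, 1600)


@dataclass(frozen=True)
class Variant:
    """One difference from the reference at a single np."""

    position: int
    kind: VariantKind
    allele: str | None = None
    heteroplasmic: bool = False

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"np must be positive, got {self.position}")
        if self.kind is VariantKind.TRANSITION and self.allele is not None:
            raise ValueError("transition allele is implied by the reference")
        if self.kind is VariantKind.TRANSVERSION:
            if self.allele not in ("A", "C", "G", "T"):
                raise ValueError(f"transversion needs an explicit base, got {self.allele!r}")
        if self.kind is VariantKind.INSERTION:
            if not self.allele or not set(self.allele) <= set("ACGT"):
                raise ValueError(f"insertion needs inserted bases, got {self.allele!r}")
        if self.kind is VariantKind.DELETION and self.allele is not None:
            raise ValueError("deletion carries no allele")

    @property
    def key(self) -> tuple[int, VariantKind, str | None]:
        """Identity used for set comparisons (heteroplasmy flag excluded)."""
        return (self.position, self.kind, self.allele)

    @property
    def label(self) -> str:
        return format_variant_label(self)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


def parse_variant_label(label: str, max_position: int = REFERENCE_LENGTH,
                        ref: "ReferenceGenome | None" = None) -> Variant:
    """Parse shorthand like ``"16049"``, ``"15953G"``, ``"364+G"``, ``"100d"``.

    A bare number is a transition; a trailing base a transversion to that
    base; ``+X`` an insertion of ``X`` after the np; ``d`` a deletion; a
    final ``h`` flags heteroplasmy.  When ``ref`` is given the transversion
    base is checked against it (it must differ from the reference base and
    from its transition partner).
    """
    m = _LABEL_RE.match(label.strip())
    if m is None:
        raise ValueError(f"malformed variant label {label!r}")
    pos = int(m.group(1))
    limit = ref.length if ref is not None else max_position
    if not (1 <= pos <= limit):
        raise ValueError(f"np {pos} outside 1..{limit} in label {label!r}")
    het = m.group(5) is not None
    if m.group(2):
        base = m.group(2)
        if ref is not None:
            refbase = ref.base(pos)
            if base == refbase:
                raise ValueError(f"{label!r}: {base} equals the reference base at np {pos}")
            if base == TRANSITION_PARTNER.get(refbase):
                raise ValueError(
                    f"{label!r}: {base} is the transition partner of reference "
                    f"{refbase} at np {pos}; write the bare position instead"
                )
        return Variant(pos, VariantKind.TRANSVERSION, base, het)
    if m.group(3):
        return Variant(pos, VariantKind.INSERTION, m.group(3), het)
    if m.group(4):
        return Variant(pos, VariantKind.DELETION, None, het)
    return Variant(pos, VariantKind.TRANSITION, None, het)


def format_variant_label(v: Variant) -> str:
    """Inverse of :func:`parse_variant_label`."""
    if v.kind is VariantKind.TRANSITION:
        core = f"{v.position}"
    elif v.kind is VariantKind.TRANSVERSION:
        core = f"{v.position}{v.allele}"
    elif v.kind is VariantKind.INSERTION:
        core = f"{v.position}+{v.allele}"
    else:
        core = f"{v.position}d"
    return core + ("h" if v.heteroplasmic else "")


@dataclass(frozen=True)
class VariantProfile:
    """The ordered, duplicate-free set of variants one mitogenome carries."""

    sample_id: str
    variants: tuple[Variant, ...] = ()

    def __post_init__(self) -> None:
        seen: dict[tuple, Variant] = {}
        for v in self.variants:
            if v.key in seen:
                raise ValueError(f"duplicate variant {v.label} in profile {self.sample_id}")
            seen[v.key] = v
        ordered = tuple(sorted(self.variants, key=lambda v: (v.position, v.label)))
        object.__setattr__(self, "variants", ordered)

    @classmethod
    def from_labels(cls, sample_id: str, labels: Iterable[str],
                    ref: "ReferenceGenome | None" = None) -> "VariantProfile":
        return cls(sample_id, tuple(parse_variant_label(l, ref=ref) for l in labels))

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(v.label for v in self.variants)

    @property
    def label_set(self) -> frozenset[str]:
        return frozenset(self.labels)

    @property
    def keys(self) -> frozenset[tuple]:
        return frozenset(v.key for v in self.variants)

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self) -> Iterator[Variant]:
        return iter(self.variants)

    def __contains__(self, item: "Variant | str") -> bool:
        if isinstance(item, str):
            item = parse_variant_label(item)
        return item.key in self.keys


@dataclass(frozen=True)
class ReferenceGenome:
    """A circular mitochondrial reference with 1-based np coordinates."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if set(seq) - set("ACGTN"):
            bad = sorted(set(seq) - set("ACGTN"))
            raise ValueError(f"reference contains non-nucleotide characters {bad}")
        object.__setattr__(self, "sequence", seq)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def base(self, position: int) -> str:
        """Reference base at 1-based np ``position``."""
        if not (1 <= position <= self.length):
            raise ValueError(f"np {position} outside 1..{self.length}")
        return self.sequence[position - 1]


def load_reference(path: str | Path | None = None) -> ReferenceGenome:
    """Load the packaged synthetic BRS stand-in, or a custom reference FASTA.

    The packaged record is a deterministic synthetic sequence of the BRS
    length (16,338 bp) carrying the features the variant notation relies on;
    it is not the GenBank V00654 sequence itself.
    """
    if path is None:
        src = resources.files("bovmt.data").joinpath("brs_synthetic.fasta")
        with src.open() as fh:
            record = next(SeqIO.parse(fh, "fasta"))
    else:
        record = next(SeqIO.parse(str(path), "fasta"))
    return ReferenceGenome(record.id, str(record.seq))


# ---------------------------------------------------------------------------
# calling

def _left_align(pos: int, base: str, ref: ReferenceGenome) -> int:
    """Left-align a single-base indel anchored at/after np ``pos``."""
    while pos >= 1 and ref.base(pos) == base:
        pos -= 1
    return pos


def _tract_position(pos: int, base: str, ref: ReferenceGenome) -> int | None:
    """If the homopolymer run of ``base`` right of ``pos`` covers a scored
    tract (np 221 C tract / np 1600 A tract), return the canonical np."""
    start = pos + 1
    end = start
    while end <= ref.length and ref.base(end) == base:
        end += 1
    end -= 1
    if end < start:
        return None
    for canon in TRACT_POSITIONS:
        if start <= canon <= end and ref.base(canon) == base:
            return canon
    return None


def _normalize_indel(anchor: int, base: str, ref: ReferenceGenome) -> int:
    """Normalize a homopolymer-type indel: left-align, then score tract-length
    variants at the tract's canonical np (221 / 1600)."""
    left = _left_align(anchor, base, ref)
    canon = _tract_position(left, base, ref)
    if canon is not None:
        return canon
    return left if left >= 1 else anchor


def call_variants(seq: "str | SeqRecord", ref: ReferenceGenome,
                  sample_id: str = "sample") -> VariantProfile:
    """Call the variant profile of ``seq`` against ``ref``.

    ``seq`` is either the same length as the reference (positionally aligned,
    ``-`` marking deletions) or is pairwise-aligned first (the circle is
    linearized at np 1).  IUPAC two-base codes that include the reference
    base yield a heteroplasmic variant for the alternative base.
    """
    if isinstance(seq, SeqRecord):
        if sample_id == "sample":
            sample_id = seq.id
        seq = str(seq.seq)
    seq = seq.upper()
    allowed = set("ACGTN-") | set(IUPAC_TWO)
    if set(seq) - allowed:
        bad = sorted(set(seq) - allowed)
        raise ValueError(f"non-nucleotide characters in {sample_id}: {bad}")
    if len(seq) == ref.length and "-" not in seq:
        return _call_ungapped(seq, ref, sample_id)
    if len(seq) == ref.length:
        ref_aln, seq_aln = ref.sequence, seq
    else:
        ref_aln, seq_aln = _pairwise_align(ref.sequence, seq.replace("-", ""))
    return _call_aligned(ref_aln, seq_aln, ref, sample_id)


def _call_ungapped(seq: str, ref: ReferenceGenome, sample_id: str) -> VariantProfile:
    """Vectorized substitution calling for gap-free, full-length sequences."""
    import numpy as np

    a = np.frombuffer(ref.sequence.encode(), dtype=np.uint8)
    b = np.frombuffer(seq.encode(), dtype=np.uint8)
    diff = np.nonzero((a != b) & (b != ord("N")) & (a != ord("N")))[0]
    variants = []
    for i in diff:
        r, s = chr(a[i]), chr(b[i])
        pos = int(i) + 1
        if s in IUPAC_TWO:
            pair = IUPAC_TWO[s]
            if r not in pair:
                raise ValueError(
                    f"{sample_id}: ambiguity code {s} at np {pos} does not "
                    f"include the reference base {r}")
            (alt,) = pair - {r}
            het = True
        else:
            alt, het = s, False
        kind = (VariantKind.TRANSITION if alt == TRANSITION_PARTNER[r]
                else VariantKind.TRANSVERSION)
        variants.append(Variant(pos, kind,
                                None if kind is VariantKind.TRANSITION else alt, het))
    return VariantProfile(sample_id, tuple(variants))


def _pairwise_align(refseq: str, seq: str) -> tuple[str, str]:
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -1
    aln = aligner.align(refseq, seq)[0]
    return str(aln[0]), str(aln[1])


def _call_aligned(ref_aln: str, seq_aln: str, ref: ReferenceGenome,
                  sample_id: str) -> VariantProfile:
    if len(ref_aln) != len(seq_aln):
        raise ValueError("aligned sequences differ in length")
    variants: dict[tuple, Variant] = {}

    def add(v: Variant) -> None:
        variants.setdefault(v.key, v)

    np_pos = 0
    i = 0
    n = len(ref_aln)
    while i < n:
        r, s = ref_aln[i], seq_aln[i]
        if r != "-":
            np_pos += 1
        if r == "-" and s == "-":
            i += 1
            continue
        if r == "-":
            # insertion run anchored after the previous reference np
            j = i
            ins = []
            while j < n and ref_aln[j] == "-":
                if seq_aln[j] != "-":
                    ins.append(seq_aln[j])
                j += 1
            bases = "".join(ins)
            if bases:
                anchor = np_pos
                if len(set(bases)) == 1:
                    anchor = _normalize_indel(np_pos, bases[0], ref)
                    if anchor < 1:
                        anchor = np_pos
                add(Variant(max(anchor, 1), VariantKind.INSERTION, bases))
            i = j
            continue
        if s == "-":
            base = ref.base(np_pos)
            pos_out = np_pos
            if base in "ACGT":
                left = np_pos
                while left > 1 and ref.base(left - 1) == base:
                    left -= 1
                canon = _tract_position(left - 1, base, ref)
                pos_out = canon if canon is not None else left
            add(Variant(pos_out, VariantKind.DELETION))
            i += 1
            continue
        if s == "N" or r == "N" or s == r:
            i += 1
            continue
        if s in IUPAC_TWO:
            pair = IUPAC_TWO[s]
            if r in pair:
                (alt,) = pair - {r}
                kind = (VariantKind.TRANSITION if alt == TRANSITION_PARTNER[r]
                        else VariantKind.TRANSVERSION)
                add(Variant(np_pos, kind, None if kind is VariantKind.TRANSITION else alt,
                            heteroplasmic=True))
            else:
                raise ValueError(
                    f"{sample_id}: ambiguity code {s} at np {np_pos} does not "
                    f"include the reference base {r}")
            i += 1
            continue
        kind = (VariantKind.TRANSITION if s == TRANSITION_PARTNER[r]
                else VariantKind.TRANSVERSION)
        add(Variant(np_pos, kind, None if kind is VariantKind.TRANSITION else s))
        i += 1
    return VariantProfile(sample_id, tuple(variants.values()))


def apply_profile(ref: ReferenceGenome, profile: VariantProfile) -> tuple[str, str]:
    """Apply a profile to the reference; returns ``(ref_aligned, seq_aligned)``.

    The pair is column-aligned (gaps inserted for indels) so that
    ``call_variants`` on the result reproduces the profile exactly.
    Heteroplasmic substitutions are written as IUPAC two-base codes.
    """
    subs: dict[int, Variant] = {}
    dels: set[int] = set()
    ins: dict[int, str] = {}
    for v in profile:
        if v.kind in (VariantKind.TRANSITION, VariantKind.TRANSVERSION):
            if v.position in subs:
                raise ValueError(f"conflicting substitutions at np {v.position}")
            subs[v.position] = v
        elif v.kind is VariantKind.DELETION:
            dels.add(v.position)
        else:
            ins[v.position] = ins.get(v.position, "") + v.allele

    ref_out, seq_out = [], []
    for pos in range(1, ref.length + 1):
        r = ref.base(pos)
        ref_out.append(r)
        if pos in dels:
            seq_out.append("-")
        elif pos in subs:
            v = subs[pos]
            alt = TRANSITION_PARTNER[r] if v.kind is VariantKind.TRANSITION else v.allele
            if alt == r:
                raise ValueError(f"variant {v.label} matches the reference base")
            if v.heteroplasmic:
                seq_out.append(_CODE_FOR_PAIR[frozenset((r, alt))])
            else:
                seq_out.append(alt)
        else:
            seq_out.append(r)
        if pos in ins:
            ref_out.append("-" * len(ins[pos]))
            seq_out.append(ins[pos])
    return "".join(ref_out), "".join(seq_out)


# ---------------------------------------------------------------------------
# filters

def filter_hypervariable(profile: VariantProfile) -> VariantProfile:
    """Drop the hypervariable sites excluded from phylogeny construction:
    the G insertion at np 364 and length variation of the homopolymer tracts
    scored at np 221 (C tract) and np 1600 (A tract)."""
    kept = []
    for v in profile:
        if v.kind in (VariantKind.INSERTION, VariantKind.DELETION):
            if v.position in TRACT_POSITIONS:
                continue
            if (v.kind is VariantKind.INSERTION and v.position == 364
                    and set(v.allele) == {"G"}):
                continue
        kept.append(v)
    return VariantProfile(profile.sample_id, tuple(kept))


def restrict_region(profile: VariantProfile, region: Region = CODING_REGION,
                    exclude_heteroplasmic: bool = False) -> VariantProfile:
    """Keep variants inside ``region``; optionally drop heteroplasmies."""
    kept = tuple(
        v for v in profile
        if v.position in region and not (exclude_heteroplasmic and v.heteroplasmic)
    )
    return VariantProfile(profile.sample_id, kept)


# ---------------------------------------------------------------------------
# IO

def read_fasta(path: str | Path) -> list[SeqRecord]:
    return list(SeqIO.parse(str(path), "fasta"))


def write_fasta(records: Iterable[tuple[str, str] | SeqRecord], path: str | Path) -> None:
    out = []
    for rec in records:
        if isinstance(rec, SeqRecord):
            out.append(rec)
        else:
            rid, seq = rec
            out.append(SeqRecord(Seq(seq), id=rid, description=""))
    SeqIO.write(out, str(path), "fasta")


def read_variant_tsv(path: str | Path,
                     ref: ReferenceGenome | None = None) -> list[VariantProfile]:
    """Read a two-column TSV (sample_id, label; one row per variant)."""
    by_sample: dict[str, list[str]] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None:
            return []
        if [h.strip().lower() for h in header[:2]] != ["sample_id", "label"]:
            raise ValueError("variant TSV must have columns sample_id, label")
        for row in reader:
            if not row or not row[0].strip():
                continue
            by_sample.setdefault(row[0].strip(), []).append(row[1].strip())
    return [VariantProfile.from_labels(sid, labels, ref=ref)
            for sid, labels in by_sample.items()]


def write_variant_tsv(profiles: Iterable[VariantProfile], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["sample_id", "label"])
        for p in profiles:
            for v in p:
                writer.writerow([p.sample_id, v.label])
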