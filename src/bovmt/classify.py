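"""Haplogroup classification from diagnostic mutation motifs.

The taurine cattle mtDNA phylogeny is a rooted tree of named haplogroups
(P, Q with Q1/Q1a/Q2, and macro-haplogroup T with T1-T5 and subclades), each
defined by the mutations that arose on the branch leading to it.  A node's
*full motif* is the union of its own defining variants and those of all its
ancestors.  A profile is assigned to the node whose full motif it matches
best under the score ``matched - lambda * mismatched``; a motif site at
which the profile shows the reference allele (including back mutations)
counts as mismatched.

The default configuration shipped with the package encodes the clade
structure of the taurine phylogeny.  Only the Q-diagnostic transversion
(np 15953 C->G, separating Q from T) is an established diagnostic position;
all other default motifs are synthetic placeholders, marked as such in the
config, and are meant to be replaced by curated motifs.  Classification
behaviour is defined relative to whatever config is loaded.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

from .variants import Variant, VariantProfile, parse_variant_label

__all__ = [
    "HaplogroupNode",
    "HaplogroupTree",
    "ClassificationResult",
    "load_haplogroup_config",
    "default_config_path",
    "classify_profile",
    "founding_set",
    "write_classification_tsv",
]


@dataclass(frozen=True)
class HaplogroupNode:
    name: str
    parent: str | None
    defining_variants: tuple[str, ...]
    status: str = "verified"


@dataclass(frozen=True)
class ClassificationResult:
    sample_id: str
    haplogroup: str
    matched: int
    mismatched: int
    score: float


class HaplogroupTree:
    """Rooted tree of haplogroup nodes keyed by name."""

    def __init__(self, nodes: Iterable[HaplogroupNode]):
        self.nodes: dict[str, HaplogroupNode] = {}
        for node in nodes:
            if node.name in self.nodes:
                raise ValueError(f"duplicate haplogroup name {node.name!r}")
            for label in node.defining_variants:
                parse_variant_label(label)  # raises on bad labels
            self.nodes[node.name] = node
        if not self.nodes:
            raise ValueError("empty haplogroup configuration")
        roots = [n.name for n in self.nodes.values() if n.parent is None]
        if len(roots) != 1:
            raise ValueError(f"expected exactly one root, found {roots}")
        self.root = roots[0]
        for node in self.nodes.values():
            if node.parent is not None and node.parent not in self.nodes:
                raise ValueError(f"unknown parent {node.parent!r} of {node.name!r}")
        # cycle check + depth/motif caches
        self._depth: dict[str, int] = {}
        self._motif: dict[str, frozenset[tuple]] = {}
        for name in self.nodes:
            self._resolve(name, trail=set())

    def _resolve(self, name: str, trail: set[str]) -> tuple[int, frozenset[tuple]]:
        if name in self._depth:
            return self._depth[name], self._motif[name]
        if name in trail:
            raise ValueError(f"cycle in haplogroup tree at {name!r}")
        trail.add(name)
        node = self.nodes[name]
        own = frozenset(parse_variant_label(l).key for l in node.defining_variants)
        if node.parent is None:
            depth, motif = 0, own
        else:
            pdepth, pmotif = self._resolve(node.parent, trail)
            depth, motif = pdepth + 1, pmotif | own
        trail.discard(name)
        self._depth[name] = depth
        self._motif[name] = motif
        return depth, motif

    def depth(self, name: str) -> int:
        return self._depth[name]

    def full_motif(self, name: str) -> frozenset[tuple]:
        """Variant keys of the node's full motif (ancestral + own)."""
        if name not in self.nodes:
            raise KeyError(f"unknown haplogroup {name!r}")
        return self._motif[name]

    def ancestors(self, name: str) -> list[str]:
        out = []
        cur = self.nodes[name].parent
        while cur is not None:
            out.append(cur)
            cur = self.nodes[cur].parent
        return out

    def children(self, name: str) -> list[str]:
        return sorted(n.name for n in self.nodes.values() if n.parent == name)

    def __contains__(self, name: str) -> bool:
        return name in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)


def default_config_path() -> Path:
    return Path(str(resources.files("bovmt.data").joinpath("haplogroups.tsv")))


def load_haplogroup_config(path: str | Path | None = None) -> HaplogroupTree:
    """Load a haplogroup motif config (TSV or YAML by extension).

    TSV columns: ``name``, ``parent`` (empty for the root),
    ``defining_variants`` (comma-separated labels), optional ``status``.
    """
    if path is None:
        path = default_config_path()
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not data:
            raise ValueError(f"empty haplogroup config {path}")
        nodes = [
            HaplogroupNode(
                name=str(entry["name"]),
                parent=entry.get("parent") or None,
                defining_variants=tuple(entry.get("defining_variants") or ()),
                status=str(entry.get("status", "verified")),
            )
            for entry in data
        ]
        return HaplogroupTree(nodes)
    nodes = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(
            (line for line in fh if not line.startswith("#")), delimiter="\t")
        if reader.fieldnames is None:
            raise ValueError(f"empty haplogroup config {path}")
        required = {"name", "parent", "defining_variants"}
        if not required <= set(reader.fieldnames):
            raise ValueError(f"config must have columns {sorted(required)}")
        for row in reader:
            labels = tuple(
                l.strip() for l in (row["defining_variants"] or "").split(",") if l.strip())
            nodes.append(HaplogroupNode(
                name=row["name"].strip(),
                parent=(row["parent"].strip() or None),
                defining_variants=labels,
                status=(row.get("status") or "verified").strip() or "verified",
            ))
    if not nodes:
        raise ValueError(f"empty haplogroup config {path}")
    return HaplogroupTree(nodes)


def classify_profile(profile: VariantProfile, tree: HaplogroupTree,
                     mismatch_penalty: float = 1.0) -> ClassificationResult:
    """Assign ``profile`` to the best-scoring haplogroup.

    Score of node ``h`` is ``matched - mismatch_penalty * mismatched`` over
    the full motif of ``h``; ties go to the deeper node, then to the
    lexicographically smaller name.  A back mutation at a motif site leaves
    the site absent from the profile and therefore scores as a mismatch.
    """
    keys = profile.keys
    best: tuple[float, int, str] | None = None
    best_counts = (0, 0)
    for name in tree.nodes:
        motif = tree.full_motif(name)
        matched = len(motif & keys)
        mismatched = len(motif) - matched
        score = matched - mismatch_penalty * mismatched
        cand = (score, tree.depth(name), name)
        if best is None or (cand[0], cand[1]) > (best[0], best[1]) or (
                cand[0] == best[0] and cand[1] == best[1] and cand[2] < best[2]):
            best = cand
            best_counts = (matched, mismatched)
    assert best is not None
    return ClassificationResult(profile.sample_id, best[2],
                                best_counts[0], best_counts[1], best[0])


def founding_set(haplogroup: str, tree: HaplogroupTree) -> frozenset[str]:
    """Full motif of ``haplogroup`` as variant labels (ancestral + own)."""
    from .variants import VariantKind, format_variant_label

    keys = tree.full_motif(haplogroup)
    return frozenset(
        format_variant_label(Variant(pos, kind, allele)) for pos, kind, allele in keys)


def write_classification_tsv(results: Iterable[ClassificationResult],
                             path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["sample_id", "haplogroup", "matched", "mismatched", "score"])
        for r in results:
            writer.writerow([r.sample_id, r.haplogroup, r.matched, r.mismatched, r.score])
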