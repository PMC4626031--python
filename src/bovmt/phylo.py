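"""Mutation-annotated parsimony trees constrained to the haplogroup backbone.

Profiles are grouped by assigned haplogroup and, within each haplogroup,
joined by greedy agglomerative parsimony: the pair of lineages sharing the
most non-founding mutations is merged first, placing the shared mutations on
one internal branch, and merging continues while it strictly reduces the
total mutation count.  Lineages sharing nothing radiate straight from the
haplogroup root (the star topology typical of rapid expansions).  Branches
carry explicit mutation lists; the tree therefore houses the per-branch
counts l_b and subtended sample counts n_b used by the rho/sigma estimators.

A motif variant *absent* from a profile is placed on that lineage's branch
as a back mutation (suffix ``@``); recurrent mutations (same change on two
or more branches) are flagged by :func:`annotate_recurrence`.
"""

from __future__ import annotations

import csv
import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from .classify import ClassificationResult, HaplogroupTree, classify_profile, founding_set
from .variants import (
    TRANSITION_PARTNER,
    Variant,
    VariantKind,
    VariantProfile,
    parse_variant_label,
)

__all__ = [
    "BranchMutation",
    "TreeNode",
    "MutationTree",
    "build_tree",
    "build_clade_tree",
    "annotate_recurrence",
    "shared_nonfounding",
    "private_mutations",
    "to_newick",
    "branch_table",
]


@dataclass(frozen=True)
class BranchMutation:
    """A mutation event on a branch; ``back=True`` marks reversion to the
    reference allele at a site mutated on an ancestral branch."""

    variant: Variant
    back: bool = False
    recurrent: bool = False

    @property
    def key(self) -> tuple:
        return (*self.variant.key, self.back)

    @property
    def label(self) -> str:
        return self.variant.label + ("@" if self.back else "")


class TreeNode:
    """Node of a mutation-annotated rooted tree.

    The branch *above* the node carries ``mutations``; tips carry a
    ``sample_id``.  ``n_tips`` and ``branch_length`` give n_b and l_b.
    """

    __slots__ = ("name", "sample_id", "children", "parent", "mutations", "haplogroup")

    def __init__(self, name: str, sample_id: str | None = None,
                 mutations: Sequence[BranchMutation] = (),
                 haplogroup: str | None = None):
        self.name = name
        self.sample_id = sample_id
        self.children: list[TreeNode] = []
        self.parent: TreeNode | None = None
        self.mutations: list[BranchMutation] = sorted(
            mutations, key=lambda m: (m.variant.position, m.label))
        self.haplogroup = haplogroup

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_tip(self) -> bool:
        return not self.children

    @property
    def branch_length(self) -> int:
        """l_b: number of mutations on the branch above this node."""
        return len(self.mutations)

    @property
    def n_tips(self) -> int:
        """n_b: number of samples subtended by this branch."""
        if self.is_tip:
            return 1
        return sum(c.n_tips for c in self.children)

    def walk(self) -> Iterator["TreeNode"]:
        """Pre-order traversal including self."""
        yield self
        for child in self.children:
            yield from child.walk()

    def tips(self) -> list["TreeNode"]:
        return [n for n in self.walk() if n.is_tip]

    def find(self, name: str) -> "TreeNode | None":
        for node in self.walk():
            if node.name == name:
                return node
        return None

    def root_to_tip_lengths(self) -> dict[str, int]:
        """Mutation count from this node down to each tip (by sample_id)."""
        out: dict[str, int] = {}

        def rec(node: TreeNode, acc: int) -> None:
            for child in node.children:
                d = acc + child.branch_length
                if child.is_tip:
                    out[child.sample_id or child.name] = d
                else:
                    rec(child, d)

        rec(self, 0)
        if self.is_tip:
            out[self.sample_id or self.name] = 0
        return out

    def total_length(self) -> int:
        """Total mutation count on all branches below (and excluding) this node."""
        return sum(n.branch_length for n in self.walk() if n is not self)


MutationTree = TreeNode  # the tree is addressed through its root node


def _residual_items(profile: VariantProfile, founders: frozenset[tuple]
                    ) -> frozenset[tuple]:
    """Items distinguishing a profile from its haplogroup founder haplotype.

    Forward items are non-founding variants carried by the profile; back
    items are founder-motif variants the profile has lost (reversions)."""
    keys = profile.keys
    forward = {(k, False) for k in keys - founders}
    back = {(k, True) for k in founders - keys}
    return frozenset(forward | back)


def _item_mutation(item: tuple) -> BranchMutation:
    (pos, kind, allele), back = item
    return BranchMutation(Variant(pos, kind, allele), back=back)


def _pair_sort_key(shared: frozenset, members_a: tuple, members_b: tuple) -> tuple:
    positions = sorted(key[0][0] for key in shared)
    return (tuple(positions), tuple(sorted(members_a + members_b)))


def _agglomerate(hg_root: TreeNode, tips: list[tuple[frozenset, TreeNode, tuple]]) -> None:
    """Greedy parsimony agglomeration under one haplogroup root.

    ``tips`` holds (item set, node, member sample ids).  Pairs sharing the
    most items merge first (ties: smallest shared positions, then sample
    ids); merging continues while any pair shares at least one item."""
    clusters = list(tips)
    counter = itertools.count(1)
    while len(clusters) > 1:
        best = None
        for i, j in itertools.combinations(range(len(clusters)), 2):
            shared = clusters[i][0] & clusters[j][0]
            if not shared:
                continue
            key = (-len(shared), _pair_sort_key(shared, clusters[i][2], clusters[j][2]))
            if best is None or key < best[0]:
                best = (key, i, j, shared)
        if best is None:
            break
        _, i, j, shared = best
        items_i, node_i, members_i = clusters[i]
        items_j, node_j, members_j = clusters[j]
        node_i.mutations = sorted(
            (_item_mutation(it) for it in items_i - shared),
            key=lambda m: (m.variant.position, m.label))
        node_j.mutations = sorted(
            (_item_mutation(it) for it in items_j - shared),
            key=lambda m: (m.variant.position, m.label))
        parent = TreeNode(f"{hg_root.name}_anc{next(counter)}",
                          haplogroup=hg_root.haplogroup)
        parent.add_child(node_i)
        parent.add_child(node_j)
        merged = (shared, parent, tuple(sorted(members_i + members_j)))
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    for items, node, _members in clusters:
        node.mutations = sorted((_item_mutation(it) for it in items),
                                key=lambda m: (m.variant.position, m.label))
        hg_root.add_child(node)


def build_tree(profiles: Sequence[VariantProfile], backbone: HaplogroupTree,
               assignments: Mapping[str, str] | None = None) -> MutationTree:
    """Build the mutation-annotated parsimony tree of ``profiles``.

    Profiles must already be filtered of hypervariable sites.  When
    ``assignments`` (sample_id -> haplogroup) is not given, each profile is
    classified against ``backbone``.  Backbone branches carry the defining
    variants of their haplogroup; within-haplogroup structure is resolved by
    greedy parsimony agglomeration.
    """
    if not profiles:
        raise ValueError("no profiles to build a tree from")
    assigned: dict[str, str] = {}
    for p in profiles:
        if assignments is not None:
            if p.sample_id not in assignments:
                raise ValueError(f"profile {p.sample_id} has no haplogroup assignment")
            hg = assignments[p.sample_id]
            if hg not in backbone:
                raise ValueError(f"unknown haplogroup {hg!r} for {p.sample_id}")
        else:
            hg = classify_profile(p, backbone).haplogroup
        assigned[p.sample_id] = hg

    # backbone subtree spanning the assigned haplogroups
    needed: set[str] = set()
    for hg in assigned.values():
        needed.add(hg)
        needed.update(backbone.ancestors(hg))
    nodes: dict[str, TreeNode] = {}

    def get_node(name: str) -> TreeNode:
        if name not in nodes:
            cfg = backbone.nodes[name]
            muts = tuple(BranchMutation(parse_variant_label(l))
                         for l in cfg.defining_variants)
            nodes[name] = TreeNode(name, mutations=muts, haplogroup=name)
            if cfg.parent is not None:
                get_node(cfg.parent).add_child(nodes[name])
        return nodes[name]

    for name in sorted(needed, key=lambda n: (backbone.depth(n), n)):
        get_node(name)
    root = nodes[backbone.root]

    by_hg: dict[str, list[VariantProfile]] = {}
    for p in profiles:
        by_hg.setdefault(assigned[p.sample_id], []).append(p)
    for hg in sorted(by_hg):
        hg_root = nodes[hg]
        founders = backbone.full_motif(hg)
        tips = []
        for p in sorted(by_hg[hg], key=lambda p: p.sample_id):
            items = _residual_items(p, founders)
            tip = TreeNode(p.sample_id, sample_id=p.sample_id, haplogroup=hg)
            tips.append((items, tip, (p.sample_id,)))
        _agglomerate(hg_root, tips)
    return root


def build_clade_tree(profiles: Sequence[VariantProfile], founders: Iterable[str],
                     name: str = "clade") -> MutationTree:
    """Within-clade mutation tree rooted at the founder haplotype.

    ``founders`` is the clade's founding motif *after* the same filtering or
    region restriction applied to the profiles (so that, e.g., a
    control-region motif site does not appear as a spurious reversion when
    dating on the coding region)."""
    from .classify import HaplogroupNode

    backbone = HaplogroupTree([HaplogroupNode(name, None, tuple(sorted(founders)))])
    root = build_tree(profiles, backbone, {p.sample_id: name for p in profiles})
    return root


def annotate_recurrence(tree: MutationTree) -> MutationTree:
    """Flag recurrent mutations and back mutations in place (idempotent).

    A mutation is recurrent when the same (position, kind, allele) change
    occurs on two or more branches.  A substitution is a back mutation when
    it restores the reference allele at a site already mutated on an
    ancestral branch; such events keep the ``@`` suffix in their label.
    """
    counts: dict[tuple, int] = {}
    for node in tree.walk():
        for m in node.mutations:
            counts[m.variant.key] = counts.get(m.variant.key, 0) + 1

    def rec(node: TreeNode, state: dict[int, str | None]) -> None:
        # state maps np -> current derived allele marker (None means reference)
        local = dict(state)
        new_muts = []
        for m in node.mutations:
            v = m.variant
            back = m.back
            if v.kind in (VariantKind.TRANSITION, VariantKind.TRANSVERSION):
                marker = "ts" if v.kind is VariantKind.TRANSITION else v.allele
                if local.get(v.position) == marker:
                    back = True
                    local[v.position] = None
                else:
                    if m.back:
                        local[v.position] = None
                    else:
                        local[v.position] = marker
            new_muts.append(BranchMutation(v, back=back,
                                           recurrent=counts[v.key] >= 2))
        node.mutations = new_muts
        for child in node.children:
            rec(child, local)

    for child in tree.children:
        rec(child, {})
    # root's own branch (usually empty) — annotate recurrence flags only
    tree.mutations = [replace(m, recurrent=counts[m.variant.key] >= 2)
                      for m in tree.mutations]
    return tree


def shared_nonfounding(a: VariantProfile, b: VariantProfile,
                       founders: Iterable[str]) -> set[str]:
    """Labels of mutations shared by ``a`` and ``b`` that are not founding
    mutations of their haplogroup: ``(a ∩ b) \\ founders``."""
    fkeys = {parse_variant_label(l).key for l in founders}
    shared = (a.keys & b.keys) - fkeys
    return {Variant(p, k, al).label for p, k, al in shared}


def private_mutations(a: VariantProfile, others: Sequence[VariantProfile],
                      founders: Iterable[str]) -> set[str]:
    """Labels carried by ``a`` alone: ``a \\ founders \\ ∪(others)``."""
    fkeys = {parse_variant_label(l).key for l in founders}
    other_keys: set[tuple] = set()
    for o in others:
        other_keys |= o.keys
    priv = a.keys - fkeys - other_keys
    return {Variant(p, k, al).label for p, k, al in priv}


# ---------------------------------------------------------------------------
# export

def to_newick(tree: MutationTree, include_mutations: bool = True) -> str:
    """Newick string; branch length = mutation count, mutation labels in a
    ``[&mutations=...]`` comment (recurrent labels carry a ``*`` prefix)."""

    def fmt(node: TreeNode) -> str:
        if node.children:
            inner = ",".join(fmt(c) for c in node.children)
            core = f"({inner}){node.name}"
        else:
            core = node.name
        out = f"{core}:{node.branch_length}"
        if include_mutations and node.mutations:
            labels = "|".join(("*" if m.recurrent else "") + m.label
                              for m in node.mutations)
            out += f"[&mutations={labels}]"
        return out

    return f"{fmt(tree)};"


def branch_table(tree: MutationTree):
    """Branch table as a pandas DataFrame:
    branch_id, parent_id, n_b, l_b, labels."""
    import pandas as pd

    rows = []
    for node in tree.walk():
        rows.append({
            "branch_id": node.name,
            "parent_id": node.parent.name if node.parent else "",
            "n_b": node.n_tips,
            "l_b": node.branch_length,
            "labels": ",".join(m.label for m in node.mutations),
        })
    return pd.DataFrame(rows)


def write_branch_table(tree: MutationTree, path: str | Path) -> None:
    branch_table(tree).to_csv(path, sep="\t", index=False)
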