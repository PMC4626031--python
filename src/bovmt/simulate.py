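"""Synthetic mitogenome datasets with the statistical structure of a
star-like multi-haplogroup expansion.

The generator emulates a sample of complete mitogenomes drawn from several
haplogroups: each clade root carries its haplogroup's founder motif on top of
the reference, lineages radiate from the root in a star (or standard
coalescent) genealogy of a chosen age, and mutations accumulate along
branches as a Poisson process at the coding-region clock rate (default one
mutation per 3,172 years), placed at sites drawn according to discrete-gamma
site rates and substituted according to HKY85 conditional probabilities.
The control region mutates at a configurable per-site multiple of the coding
per-site rate.  Defaults reproduce the study conditions: 31 samples split
T1:18, T2:6, T3:5, Q1:2 with clade ages from the rho column of the age table.

Every run is fully determined by one seed and returns a truth manifest
(haplogroup per sample, true ages, per-branch mutation events, genealogy in
newick) against which the pipeline can be validated end to end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .classify import HaplogroupTree, founding_set, load_haplogroup_config
from .dating import ClockModel, SubstitutionModel, discretize_gamma, hky85_rate_matrix
from .variants import (
    CODING_REGION,
    TRANSITION_PARTNER,
    ReferenceGenome,
    VariantProfile,
    call_variants,
    load_reference,
    parse_variant_label,
    write_fasta,
    write_variant_tsv,
)

__all__ = [
    "SimConfig",
    "SimNode",
    "SimTruth",
    "SimulatedDataset",
    "simulate_genealogy",
    "simulate_mutations",
    "generate_dataset",
]

GENEALOGY_MODES = ("star", "coalescent_constant", "coalescent_growth")

#: Default clade composition (study sample: 31 mitogenomes).
DEFAULT_MIX = {"T1": 18, "T2": 6, "T3": 5, "Q1": 2}

#: Default clade ages (ky), the rho-based ages of the corresponding rows of
#: the age table (T1 15.57, T2 13.64, T3 12.53, Q1 19.29).
DEFAULT_AGES_KY = {"T1": 15.57, "T2": 13.64, "T3": 12.53, "Q1": 19.29}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic dataset; ``seed`` fully determines it."""

    seed: int = 0
    haplogroup_mix: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_MIX))
    clade_age_ky: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AGES_KY))
    genealogy: str = "star"
    clock: ClockModel = field(default_factory=ClockModel)
    model: SubstitutionModel = field(
        default_factory=lambda: SubstitutionModel(
            kappa=20.0, base_freqs=(0.333, 0.259, 0.132, 0.276), alpha=0.5))
    control_region_rate_multiplier: float = 5.0
    growth_rate_per_ky: float = 0.5  # coalescent_growth only

    def __post_init__(self) -> None:
        if self.genealogy not in GENEALOGY_MODES:
            raise ValueError(f"genealogy must be one of {GENEALOGY_MODES}")
        for hg, count in self.haplogroup_mix.items():
            if count < 1:
                raise ValueError(f"count for {hg} must be >= 1")
            if hg not in self.clade_age_ky:
                raise ValueError(f"no clade age configured for {hg}")
            if self.clade_age_ky[hg] < 0:
                raise ValueError(f"age for {hg} must be non-negative")
        if self.control_region_rate_multiplier < 0:
            raise ValueError("control-region multiplier must be non-negative")

    @property
    def n_samples(self) -> int:
        return sum(self.haplogroup_mix.values())


class SimNode:
    """Node of a timed genealogy; ``branch_years`` is the branch above."""

    __slots__ = ("name", "sample_id", "children", "branch_years", "events")

    def __init__(self, name: str, sample_id: str | None = None,
                 branch_years: float = 0.0):
        self.name = name
        self.sample_id = sample_id
        self.children: list[SimNode] = []
        self.branch_years = branch_years
        self.events: list[dict] = []  # mutation events on the branch above

    def add(self, child: "SimNode") -> "SimNode":
        self.children.append(child)
        return child

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()

    def tips(self) -> list["SimNode"]:
        return [n for n in self.walk() if not n.children]

    def height_years(self) -> float:
        if not self.children:
            return 0.0
        return max(c.branch_years + c.height_years() for c in self.children)

    def to_newick(self) -> str:
        def fmt(node: SimNode) -> str:
            if node.children:
                inner = ",".join(fmt(c) for c in node.children)
                core = f"({inner}){node.name}"
            else:
                core = node.name
            return f"{core}:{node.branch_years / 1000.0:.6g}"

        return f"{fmt(self)};"


def _coalescent_heights(n: int, rng: np.random.Generator,
                        growth: float | None) -> tuple[list[float], float]:
    """Coalescence event heights (most recent first) in scaled units."""
    heights = []
    t = 0.0
    for k in range(n, 1, -1):
        t += rng.exponential(2.0 / (k * (k - 1)))
        heights.append(t)
    if growth is not None and growth > 0:
        heights = [np.log1p(growth * h) / growth for h in heights]
    return heights, heights[-1]


def _expected_root_height(n: int, mode: str, growth: float,
                          rng: np.random.Generator, reps: int = 512) -> float:
    if mode == "coalescent_constant":
        return 2.0 * (1.0 - 1.0 / n)
    total = 0.0
    for _ in range(reps):
        _, h = _coalescent_heights(n, rng, growth)
        total += h
    return total / reps


def simulate_genealogy(cfg: SimConfig, clade: str,
                       rng: np.random.Generator | None = None) -> SimNode:
    """Timed genealogy of one clade (branch lengths in years).

    Star mode attaches every tip to the root at the clade age; coalescent
    modes draw standard n-coalescent waiting times (with an exponential
    time transform in growth mode), rescaled so the expected root height
    equals the clade age."""
    if clade not in cfg.haplogroup_mix:
        raise ValueError(f"clade {clade!r} not in haplogroup_mix")
    if rng is None:
        rng = np.random.default_rng([cfg.seed, _clade_tag(clade)])
    n = cfg.haplogroup_mix[clade]
    age_years = cfg.clade_age_ky[clade] * 1000.0
    names = [f"{clade}_{i + 1:02d}" for i in range(n)]
    root = SimNode(f"{clade}_root")
    if cfg.genealogy == "star" or n == 1:
        for name in names:
            root.add(SimNode(name, sample_id=name, branch_years=age_years))
        return root
    growth = cfg.growth_rate_per_ky if cfg.genealogy == "coalescent_growth" else None
    expect = _expected_root_height(n, cfg.genealogy, growth or 0.0,
                                   np.random.default_rng([cfg.seed, _clade_tag(clade), 7]))
    heights, h_root = _coalescent_heights(n, rng, growth)
    scale = age_years / (expect if expect > 0 else 1.0)
    node_height: dict[int, float] = {}
    active: list[SimNode] = []
    for name in names:
        tip = SimNode(name, sample_id=name)
        node_height[id(tip)] = 0.0
        active.append(tip)
    for k, h in enumerate(heights):
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        a, b = active[i], active[j]
        parent = SimNode(f"{clade}_c{k + 1}")
        node_height[id(parent)] = h * scale
        a.branch_years = h * scale - node_height[id(a)]
        b.branch_years = h * scale - node_height[id(b)]
        parent.add(a)
        parent.add(b)
        active = [x for t, x in enumerate(active) if t not in (i, j)]
        active.append(parent)
    (last,) = active
    last.name = f"{clade}_root"
    return last


def _clade_tag(clade: str) -> int:
    # stable small integer from the clade name for seed derivation
    return sum(ord(c) for c in clade) % 10007


def _founder_sequence(ref: ReferenceGenome, clade: str,
                      backbone: HaplogroupTree) -> np.ndarray:
    seq = np.frombuffer(ref.sequence.encode(), dtype=np.uint8).copy()
    for label in sorted(founding_set(clade, backbone)):
        v = parse_variant_label(label, ref=None)
        refbase = ref.base(v.position)
        if v.kind.value == "transition":
            alt = TRANSITION_PARTNER[refbase]
        elif v.kind.value == "transversion":
            alt = v.allele
        else:
            continue  # indel motifs are not applied to simulated sequences
        seq[v.position - 1] = ord(alt)
    return seq


def simulate_mutations(tree: SimNode, cfg: SimConfig, ref: ReferenceGenome,
                       backbone: HaplogroupTree, clade: str,
                       rng: np.random.Generator) -> dict[str, str]:
    """Drop mutations on a timed genealogy and emit tip sequences.

    Per branch the number of coding-region mutations is Poisson with mean
    ``branch_years / years_per_mutation``; control-region mutations are
    Poisson at the per-site coding rate times the configured multiplier.
    Sites are drawn proportionally to their discrete-gamma rate; the new
    base follows the HKY85 conditional substitution probabilities given the
    current base.  Events are recorded on ``tree`` nodes; returns
    ``{sample_id: sequence}``."""
    L = ref.length
    rates = discretize_gamma(cfg.model.alpha, cfg.model.n_categories)
    site_rate = rates[rng.integers(0, cfg.model.n_categories, size=L)]
    coding_mask = np.zeros(L, dtype=bool)
    coding_mask[CODING_REGION.start - 1:CODING_REGION.end] = True
    w_cod = site_rate * coding_mask
    w_cod = w_cod / w_cod.sum()
    w_ctl = site_rate * ~coding_mask
    w_ctl_total = w_ctl.sum()
    if w_ctl_total > 0:
        w_ctl = w_ctl / w_ctl_total
    Q = hky85_rate_matrix(cfg.model)
    ypm = cfg.clock.years_per_mutation
    n_coding_sites = len(CODING_REGION)
    n_control_sites = L - n_coding_sites
    ctl_mean_factor = (cfg.control_region_rate_multiplier
                       * n_control_sites / n_coding_sites)
    base_codes = np.frombuffer(b"ACGT", dtype=np.uint8)
    code_index = {int(c): i for i, c in enumerate(base_codes)}

    sequences: dict[str, str] = {}

    def mutate(seq: np.ndarray, node: SimNode) -> None:
        t = node.branch_years
        node.events = []
        if t > 0:
            n_cod = rng.poisson(t / ypm)
            n_ctl = rng.poisson(t / ypm * ctl_mean_factor) if w_ctl_total > 0 else 0
            sites = []
            if n_cod:
                sites.extend(rng.choice(L, size=n_cod, p=w_cod))
            if n_ctl:
                sites.extend(rng.choice(L, size=n_ctl, p=w_ctl))
            for s in sites:
                cur = code_index[int(seq[s])]
                probs = Q[cur].copy()
                probs[cur] = 0.0
                probs = probs / probs.sum()
                new = rng.choice(4, p=probs)
                node.events.append({
                    "np": int(s + 1),
                    "from": chr(seq[s]),
                    "to": BASES[new],
                })
                seq[s] = base_codes[new]
        if node.children:
            for child in node.children:
                mutate(seq.copy(), child)
        else:
            sequences[node.sample_id or node.name] = seq.tobytes().decode()

    founder = _founder_sequence(ref, clade, backbone)
    for child in tree.children:
        mutate(founder.copy(), child)
    if not tree.children:  # degenerate single-node clade
        sequences[tree.sample_id or tree.name] = founder.tobytes().decode()
    return sequences


BASES = "ACGT"


@dataclass
class SimTruth:
    """Manifest of the true parameters behind one simulated dataset."""

    seed: int
    genealogy_mode: str
    sample_haplogroup: dict[str, str]
    clade_age_ky: dict[str, float]
    branch_mutation_counts: dict[str, dict[str, int]]
    genealogy_newick: dict[str, str]
    variant_labels: dict[str, list[str]]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


@dataclass
class SimulatedDataset:
    config: SimConfig
    sequences: dict[str, str]
    profiles: list[VariantProfile]
    truth: SimTruth
    trees: dict[str, SimNode]

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(sorted(self.sequences.items()), out / "mitogenomes.fasta")
        write_variant_tsv(self.profiles, out / "variants.tsv")
        self.truth.to_json(out / "truth.json")
        with open(out / "genealogies.nwk", "w") as fh:
            for clade in sorted(self.trees):
                fh.write(self.trees[clade].to_newick() + "\n")


def generate_dataset(cfg: SimConfig,
                     ref: ReferenceGenome | None = None,
                     backbone: HaplogroupTree | None = None) -> SimulatedDataset:
    """Simulate a full dataset: FASTA sequences, called variant profiles and
    the truth manifest.  Deterministic given ``cfg.seed``."""
    if ref is None:
        ref = load_reference()
    if backbone is None:
        backbone = load_haplogroup_config()
    for hg in cfg.haplogroup_mix:
        if hg not in backbone:
            raise ValueError(f"haplogroup {hg!r} not in the backbone config")
    sequences: dict[str, str] = {}
    trees: dict[str, SimNode] = {}
    sample_hg: dict[str, str] = {}
    branch_counts: dict[str, dict[str, int]] = {}
    newicks: dict[str, str] = {}
    for clade in sorted(cfg.haplogroup_mix):
        rng = np.random.default_rng([cfg.seed, _clade_tag(clade)])
        tree = simulate_genealogy(cfg, clade, rng)
        seqs = simulate_mutations(tree, cfg, ref, backbone, clade, rng)
        sequences.update(seqs)
        trees[clade] = tree
        newicks[clade] = tree.to_newick()
        branch_counts[clade] = {
            node.name: len(node.events) for node in tree.walk() if node is not tree}
        for sid in seqs:
            sample_hg[sid] = clade
    profiles = [call_variants(sequences[sid], ref, sample_id=sid)
                for sid in sorted(sequences)]
    truth = SimTruth(
        seed=cfg.seed,
        genealogy_mode=cfg.genealogy,
        sample_haplogroup=sample_hg,
        clade_age_ky={h: float(cfg.clade_age_ky[h]) for h in cfg.haplogroup_mix},
        branch_mutation_counts=branch_counts,
        genealogy_newick=newicks,
        variant_labels={p.sample_id: list(p.labels) for p in profiles},
    )
    return SimulatedDataset(config=cfg, sequences=sequences, profiles=profiles,
                            truth=truth, trees=trees)
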