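# bovmt

Analysis toolkit for complete cattle (*Bos taurus*) mitochondrial genomes:
variant profiling against the bovine reference sequence, haplogroup
classification from diagnostic motifs, mutation-annotated parsimony
phylogenies, clade dating with the ρ statistic and clock-constrained maximum
likelihood, and diversity statistics — plus a fully deterministic simulator
so every stage can be validated against known truth without any downloads.

It is written for population geneticists working on mtDNA phylogeography:
the kind of study that sequences a few dozen mitogenomes from a breed or
region, places them in the taurine haplogroup phylogeny (P, Q, R and
macro-haplogroup T with T1–T5), and asks when each clade coalesced and how
diverse the sample is.

## The statistics at the core

All variants are expressed in the field's shorthand against the 16,338-bp
bovine reference (1-based "np" coordinates): `16049` is a transition,
`15953G` a transversion to G, `364+G` an insertion, `100d` a deletion, a
trailing `h` heteroplasmy, and `@` a reversion to the reference allele.

* **ρ dating.** For a clade with a mutation-annotated genealogy, where
  branch *b* carries *l<sub>b</sub>* mutations and subtends *n<sub>b</sub>*
  of the *n* haplotypes,

  ρ = Σ<sub>b</sub> l<sub>b</sub>·n<sub>b</sub> / n (the mean mutational
  distance of haplotypes from the clade root), with the heuristic standard
  error σ = √(Σ<sub>b</sub> l<sub>b</sub>·n<sub>b</sub>²) / n.

* **ML dating.** Clock-constrained (equal root-to-tip height) maximum
  likelihood under HKY85 with gamma-distributed site rates approximated by
  32 equal-probability discrete categories, computed with Felsenstein's
  pruning algorithm on the coding region (np 364–15791, 15,428 sites).
  The reported divergence is per-site root height × region length; its SE
  comes from the curvature of the log-likelihood.

* **Clock.** Mutational divergences convert to ages as
  T = divergence × 3,172 years (one coding-region mutation per 3,172 years).

* **Diversity.** Nei's unbiased haplotype diversity
  H = n/(n−1)·(1 − Σp<sub>i</sub>²) with its standard sampling variance,
  and mean pairwise differences M within haplogroups.

Mutations are counted after excluding the hypervariable sites (the np 364 G
insertion and tract-length variation scored at np 221 and np 1600) and, for
dating, restricted to coding-region substitutions with heteroplasmies
excluded.

## Worked example

Simulate the default study composition (31 mitogenomes, T1:18 / T2:6 / T3:5 /
Q1:2, star genealogies), re-call the variants, classify and summarize:

```bash
python examples/05_diversity.py
```

prints

```
n = 31
H = 1.0 +/- 0.008 (Nei gene diversity)
  Q1: N = 2, 6.5%, M = 18.0
  T1: N = 18, 58.1%, M = 10.9
  T2: N = 6, 19.4%, M = 11.0
  T3: N = 5, 16.1%, M = 10.8
```

— every simulated haplotype is distinct (H = 1 with Nei SE 0.008, the
hallmark of a star-like expansion at these clade depths), the frequencies
follow the 18/6/5/2 composition, and M is the mean number of pairwise
nucleotide differences within each haplogroup. Dating the same kind of clade
(`python examples/04_clade_dating.py`) prints a ρ and ML age table row for a
star clade simulated at 17.64 ky, e.g. `rho = 6.00, sigma = 0.87 → T = 19.03
+/- 2.75 ky`, recovering the true age within its uncertainty.

The other examples cover variant notation and calling (`01`), motif
classification (`02`), parsimony trees with recurrence/back-mutation
annotation (`03`), and the full truth-manifest round trip (`06`). Datasets
can also be generated from the shell:

```bash
bovmt simulate --seed 5 --out simdata/
```

## Layout

* `src/bovmt/variants.py` — notation, calling, filtering, FASTA/TSV IO
* `src/bovmt/classify.py` — motif config and haplogroup assignment
* `src/bovmt/phylo.py` — greedy parsimony trees, recurrence annotation,
  shared/private mutation analysis, newick export
* `src/bovmt/dating.py` — ρ/σ, HKY85+Γ pruning ML, clock conversion, age table
* `src/bovmt/diversity.py` — H ± SE, M, haplogroup frequencies
* `src/bovmt/simulate.py` — star/coalescent simulator with truth manifest
* `docs/methods.md` — models, assumptions, parameter choices and limitations
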